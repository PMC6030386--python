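"""Synthetic microbiome data with phylogenetically clustered outcome signal.

The generator emulates a 16S-style study: a random phylogeny over ``p``
OTUs, Dirichlet-multinomial (DM) counts with negative-binomial library
sizes, and an outcome driven by the cumulative abundance of a few
outcome-associated OTU clusters ("aClusters") carved out of the tree by
partitioning-around-medoids (PAM) on the patristic distances.

Study conditions (defaults follow the simulation design the package is
tested under):

* library sizes ~ NegBin(mean 5000, size 25);
* OTUs grouped into ``m`` PAM clusters; ``m_c = floor(m * s%)`` aClusters
  chosen at a low/medium/high cumulative-abundance level out of 1000
  random draws;
* one shared coefficient ``b_l ~ N(0, sigma_b^2)`` per aCluster
  (``sigma_b^2``: 2 continuous, 4 binary), linear predictor
  ``eta_i = beta_0 + sum_l b_l * sum_{k in C_l} f(z_ik)``;
* continuous outcome ``y = eta + eps`` with residual variance set so that
  the OTU signal explains 80% of outcome variability
  (``sigma_e^2 = var(signal)/4``); binary outcome ~ Bernoulli(logistic(eta));
* optional non-linear signal transforms (square root, presence/absence)
  and "noisy tree" row/column permutations of the distance matrix.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .kernel import power_transform
from .tree import PhyloDistances

#: Signal-density percentages (low, medium, high) keyed by cluster count;
#: the ``None`` row applies to singleton clustering (m == p).
SIGNAL_DENSITY_PCT = {
    10: {"low": 10.0, "medium": 20.0, "high": 40.0},
    100: {"low": 1.0, "medium": 5.0, "high": 25.0},
    None: {"low": 1.0, "medium": 5.0, "high": 30.0},
}


def signal_density_pct(m: int, level: str, p: int | None = None) -> float:
    """Conventional s% for a density level given the cluster count."""
    key = m if m in SIGNAL_DENSITY_PCT and (p is None or m != p) else None
    return SIGNAL_DENSITY_PCT[key][level]


@dataclass
class DmParams:
    """Dirichlet-multinomial parameters plus the library-size law.

    ``phi`` in (0, 1) is the DM overdispersion: the Dirichlet concentration
    is ``alpha = mean_proportions * (1 - phi) / phi``.
    """

    mean_proportions: np.ndarray
    phi: float = 0.02
    library_mean: float = 5000.0
    library_size_param: float = 25.0

    def __post_init__(self) -> None:
        pi = np.asarray(self.mean_proportions, dtype=float).ravel()
        if np.any(pi < 0) or not np.isclose(pi.sum(), 1.0, atol=1e-8):
            raise ValueError("mean proportions must be a simplex vector")
        if not (0 < self.phi < 1):
            raise ValueError("phi must be in (0, 1)")
        self.mean_proportions = pi / pi.sum()

    @property
    def n_taxa(self) -> int:
        return len(self.mean_proportions)

    @classmethod
    def default(cls, p: int, sigma: float = 2.0, phi: float = 0.02) -> "DmParams":
        """Ranked log-normal mean proportions (heavy-tailed, microbiome-like)."""
        from scipy.stats import norm

        q = norm.ppf((np.arange(p) + 0.5) / p)
        props = np.exp(sigma * q)[::-1]
        return cls(mean_proportions=props / props.sum(), phi=phi)


@dataclass
class SimulationDesign:
    """One cell of the simulation grid."""

    m: int = 10
    signal_density_pct: float = 10.0
    abundance_level: str = "high"  # low | medium | high
    outcome_type: str = "continuous"  # continuous | binary
    signal_transform: str = "identity"  # identity | sqrt | presence
    sigma_b2: float | None = None  # default: 2 continuous, 4 binary
    explained_variance: float = 0.8  # fraction of outcome variance from OTUs
    beta0: float = 0.0
    tree_permute_pct: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.signal_density_pct <= 100):
            raise ValueError("signal density must be in (0, 100]")
        if self.abundance_level not in ("low", "medium", "high"):
            raise ValueError("abundance_level must be low|medium|high")
        if self.outcome_type not in ("continuous", "binary"):
            raise ValueError("outcome_type must be continuous|binary")
        if self.signal_transform not in ("identity", "sqrt", "presence"):
            raise ValueError("signal_transform must be identity|sqrt|presence")
        if not (0 < self.explained_variance < 1):
            raise ValueError("explained_variance must be in (0, 1)")
        if self.sigma_b2 is None:
            self.sigma_b2 = 2.0 if self.outcome_type == "continuous" else 4.0

    @property
    def n_aclusters(self) -> int:
        return max(int(self.m * self.signal_density_pct / 100.0), 1)


@dataclass
class SimulatedDataset:
    dist: PhyloDistances
    newick: str
    counts: np.ndarray = field(repr=False)  # samples x OTUs
    proportions: np.ndarray = field(repr=False)
    outcome: np.ndarray = field(repr=False)
    eta: np.ndarray = field(repr=False)
    beta0: float = 0.0
    coefficients: np.ndarray = field(default=None, repr=False)  # one per aCluster
    acluster_members: list = field(default_factory=list)
    sigma_e2: float = 0.0
    design: SimulationDesign | None = None


# ---------------------------------------------------------------------------
# trees


def random_tree(p: int, seed: int = 0) -> tuple[PhyloDistances, str]:
    """Pure-birth (Yule) tree over ``p`` tips; deterministic per seed."""
    if p < 2:
        raise ValueError("need at least 2 tips")
    rng = _pyrandom.Random(int(seed))
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=p, rng=rng
    )
    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    return PhyloDistances.from_newick(newick), newick


def permute_tree(dist: PhyloDistances, pct: float, seed: int = 0) -> PhyloDistances:
    """Noisy tree: symmetrically permute rows/columns for pct% of the tips."""
    if not (0 <= pct <= 100):
        raise ValueError("pct must be in [0, 100]")
    p = dist.n_tips
    k = int(np.ceil(pct * p / 100.0))
    if k <= 1:
        return PhyloDistances(list(dist.tip_labels), dist.D.copy())
    rng = np.random.default_rng(seed)
    chosen = rng.choice(p, size=k, replace=False)
    perm = rng.permutation(k)
    idx = np.arange(p)
    idx[chosen] = chosen[perm]
    return PhyloDistances(list(dist.tip_labels), dist.D[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# Dirichlet-multinomial counts


def sample_library_sizes(dm: DmParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial library sizes; zero draws are redrawn."""
    size = dm.library_size_param
    prob = size / (size + dm.library_mean)
    lib = rng.negative_binomial(size, prob, size=n)
    for _ in range(100):
        zero = lib == 0
        if not zero.any():
            break
        lib[zero] = rng.negative_binomial(size, prob, size=int(zero.sum()))
    return lib.astype(np.int64)


def simulate_counts(
    dm: DmParams, n: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """DM counts and proportions for ``n`` samples (samples x taxa)."""
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    alpha = dm.mean_proportions * (1.0 - dm.phi) / dm.phi
    lib = sample_library_sizes(dm, n, rng)
    probs = rng.dirichlet(alpha, size=n)
    counts = np.empty((n, dm.n_taxa), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(lib[i], probs[i])
    z = counts / lib[:, None]
    return counts, z


def estimate_dm(counts: np.ndarray) -> DmParams:
    """Method-of-moments DM estimate from a (samples x taxa) count table.

    The per-taxon variance of the observed proportions satisfies
    ``Var(z_j) = pi_j (1 - pi_j) (phi + (1 - phi)/N)`` at library size N;
    phi is recovered by a pi(1-pi)-weighted average over taxa.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    n, p = counts.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    lib = counts.sum(axis=1)
    if np.any(lib <= 0):
        raise ValueError("every sample needs a positive total count")
    z = counts / lib[:, None]
    pi = z.mean(axis=0)
    if np.count_nonzero(pi) < 2:
        raise ValueError("need at least two taxa with nonzero abundance")
    v = z.var(axis=0, ddof=1)
    w = pi * (1.0 - pi)
    nbar = float(np.mean(lib))
    mask = w > 0
    # phi + (1-phi)/N = sum(v) / sum(w)  under the weighting by w
    ratio = float(v[mask].sum() / w[mask].sum())
    phi = (ratio - 1.0 / nbar) / (1.0 - 1.0 / nbar)
    phi = float(np.clip(phi, 1e-6, 1.0 - 1e-6))
    return DmParams(
        mean_proportions=pi / pi.sum(),
        phi=phi,
        library_mean=nbar,
    )


# ---------------------------------------------------------------------------
# PAM clustering on the patristic distances


def pam_clusters(dist: PhyloDistances, m: int, max_iter: int = 100) -> list[np.ndarray]:
    """Classic PAM (BUILD + SWAP) on the precomputed distance matrix.

    Returns ``m`` disjoint index arrays covering all OTUs.  The algorithm
    is deterministic: BUILD greedily seeds the medoids and SWAP applies
    the best improving (medoid, candidate) exchange until none remains.
    """
    p = dist.n_tips
    if not (1 <= m <= p):
        raise ValueError("m must be in [1, p]")
    if m == p:
        return [np.array([i]) for i in range(p)]
    D = dist.D

    # BUILD
    medoids = [int(np.argmin(D.sum(axis=0)))]
    dnear = D[:, medoids[0]].copy()
    while len(medoids) < m:
        gains = np.maximum(dnear[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        c = int(np.argmax(gains))
        medoids.append(c)
        dnear = np.minimum(dnear, D[:, c])

    medoids = np.array(medoids)

    def nearest_two(meds):
        sub = D[:, meds]
        order = np.argsort(sub, axis=1, kind="stable")
        near = order[:, 0]
        d1 = sub[np.arange(p), near]
        d2 = sub[np.arange(p), order[:, 1]] if len(meds) > 1 else np.full(p, np.inf)
        return near, d1, d2

    for _ in range(max_iter):
        near, d1, d2 = nearest_two(medoids)
        best_delta, best_swap = -1e-12, None
        is_medoid = np.zeros(p, bool)
        is_medoid[medoids] = True
        for mi, med in enumerate(medoids):
            mine = near == mi
            # cost change of replacing `med` by each candidate column h
            t_mine = (np.minimum(d2[mine, None], D[mine, :]) - d1[mine, None]).sum(0)
            t_rest = np.minimum(D[~mine, :] - d1[~mine, None], 0.0).sum(0)
            delta = t_mine + t_rest  # negative = improvement
            delta[is_medoid] = np.inf
            h = int(np.argmin(delta))
            if delta[h] < best_delta:
                best_delta, best_swap = float(delta[h]), (mi, h)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]

    near, _, _ = nearest_two(medoids)
    return [np.flatnonzero(near == i) for i in range(m)]


def select_aclusters(
    clusters: list[np.ndarray],
    proportions: np.ndarray,
    m_c: int,
    abundance_level: str,
    seed: int = 0,
    n_draws: int = 1000,
) -> list[int]:
    """Pick ``m_c`` aClusters at a target cumulative-abundance level.

    Draw ``m_c`` of the ``m`` clusters ``n_draws`` times; return the draw
    with the maximal (high), median (medium) or minimal (low) cumulative
    mean abundance.
    """
    m = len(clusters)
    if not (1 <= m_c <= m):
        raise ValueError("m_c must be in [1, m]")
    z = np.atleast_2d(np.asarray(proportions, dtype=float))
    cluster_ab = np.array([z[:, c].sum(axis=1).mean() for c in clusters])
    if m_c == m:
        return list(range(m))
    rng = np.random.default_rng(seed)
    draws = [rng.choice(m, size=m_c, replace=False) for _ in range(n_draws)]
    totals = np.array([cluster_ab[d].sum() for d in draws])
    order = np.argsort(totals, kind="stable")
    if abundance_level == "high":
        pick = order[-1]
    elif abundance_level == "low":
        pick = order[0]
    else:
        pick = order[len(order) // 2]
    return sorted(int(i) for i in draws[pick])


# ---------------------------------------------------------------------------
# outcomes


_TRANSFORMS = {
    "identity": lambda z: z,
    "sqrt": lambda z: power_transform(z, 0.5),
    "presence": lambda z: power_transform(z, 0.0),
}


def generate_outcome(
    z: np.ndarray,
    acluster_members: list[np.ndarray],
    design: SimulationDesign,
    seed: int = 0,
):
    """Outcome vector plus ground truth from aCluster abundances.

    Returns ``(y, eta, coefficients, sigma_e2)``.  The residual variance
    of a continuous outcome is set from the empirical variance of the
    aggregate OTU signal so that the signal explains the designed fraction
    of outcome variability (default 80%).
    """
    if len(acluster_members) == 0:
        raise ValueError("need at least one aCluster")
    z = np.atleast_2d(np.asarray(z, dtype=float))
    f = _TRANSFORMS[design.signal_transform]
    fz = f(z)
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, np.sqrt(design.sigma_b2), size=len(acluster_members))
    signal = np.zeros(z.shape[0])
    for bl, members in zip(b, acluster_members):
        signal += fz[:, np.asarray(members)].sum(axis=1) * bl
    eta = design.beta0 + signal
    if design.outcome_type == "continuous":
        v = design.explained_variance
        sigma_e2 = float(np.var(signal)) * (1.0 - v) / v
        y = eta + rng.normal(0.0, np.sqrt(sigma_e2), size=len(eta))
        return y, eta, b, sigma_e2
    pi = 1.0 / (1.0 + np.exp(-eta))
    y = rng.binomial(1, pi).astype(float)
    return y, eta, b, 0.0


def simulate_dataset(
    design: SimulationDesign,
    n: int,
    p: int = 778,
    dm: DmParams | None = None,
    dist: PhyloDistances | None = None,
    newick: str = "",
) -> SimulatedDataset:
    """End-to-end draw of one dataset under a simulation design.

    The single ``design.seed`` drives the tree, the counts, the cluster
    selection and the outcome (via distinct sub-streams).
    """
    seed = int(design.seed)
    ss = np.random.SeedSequence(seed).spawn(4)
    sub = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss]
    if dist is None:
        dist, newick = random_tree(p, seed=sub[0])
    p = dist.n_tips
    dm = dm or DmParams.default(p)
    if dm.n_taxa != p:
        raise ValueError("DM parameter dimension does not match the tree")
    counts, z = simulate_counts(dm, n, seed=sub[1])
    clusters = pam_clusters(dist, design.m)
    chosen = select_aclusters(
        clusters, z, design.n_aclusters, design.abundance_level, seed=sub[2]
    )
    members = [clusters[i] for i in chosen]
    y, eta, b, sigma_e2 = generate_outcome(z, members, design, seed=sub[3])
    # the outcome is generated from the true tree; the analyst sees the
    # (optionally) permuted, "noisy" distance matrix
    analysis_dist = (
        permute_tree(dist, design.tree_permute_pct, seed=sub[0])
        if design.tree_permute_pct > 0
        else dist
    )
    return SimulatedDataset(
        dist=analysis_dist,
        newick=newick,
        counts=counts,
        proportions=z,
        outcome=y,
        eta=eta,
        beta0=design.beta0,
        coefficients=b,
        acluster_members=members,
        sigma_e2=sigma_e2,
        design=design,
    )
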