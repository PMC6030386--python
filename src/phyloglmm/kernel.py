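"""Phylogeny-induced correlation among OTU effects and the sample kernel.

Under a Brownian/Ornstein-Uhlenbeck style trait-evolution model, the
correlation between the effects of OTU *i* and OTU *j* decays with their
patristic distance ``d_ij``::

    C_ij(rho) = exp(-2 * rho * d_ij)        (plain distance)
    C_ij(rho) = exp(-2 * rho * d_ij**2)     (squared distance, the default)

``rho >= 0`` acts as an evolutionary-rate / phylogenetic-depth parameter:
``rho = 0`` makes all OTU effects identical (C is the all-ones matrix) while
``rho -> inf`` decorrelates them completely (C -> I, the tree carries no
information).  The squared-distance form groups signal more sharply and is
the default; it is not guaranteed positive definite, so an eigenvalue
clipping correction is applied when needed.

Sample-level similarity is measured by the kernel

    K(z_i, z_j; gamma, rho) = f(z_i; gamma)^T C(rho) f(z_j; gamma)

where ``f(z; gamma)`` is the elementwise power transform ``z**gamma`` with
zeros kept at zero.  Small ``gamma`` up-weights rare taxa; ``gamma = 0``
reduces abundances to presence/absence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .tree import PhyloDistances

#: Relative eigenvalue floor used both to detect indefiniteness and as the
#: clipping level of the positive-definiteness correction.
PD_FLOOR = 1e-10


@dataclass(frozen=True)
class KernelSpec:
    """Tuning state defining the transform f and the correlation C.

    Parameters
    ----------
    rho
        Evolutionary-rate parameter, ``>= 0``.  ``numpy.inf`` is accepted as
        a sentinel and maps to the identity correlation exactly.
    gamma
        Power-transform exponent, ``>= 0``.
    squared_distance
        Use ``d**2`` (default) rather than ``d`` in the exponent.
    """

    rho: float = 1.0
    gamma: float = 1.0
    squared_distance: bool = True

    def __post_init__(self) -> None:
        if not (self.rho >= 0):
            raise ValueError("rho must be >= 0")
        if not np.isfinite(self.gamma) or self.gamma < 0:
            raise ValueError("gamma must be finite and >= 0")


@dataclass
class CorrelationMatrix:
    C: np.ndarray
    pd_corrected: bool = False


def correlation_matrix(dist: PhyloDistances, spec: KernelSpec) -> CorrelationMatrix:
    """Build ``C(rho)`` from patristic distances.

    The diagonal is exactly 1.  If the smallest eigenvalue falls below
    ``-PD_FLOOR * lambda_max`` (possible with the squared-distance form),
    eigenvalues below ``PD_FLOOR * lambda_max`` are clipped to that floor,
    the matrix is reconstructed and its diagonal re-normalized to 1.
    """
    D = dist.D
    if np.isinf(spec.rho):
        return CorrelationMatrix(np.eye(dist.n_tips), pd_corrected=False)
    d = D * D if spec.squared_distance else D
    with np.errstate(under="ignore"):
        C = np.exp(-2.0 * spec.rho * d)
    np.fill_diagonal(C, 1.0)
    eigvals = np.linalg.eigvalsh(C)
    lam_max = max(eigvals[-1], 1.0)
    if eigvals[0] < -PD_FLOOR * lam_max:
        C = _clip_to_psd(C, lam_max)
        return CorrelationMatrix(C, pd_corrected=True)
    return CorrelationMatrix(C, pd_corrected=False)


def _clip_to_psd(C: np.ndarray, lam_max: float) -> np.ndarray:
    lam, V = np.linalg.eigh(C)
    floor = PD_FLOOR * lam_max
    lam = np.maximum(lam, floor)
    C = (V * lam) @ V.T
    # re-normalize to unit diagonal, keep exact symmetry
    s = 1.0 / np.sqrt(np.diag(C))
    C = C * s[:, None] * s[None, :]
    C = 0.5 * (C + C.T)
    np.fill_diagonal(C, 1.0)
    return np.clip(C, 0.0, 1.0)


def power_transform(z: np.ndarray, gamma: float) -> np.ndarray:
    """Elementwise ``z**gamma`` with zeros mapped to exactly zero.

    At ``gamma = 0`` this is the presence/absence indicator.  Input must be
    proportions (or any non-negative abundances); negative entries raise.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("abundances must be non-negative")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    if gamma == 1.0:
        return z.copy()
    out = np.zeros_like(z)
    nz = z != 0
    if gamma == 0.0:
        out[nz] = 1.0
    else:
        out[nz] = z[nz] ** gamma
    return out


def kernel(
    z_a: np.ndarray,
    z_b: np.ndarray,
    dist: PhyloDistances,
    spec: KernelSpec,
    C: np.ndarray | None = None,
) -> np.ndarray:
    """Sample-level kernel ``K = f(Z_a) C(rho) f(Z_b)^T``.

    ``z_a`` and ``z_b`` are (samples x OTUs) abundance matrices whose
    columns follow ``dist.tip_labels`` order.  When ``z_a is z_b`` the
    result is symmetric PSD up to the correction floor.  A precomputed
    correlation matrix ``C`` may be supplied to avoid rebuilding it.
    """
    z_a = np.atleast_2d(np.asarray(z_a, dtype=float))
    z_b = np.atleast_2d(np.asarray(z_b, dtype=float))
    p = dist.n_tips
    if z_a.shape[1] != p or z_b.shape[1] != p:
        raise ValueError(
            f"abundance matrices must have {p} columns matching the tree tips"
        )
    if C is None:
        C = correlation_matrix(dist, spec).C
    fa = power_transform(z_a, spec.gamma)
    fb = fa if z_b is z_a else power_transform(z_b, spec.gamma)
    K = fa @ C @ fb.T
    if z_b is z_a or fa.shape == fb.shape and np.array_equal(fa, fb):
        K = 0.5 * (K + K.T)
    return K


def check_psd(K: np.ndarray, rel_tol: float = 1e-8, warn: bool = True) -> np.ndarray:
    """Symmetrize and verify PSD-ness of a square kernel; clip if violated."""
    K = 0.5 * (K + np.asarray(K).T)
    lam = np.linalg.eigvalsh(K)
    lam_max = max(lam[-1], 1e-300)
    if lam[0] < -rel_tol * lam_max:
        if warn:
            warnings.warn(
                f"kernel matrix is not PSD (min eig {lam[0]:.3g}); "
                "clipping negative eigenvalues",
                RuntimeWarning,
                stacklevel=2,
            )
        lam_c, V = np.linalg.eigh(K)
        K = (V * np.maximum(lam_c, 0.0)) @ V.T
        K = 0.5 * (K + K.T)
    return K
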