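"""Population covariances and the marker-by-population interaction kernel.

Two constructions of the n x n population covariance Omega:

* mixture:  Omega = rho * A Theta A' + (1 - rho) * J, interpolating between
  one homogeneous population (rho = 0, Omega = all-ones) and cluster-specific
  relationships (rho = 1);
* Matern:   Omega_ij = kappa_{nu,h}(||p_i - p_j||), a Matern correlation of
  the Euclidean distance between PC coordinates, with shape nu and scale h.

The interaction kernel is the Hadamard product Omega o XX', positive
semidefinite whenever Omega and XX' are (Schur product theorem). With
Omega = J it collapses to the plain marker kernel XX' of standard GBLUP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special
from scipy.spatial.distance import pdist, squareform

from .geno_io import DosageMatrix
from .popstruct import AdmixtureMatrix

# above this shape the Matern correlation is numerically indistinguishable
# from its Gaussian limit exp(-d^2 / (2 h^2))
_GAUSSIAN_LIMIT_NU = 50.0


@dataclass(frozen=True)
class MaternParams:
    """Matern shape nu, scale h, and the reference distance d_max."""

    nu: float
    h: float
    d_max: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.nu) and self.nu > 0):
            raise ValueError(f"Matern shape nu={self.nu} must be finite positive")
        if not (np.isfinite(self.h) and self.h > 0):
            raise ValueError(f"Matern scale h={self.h} must be finite positive")
        if self.d_max is not None and not self.d_max > 0:
            raise ValueError(f"reference distance d_max={self.d_max} must be positive")

    @property
    def h_star(self) -> float | None:
        """Scale expressed as a fraction of the reference distance."""
        return None if self.d_max is None else self.h / self.d_max


@dataclass
class PopulationCovariance:
    """Omega: symmetric PSD covariance over population backgrounds."""

    omega: np.ndarray
    kind: str  # {"mixture", "matern", "ones"}

    @property
    def n(self) -> int:
        return self.omega.shape[0]


@dataclass
class InteractionKernel:
    """C = Omega o XX': covariance of genetic values under interaction."""

    C: np.ndarray
    kind: str


def matern_kappa(dist, params: MaternParams) -> np.ndarray | float:
    """Matern correlation kappa(d) = 2^(1-nu)/Gamma(nu) * x^nu * K_nu(x).

    The argument is x = sqrt(2 nu) d / h, so nu = 0.5 gives exp(-d/h)
    (exponential kernel) and nu -> infinity gives exp(-d^2/(2 h^2))
    (Gaussian kernel). Evaluated in log space; for nu above 50 the Gaussian
    limit is used directly. Returns 1 at d = 0 (continuity limit).
    """
    scalar_input = np.isscalar(dist) or np.ndim(dist) == 0
    d = np.atleast_1d(np.asarray(dist, dtype=float))
    if not np.isfinite(d).all() or (d < 0).any():
        raise ValueError("distances must be finite and nonnegative")
    nu, h = params.nu, params.h
    if nu > _GAUSSIAN_LIMIT_NU:
        out = np.exp(-0.5 * (d / h) ** 2)
        return float(out[0]) if scalar_input else out.reshape(np.shape(dist))

    x = np.sqrt(2.0 * nu) * d / h
    out = np.ones_like(x)
    pos = x > 0
    if pos.any():
        xp = x[pos]
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            log_kv = np.log(special.kve(nu, xp)) - xp
            log_kappa = (1.0 - nu) * np.log(2.0) - special.gammaln(nu) \
                + nu * np.log(xp) + log_kv
        val = np.exp(log_kappa)
        # kve overflows only for tiny x where kappa -> 1; kv underflow at
        # large x drives log_kappa -> -inf, i.e. kappa -> 0 — both safe.
        val = np.where(np.isnan(log_kappa) | (log_kappa > 0), 1.0, val)
        out[pos] = val
    return float(out[0]) if scalar_input else out.reshape(np.shape(dist))


def pc_distances(P_rows: np.ndarray) -> tuple[np.ndarray, float]:
    """Pairwise Euclidean distance matrix over PC coordinates and its max."""
    P_rows = np.atleast_2d(np.asarray(P_rows, dtype=float))
    if P_rows.shape[0] < 2:
        raise ValueError("pairwise distances require at least 2 individuals")
    D = squareform(pdist(P_rows))
    return D, float(D.max())


def omega_mixture(
    A: AdmixtureMatrix, rho: float, theta: np.ndarray | None = None
) -> PopulationCovariance:
    """Omega = rho * A Theta A' + (1 - rho) * J (Theta defaults to I_K)."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"mixture weight rho={rho} outside [0, 1]")
    coeff = A.coeff
    if theta is None:
        cluster_part = coeff @ coeff.T
    else:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (A.K, A.K):
            raise ValueError("Theta must be K x K")
        cluster_part = coeff @ theta @ coeff.T
    n = coeff.shape[0]
    omega = rho * cluster_part + (1.0 - rho) * np.ones((n, n))
    return PopulationCovariance(omega=(omega + omega.T) / 2.0, kind="mixture")


def omega_matern(P_rows: np.ndarray, params: MaternParams) -> PopulationCovariance:
    """Omega_ij = kappa_{nu,h}(||p_i - p_j||); unit diagonal by construction."""
    D, _ = pc_distances(P_rows)
    omega = matern_kappa(D, params)
    np.fill_diagonal(omega, 1.0)
    return PopulationCovariance(omega=(omega + omega.T) / 2.0, kind="matern")


def omega_ones(n: int) -> PopulationCovariance:
    """The homogeneous-population covariance J (standard GBLUP)."""
    return PopulationCovariance(omega=np.ones((n, n)), kind="ones")


def marker_kernel(D: DosageMatrix, center: bool = True) -> np.ndarray:
    """XX' on dosages, optionally column-centered by 2 * pi_hat.

    Centering leaves predictions invariant when an intercept is present and
    improves conditioning; the uncentered product is available for literal
    replication of the raw-dosage form.
    """
    X = D.values
    if np.isnan(X).any():
        raise ValueError("dosages contain missing values; impute first")
    if center:
        X = X - X.mean(axis=0)
    return X @ X.T


def interaction_covariance(
    omega: PopulationCovariance, D: DosageMatrix, center: bool = True
) -> InteractionKernel:
    """C = Omega o XX' (Hadamard); collapses to XX' when Omega = J."""
    K = marker_kernel(D, center=center)
    if omega.omega.shape != K.shape:
        raise ValueError(
            f"Omega is {omega.omega.shape} but the marker kernel is {K.shape}"
        )
    if omega.kind == "ones":
        C = K.copy()  # bit-identical collapse to standard GBLUP
    else:
        C = omega.omega * K
    return InteractionKernel(C=(C + C.T) / 2.0, kind=omega.kind)
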