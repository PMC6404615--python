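"""REML estimation and BLUP prediction for the single-kernel mixed model

    y = Q alpha + u + e,   u ~ N(0, C sigma2_u),   e ~ N(0, I sigma2_e),

where C is a marker-derived (possibly interaction) covariance. The restricted
likelihood is profiled over the variance ratio lambda = sigma2_e / sigma2_u
after one eigendecomposition of C: rotating y and Q by the eigenvectors makes
every evaluation along the profile O(n p^2), so hyperparameter searches that
refit the model many times stay cheap.

The restricted log-likelihood convention includes the -((n-p)/2) log(2 pi)
constant and the +0.5 log|Q'Q| term (Patterson-Thompson form), so values are
comparable across kernels on the same y and Q; likelihood-ratio statistics
are free of the constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .geno_io import SampleMetadata
from .popstruct import PCScores

_RATIO_GRID = np.logspace(-5, 5, 64)
_JITTER = 1e-8


class NonIdentifiableWarning(UserWarning):
    """The kernel is numerically proportional to the identity."""


@dataclass
class MeanStructure:
    """Fixed-effect design matrix Q with a named construction."""

    Q: np.ndarray
    kind: str
    names: list[str] = field(default_factory=list)

    @property
    def p(self) -> int:
        return self.Q.shape[1]


def build_mean_structure(
    kind: str,
    n: int | None = None,
    meta: SampleMetadata | None = None,
    P: PCScores | None = None,
) -> MeanStructure:
    """Construct Q for one of the four mean structures.

    * ``intercept``: a single column of ones;
    * ``pca``: [1 P], ones plus the d PC score columns;
    * ``panel``: one-hot panel membership (no intercept column);
    * ``group``: one-hot population-group membership (no intercept column).
    """
    kind = kind.lower()
    if kind == "intercept":
        if n is None:
            n = len(meta.population) if meta is not None else P.scores.shape[0]
        Q, names = np.ones((n, 1)), ["intercept"]
    elif kind == "pca":
        if P is None:
            raise ValueError("PCA mean structure requires PC scores")
        Q = np.column_stack([np.ones(P.scores.shape[0]), P.scores])
        names = ["intercept"] + [f"PC{k + 1}" for k in range(P.d)]
    elif kind == "panel":
        if meta is None or meta.panel is None:
            raise ValueError("panel mean structure requires panel labels")
        dummies = pd.get_dummies(meta.panel)
        Q, names = dummies.to_numpy(dtype=float), [str(c) for c in dummies.columns]
    elif kind == "group":
        if meta is None:
            raise ValueError("group mean structure requires population labels")
        dummies = pd.get_dummies(meta.population)
        Q, names = dummies.to_numpy(dtype=float), [str(c) for c in dummies.columns]
    else:
        raise ValueError(f"unknown mean structure {kind!r}")
    rank = np.linalg.matrix_rank(Q)
    if rank < Q.shape[1]:
        raise ValueError(
            f"mean structure {kind!r} is rank-deficient (rank {rank} < {Q.shape[1]} "
            f"columns: {names})"
        )
    return MeanStructure(Q=Q, kind=kind, names=names)


@dataclass
class MixedModelFit:
    """REML solution for one kernel: variances, fixed effects, BLUPs."""

    alpha_hat: np.ndarray
    sigma2_u: float
    sigma2_e: float
    reml_loglik: float
    blups: np.ndarray
    kernel_ref: str
    y: np.ndarray
    Q: np.ndarray
    jitter_applied: bool = False

    @property
    def ratio(self) -> float:
        """Variance ratio sigma2_e / sigma2_u (inf when sigma2_u = 0)."""
        return self.sigma2_e / self.sigma2_u if self.sigma2_u > 0 else np.inf

    def summary(self) -> dict[str, float]:
        return {
            "sigma2_u": self.sigma2_u,
            "sigma2_e": self.sigma2_e,
            "ratio": self.ratio,
            "reml_loglik": self.reml_loglik,
        }


def _profile_loglik(lam: float, d: np.ndarray, ytil: np.ndarray, Qtil: np.ndarray,
                    logdet_QtQ: float) -> tuple[float, float, np.ndarray]:
    """Restricted loglik profiled at ratio lam; returns (ll, sigma2_u, alpha)."""
    n, p = Qtil.shape
    w = 1.0 / (d + lam)
    A = (Qtil * w[:, None]).T @ Qtil
    b = (Qtil * w[:, None]).T @ ytil
    try:
        cho = np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        return -np.inf, 0.0, np.zeros(p)
    alpha = np.linalg.solve(A, b)
    quad = float(ytil @ (w * ytil) - b @ alpha)
    if quad <= 0:
        return -np.inf, 0.0, alpha
    sigma2_u = quad / (n - p)
    logdet_A = 2.0 * float(np.sum(np.log(np.diag(cho))))
    ll = -0.5 * (
        (n - p) * np.log(2 * np.pi)
        + (n - p) * np.log(sigma2_u)
        + float(np.sum(np.log(d + lam)))
        + logdet_A
        + (n - p)
    ) + 0.5 * logdet_QtQ
    return ll, sigma2_u, alpha


def reml_fit(
    y: np.ndarray,
    Q: MeanStructure | np.ndarray,
    C: np.ndarray,
    kernel_ref: str = "kernel",
) -> MixedModelFit:
    """Fit the mixed model by eigen-profile REML.

    One eigendecomposition of C, then a log-spaced grid over the variance
    ratio followed by bounded scalar refinement. alpha_hat is the GLS
    solution at the optimum and the BLUPs are
    u_hat = sigma2_u C V^-1 (y - Q alpha_hat).
    """
    y = np.asarray(y, dtype=float)
    Qm = Q.Q if isinstance(Q, MeanStructure) else np.asarray(Q, dtype=float)
    n, p = Qm.shape
    if y.shape[0] != n:
        raise ValueError("y and Q have mismatched lengths")
    if n <= p:
        raise ValueError(f"need n > p (n={n}, p={p})")
    if np.ptp(y) == 0:
        raise ValueError("y is constant; variance components undefined")
    C = np.asarray(C, dtype=float)

    d, U = np.linalg.eigh((C + C.T) / 2.0)
    jitter_applied = False
    if d.min() < -1e-6 * max(1.0, abs(d.max())):
        raise ValueError(f"kernel has a substantially negative eigenvalue {d.min():.3g}")
    if d.min() < _JITTER:
        d = d + (_JITTER - min(d.min(), 0.0))
        jitter_applied = True
    if np.ptp(d) < 1e-8 * max(1.0, abs(d.mean())):
        warnings.warn(
            "kernel is numerically proportional to the identity; the variance "
            "ratio is not identifiable (flat profile)",
            NonIdentifiableWarning, stacklevel=2,
        )

    ytil = U.T @ y
    Qtil = U.T @ Qm
    sign, logdet_QtQ = np.linalg.slogdet(Qm.T @ Qm)

    scale = float(d.mean())
    grid = _RATIO_GRID * scale
    lls = np.array([_profile_loglik(lam, d, ytil, Qtil, logdet_QtQ)[0] for lam in grid])
    finite = np.isfinite(lls)
    if finite.sum() > 2:
        diffs = np.sign(np.diff(lls[finite]))
        n_maxima = int(((diffs[:-1] > 0) & (diffs[1:] < 0)).sum()) + (diffs[-1] > 0)
        if n_maxima > 1:
            warnings.warn(
                f"restricted-likelihood profile shows {n_maxima} local maxima "
                "over the ratio grid; reporting the global grid optimum",
                stacklevel=2,
            )
    k = int(np.argmax(lls))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda loglam: -_profile_loglik(np.exp(loglam), d, ytil, Qtil, logdet_QtQ)[0],
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    lam = float(np.exp(res.x))
    ll, sigma2_u, alpha = _profile_loglik(lam, d, ytil, Qtil, logdet_QtQ)
    if not np.isfinite(ll):
        raise RuntimeError("restricted likelihood non-finite at the optimum")

    rtil = ytil - Qtil @ alpha
    u = U @ (d / (d + lam) * rtil)
    return MixedModelFit(
        alpha_hat=alpha,
        sigma2_u=sigma2_u,
        sigma2_e=lam * sigma2_u,
        reml_loglik=ll,
        blups=u,
        kernel_ref=kernel_ref,
        y=y,
        Q=Qm,
        jitter_applied=jitter_applied,
    )


def reml_loglik_at(
    y: np.ndarray, Q: np.ndarray, C: np.ndarray, ratio: float
) -> float:
    """Profiled restricted loglik at a fixed variance ratio (for diagnostics)."""
    y = np.asarray(y, dtype=float)
    Q = np.asarray(Q, dtype=float)
    d, U = np.linalg.eigh((C + C.T) / 2.0)
    d = np.clip(d, 0.0, None) + _JITTER
    _, logdet_QtQ = np.linalg.slogdet(Q.T @ Q)
    return _profile_loglik(ratio, d, U.T @ y, U.T @ Q, logdet_QtQ)[0]


def predict_blup(
    fit: MixedModelFit,
    C_full: np.ndarray,
    Q_full: MeanStructure | np.ndarray,
    cs_index: np.ndarray,
    ts_index: np.ndarray,
) -> np.ndarray:
    """Predict testing-set outcomes from a calibration-set fit.

    y_hat_TS = Q_TS alpha_hat
             + C_{TS,CS} (C_{CS,CS} sigma2_u + I sigma2_e)^-1 sigma2_u (y_CS - Q_CS alpha_hat)
    """
    cs = np.asarray(cs_index)
    ts = np.asarray(ts_index)
    if np.intersect1d(cs, ts).size:
        raise ValueError("calibration and testing sets overlap")
    Qm = Q_full.Q if isinstance(Q_full, MeanStructure) else np.asarray(Q_full, dtype=float)
    mean_ts = Qm[ts] @ fit.alpha_hat
    if fit.sigma2_u <= 0:
        return mean_ts
    C_cs = C_full[np.ix_(cs, cs)]
    C_ts_cs = C_full[np.ix_(ts, cs)]
    V = fit.sigma2_u * C_cs + fit.sigma2_e * np.eye(len(cs))
    resid = fit.y - Qm[cs] @ fit.alpha_hat
    return mean_ts + C_ts_cs @ np.linalg.solve(V, fit.sigma2_u * resid)


def lrt(fit0: MixedModelFit, fit1: MixedModelFit, df: int) -> tuple[float, float]:
    """Likelihood-ratio test of a nested pair: -2 log(L0/L1) vs chi2(df).

    The statistic is floored at 0; a negative difference beyond tolerance
    indicates the larger model's optimizer failed and triggers a warning.
    """
    diff = fit1.reml_loglik - fit0.reml_loglik
    if diff < -1e-6:
        warnings.warn(
            f"extended model has lower restricted loglik by {-diff:.3g}; "
            "optimization may have failed",
            stacklevel=2,
        )
    statistic = max(0.0, 2.0 * diff)
    return statistic, float(stats.chi2.sf(statistic, df=df))


def bic(fit: MixedModelFit, k_params: int, n: int) -> float:
    """Bayesian information criterion -2 loglik + k log n."""
    return -2.0 * fit.reml_loglik + k_params * np.log(n)


def bic_compare(
    fit0: MixedModelFit, fit1: MixedModelFit, extra_params: int, n: int
) -> float:
    """Delta BIC of the extended model relative to the base (negative favors it)."""
    return float(-2.0 * (fit1.reml_loglik - fit0.reml_loglik) + extra_params * np.log(n))
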