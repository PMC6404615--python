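"""Estimation of population-covariance hyperparameters by REML, and the four
prediction procedures.

* ``fit_mpm_mixture`` maximizes the restricted likelihood over the mixture
  weight rho in [0, 1] (bounded 1-D search, tolerance 1e-4).
* ``fit_mpm_matern`` maximizes over (nu, h) by Nelder-Mead in log-parameters
  from four starting points (0.5, Dmax/2), (0.5, Dmax), (10, Dmax/2),
  (10, Dmax), where Dmax is the maximum pairwise PC distance in the
  calibration rows; the best converged start wins, ties prefer the smoother
  (larger-h) solution.
* ``procedure_dispatch`` runs GBLUP, GBLUP-Target, MPM-Mixture or MPM-Matern
  end-to-end on a calibration/testing split. Kernels are built on the full
  sample so prediction cross-blocks are consistent; hyperparameters are
  estimated on the calibration rows only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .geno_io import DosageMatrix, SampleMetadata
from .kernels import MaternParams, matern_kappa, marker_kernel, pc_distances
from .mixedmodel import MeanStructure, MixedModelFit, lrt, reml_fit
from .popstruct import AdmixtureMatrix

PROCEDURES = ("GBLUP", "GBLUP-Target", "MPM-Mixture", "MPM-Matern")


@dataclass
class MixtureFit:
    """MPM-Mixture REML solution: rho, inner mixed-model fit, LRT vs GBLUP."""

    rho_hat: float
    reml_loglik: float
    inner_fit: MixedModelFit
    lrt_vs_gblup: tuple[float, float]


@dataclass
class MaternFit:
    """MPM-Matern REML solution with the four-start search record."""

    params: MaternParams
    reml_loglik: float
    inner_fit: MixedModelFit
    starts: list[dict] = field(default_factory=list)

    @property
    def nu_hat(self) -> float:
        return self.params.nu

    @property
    def h_hat(self) -> float:
        return self.params.h


def fit_mpm_mixture(
    y: np.ndarray,
    Q: MeanStructure | np.ndarray,
    D: DosageMatrix,
    A: AdmixtureMatrix,
    center: bool = True,
    rho_tol: float = 1e-4,
) -> MixtureFit:
    """Estimate the mixture weight rho by bounded REML maximization.

    The interaction kernel is C(rho) = (rho AA' + (1-rho) J) o XX', linear
    in rho between the GBLUP kernel (rho=0) and the cluster-specific kernel
    (rho=1). A coarse grid brackets the optimum before bounded refinement;
    the GBLUP fit at rho=0 provides the 1-df likelihood-ratio test.
    """
    Qm = Q.Q if isinstance(Q, MeanStructure) else np.asarray(Q, dtype=float)
    M = marker_kernel(D, center=center)
    return fit_mpm_mixture_from_kernels(
        np.asarray(y, dtype=float), Qm, M, A.coeff @ A.coeff.T, rho_tol=rho_tol
    )


def fit_mpm_matern(
    y: np.ndarray,
    Q: MeanStructure | np.ndarray,
    D: DosageMatrix,
    P_rows: np.ndarray,
    center: bool = True,
    maxiter: int = 200,
) -> MaternFit:
    """Estimate (nu, h) by Nelder-Mead REML maximization from four starts.

    Optimization runs in (log nu, log h) so positivity is automatic. Dmax
    and the pairwise distances come from the rows supplied (the calibration
    set); extending Omega to new individuals later extrapolates through the
    fitted kappa.
    """
    Qm = Q.Q if isinstance(Q, MeanStructure) else np.asarray(Q, dtype=float)
    M = marker_kernel(D, center=center)
    return fit_mpm_matern_from_kernels(
        np.asarray(y, dtype=float), Qm, M, P_rows, maxiter=maxiter
    )


def fit_summary_table(fits: dict) -> "object":
    """Delimited summary of interaction fits: estimates, LRT statistic, p.

    ``fits`` maps a row label (e.g. trait name) to a MixtureFit or
    MaternFit; Matern rows require an accompanying GBLUP fit passed as a
    tuple (fit, gblup_fit) so the 2-df LRT can be formed.
    """
    import pandas as pd

    rows = []
    for label, entry in fits.items():
        if isinstance(entry, tuple):
            fit, base = entry
        else:
            fit, base = entry, None
        if isinstance(fit, MixtureFit):
            stat, p = fit.lrt_vs_gblup
            rows.append({"label": label, "procedure": "MPM-Mixture",
                         "rho": fit.rho_hat, "nu": np.nan, "h": np.nan,
                         "h_star": np.nan, "lrt": stat, "p": p})
        elif isinstance(fit, MaternFit):
            if base is None:
                stat = p = np.nan
            else:
                stat, p = lrt(base, fit.inner_fit, df=2)
            rows.append({"label": label, "procedure": "MPM-Matern",
                         "rho": np.nan, "nu": fit.nu_hat, "h": fit.h_hat,
                         "h_star": fit.params.h_star, "lrt": stat, "p": p})
        else:
            raise TypeError(f"unsupported fit type for {label!r}: {type(fit)}")
    return pd.DataFrame(rows)


@dataclass
class DataBundle:
    """Everything a prediction procedure needs on the full sample."""

    y: np.ndarray
    D: DosageMatrix
    meta: SampleMetadata
    A: AdmixtureMatrix | None = None
    P_scores: np.ndarray | None = None  # n x d PC coordinates
    Q: MeanStructure | np.ndarray | None = None  # defaults to intercept

    def mean_matrix(self) -> np.ndarray:
        if self.Q is None:
            return np.ones((len(self.y), 1))
        return self.Q.Q if isinstance(self.Q, MeanStructure) else np.asarray(self.Q)


def procedure_dispatch(
    name: str,
    bundle: DataBundle,
    cs_index: np.ndarray,
    ts_index: np.ndarray,
    scheme: str = "whole_sample",
    center: bool = True,
    fit_cache: dict | None = None,
) -> tuple[np.ndarray, dict]:
    """Run one named procedure on a CS/TS split; return TS predictions.

    Hyperparameters (rho, or nu/h with Dmax) are estimated on the calibration
    rows only; the full-sample kernel supplies the prediction cross-block.
    GBLUP-Target narrows the CS to the testing set's own population and is
    refused under cross-population calibration, where that intersection is
    empty by design.

    ``fit_cache`` (a mutable mapping owned by the caller) memoizes the fitted
    model per (procedure, calibration set): under cross-population validation
    every replicate shares the same calibration set, so the expensive
    hyperparameter search runs once and only the testing rows change.
    """
    from .mixedmodel import predict_blup  # local import avoids cycles

    cs = np.asarray(cs_index)
    ts = np.asarray(ts_index)
    y, D = bundle.y, bundle.D
    Qm = bundle.mean_matrix()
    info: dict = {"procedure": name}

    cache_key = (name, cs.tobytes()) if fit_cache is not None else None
    if cache_key is not None and cache_key in fit_cache:
        fit, C_full, info = fit_cache[cache_key]
        yhat = predict_blup(fit, C_full, Qm, np.asarray(info["cs_used"]), ts)
        return yhat, info

    if name == "GBLUP-Target":
        if scheme != "whole_sample":
            raise ValueError(
                "GBLUP-Target requires whole-sample calibration: under the "
                "cross-population scheme its calibration set would be empty"
            )
        pops = np.asarray(bundle.meta.population.values)
        target = pops[ts[0]]
        if not (pops[ts] == target).all():
            raise ValueError("testing set spans multiple populations")
        cs = cs[pops[cs] == target]
        info["cs_size_target"] = len(cs)
        name_inner = "GBLUP"
    else:
        name_inner = name

    if name_inner == "GBLUP":
        C_full = marker_kernel(D, center=center)
        fit = reml_fit(y[cs], Qm[cs], C_full[np.ix_(cs, cs)], kernel_ref="gblup")
        info["fit"] = fit.summary()
    elif name == "MPM-Mixture":
        if bundle.A is None:
            raise ValueError("MPM-Mixture requires an admixture matrix")
        # kernel centered on the full sample, then restricted, so the CS
        # blocks match the full-sample kernel used for prediction
        M = marker_kernel(D, center=center)
        AA = bundle.A.coeff @ bundle.A.coeff.T
        mix = fit_mpm_mixture_from_kernels(
            y[cs], Qm[cs], M[np.ix_(cs, cs)], AA[np.ix_(cs, cs)]
        )
        rho = mix.rho_hat
        C_full = (rho * AA + (1.0 - rho) * np.ones_like(AA)) * M
        fit = mix.inner_fit
        info.update({"rho_hat": rho, "lrt": mix.lrt_vs_gblup, "fit": fit.summary()})
    elif name == "MPM-Matern":
        if bundle.P_scores is None:
            raise ValueError("MPM-Matern requires PC coordinates")
        M = marker_kernel(D, center=center)
        mat = fit_mpm_matern_from_kernels(
            y[cs], Qm[cs], M[np.ix_(cs, cs)], bundle.P_scores[cs]
        )
        dist_full, _ = pc_distances(bundle.P_scores)
        omega_full = matern_kappa(dist_full, mat.params)
        np.fill_diagonal(omega_full, 1.0)
        C_full = omega_full * M
        fit = mat.inner_fit
        info.update(
            {
                "nu_hat": mat.nu_hat,
                "h_hat": mat.h_hat,
                "h_star": mat.params.h_star,
                "fit": fit.summary(),
            }
        )
    else:
        raise ValueError(f"unknown procedure {name!r}; expected one of {PROCEDURES}")

    info["cs_used"] = cs.tolist()
    if cache_key is not None:
        fit_cache[cache_key] = (fit, C_full, info)
    yhat = predict_blup(fit, C_full, Qm, cs, ts)
    return yhat, info


def fit_mpm_mixture_from_kernels(
    y: np.ndarray,
    Q: np.ndarray,
    M: np.ndarray,
    AA: np.ndarray,
    rho_tol: float = 1e-4,
) -> MixtureFit:
    """rho search on precomputed CS kernels (M = XX', AA = admixture gram)."""
    B = AA * M
    cache: dict[float, MixedModelFit] = {}

    def fit_at(rho: float) -> MixedModelFit:
        if rho not in cache:
            cache[rho] = reml_fit(
                y, Q, rho * B + (1 - rho) * M, kernel_ref=f"mixture(rho={rho:.6f})"
            )
        return cache[rho]

    grid = np.linspace(0.0, 1.0, 11)
    lls = [fit_at(r).reml_loglik for r in grid]
    k = int(np.argmax(lls))
    lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda r: -fit_at(float(r)).reml_loglik,
        bounds=(lo, hi), method="bounded", options={"xatol": rho_tol},
    )
    rho_hat = float(res.x)
    inner, fit0 = fit_at(rho_hat), fit_at(0.0)
    if inner.reml_loglik < fit0.reml_loglik:
        rho_hat, inner = 0.0, fit0
    return MixtureFit(
        rho_hat=rho_hat,
        reml_loglik=inner.reml_loglik,
        inner_fit=inner,
        lrt_vs_gblup=lrt(fit0, inner, df=1),
    )


def fit_mpm_matern_from_kernels(
    y: np.ndarray,
    Q: np.ndarray,
    M: np.ndarray,
    P_rows: np.ndarray,
    maxiter: int = 300,
) -> MaternFit:
    """(nu, h) search on a precomputed CS marker kernel.

    Besides the four Nelder-Mead starts, the smooth limit (h far beyond
    Dmax, where Omega approaches the all-ones matrix and the model collapses
    to GBLUP) is always evaluated as a candidate: it anchors the search when
    the data carry no population heterogeneity and guarantees the fit never
    reports a restricted likelihood below the nested GBLUP model.
    """
    from scipy.spatial.distance import pdist, squareform

    P_rows = np.atleast_2d(np.asarray(P_rows, dtype=float))
    condensed = pdist(P_rows)
    d_max = float(condensed.max())
    if d_max <= 0:
        raise ValueError("all PC coordinates identical: d_max = 0, Matern degenerate")
    # distance grid for fast kappa lookup inside the search; denser near 0
    # where the kernel bends hardest (the reported optimum is refit exactly)
    dgrid = (np.linspace(0.0, 1.0, 4096) ** 1.5) * d_max

    def omega_of(params: MaternParams, exact: bool) -> np.ndarray:
        if exact:
            kvals = matern_kappa(condensed, params)
        else:
            kvals = np.interp(condensed, dgrid, matern_kappa(dgrid, params))
        omega = squareform(kvals)
        np.fill_diagonal(omega, 1.0)
        return omega

    def objective(logparams: np.ndarray, exact: bool = False) -> float:
        with np.errstate(over="ignore"):
            nu, h = np.exp(np.asarray(logparams, dtype=float))
        if not (np.isfinite(nu) and np.isfinite(h)):
            return np.inf
        if not (1e-3 <= nu and h <= 1e10 * d_max):
            return np.inf  # degenerate ridge nu->0, h->inf
        params = MaternParams(nu=float(nu), h=float(h), d_max=d_max)
        try:
            C = omega_of(params, exact) * M
            return -reml_fit(y, Q, C, kernel_ref="matern").reml_loglik
        except (np.linalg.LinAlgError, RuntimeError, ValueError):
            return np.inf

    starts = [(0.5, d_max / 2), (0.5, d_max), (10.0, d_max / 2), (10.0, d_max)]
    records = []
    for nu0, h0 in starts:
        res = optimize.minimize(
            objective, x0=np.log([nu0, h0]), method="Nelder-Mead",
            options={"maxiter": maxiter, "fatol": 1e-3, "xatol": 5e-3},
        )
        nu, h = np.exp(res.x)
        records.append(
            {"start": (nu0, h0), "nu": float(nu), "h": float(h),
             "loglik": -float(res.fun),
             "converged": bool(res.success) and np.isfinite(res.fun),
             "n_evals": int(res.nfev)}
        )
    h_limit = 1e8 * d_max
    records.append(
        {"start": ("smooth-limit",), "nu": 0.5, "h": h_limit,
         "loglik": -objective(np.log([0.5, h_limit]), exact=True),
         "converged": True, "n_evals": 1}
    )
    converged = [r for r in records if np.isfinite(r["loglik"])]
    if not converged:
        raise RuntimeError(f"all Matern starts failed: {records}")
    best_ll = max(r["loglik"] for r in converged)
    best = max((r for r in converged if r["loglik"] >= best_ll - 1e-6),
               key=lambda r: r["h"])
    params = MaternParams(nu=best["nu"], h=best["h"], d_max=d_max)
    inner = reml_fit(y, Q, omega_of(params, exact=True) * M, kernel_ref="matern")
    return MaternFit(params=params, reml_loglik=inner.reml_loglik,
                     inner_fit=inner, starts=records)
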