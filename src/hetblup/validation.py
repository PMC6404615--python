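"""Cross-validation of prediction procedures and paired accuracy tests.

Two calibration schemes are supported for a named target population:

* whole-sample: the testing set (TS) is a random fifth of the target
  population; everyone else, including the rest of the target population,
  calibrates the model;
* cross-population: same TS, but the calibration set excludes the target
  population entirely.

Accuracy is the Pearson correlation between observed and predicted outcomes
in the TS. Procedures are compared pairwise on Fisher-transformed accuracies
delta = atanh(c_t) - atanh(c_0), with two standard errors for the mean:
liberal (replicates treated as independent, SD(delta)/sqrt(nrep)) and
conservative (inflated by the expected TS overlap o across replicates,
SD(delta) * sqrt(1/nrep + o/(1-o))). With o = 1/5 the conservative SE is
sqrt(6) times the liberal one at nrep = 20.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geno_io import SampleMetadata
from .mpm import DataBundle, procedure_dispatch


@dataclass(frozen=True)
class CVScheme:
    """Replication plan for one target population."""

    target_population: str
    scheme: str = "whole_sample"  # or "cross_population"
    nrep: int = 20
    ts_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("whole_sample", "cross_population"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if not 0.0 < self.ts_fraction < 1.0:
            raise ValueError("ts_fraction must lie in (0, 1)")
        if self.nrep < 2:
            raise ValueError("nrep must be at least 2")


@dataclass
class CVResult:
    """Per-replicate accuracies and predictions for each procedure."""

    accuracies: dict[str, np.ndarray]
    predictions: list[dict[str, np.ndarray]] = field(default_factory=list)
    splits: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    failures: dict[str, int] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        """Mean (SD) accuracy per procedure across replicates."""
        rows = []
        for name, acc in self.accuracies.items():
            ok = np.isfinite(acc)
            rows.append(
                {"procedure": name, "mean_accuracy": float(np.mean(acc[ok])),
                 "sd_accuracy": float(np.std(acc[ok], ddof=1)),
                 "n_replicates": int(ok.sum())}
            )
        return pd.DataFrame(rows)


@dataclass
class ComparisonResult:
    """Paired Fisher-z comparison of a procedure against a baseline."""

    procedure: str
    baseline: str
    delta_bar: float
    se_liberal: float
    se_conservative: float
    t_liberal: float
    t_conservative: float
    p_liberal: float
    p_conservative: float
    nrep: int


def make_splits(
    meta: SampleMetadata, scheme: CVScheme
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random CS/TS index pairs, one per replicate, reproducible under seed.

    The TS is floor(ts_fraction * target size) members of the target
    population drawn without replacement; replicates use independent
    substreams spawned from the master seed, so adding procedures or
    replicates never disturbs earlier splits.
    """
    pops = np.asarray(meta.population.values)
    target_idx = np.flatnonzero(pops == scheme.target_population)
    if target_idx.size == 0:
        raise ValueError(f"unknown target population {scheme.target_population!r}")
    if target_idx.size < 5:
        raise ValueError(
            f"target population {scheme.target_population!r} has fewer than 5 members"
        )
    ts_size = math.floor(scheme.ts_fraction * target_idx.size)
    all_idx = np.arange(len(pops))
    streams = np.random.SeedSequence(scheme.seed).spawn(scheme.nrep)
    splits = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        ts = np.sort(rng.choice(target_idx, size=ts_size, replace=False))
        if scheme.scheme == "whole_sample":
            cs = np.setdiff1d(all_idx, ts)
        else:
            cs = np.setdiff1d(all_idx, target_idx)
        splits.append((cs, ts))
    return splits


def accuracy(y_ts: np.ndarray, yhat_ts: np.ndarray) -> float:
    """Pearson correlation between observed and predicted TS outcomes.

    Returns NaN (replicate excluded from averaging) when either vector is
    constant, with a logged warning.
    """
    y_ts = np.asarray(y_ts, dtype=float)
    yhat_ts = np.asarray(yhat_ts, dtype=float)
    if y_ts.size < 3:
        raise ValueError("accuracy needs at least 3 testing individuals")
    if np.ptp(y_ts) == 0 or np.ptp(yhat_ts) == 0:
        warnings.warn("constant vector in accuracy computation; replicate excluded",
                      stacklevel=2)
        return np.nan
    return float(np.corrcoef(y_ts, yhat_ts)[0, 1])


def compare_procedures(
    c_t: np.ndarray, c_0: np.ndarray, o: float,
    procedure: str = "tested", baseline: str = "baseline",
) -> ComparisonResult:
    """Paired t-tests on Fisher-transformed accuracy differences.

    Replicates where either accuracy is undefined are excluded pairwise.
    Two-sided p-values with nrep - 1 degrees of freedom; the conservative
    variant inflates the SE by the overlap term o/(1-o).
    """
    c_t = np.asarray(c_t, dtype=float)
    c_0 = np.asarray(c_0, dtype=float)
    if c_t.shape != c_0.shape:
        raise ValueError("paired accuracy vectors differ in length")
    ok = np.isfinite(c_t) & np.isfinite(c_0)
    c_t, c_0 = c_t[ok], c_0[ok]
    nrep = c_t.size
    if nrep < 2:
        raise ValueError("fewer than 2 paired replicates")
    clip = 1.0 - 1e-12
    delta = np.arctanh(np.clip(c_t, -clip, clip)) - np.arctanh(np.clip(c_0, -clip, clip))
    delta_bar = float(delta.mean())
    sd = float(delta.std(ddof=1))
    se_lib = sd * math.sqrt(1.0 / nrep)
    se_cons = sd * math.sqrt(1.0 / nrep + o / (1.0 - o))
    if sd == 0.0:
        t_lib = t_cons = 0.0
        p_lib = p_cons = 1.0
    else:
        t_lib = delta_bar / se_lib
        t_cons = delta_bar / se_cons
        p_lib = float(2.0 * stats.t.sf(abs(t_lib), df=nrep - 1))
        p_cons = float(2.0 * stats.t.sf(abs(t_cons), df=nrep - 1))
    return ComparisonResult(
        procedure=procedure, baseline=baseline,
        delta_bar=delta_bar, se_liberal=se_lib, se_conservative=se_cons,
        t_liberal=t_lib, t_conservative=t_cons,
        p_liberal=p_lib, p_conservative=p_cons, nrep=nrep,
    )


def run_experiment(
    bundle: DataBundle,
    procedures: list[str],
    scheme: CVScheme,
    baseline: str | None = None,
) -> tuple[CVResult, list[ComparisonResult]]:
    """Cross-validate the named procedures under one scheme.

    Hyperparameters are re-estimated on each replicate's calibration set.
    Failing replicates are recorded (NaN accuracy) rather than silently
    dropped; comparisons exclude them pairwise. The overlap correction uses
    o = ts_fraction, the expected fraction of shared individuals between two
    random testing sets of that size.
    """
    splits = make_splits(bundle.meta, scheme)
    acc: dict[str, list[float]] = {name: [] for name in procedures}
    predictions: list[dict[str, np.ndarray]] = []
    failures: dict[str, int] = {name: 0 for name in procedures}
    fit_cache: dict = {}  # shared CS across replicates -> one fit
    for cs, ts in splits:
        per_rep: dict[str, np.ndarray] = {}
        for name in procedures:
            try:
                yhat, _ = procedure_dispatch(
                    name, bundle, cs, ts, scheme=scheme.scheme,
                    fit_cache=fit_cache,
                )
                per_rep[name] = yhat
                acc[name].append(accuracy(bundle.y[ts], yhat))
            except Exception as exc:  # noqa: BLE001 - recorded, not dropped
                warnings.warn(f"{name} failed on a replicate: {exc}", stacklevel=2)
                per_rep[name] = np.full(ts.size, np.nan)
                acc[name].append(np.nan)
                failures[name] += 1
        predictions.append(per_rep)
    result = CVResult(
        accuracies={k: np.asarray(v) for k, v in acc.items()},
        predictions=predictions,
        splits=splits,
        failures=failures,
    )
    baseline = baseline or procedures[0]
    comparisons = [
        compare_procedures(
            result.accuracies[name], result.accuracies[baseline],
            o=scheme.ts_fraction, procedure=name, baseline=baseline,
        )
        for name in procedures
        if name != baseline
    ]
    return result, comparisons
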