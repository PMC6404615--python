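"""Loading, filtering and imputation of expected-allelic-dosage matrices.

Marker data are expected allelic dosages at biallelic SNPs: real values in
[0, 2] giving the posterior-mean count of the alternate allele per individual.
Missing entries are represented by NaN throughout.

Filtering applies four criteria, in order:

(i)   proportion of missing values strictly below ``max_missing``;
(ii)  minor allele frequency strictly above ``maf_min`` AND dosage variance
      strictly above ``var_min``;
(iii) Hardy-Weinberg equilibrium p-value strictly above ``hwe_pmin`` in each
      population named in ``hwe_populations``;
(iv)  availability of genomic-position information (when required).

All thresholds are strict inequalities. Allele frequencies for (ii) use
observed (non-missing) entries only, since filtering precedes imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats


class DosageValidationError(ValueError):
    """A dosage entry lies outside [0, 2] or ids are malformed."""


@dataclass
class DosageMatrix:
    """n individuals x m markers of expected allelic dosages in [0, 2].

    Missing entries are NaN. ``positions`` optionally maps marker index to
    (chromosome, coordinate); markers absent from it have unknown location.
    """

    values: np.ndarray
    individual_ids: list[str]
    marker_ids: list[str]
    positions: dict[str, tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DosageValidationError("dosage values must be a 2-D matrix")
        n, m = self.values.shape
        if len(self.individual_ids) != n or len(self.marker_ids) != m:
            raise DosageValidationError("id lengths do not match matrix shape")
        if len(set(self.individual_ids)) != n:
            raise DosageValidationError("individual ids are not unique")
        if len(set(self.marker_ids)) != m:
            raise DosageValidationError("marker ids are not unique")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 2.0):
            bad = finite[(finite < 0.0) | (finite > 2.0)][0]
            raise DosageValidationError(
                f"dosage entry {bad!r} outside the admissible range [0, 2]"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def subset_markers(self, keep: np.ndarray) -> "DosageMatrix":
        keep = np.asarray(keep)
        marker_ids = [self.marker_ids[j] for j in np.flatnonzero(keep)] \
            if keep.dtype == bool else [self.marker_ids[j] for j in keep]
        return DosageMatrix(
            values=self.values[:, keep],
            individual_ids=list(self.individual_ids),
            marker_ids=marker_ids,
            positions=self.positions,
        )

    def subset_individuals(self, keep: np.ndarray) -> "DosageMatrix":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return DosageMatrix(
            values=self.values[idx, :],
            individual_ids=[self.individual_ids[i] for i in idx],
            marker_ids=list(self.marker_ids),
            positions=self.positions,
        )


@dataclass
class SampleMetadata:
    """Per-individual population and (optional) panel labels."""

    population: pd.Series
    panel: pd.Series | None = None
    hwe_populations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        observed = set(self.population.unique())
        unknown = set(self.hwe_populations) - observed
        if unknown:
            raise ValueError(f"hwe_populations not observed in sample: {sorted(unknown)}")

    @property
    def individual_ids(self) -> list[str]:
        return list(self.population.index)


@dataclass(frozen=True)
class FilterSpec:
    """Thresholds for the four marker filters; all comparisons are strict.

    Defaults follow common dosage-data practice: markers must be nearly
    complete, polymorphic beyond the single-copy limit 1/(2n), variable
    beyond the corresponding binomial floor, HWE-consistent within the
    designated populations, and genomically located.
    """

    max_missing: float = 0.02
    maf_min: float | None = None      # None -> 1/(2n)
    var_min: float | None = None      # None -> 2*(1/(2n))*(1 - 1/(2n))
    hwe_pmin: float = 1e-4
    require_position: bool = True

    def resolved(self, n: int) -> "FilterSpec":
        """Fill sample-size-dependent defaults for a sample of n individuals."""
        maf = self.maf_min if self.maf_min is not None else 1.0 / (2 * n)
        var = self.var_min if self.var_min is not None else 2 * (1.0 / (2 * n)) * (1 - 1.0 / (2 * n))
        for name, val in [("max_missing", self.max_missing), ("maf_min", maf),
                          ("hwe_pmin", self.hwe_pmin)]:
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"filter threshold {name}={val} outside [0, 1]")
        if var < 0:
            raise ValueError(f"var_min={var} negative")
        return replace(self, maf_min=maf, var_min=var)


@dataclass
class FilterReport:
    """Removal counts per criterion, in application order (i) -> (iv)."""

    n_input: int
    removed_missing: int
    removed_maf_var: int
    removed_hwe: int
    removed_position: int
    n_retained: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "criterion": ["missingness", "maf_variance", "hwe", "position"],
                "removed": [self.removed_missing, self.removed_maf_var,
                            self.removed_hwe, self.removed_position],
            }
        )


# ---------------------------------------------------------------------------
# loading


def load_dosages(path, format: str = "matrix") -> DosageMatrix:
    """Read a dosage matrix from delimited text or VCF.

    The matrix layout has individuals as rows: a header row of marker ids and
    a first column of individual ids. VCF import converts diploid genotypes
    to alternate-allele counts (``./.`` becomes missing) and accepts
    biallelic SNPs only.
    """
    if format == "matrix":
        return _load_matrix(path)
    if format == "vcf":
        return _load_vcf(path)
    raise ValueError(f"unknown dosage format {format!r}")


def _load_matrix(path) -> DosageMatrix:
    try:
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    except Exception as exc:  # surface the offending line if pandas names it
        raise DosageValidationError(f"malformed dosage matrix {path}: {exc}") from exc
    values = df.to_numpy(dtype=float)
    return DosageMatrix(
        values=values,
        individual_ids=[str(i) for i in df.index],
        marker_ids=[str(c) for c in df.columns],
    )


def _load_vcf(path) -> DosageMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF import requires cyvcf2 (install hetblup[vcf])") from exc
    vcf = VCF(str(path))
    ids = list(vcf.samples)
    rows: list[np.ndarray] = []
    marker_ids: list[str] = []
    positions: dict[str, tuple[str, int]] = {}
    for variant in vcf:
        if len(variant.ALT) != 1 or not variant.is_snp:
            continue
        mid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        marker_ids.append(mid)
        positions[mid] = (variant.CHROM, variant.POS)
        gts = variant.genotype.array()[:, :2]
        dose = np.where((gts < 0).any(axis=1), np.nan, gts.clip(min=0).sum(axis=1))
        rows.append(dose.astype(float))
    values = np.column_stack(rows) if rows else np.empty((len(ids), 0))
    return DosageMatrix(values=values, individual_ids=ids,
                        marker_ids=marker_ids, positions=positions)


def load_metadata(path, hwe_populations: tuple[str, ...] = ()) -> SampleMetadata:
    """Read id/population[/panel] metadata from a delimited file."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    df = df.set_index(df.columns[0])
    population = df.iloc[:, 0]
    panel = df.iloc[:, 1] if df.shape[1] > 1 else None
    return SampleMetadata(population=population, panel=panel,
                          hwe_populations=hwe_populations)


def write_dosages(D: DosageMatrix, path) -> None:
    pd.DataFrame(D.values, index=D.individual_ids, columns=D.marker_ids).to_csv(path)


# ---------------------------------------------------------------------------
# filtering


def allele_frequency(column: np.ndarray) -> float:
    """Alternate-allele frequency = mean observed dosage / 2."""
    obs = column[np.isfinite(column)]
    if obs.size == 0:
        return np.nan
    return float(obs.mean() / 2.0)


def hwe_pvalue(dosages: np.ndarray) -> float:
    """Chi-square (1 df) goodness-of-fit p-value for Hardy-Weinberg equilibrium.

    Dosages are rounded to the nearest integer genotype before counting;
    monomorphic markers return p = 1 by convention.
    """
    obs = np.asarray(dosages, dtype=float)
    obs = obs[np.isfinite(obs)]
    if obs.size == 0:
        return 1.0
    geno = np.clip(np.rint(obs), 0, 2).astype(int)
    counts = np.bincount(geno, minlength=3)[:3].astype(float)
    n = counts.sum()
    p = (2 * counts[2] + counts[1]) / (2 * n)
    if p <= 0.0 or p >= 1.0:
        return 1.0
    expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def filter_markers(
    D: DosageMatrix,
    meta: SampleMetadata | None = None,
    spec: FilterSpec | None = None,
) -> tuple[DosageMatrix, FilterReport]:
    """Apply the four marker filters; return surviving markers and a report.

    Criteria are evaluated jointly on the input (outcome independent of
    order); the report attributes each removed marker to the first criterion
    it fails, in order (i) missingness, (ii) MAF/variance, (iii) HWE,
    (iv) position.
    """
    if D.n < 2:
        raise ValueError("filtering requires at least 2 individuals")
    spec = (spec or FilterSpec()).resolved(D.n)
    X = D.values
    n, m = X.shape
    miss_prop = np.isnan(X).mean(axis=0)
    fail_miss = ~(miss_prop < spec.max_missing)

    freqs = np.array([allele_frequency(X[:, j]) for j in range(m)])
    maf = np.minimum(freqs, 1 - freqs)
    with np.errstate(invalid="ignore"):
        variances = np.array(
            [np.var(X[np.isfinite(X[:, j]), j]) if np.isfinite(X[:, j]).any() else 0.0
             for j in range(m)]
        )
    fail_maf = ~((maf > spec.maf_min) & (variances > spec.var_min))

    fail_hwe = np.zeros(m, dtype=bool)
    if meta is not None and meta.hwe_populations:
        pops = np.asarray(meta.population.values)
        for pop in meta.hwe_populations:
            rows = pops == pop
            for j in range(m):
                if not fail_hwe[j]:
                    pval = hwe_pvalue(X[rows, j])
                    if not pval > spec.hwe_pmin:
                        fail_hwe[j] = True

    if spec.require_position:
        if D.positions is None:
            fail_pos = np.ones(m, dtype=bool)
        else:
            fail_pos = np.array([mid not in D.positions for mid in D.marker_ids])
    else:
        fail_pos = np.zeros(m, dtype=bool)

    keep = ~(fail_miss | fail_maf | fail_hwe | fail_pos)
    # first-failure attribution for the report
    rem_miss = int(fail_miss.sum())
    rem_maf = int((fail_maf & ~fail_miss).sum())
    rem_hwe = int((fail_hwe & ~fail_miss & ~fail_maf).sum())
    rem_pos = int((fail_pos & ~fail_miss & ~fail_maf & ~fail_hwe).sum())
    report = FilterReport(
        n_input=m,
        removed_missing=rem_miss,
        removed_maf_var=rem_maf,
        removed_hwe=rem_hwe,
        removed_position=rem_pos,
        n_retained=int(keep.sum()),
    )
    return D.subset_markers(keep), report


def impute_mode(D: DosageMatrix) -> DosageMatrix:
    """Replace each missing entry by the modal value of its marker column.

    The mode is taken over the whole sample; ties break toward the lowest
    dosage value. Idempotent; errors on a fully-missing column.
    """
    X = D.values.copy()
    for j in range(X.shape[1]):
        col = X[:, j]
        missing = np.isnan(col)
        if not missing.any():
            continue
        obs = col[~missing]
        if obs.size == 0:
            raise ValueError(f"marker {D.marker_ids[j]!r} fully missing; mode undefined")
        vals, counts = np.unique(obs, return_counts=True)
        mode = vals[counts == counts.max()].min()
        col[missing] = mode
    return DosageMatrix(
        values=X,
        individual_ids=list(D.individual_ids),
        marker_ids=list(D.marker_ids),
        positions=D.positions,
    )
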