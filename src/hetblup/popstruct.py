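"""Population structure: the genomic relationship matrix G, principal
components, the decomposition G = PP' + G_P, and individual-specific allele
frequencies.

G follows the VanRaden construction: with dosages X (n x m) and whole-sample
allele frequencies pi_hat, the centered matrix is Xdot = X - 2*pi_hat and

    G = Xdot Xdot' / v,      v = 2 * sum_l pi_hat_l (1 - pi_hat_l).

PC scores are eigenvectors of G scaled by the square root of their
eigenvalues, so that PP' is literally the rank-d spectral truncation of G and
G = PP' + G_P holds exactly. With that convention, Euclidean distances in PC
space relate to distances between individual-specific allele-frequency
vectors by ||p_i - p_j|| = 2 ||pi_Pi - pi_Pj|| (after accounting for the
common 1/sqrt(v) scale; see ``indiv_allele_freqs``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geno_io import DosageMatrix


@dataclass
class AlleleFrequencies:
    """Whole-sample alternate-allele frequencies and the VanRaden scale v."""

    freq: np.ndarray

    @property
    def v(self) -> float:
        return float(2.0 * np.sum(self.freq * (1.0 - self.freq)))


@dataclass
class PCScores:
    """Top-d principal components of G, scaled so that PP' truncates G.

    ``scores`` columns are eigenvectors of G multiplied by sqrt(eigenvalue),
    ordered by descending eigenvalue; ``explained`` holds the eigenvalues.
    """

    scores: np.ndarray
    explained: np.ndarray

    @property
    def d(self) -> int:
        return self.scores.shape[1]


@dataclass
class AdmixtureMatrix:
    """n x K admixture (cluster membership) coefficients; rows sum to 1."""

    coeff: np.ndarray

    def __post_init__(self) -> None:
        self.coeff = np.asarray(self.coeff, dtype=float)
        if (self.coeff < 0).any():
            raise ValueError("admixture coefficients must be nonnegative")
        row_sums = self.coeff.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-12):
            raise ValueError("admixture rows must sum to 1")

    @property
    def K(self) -> int:
        return self.coeff.shape[1]


@dataclass
class RelationshipDecomposition:
    """G split into a structured part PP' and a conditional part G_P."""

    G: np.ndarray
    structured: np.ndarray
    conditional: np.ndarray


@dataclass
class IndivAlleleFreqs:
    """n x m individual-specific allele frequencies implied by [1 P].

    Values are not clipped to [0, 1]: small excursions can occur and clipping
    would break the factor-2 distance identity with PC coordinates.
    """

    freq: np.ndarray


def compute_G(D: DosageMatrix) -> tuple[np.ndarray, AlleleFrequencies]:
    """Genomic relationship matrix G = Xdot Xdot'/v from imputed dosages."""
    X = D.values
    if np.isnan(X).any():
        raise ValueError("dosages contain missing values; impute first")
    pi_hat = X.mean(axis=0) / 2.0
    freqs = AlleleFrequencies(freq=pi_hat)
    if freqs.v <= 0.0:
        raise ValueError("all markers monomorphic: VanRaden scale v = 0")
    Xdot = X - 2.0 * pi_hat
    G = Xdot @ Xdot.T / freqs.v
    return (G + G.T) / 2.0, freqs


def compute_pcs(G: np.ndarray, d: int = 4) -> PCScores:
    """Top-d eigenpairs of G as sqrt(eigenvalue)-scaled scores."""
    n = G.shape[0]
    if d >= n:
        raise ValueError(f"d={d} must be smaller than n={n}")
    eigvals, eigvecs = np.linalg.eigh(G)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    if d < n - 1 and abs(eigvals[d - 1] - eigvals[d]) < 1e-10 * max(1.0, abs(eigvals[0])):
        warnings.warn(
            f"eigenvalues {d} and {d + 1} of G are tied; the PC subspace is not unique",
            stacklevel=2,
        )
    top = np.clip(eigvals[:d], 0.0, None)
    scores = eigvecs[:, :d] * np.sqrt(top)
    return PCScores(scores=scores, explained=eigvals[:d])


def decompose_G(G: np.ndarray, P: PCScores) -> RelationshipDecomposition:
    """G = PP' + G_P with G_P the structure-conditional relationships."""
    if P.scores.shape[0] != G.shape[0]:
        raise ValueError("PC scores and G have mismatched dimensions")
    structured = P.scores @ P.scores.T
    conditional = G - structured
    conditional = (conditional + conditional.T) / 2.0
    return RelationshipDecomposition(G=G, structured=structured, conditional=conditional)


def indiv_allele_freqs(
    D: DosageMatrix, P: PCScores, freqs: AlleleFrequencies
) -> IndivAlleleFreqs:
    """Individual-specific allele frequencies from the rank-d structure model.

    Row i is pi_hat + (rank-d reconstruction of the centered dosage matrix,
    row i)/2: the allele frequencies an individual's population background
    implies, with the background described by the top-d PC subspace. Dividing
    dosage deviations by 2 converts them to frequency units, so pairwise PC
    distances in dosage units (``pc_scores_dosage_units``) equal exactly
    twice the distances between these frequency vectors.
    """
    X = D.values
    if np.isnan(X).any():
        raise ValueError("dosages contain missing values; impute first")
    Xdot = X - 2.0 * freqs.freq
    lam = np.clip(P.explained, 0.0, None)
    nonzero = lam > 1e-12
    # orthonormal eigenvectors of G recovered from the sqrt(lambda) scaling
    U = P.scores[:, nonzero] / np.sqrt(lam[nonzero])
    recon = U @ (U.T @ Xdot)  # rank-d truncation of Xdot, dosage units
    freq = freqs.freq + recon / 2.0
    return IndivAlleleFreqs(freq=freq)


def pc_scores_dosage_units(P: PCScores, freqs: AlleleFrequencies) -> np.ndarray:
    """PC coordinates rescaled from the G scale back to dosage units.

    ``compute_pcs`` scores live on the scale of G (centered dosages divided
    by sqrt(v)); multiplying by sqrt(v) restores the scale of the centered
    dosage matrix itself, the scale on which the factor-2 identity with
    individual-specific allele frequencies holds:
    ||p_i - p_j|| = 2 ||pi_Pi - pi_Pj||.
    """
    return P.scores * np.sqrt(freqs.v)


def normalize_admixture(A_raw: np.ndarray, clip: float = 1e-5) -> AdmixtureMatrix:
    """Zero coefficients at or below ``clip`` and rescale each row to sum 1."""
    A = np.asarray(A_raw, dtype=float).copy()
    if (A < 0).any():
        raise ValueError("admixture coefficients must be nonnegative")
    A[A <= clip] = 0.0
    row_sums = A.sum(axis=1)
    if (row_sums == 0).any():
        bad = int(np.flatnonzero(row_sums == 0)[0])
        raise ValueError(f"admixture row {bad} sums to 0 after clipping")
    return AdmixtureMatrix(coeff=A / row_sums[:, None])


def load_admixture(path) -> AdmixtureMatrix:
    """Read an admixture matrix in Q-file layout (whitespace-delimited, n x K)."""
    A = pd.read_csv(path, sep=r"\s+", header=None).to_numpy(dtype=float)
    return normalize_admixture(A)


def write_matrix(M: np.ndarray, ids: list[str], path) -> None:
    """Write a symmetric matrix (G, P'P, kernels) with id headers."""
    pd.DataFrame(M, index=ids, columns=ids if M.shape[0] == M.shape[1] else None).to_csv(path)
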