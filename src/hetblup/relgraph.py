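"""Graphs of recent relationships via the graphical LASSO on G_P.

After removing the population-structure part PP' from the genomic
relationship matrix, the conditional matrix G_P concentrates around zero for
unrelated pairs. Treating G_P as a covariance, an L1-penalized Gaussian
precision estimate (graphical LASSO, off-diagonal penalty only) yields a
sparse partial-covariance pattern whose nonzero entries define edges between
recently related individuals. The penalty lambda is selected by refitting a
GBLUP model on the regularized relationship matrix

    G_tilde(lambda) = PP' + inverse(Theta_hat(lambda))

and maximizing the restricted likelihood over a grid; different phenotypes
may select different penalties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso

from .geno_io import SampleMetadata
from .mixedmodel import MeanStructure, reml_fit
from .popstruct import RelationshipDecomposition

_EDGE_EPS = 1e-8


@dataclass
class RecentGraph:
    """Sparse precision estimate over G_P and the implied edge set."""

    precision: np.ndarray
    covariance: np.ndarray  # regularized G_P = inverse(precision)
    lam: float
    individual_ids: list[str] | None = None

    @property
    def n(self) -> int:
        return self.precision.shape[0]

    @property
    def edges(self) -> list[tuple[int, int]]:
        i, j = np.nonzero(np.triu(np.abs(self.precision) > _EDGE_EPS, k=1))
        return list(zip(i.tolist(), j.tolist()))

    @property
    def degrees(self) -> np.ndarray:
        adj = (np.abs(self.precision) > _EDGE_EPS) & ~np.eye(self.n, dtype=bool)
        return adj.sum(axis=1)

    def edge_table(self) -> pd.DataFrame:
        ids = self.individual_ids or [str(i) for i in range(self.n)]
        rows = [
            (ids[i], ids[j], self.precision[i, j]) for i, j in self.edges
        ]
        return pd.DataFrame(rows, columns=["id_i", "id_j", "partial_covariance"])

    def to_networkx(self):
        import networkx as nx

        ids = self.individual_ids or [str(i) for i in range(self.n)]
        g = nx.Graph()
        g.add_nodes_from(ids)
        for i, j in self.edges:
            g.add_edge(ids[i], ids[j], partial_covariance=float(self.precision[i, j]))
        return g

    def write_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)


def _ensure_pd(S: np.ndarray, rel_eps: float = 1e-3) -> np.ndarray:
    """Diagonal jitter making S positive definite for the LASSO solver.

    The floor is relative to the mean diagonal: G_P is exactly singular by
    construction (its top-d eigenpairs were removed), and a merely-positive
    minimum eigenvalue still defeats the coordinate-descent solver.
    """
    S = (S + S.T) / 2.0
    eps = rel_eps * float(np.mean(np.diag(S)))
    min_eig = float(np.linalg.eigvalsh(S).min())
    if min_eig < eps:
        S = S + (eps - min_eig) * np.eye(S.shape[0])
    return S


def graphical_lasso_fit(
    G_P: np.ndarray,
    lam: float,
    individual_ids: list[str] | None = None,
    max_iter: int = 500,
) -> RecentGraph:
    """L1-penalized precision estimate treating G_P as a covariance.

    Off-diagonal entries only are penalized; lam = 0 reduces to the dense
    inverse. G_P is jittered on the diagonal if needed for positive
    definiteness (it is rank-deficient by construction after removing the
    top-d eigenpairs).
    """
    if lam < 0:
        raise ValueError(f"penalty lam={lam} must be nonnegative")
    G_P = np.asarray(G_P, dtype=float)
    if lam == 0.0:
        S = _ensure_pd(G_P)
        precision = np.linalg.inv(S)
        covariance = S
    else:
        # near-singular inputs at small penalties destabilize the coordinate
        # descent; retry with progressively heavier diagonal loading
        last_exc: Exception | None = None
        for rel_eps in (1e-3, 1e-2, 1e-1):
            S = _ensure_pd(G_P, rel_eps=rel_eps)
            try:
                covariance, precision = _sk_graphical_lasso(
                    S, alpha=lam, max_iter=max_iter
                )
                break
            except FloatingPointError as exc:
                last_exc = exc
        else:
            raise RuntimeError(
                f"graphical LASSO failed to converge at lam={lam} "
                f"within {max_iter} iterations: {last_exc}"
            ) from last_exc
    return RecentGraph(
        precision=precision, covariance=covariance, lam=lam,
        individual_ids=individual_ids,
    )


def default_lambda_grid(G_P: np.ndarray, n_points: int = 20) -> np.ndarray:
    """Log-spaced penalties spanning [1e-3, 1] x max |off-diagonal of G_P|."""
    off = np.abs(G_P - np.diag(np.diag(G_P))).max()
    return np.logspace(-3, 0, n_points) * off


def select_lambda(
    y: np.ndarray,
    Q: MeanStructure | np.ndarray,
    decomposition: RelationshipDecomposition,
    grid: np.ndarray | None = None,
) -> tuple[float, pd.DataFrame]:
    """Choose the penalty maximizing the restricted likelihood of GBLUP on
    G_tilde(lambda) = PP' + regularized G_P.

    Selection is per-phenotype: different y on the same genotypes may prefer
    different penalties. Returns the winning lambda and the per-lambda table
    of restricted logliks and edge counts.
    """
    if grid is None:
        grid = default_lambda_grid(decomposition.conditional)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty penalty grid")
    records = []
    for lam in grid:
        try:
            graph = graphical_lasso_fit(decomposition.conditional, float(lam))
            G_tilde = decomposition.structured + graph.covariance
            fit = reml_fit(y, Q, G_tilde, kernel_ref=f"regularized(lam={lam:.4g})")
            records.append(
                {"lam": float(lam), "reml_loglik": fit.reml_loglik,
                 "n_edges": len(graph.edges)}
            )
        except (RuntimeError, np.linalg.LinAlgError) as exc:
            records.append(
                {"lam": float(lam), "reml_loglik": -np.inf, "n_edges": np.nan,
                 "error": str(exc)}
            )
    table = pd.DataFrame(records)
    if not np.isfinite(table["reml_loglik"]).any():
        raise RuntimeError("all penalized fits failed over the grid")
    lam_star = float(table.loc[table["reml_loglik"].idxmax(), "lam"])
    return lam_star, table


def graph_summary(g: RecentGraph, meta: SampleMetadata) -> dict:
    """Per-population mean degree and within/between edge counts."""
    pops = np.asarray(meta.population.values)
    if len(pops) != g.n:
        raise ValueError("metadata and graph sizes differ")
    degrees = g.degrees
    mean_degree = {
        pop: float(degrees[pops == pop].mean()) for pop in pd.unique(pops)
    }
    within = between = 0
    cross: dict[tuple[str, str], int] = {}
    for i, j in g.edges:
        if pops[i] == pops[j]:
            within += 1
        else:
            between += 1
            key = tuple(sorted((pops[i], pops[j])))
            cross[key] = cross.get(key, 0) + 1
    return {
        "mean_degree": mean_degree,
        "n_edges_within": within,
        "n_edges_between": between,
        "between_by_pair": cross,
    }
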