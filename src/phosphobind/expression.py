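"""Expression-ratio computation, clustering and candidate selection.

Consumes an already-normalized log2-scale gene-level intensity matrix with
a (condition, timepoint, replicate) design: per condition, replicate
intensities are averaged per timepoint and the expression change is
``mean(24h) - mean(0h)`` on the log2 scale.  Downstream operations:
correlation of changes between treatments, counting bound genes that
change at least a fold threshold, k-means clustering of change profiles
under the uncentered-correlation distance, and selection of peaks with
condition-preferential phospho-specific binding whose genes also change
between treatments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionTable",
    "compute_ratios",
    "treatment_correlation",
    "percent_changed",
    "select_bound_changed",
    "uncentered_correlation",
    "kmeans_uncentered",
    "select_differential_ptm_candidates",
    "expression_change_ttest",
]


@dataclass
class ExpressionTable:
    """Gene x sample log2 intensities plus the sample design.

    ``samples`` needs columns ``sample_id``, ``condition``, ``timepoint``
    (``0h``/``24h``) and ``replicate``; every (condition, timepoint) cell
    must have at least one replicate.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "condition", "timepoint", "replicate"}
        if not required.issubset(self.samples.columns):
            raise ValueError(f"sample sheet needs columns {sorted(required)}")
        missing = set(self.samples["sample_id"]) - set(self.values.columns)
        if missing:
            raise ValueError(f"samples absent from the matrix: {sorted(missing)}")
        if self.values.index.duplicated().any():
            raise ValueError("gene ids must be unique")

    @classmethod
    def from_files(cls, values_path, samples_path) -> "ExpressionTable":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", dtype=str)
        return cls(values, samples)

    def conditions(self) -> list[str]:
        return sorted(self.samples["condition"].unique())


def compute_ratios(
    table: ExpressionTable, t0: str = "0h", t1: str = "24h"
) -> pd.DataFrame:
    """Per-condition log2 expression change (gene x condition).

    Replicates are averaged per timepoint; the change is the difference of
    timepoint means on the log2 scale (i.e. log2 of the intensity ratio).
    """
    out = {}
    for cond in table.conditions():
        cond_samples = table.samples[table.samples["condition"] == cond]
        means = {}
        for tp in (t0, t1):
            ids = cond_samples.loc[cond_samples["timepoint"] == tp, "sample_id"]
            if ids.empty:
                raise ValueError(f"condition {cond!r} lacks timepoint {tp!r}")
            means[tp] = table.values[list(ids)].mean(axis=1)
        out[cond] = means[t1] - means[t0]
    ratios = pd.DataFrame(out)
    if not np.isfinite(ratios.to_numpy()).all():
        raise ValueError("non-finite expression changes")
    return ratios


def treatment_correlation(ratios: pd.DataFrame, cond_a: str, cond_b: str) -> float:
    """Pearson correlation of per-gene log2 changes between two conditions."""
    x = ratios[cond_a].to_numpy(dtype=float)
    y = ratios[cond_b].to_numpy(dtype=float)
    if len(x) < 2:
        raise ValueError("need >=2 genes")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant changes")
    return float(np.corrcoef(x, y)[0, 1])


def percent_changed(n_bound: int, n_changed: int) -> int:
    """Integer percentage of bound genes that changed expression."""
    if n_bound <= 0:
        raise ValueError("bound-gene count must be positive")
    return int(round(100.0 * n_changed / n_bound))


def select_bound_changed(
    bound_genes,
    ratios: pd.DataFrame,
    condition: str,
    fold: float = 1.7,
) -> tuple[int, int, int]:
    """Count bound genes changing at least ``fold`` in one condition.

    ``bound_genes`` is the set of genes with >=1 assigned peak.  A gene
    counts as changed when ``|log2 change| >= log2(fold)`` (inclusive).
    Returns ``(n_bound, n_changed, percent)``.
    """
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    bound = [g for g in bound_genes if g in ratios.index]
    if not bound:
        return 0, 0, 0
    changes = ratios.loc[bound, condition].to_numpy(dtype=float)
    n_changed = int((np.abs(changes) >= np.log2(fold)).sum())
    return len(bound), n_changed, percent_changed(len(bound), n_changed)


def uncentered_correlation(x, y) -> float:
    """Cosine-like similarity without mean-centering.

    ``sum(x*y) / sqrt(sum(x^2) * sum(y^2))``; scale-invariant but not
    shift-invariant.  The clustering distance is one minus this value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    nx = np.sqrt(np.sum(x * x))
    ny = np.sqrt(np.sum(y * y))
    if nx == 0 or ny == 0:
        raise ValueError("uncentered correlation undefined for a zero vector")
    return float(np.dot(x, y) / (nx * ny))


def _normalize_rows(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-norm row in clustering input")
    return X / norms


def kmeans_uncentered(
    X,
    k: int = 10,
    seed: int = 0,
    max_iter: int = 100,
    n_restarts: int = 10,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd k-means under the 1 - uncentered-correlation distance.

    Centroids are the L2-normalized means of their members (spherical
    k-means, which makes the objective non-increasing per iteration).
    Empty clusters are re-seeded from the point farthest from its
    centroid.  ``n_restarts`` seeded initializations are run and the best
    objective kept; the result is deterministic given the seed.

    Returns ``(labels, centroids, objective)`` where the objective is the
    sum over points of their distance to the assigned centroid.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} points, got {n}")
    U = _normalize_rows(X)
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(n_restarts):
        idx = rng.choice(n, size=k, replace=False)
        centroids = U[idx].copy()
        labels = np.full(n, -1, dtype=int)
        for _it in range(max_iter):
            sims = U @ centroids.T
            new_labels = np.argmax(sims, axis=1)
            for c in range(k):
                if not np.any(new_labels == c):
                    worst = int(np.argmin(sims[np.arange(n), new_labels]))
                    new_labels[worst] = c
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for c in range(k):
                members = U[labels == c]
                mean = members.mean(axis=0)
                norm = np.linalg.norm(mean)
                if norm > 0:
                    centroids[c] = mean / norm
        objective = float(
            np.sum(1.0 - (U * centroids[labels]).sum(axis=1))
        )
        if best is None or objective < best[0]:
            best = (objective, labels.copy(), centroids.copy())
    objective, labels, centroids = best
    return labels, centroids, objective


def select_differential_ptm_candidates(
    peak_names: list[str],
    ptm_rpp_a,
    ptm_rpp_b,
    gene_peak_table: pd.DataFrame,
    ratios: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    ptm_fold: float = 2.0,
    expr_fold: float = 1.2,
) -> pd.DataFrame:
    """Peaks with condition-B-preferential phospho binding at genes whose
    expression differs between treatments.

    A peak passes when ``(rpp_B + 1) / (rpp_A + 1) >= ptm_fold`` (the
    pseudo-count guards zero counts); its assigned gene passes when
    ``|log2 change_B - log2 change_A| >= log2(expr_fold)`` (inclusive).
    Returns one row per (peak, gene) pair with flags; the candidates are
    the rows where both flags hold.
    """
    rpp_a = np.asarray(ptm_rpp_a, dtype=float)
    rpp_b = np.asarray(ptm_rpp_b, dtype=float)
    ptm_ratio = dict(
        zip(peak_names, (rpp_b + 1.0) / (rpp_a + 1.0))
    )
    rpp_a_map = dict(zip(peak_names, rpp_a))
    rpp_b_map = dict(zip(peak_names, rpp_b))
    rows = []
    for _, rec in gene_peak_table.iterrows():
        peak, gene = rec["peak"], rec["gene_id"]
        if peak not in ptm_ratio or gene not in ratios.index:
            continue
        dlog2 = float(ratios.at[gene, cond_b] - ratios.at[gene, cond_a])
        ptm_pass = bool(ptm_ratio[peak] >= ptm_fold)
        expr_pass = bool(abs(dlog2) >= np.log2(expr_fold))
        rows.append(
            {
                "peak": peak,
                "gene_id": gene,
                "ptm_rpp_a": rpp_a_map[peak],
                "ptm_rpp_b": rpp_b_map[peak],
                "ptm_ratio": ptm_ratio[peak],
                "expr_dlog2": dlog2,
                "ptm_fold_pass": ptm_pass,
                "expr_fold_pass": expr_pass,
                "candidate": ptm_pass and expr_pass,
            }
        )
    cols = [
        "peak", "gene_id", "ptm_rpp_a", "ptm_rpp_b", "ptm_ratio",
        "expr_dlog2", "ptm_fold_pass", "expr_fold_pass", "candidate",
    ]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["peak", "gene_id"]).reset_index(drop=True)


def expression_change_ttest(changes_a, changes_b) -> tuple[float, float]:
    """Two-sample t-test on replicate-level expression changes."""
    res = stats.ttest_ind(np.asarray(changes_a), np.asarray(changes_b))
    return float(res.statistic), float(res.pvalue)
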