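"""Within-individual correlation networks and Frobenius variability diagnostics.

The central idea: for repeated-measures designs, gene-gene Pearson
correlations are computed per individual across that individual's own time
series, never by pooling samples across individuals. A gene pair becomes a
network edge when its correlation is strong (|r| >= cutoff) in a sufficient
fraction of the group's individuals and all those strong correlations agree
in sign. The Frobenius norm between an individual's correlation matrix and
the group mean matrix quantifies how atypical that individual's co-expression
structure is.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import (
    CoexpressionNetwork,
    CorrelationMatrix,
    EDGE_COLUMNS,
    ExpressionMatrix,
    IndividualCorrelationStack,
    NetworkParams,
)


def _pearson_matrix(values: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation; NaN rows/cols for zero-variance genes,
    diagonal 1 where defined."""
    sd = values.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(values)
    c = np.atleast_2d(np.asarray(c, dtype=float))
    zero = sd == 0
    c[zero, :] = np.nan
    c[:, zero] = np.nan
    c = np.clip(c, -1.0, 1.0)
    idx = np.where(~zero)[0]
    c[idx, idx] = 1.0
    # enforce exact symmetry against float round-off
    return (c + c.T) / 2.0


def individual_correlations(expr: ExpressionMatrix, genes, group: str) -> IndividualCorrelationStack:
    """Pearson correlation of each gene pair across each individual's time series.

    Every individual of ``group`` must have a complete time series (all T
    time points, T >= 3). Entries are NaN where either gene has zero
    variance over the individual's time points.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to correlate")
    missing = set(genes) - set(expr.gene_ids)
    if missing:
        raise ValueError(f"gene(s) not in expression matrix: {sorted(missing)[:5]}")
    ann = expr.samples[expr.samples["group"] == group]
    if ann.empty:
        raise ValueError(f"no samples in group {group!r}")
    timepoints = sorted(ann["timepoint"].unique())
    if len(timepoints) < 3:
        raise ValueError(f"group {group!r} has fewer than 3 time points")
    sub = expr.values.loc[genes]
    matrices: dict[str, np.ndarray] = {}
    for ind in sorted(ann["individual_id"].unique()):
        rows = ann[ann["individual_id"] == ind].sort_values("timepoint")
        if list(rows["timepoint"]) != timepoints:
            raise ValueError(f"individual {ind!r} has an incomplete time series")
        matrices[ind] = _pearson_matrix(sub[rows.index].to_numpy(dtype=float))
    return IndividualCorrelationStack(gene_ids=genes, matrices=matrices)


def build_network(stack: IndividualCorrelationStack, params: NetworkParams | None = None,
                  provenance: str = "", include_all_nodes: bool = False) -> CoexpressionNetwork:
    """Retain gene pairs strongly and sign-consistently correlated across individuals.

    A pair qualifies in individual i when its correlation is defined and
    |r_i| >= corr_cutoff. It becomes an edge when qualifying individuals make
    up at least ``support_fraction`` of the group (denominator: all
    individuals, NaNs included) and all qualifying r_i share one sign. The
    edge weight is the mean r over qualifying individuals only (hence
    |weight| >= corr_cutoff); support is the qualifying fraction.
    """
    params = params or NetworkParams()
    if stack.n_individuals == 0:
        raise ValueError("empty correlation stack")
    R = stack.as_array()  # (n, G, G)
    n = R.shape[0]
    with np.errstate(invalid="ignore"):
        qual = ~np.isnan(R) & (np.abs(R) >= params.corr_cutoff)
        n_pos = (qual & (R > 0)).sum(axis=0)
        n_neg = (qual & (R < 0)).sum(axis=0)
    total = n_pos + n_neg
    support = total / n
    consistent = (n_pos == 0) | (n_neg == 0)
    is_edge = (support >= params.support_fraction) & consistent & (total > 0)
    with np.errstate(invalid="ignore"):
        weight = np.where(total > 0, np.where(qual, R, 0.0).sum(axis=0) / np.maximum(total, 1), np.nan)

    genes = stack.gene_ids
    rows = []
    gi, gj = np.triu_indices(len(genes), k=1)
    for a, b in zip(gi, gj):
        if not is_edge[a, b]:
            continue
        ga, gb = genes[a], genes[b]
        if gb < ga:
            ga, gb = gb, ga
        w = float(weight[a, b])
        rows.append({"source": ga, "target": gb, "weight": w,
                     "support": float(support[a, b]), "sign": "+" if w > 0 else "-"})
    edges = pd.DataFrame(rows, columns=list(EDGE_COLUMNS))
    extra = tuple(sorted(genes)) if include_all_nodes else ()
    return CoexpressionNetwork(edges, provenance=provenance, extra_nodes=extra)


def group_mean_correlation(stack: IndividualCorrelationStack) -> CorrelationMatrix:
    """Entry-wise NaN-aware mean of the individual matrices; diagonal 1 where defined."""
    if stack.n_individuals == 0:
        raise ValueError("empty correlation stack")
    R = stack.as_array()
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices stay NaN
        mean = np.nanmean(R, axis=0)
    mean = np.clip(mean, -1.0, 1.0)
    diag_defined = ~np.isnan(np.diagonal(mean))
    idx = np.where(diag_defined)[0]
    mean[idx, idx] = 1.0
    mean = (mean + mean.T) / 2.0
    return CorrelationMatrix(stack.gene_ids, mean)


def frobenius_distance(a: CorrelationMatrix, b: CorrelationMatrix,
                       on_nan: str = "omit") -> float:
    """Frobenius norm of the element-wise difference of two correlation matrices.

    The double sum runs over the full matrix (both triangles and the
    diagonal). With ``on_nan='omit'`` (default) index pairs undefined in
    either matrix are excluded; 'error' raises instead.
    """
    if a.gene_ids != b.gene_ids:
        raise ValueError("correlation matrices are over different gene sets")
    diff = a.values - b.values
    nan_mask = np.isnan(a.values) | np.isnan(b.values)
    if on_nan == "error":
        if nan_mask.any():
            raise ValueError("undefined correlations present")
    elif on_nan != "omit":
        raise ValueError(f"unknown on_nan policy {on_nan!r}")
    diff = np.where(nan_mask, 0.0, diff)
    return float(np.sqrt(np.sum(np.abs(diff) ** 2)))


def individual_distance_profile(stack: IndividualCorrelationStack,
                                on_nan: str = "omit") -> pd.Series:
    """Frobenius distance of each individual's matrix to the group mean matrix.

    Returns a Series indexed by individual, sorted descending — the most
    atypical individuals first. Useful as an outlier diagnostic before
    trusting a group network.
    """
    if stack.n_individuals < 2:
        raise ValueError("need at least 2 individuals for a distance profile")
    mean = group_mean_correlation(stack)
    dist = {
        ind: frobenius_distance(stack.matrix_for(ind), mean, on_nan=on_nan)
        for ind in stack.individual_ids
    }
    out = pd.Series(dist, name="frobenius_distance")
    return out.sort_values(ascending=False, kind="mergesort")


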