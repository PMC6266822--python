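"""Background-expression filtering via the female Y-chromosome noise floor.

Y-chromosome genes are not expressed in females, so their measured signal in
female samples estimates the platform's noise floor. Genes whose median
expression over the whole dataset does not exceed that floor are treated as
background and removed (boundary included: median equal to the threshold is
removed).
"""

from __future__ import annotations

import numpy as np

from .datatypes import ExpressionMatrix


def y_background_threshold(expr: ExpressionMatrix, chrom: dict[str, str],
                           method: str = "pooled") -> float:
    """Noise-floor threshold from Y-gene expression in female samples.

    method "pooled" (default) takes the median of all (Y gene, female sample)
    values pooled into one vector; "per_gene" takes the median of the
    per-Y-gene medians instead.
    """
    if method not in ("pooled", "per_gene"):
        raise ValueError(f"unknown method {method!r}")
    female = expr.samples.index[expr.samples["sex"] == "female"]
    if len(female) == 0:
        raise ValueError("no female samples: Y-based background threshold undefined")
    y_genes = [g for g in expr.gene_ids if chrom.get(g) == "Y"]
    if not y_genes:
        raise ValueError("no Y-chromosome genes present in the expression matrix")
    block = expr.values.loc[y_genes, female].to_numpy(dtype=float)
    if method == "pooled":
        return float(np.median(block))
    return float(np.median(np.median(block, axis=1)))


def filter_background(expr: ExpressionMatrix, threshold: float) -> ExpressionMatrix:
    """Drop genes whose all-sample median is equal-to or lower-than ``threshold``.

    Keeps exactly the genes with median strictly above the threshold; the
    sample set is unchanged. Raises if nothing survives (degenerate
    threshold). Idempotent at a fixed threshold.
    """
    if not np.isfinite(threshold) and threshold > 0:
        raise ValueError("threshold must not be +inf")
    medians = expr.values.median(axis=1)
    keep = medians[medians > threshold].index
    if len(keep) == 0:
        raise ValueError(
            f"background filter at threshold {threshold} removed all "
            f"{expr.n_genes} genes; threshold looks degenerate"
        )
    return ExpressionMatrix(expr.values.loc[keep], expr.samples.copy())


def background_filter_report(expr: ExpressionMatrix, filtered: ExpressionMatrix,
                             threshold: float) -> dict:
    return {
        "threshold": threshold,
        "n_input_genes": expr.n_genes,
        "n_kept": filtered.n_genes,
        "n_removed": expr.n_genes - filtered.n_genes,
    }
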