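"""Paired within-individual differential expression with q-value FDR.

Each individual contributes one log2 difference per gene between two time
points of the same group; genes are tested with a one-sample t on those
differences, either plain or with limma-style empirical-Bayes variance
moderation. Fold changes use the signed linear convention (downregulation
maps to -2^|log2fc|) so a single cut |FC| >= 1.2 covers both directions.
Multiple testing is handled by Storey q-values; with the null proportion
pi0 fixed at 1 the procedure reduces exactly to Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .datatypes import DEParams, ExpressionMatrix

RESULT_COLUMNS = ("log2fc", "fc", "t_stat", "p_value", "q_value", "significant")


@dataclass
class ContrastResult:
    """Per-gene outcome of one paired contrast (time point B minus A)."""

    table: pd.DataFrame  # indexed by gene: log2fc, fc, t_stat, p_value, q_value, significant
    group: str
    tp_a: int
    tp_b: int
    params: DEParams
    pi0: float = 1.0
    d0: float = 0.0  # prior degrees of freedom of the moderated fit (0 = plain t)
    s0_sq: float = float("nan")
    n_individuals: int = 0
    zero_variance: pd.Index = field(default_factory=lambda: pd.Index([]))

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def significant_genes(self, params: DEParams | None = None) -> set[str]:
        return significant_genes(self, params or self.params)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format="%.10g")


def signed_fold_change(log2fc: np.ndarray) -> np.ndarray:
    """Signed linear fold change: 2^log2fc when up, -2^(-log2fc) when down.

    log2fc = 0 maps to +1 so sign(fc) == sign(log2fc) with the +1 convention.
    """
    log2fc = np.asarray(log2fc, dtype=float)
    return np.where(log2fc >= 0, np.exp2(log2fc), -np.exp2(-log2fc))


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/trigamma)."""
    if y <= 0:
        return float("inf")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Matches the first two moments of log sample variances against the
    log-F distribution implied by s_g^2 ~ s0^2 * F(df, d0); returns
    (d0, s0_sq). d0 = inf when the observed spread of log variances is no
    larger than expected from sampling alone (complete shrinkage). Genes
    with zero sample variance are excluded from the fit.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        return float("inf"), float(np.median(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return float("inf"), float(np.exp(e_mean))
    d0 = 2.0 * trigamma_inverse(excess)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def paired_contrast(expr: ExpressionMatrix, group: str, tp_a: int, tp_b: int,
                    params: DEParams | None = None, d0: float | None = None,
                    pi0_method: str = "smoother") -> ContrastResult:
    """Test every gene for change between two time points within one group.

    Differences d_i = x(tp_b, i) - x(tp_a, i) per individual i; log2fc is
    their mean. ``params.test`` selects plain or moderated paired t. ``d0``
    overrides the fitted prior degrees of freedom of the moderated test
    (d0 = 0 reproduces the plain t exactly).
    """
    params = params or DEParams()
    ann = expr.samples[expr.samples["group"] == group]
    if ann.empty:
        raise ValueError(f"no samples in group {group!r}")
    individuals = sorted(ann["individual_id"].unique())
    cols_a, cols_b = [], []
    for ind in individuals:
        sub = ann[ann["individual_id"] == ind]
        for tp, acc in ((tp_a, cols_a), (tp_b, cols_b)):
            hit = sub.index[sub["timepoint"] == tp]
            if len(hit) != 1:
                raise ValueError(f"individual {ind!r} misses timepoint {tp}")
            acc.append(hit[0])
    n = len(individuals)
    if n < 3:
        raise ValueError(f"need at least 3 individuals in group {group!r}, found {n}")

    X = expr.values
    d = X[cols_b].to_numpy(dtype=float) - X[cols_a].to_numpy(dtype=float)  # genes x n
    log2fc = d.mean(axis=1)
    s2 = d.var(axis=1, ddof=1)
    df = n - 1
    zero_var = s2 == 0

    if params.test == "paired_t":
        eff_d0, s0_sq = 0.0, float("nan")
    else:
        if d0 is None:
            eff_d0, s0_sq = fit_variance_prior(s2, df)
        else:
            eff_d0 = float(d0)
            _, s0_sq = fit_variance_prior(s2, df) if eff_d0 > 0 else (0.0, float("nan"))

    with np.errstate(divide="ignore", invalid="ignore"):
        if eff_d0 == 0.0:
            post_var = s2
            total_df = float(df)
        elif np.isinf(eff_d0):
            post_var = np.full_like(s2, s0_sq)
            total_df = float("inf")
        else:
            post_var = (eff_d0 * s0_sq + df * s2) / (eff_d0 + df)
            total_df = df + eff_d0
        se = np.sqrt(post_var / n)
        t = log2fc / se
    if np.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), total_df)
    # degenerate variance under the plain t: test undefined, never significant
    undefined = zero_var & (eff_d0 == 0.0)
    t = np.where(undefined, np.nan, t)
    p = np.where(undefined, np.nan, p)

    q = np.full_like(p, np.nan)
    valid = ~np.isnan(p)
    pi0 = 1.0
    if valid.any():
        q[valid], pi0 = storey_qvalue(p[valid], pi0_method=pi0_method)

    fc = signed_fold_change(log2fc)
    sig = (np.abs(fc) >= params.fc_threshold) & (p < params.p_threshold) & valid
    table = pd.DataFrame(
        {"log2fc": log2fc, "fc": fc, "t_stat": t, "p_value": p, "q_value": q, "significant": sig},
        index=expr.values.index,
    )
    return ContrastResult(
        table=table, group=group, tp_a=tp_a, tp_b=tp_b, params=params, pi0=pi0,
        d0=eff_d0, s0_sq=s0_sq, n_individuals=n,
        zero_variance=expr.values.index[zero_var],
    )


def storey_qvalue(p_values, pi0_method: str = "smoother",
                  lambdas=None, pi0: float | None = None) -> tuple[np.ndarray, float]:
    """Storey q-values with smoother-estimated null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on a lambda
    grid (default 0.05..0.95 step 0.05), smoothed with a cubic polynomial and
    read off at the largest lambda, then clipped to (0, 1]. With
    ``pi0_method='fixed'`` and ``pi0=1`` the result equals Benjamini-Hochberg
    exactly. q_(i) = min_{j>=i} pi0 * m * p_(j) / j over sorted p, capped at
    1; tied p share a q.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and within [0, 1]")
    m = p.size

    if pi0_method == "fixed":
        if pi0 is None:
            pi0 = 1.0
    elif pi0_method == "smoother":
        if lambdas is None:
            lambdas = np.arange(0.05, 0.96, 0.05)
        lambdas = np.asarray(lambdas, dtype=float)
        if m < 30 or p.max() < lambdas.min():
            pi0 = 1.0  # too few tests to estimate pi0 stably
        else:
            pi0_lambda = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
            coeffs = np.polyfit(lambdas, pi0_lambda, deg=3)
            pi0 = float(np.polyval(coeffs, lambdas.max()))
        pi0 = float(min(1.0, max(pi0, 1.0 / m)))
    else:
        raise ValueError(f"unknown pi0_method {pi0_method!r}")

    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    ranks = np.arange(1, m + 1)
    raw = pi0 * m * ranked / ranks
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, float(pi0)


def significant_genes(result: ContrastResult, params: DEParams | None = None) -> set[str]:
    """Genes passing |fc| >= fc_threshold (boundary in) and p < p_threshold (boundary out)."""
    params = params or result.params
    t = result.table
    mask = (t["fc"].abs() >= params.fc_threshold) & (t["p_value"] < params.p_threshold)
    mask &= t["p_value"].notna()
    return set(t.index[mask])


def de_gene_union(contrasts, params: DEParams | None = None) -> set[str]:
    """Union of significant genes over several contrasts of one group."""
    contrasts = list(contrasts)
    if not contrasts:
        raise ValueError("empty contrast list")
    groups = {c.group for c in contrasts}
    if len(groups) > 1:
        raise ValueError(f"contrasts span several groups: {sorted(groups)}")
    out: set[str] = set()
    for c in contrasts:
        out |= significant_genes(c, params or c.params)
    return out
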