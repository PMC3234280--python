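"""CNV-expression and methylation-expression screens.

The centerpiece is the CNV-stratified rank test: per gene, tumor samples are
split into a low-copy group (seg.mean below the low screen threshold) and a
high-copy group (seg.mean at or above the high screen threshold); expression
in the two groups is compared with a two-sample Mann-Whitney rank-sum test,
and Benjamini-Hochberg q-values control the FDR across tested genes.  A gene
is tested only when each group holds at least ``min_sample_fraction`` of the
tumor samples, which restricts the screen to recurrently altered loci and
makes the gene count threshold-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import ThresholdConfig
from .io import GeneSampleMatrix

__all__ = [
    "bh_adjust",
    "expression_by_cnv_bins",
    "cnv_expression_cdf_gap",
    "per_gene_correlation",
    "rank_sum_test",
    "wilcoxon_cnv_screen",
    "threshold_sweep",
    "normal_deviation_filter",
]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# binned means and CDF gap
# ---------------------------------------------------------------------------

def expression_by_cnv_bins(
    expr: GeneSampleMatrix, cnv: GeneSampleMatrix, bin_edges
) -> pd.DataFrame:
    """Mean expression of all gene/sample pairs per seg.mean bin.

    Bins are ``[e_i, e_{i+1})`` with the last bin right-closed; empty bins
    report a missing mean.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or (np.diff(edges) <= 0).any():
        raise ValueError("bin_edges must be strictly increasing with >= 2 values")
    genes = expr.data.index.intersection(cnv.data.index)
    samples = [s for s in expr.samples if s in set(cnv.samples)]
    e = expr.data.loc[genes, samples].to_numpy().ravel()
    c = cnv.data.loc[genes, samples].to_numpy().ravel()
    ok = np.isfinite(e) & np.isfinite(c)
    e, c = e[ok], c[ok]
    idx = np.digitize(c, edges) - 1
    idx[c == edges[-1]] = len(edges) - 2  # right-close the last bin
    rows = []
    for b in range(len(edges) - 1):
        inb = idx == b
        in_range = inb & (c >= edges[0]) & (c <= edges[-1])
        n = int(in_range.sum())
        rows.append(
            {
                "bin_left": edges[b],
                "bin_right": edges[b + 1],
                "n_pairs": n,
                "mean_expression": float(e[in_range].mean()) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def cnv_expression_cdf_gap(expr_deleted, expr_amplified) -> float:
    """Maximum gap between the empirical expression CDFs of deleted and
    amplified gene/sample pairs: ``sup_x |F_del(x) - F_amp(x)|``."""
    d = np.asarray(expr_deleted, dtype=float)
    a = np.asarray(expr_amplified, dtype=float)
    d, a = d[np.isfinite(d)], a[np.isfinite(a)]
    if d.size == 0 or a.size == 0:
        raise ValueError("both pair sets must be non-empty")
    grid = np.concatenate([d, a])
    d_sorted, a_sorted = np.sort(d), np.sort(a)
    f_d = np.searchsorted(d_sorted, grid, side="right") / d.size
    f_a = np.searchsorted(a_sorted, grid, side="right") / a.size
    return float(np.abs(f_d - f_a).max())


# ---------------------------------------------------------------------------
# per-gene Pearson screens
# ---------------------------------------------------------------------------

def per_gene_correlation(
    x_matrix: GeneSampleMatrix,
    y_matrix: GeneSampleMatrix,
    min_pairs: int = 3,
    negate_x: bool = False,
    test_name: str | None = None,
) -> pd.DataFrame:
    """Per-gene Pearson r between two modalities over shared samples.

    ``negate_x=True`` implements the methylation-expression sign convention:
    r is computed on (-x, y) so genes where methylation represses expression
    score positive; the output flags the convention.  p-values come from the
    t-transform with n-2 degrees of freedom; genes with fewer than
    ``min_pairs`` complete pairs or zero variance report missing r.
    """
    if min_pairs < 3:
        raise ValueError("min_pairs must be >= 3")
    genes = x_matrix.data.index.intersection(y_matrix.data.index)
    samples = [s for s in x_matrix.samples if s in set(y_matrix.samples)]
    name = test_name or ("pearson_meth_expr" if negate_x else "pearson_cnv_expr")
    xs = x_matrix.data.loc[genes, samples].to_numpy()
    ys = y_matrix.data.loc[genes, samples].to_numpy()
    if negate_x:
        xs = -xs
    rows = []
    for gi, gene in enumerate(genes):
        x, y = xs[gi], ys[gi]
        ok = np.isfinite(x) & np.isfinite(y)
        n = int(ok.sum())
        r = p = np.nan
        if n >= min_pairs:
            xo, yo = x[ok], y[ok]
            sx, sy = xo.std(), yo.std()
            if sx > 0 and sy > 0:
                r = float(np.clip(((xo - xo.mean()) * (yo - yo.mean())).sum()
                                  / (n * sx * sy), -1.0, 1.0))
                if abs(r) == 1.0:
                    p = 0.0
                else:
                    t = r * np.sqrt((n - 2) / (1 - r * r))
                    p = float(2 * stats.t.sf(abs(t), df=n - 2))
        rows.append({"gene_id": gene, "test": name, "r": r, "p_value": p, "n": n,
                     "sign_flipped": negate_x})
    table = pd.DataFrame(rows)
    tested = table["p_value"].notna()
    table["q_value"] = np.nan
    if tested.any():
        table.loc[tested, "q_value"] = bh_adjust(table.loc[tested, "p_value"])
    return table


# ---------------------------------------------------------------------------
# rank-sum screen
# ---------------------------------------------------------------------------

def rank_sum_test(low: np.ndarray, high: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney p for two independent expression groups.

    Exact when both groups have <= 8 observations and the pooled values are
    tie-free; otherwise the tie-corrected normal approximation with a 0.5
    continuity correction.  Returns (U statistic of the low group, p).
    """
    low = np.asarray(low, dtype=float)
    high = np.asarray(high, dtype=float)
    pooled = np.concatenate([low, high])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (low.size <= 8 and high.size <= 8 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(low, high, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class _Gate:
    n_low: int
    n_high: int
    tested: bool
    reason: str


def _gate(n_low: int, n_high: int, n_tumor: int, config: ThresholdConfig) -> _Gate:
    need = config.min_sample_fraction * n_tumor
    if config.gate_mode == "per_group":
        ok = n_low >= need and n_high >= need
        reason = "" if ok else f"group below {config.min_sample_fraction:.0%} of tumors"
    else:
        ok = (n_low + n_high) >= need and n_low >= 1 and n_high >= 1
        reason = "" if ok else f"combined groups below {config.min_sample_fraction:.0%}"
    return _Gate(n_low, n_high, ok, reason)


def wilcoxon_cnv_screen(
    expr: GeneSampleMatrix,
    cnv: GeneSampleMatrix,
    config: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Rank-sum screen of expression between low- and high-copy tumor groups.

    Only tumor samples participate.  Per gene the low group holds tumors with
    seg.mean < ``low_screen_threshold`` and the high group tumors with
    seg.mean >= ``high_screen_threshold``; the gene is tested only when each
    group passes the 20%-of-tumors gate.  Untested genes keep their skip
    reason; q-values are BH over tested genes only.
    """
    config = config or ThresholdConfig()
    genes = expr.data.index.intersection(cnv.data.index)
    tumors = [s for s in cnv.tumor_samples if s in set(expr.samples)]
    if not tumors:
        # no group labels: treat every shared sample as tumor
        tumors = [s for s in cnv.samples if s in set(expr.samples)]
    n_tumor = len(tumors)
    e = expr.data.loc[genes, tumors].to_numpy()
    c = cnv.data.loc[genes, tumors].to_numpy()
    rows = []
    for gi, gene in enumerate(genes):
        ok = np.isfinite(e[gi]) & np.isfinite(c[gi])
        low_mask = ok & (c[gi] < config.low_screen_threshold)
        high_mask = ok & (c[gi] >= config.high_screen_threshold)
        gate = _gate(int(low_mask.sum()), int(high_mask.sum()), n_tumor, config)
        stat = p = np.nan
        if gate.tested:
            stat, p = rank_sum_test(e[gi][low_mask], e[gi][high_mask])
        rows.append(
            {
                "gene_id": gene,
                "test": "wilcoxon_cnv",
                "statistic": stat,
                "p_value": p,
                "n_low": gate.n_low,
                "n_high": gate.n_high,
                "tested": gate.tested,
                "skip_reason": gate.reason,
            }
        )
    table = pd.DataFrame(rows)
    table["q_value"] = np.nan
    tested = table["tested"].to_numpy()
    if tested.any():
        table.loc[tested, "q_value"] = bh_adjust(table.loc[tested, "p_value"])
    return table


def threshold_sweep(
    expr: GeneSampleMatrix,
    cnv: GeneSampleMatrix,
    high_grid,
    low_fixed: float = -0.50,
    fdr_level: float = 0.05,
    config: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Rerun the rank-sum screen across high-copy thresholds.

    Reports, per grid value, how many genes pass the group-size gate and how
    many are significant at ``q < fdr_level`` — the gene count is a function
    of the high-copy cut, with the low cut pinned at one-copy loss.
    """
    grid = list(high_grid)
    if not grid:
        raise ValueError("high_grid must be non-empty")
    base = config or ThresholdConfig()
    rows = []
    for t in grid:
        cfg = ThresholdConfig(
            amp_threshold=base.amp_threshold,
            del_threshold=base.del_threshold,
            high_screen_threshold=float(t),
            low_screen_threshold=float(low_fixed),
            min_num_info=base.min_num_info,
            near_zero_trim=base.near_zero_trim,
            min_sample_fraction=base.min_sample_fraction,
            gate_mode=base.gate_mode,
        )
        res = wilcoxon_cnv_screen(expr, cnv, cfg)
        rows.append(
            {
                "high_threshold": float(t),
                "tested": int(res["tested"].sum()),
                "significant": int((res["q_value"] < fdr_level).sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# normal-deviation filter
# ---------------------------------------------------------------------------

def normal_deviation_filter(
    expr: GeneSampleMatrix,
    cnv: GeneSampleMatrix,
    normal_expr: GeneSampleMatrix | None = None,
    config: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Genes whose CNV-gated tumor expression deviates from tissue normals.

    A gene passes the CNV gate when at least ``min_sample_fraction`` of tumor
    samples have |seg.mean| above ``dev_threshold`` (one copy gained or
    lost).  Among gated samples the gene is retained as deviant when the
    tumor expression mean differs from the normal mean by more than one
    tumor standard deviation.
    """
    config = config or ThresholdConfig()
    genes = expr.data.index.intersection(cnv.data.index)
    tumors = [s for s in cnv.tumor_samples if s in set(expr.samples)] or [
        s for s in cnv.samples if s in set(expr.samples)
    ]
    if normal_expr is None:
        normal_cols = expr.normal_samples
        if not normal_cols:
            raise ValueError("no normal expression available")
        normal_data = expr.data.loc[genes, normal_cols]
    else:
        normal_data = normal_expr.data.reindex(genes)
    n_tumor = len(tumors)
    e = expr.data.loc[genes, tumors].to_numpy()
    c = cnv.data.loc[genes, tumors].to_numpy()
    rows = []
    for gi, gene in enumerate(genes):
        ok = np.isfinite(e[gi]) & np.isfinite(c[gi])
        gated = ok & (np.abs(c[gi]) > config.dev_threshold)
        n_gated = int(gated.sum())
        passes_gate = n_gated >= config.min_sample_fraction * n_tumor
        t_mean = t_sd = np.nan
        retained = False
        n_mean = float(np.nanmean(normal_data.loc[gene])) if len(normal_data.columns) else np.nan
        if passes_gate and n_gated >= 2 and np.isfinite(n_mean):
            vals = e[gi][gated]
            t_mean = float(vals.mean())
            t_sd = float(vals.std(ddof=1))
            retained = abs(t_mean - n_mean) > t_sd
        rows.append(
            {
                "gene_id": gene,
                "n_gated": n_gated,
                "passes_gate": bool(passes_gate),
                "tumor_mean": t_mean,
                "tumor_sd": t_sd,
                "normal_mean": n_mean,
                "retained": bool(retained),
            }
        )
    return pd.DataFrame(rows)
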