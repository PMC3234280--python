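"""Feature-quadrant classifier for tumor-suppressor-like and oncogene-like genes.

Genes at extreme copy number are placed in a methylation x expression-ratio
plane; the four quadrants, cut at the 25%/75% quantiles of the cohort-wide
distributions, define the feature classes:

* amplified + high expression ratio + low methylation  -> oncogene_like
* deleted  + low expression ratio  + high methylation  -> ts_like
* amplified + low ratio + high methylation -> amplified_suppressed
  (epigenetic silencing overriding a copy gain)
* deleted + high ratio + low methylation -> deleted_expressed
  (hypomethylation sustaining expression despite copy loss)

Each call carries tumor-vs-normal significance: per-modality Welch t-tests,
Euclidean distances between group means as effect sizes, a joint two-sample
Hotelling T^2 on the (methylation, expression) pairs, and BH q-values across
genes; passing calls are percentile-ranked by q.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import ThresholdConfig
from .io import GeneSampleMatrix
from .assignment import cnv_state_matrix
from .associations import bh_adjust

__all__ = [
    "FeatureCall",
    "QuantileThresholds",
    "select_extreme_cnv_genes",
    "tumor_normal_expression_ratio",
    "compute_quantile_thresholds",
    "classify_features",
    "class_methylation_means",
    "hotelling_t2_two_sample",
    "normal_vs_tumor_significance",
    "at_class_significance",
    "attach_significance",
    "percentile_rank_calls",
    "calls_to_frame",
]

FEATURE_CLASSES = (
    "oncogene_like",
    "ts_like",
    "amplified_suppressed",
    "deleted_expressed",
    "none",
)


@dataclass
class FeatureCall:
    gene_id: str
    cnv_class: str  # 'amplified' or 'deleted'
    meth_mean: float
    expr_ratio: float
    feature_class: str = "none"
    euclid_meth: float = np.nan
    euclid_expr: float = np.nan
    p_uni_meth: float = np.nan
    p_uni_expr: float = np.nan
    p_multi: float = np.nan
    q_multi: float = np.nan
    percentile_rank: float | None = None


@dataclass(frozen=True)
class QuantileThresholds:
    ratio_low: float
    ratio_high: float
    meth_low: float
    meth_high: float

    def __post_init__(self):
        if self.ratio_low > self.ratio_high or self.meth_low > self.meth_high:
            raise ValueError("quantile thresholds must satisfy low <= high")


def select_extreme_cnv_genes(
    cnv: GeneSampleMatrix, config: ThresholdConfig | None = None
) -> tuple[set[str], set[str]]:
    """Genes recurrently amplified / deleted across the tumor cohort.

    A gene enters the amplified class when at least ``min_sample_fraction``
    of its non-missing tumor samples sit at or above the extreme
    amplification cut (one copy gained), and the deleted class analogously
    below the extreme deletion cut (at minimum a one-copy loss); a gene may
    enter both classes through different sample subsets.
    """
    config = config or ThresholdConfig()
    tumors = cnv.tumor_samples or cnv.samples
    states = cnv_state_matrix(cnv.subset_samples(tumors), config.extreme_state_config())
    arr = states.to_numpy(dtype=object)
    amplified: set[str] = set()
    deleted: set[str] = set()
    for gi, gene in enumerate(states.index):
        row = [s for s in arr[gi] if isinstance(s, str)]
        if not row:
            continue
        n = len(row)
        if row.count("amplified") / n >= config.min_sample_fraction:
            amplified.add(gene)
        if row.count("deleted") / n >= config.min_sample_fraction:
            deleted.add(gene)
    return amplified, deleted


def tumor_normal_expression_ratio(
    expr: GeneSampleMatrix,
    donor_normals: GeneSampleMatrix | None = None,
    bootstrap_reps: int = 50,
    seed: int = 0,
    linear: bool = True,
) -> pd.Series:
    """Per-gene tumor:normal expression ratio.

    Expression matrices are log2, so with ``linear=True`` (default) means are
    taken after unlogging, matching the "tumor to normal ratio" semantics.
    When the cohort has no native normal samples, the normal mean is the
    average over ``bootstrap_reps`` bootstrap resamples (with replacement,
    size = donor normal count) of the donor cohort's normals; deterministic
    given ``seed``.
    """
    tumors = expr.tumor_samples or expr.samples
    t = expr.data[tumors].to_numpy()
    if linear:
        t = np.power(2.0, t)
    t_mean = np.nanmean(t, axis=1)

    normals = expr.normal_samples
    if normals:
        n = expr.data[normals].to_numpy()
        if linear:
            n = np.power(2.0, n)
        n_mean = np.nanmean(n, axis=1)
        n_mean = pd.Series(n_mean, index=expr.data.index)
    else:
        if donor_normals is None:
            raise ValueError("no normal samples and no donor normal matrix")
        donor_cols = donor_normals.normal_samples or donor_normals.samples
        donor = donor_normals.data[donor_cols].reindex(expr.data.index).to_numpy()
        if linear:
            donor = np.power(2.0, donor)
        rng = np.random.default_rng(seed)
        k = donor.shape[1]
        means = np.full((bootstrap_reps, donor.shape[0]), np.nan)
        for rep in range(bootstrap_reps):
            idx = rng.integers(0, k, size=k)
            means[rep] = np.nanmean(donor[:, idx], axis=1)
        n_mean = pd.Series(np.nanmean(means, axis=0), index=expr.data.index)

    ratio = pd.Series(t_mean, index=expr.data.index) / n_mean
    ratio.name = "expr_ratio"
    return ratio


def compute_quantile_thresholds(
    ratios, meth_values, q: float = 0.25
) -> QuantileThresholds:
    """Cutpoints at the q / 1-q empirical quantiles (linear interpolation)."""
    if not (0 < q <= 0.5):
        raise ValueError("q must lie in (0, 0.5]")
    r = np.asarray(ratios, dtype=float)
    m = np.asarray(meth_values, dtype=float)
    r, m = r[np.isfinite(r)], m[np.isfinite(m)]
    if r.size < 4 or m.size < 4:
        raise ValueError("need >= 4 observed values for each distribution")
    return QuantileThresholds(
        ratio_low=float(np.quantile(r, q)),
        ratio_high=float(np.quantile(r, 1 - q)),
        meth_low=float(np.quantile(m, q)),
        meth_high=float(np.quantile(m, 1 - q)),
    )


def class_methylation_means(
    meth: GeneSampleMatrix,
    cnv: GeneSampleMatrix,
    config: ThresholdConfig | None = None,
) -> dict[str, pd.Series]:
    """Per-gene tumor methylation mean over the samples in each extreme CNV
    state (the same cuts that define the feature classifier's gene sets)."""
    config = config or ThresholdConfig()
    tumors = [s for s in (cnv.tumor_samples or cnv.samples) if s in set(meth.samples)]
    states = cnv_state_matrix(cnv.subset_samples(tumors), config.extreme_state_config())
    genes = meth.data.index.intersection(states.index)
    m = meth.data.loc[genes, tumors].to_numpy()
    st = states.loc[genes].to_numpy(dtype=object)
    out = {}
    for cls in ("amplified", "deleted"):
        mask = (st == cls) & np.isfinite(m)
        with np.errstate(invalid="ignore"):
            sums = np.where(mask, m, 0.0).sum(axis=1)
            counts = mask.sum(axis=1)
            vals = np.divide(sums, counts, out=np.full(len(genes), np.nan),
                             where=counts > 0)
        out[cls] = pd.Series(vals, index=genes, name=f"meth_{cls}")
    return out


def classify_features(
    amplified_genes: set[str],
    deleted_genes: set[str],
    ratios: pd.Series,
    meth_by_class: dict[str, pd.Series],
    thresholds: QuantileThresholds,
) -> list[FeatureCall]:
    """Assign each extreme-CNV gene its feature-quadrant class.

    Exactly one class (possibly 'none') per gene per CNV class; a gene in
    both CNV classes yields two calls.
    """
    calls: list[FeatureCall] = []
    for cnv_class, members in (("amplified", amplified_genes), ("deleted", deleted_genes)):
        meth = meth_by_class.get(cnv_class, pd.Series(dtype=float))
        for gene in sorted(members):
            r = float(ratios.get(gene, np.nan))
            m = float(meth.get(gene, np.nan))
            cls = "none"
            if np.isfinite(r) and np.isfinite(m):
                high_r = r >= thresholds.ratio_high
                low_r = r <= thresholds.ratio_low
                high_m = m >= thresholds.meth_high
                low_m = m <= thresholds.meth_low
                if cnv_class == "amplified" and high_r and low_m:
                    cls = "oncogene_like"
                elif cnv_class == "deleted" and low_r and high_m:
                    cls = "ts_like"
                elif cnv_class == "amplified" and low_r and high_m:
                    cls = "amplified_suppressed"
                elif cnv_class == "deleted" and high_r and low_m:
                    cls = "deleted_expressed"
            calls.append(FeatureCall(gene, cnv_class, m, r, cls))
    return calls


# ---------------------------------------------------------------------------
# tumor-vs-normal significance
# ---------------------------------------------------------------------------

def hotelling_t2_two_sample(x: np.ndarray, y: np.ndarray):
    """Two-sample Hotelling T^2 with an F-distributed p-value.

    ``x`` (n1 x p) and ``y`` (n2 x p) are per-sample observation matrices.
    Returns (T2, F, p); p is NaN when the pooled covariance is singular or
    the group sizes cannot support the F reference (n1+n2 <= p+1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, p = x.shape
    n2 = y.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 observations")
    d = x.mean(axis=0) - y.mean(axis=0)
    s = ((n1 - 1) * np.cov(x, rowvar=False) + (n2 - 1) * np.cov(y, rowvar=False)) / (
        n1 + n2 - 2
    )
    s = np.atleast_2d(s)
    try:
        cond = np.linalg.cond(s)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        # degenerate covariance: T^2 via the pseudo-inverse is still a valid
        # effect size (it collapses to the squared pooled-variance t in the
        # non-degenerate subspace) but the F reference no longer applies
        t2 = float(n1 * n2 / (n1 + n2) * d @ np.linalg.pinv(s) @ d)
        return t2, np.nan, np.nan
    t2 = float(n1 * n2 / (n1 + n2) * d @ np.linalg.solve(s, d))
    dof2 = n1 + n2 - p - 1
    if dof2 < 1:
        return t2, np.nan, np.nan
    f = t2 * dof2 / (p * (n1 + n2 - 2))
    p_val = float(stats.f.sf(f, p, dof2))
    return t2, float(f), p_val


def normal_vs_tumor_significance(
    meth: GeneSampleMatrix,
    expr: GeneSampleMatrix,
    tumor_subsets: dict[str, list[str]] | None = None,
    adjust: bool = True,
) -> pd.DataFrame:
    """Per-gene tumor-vs-normal separation in methylation and expression.

    Euclidean distances between the tumor-mean and normal-mean vectors serve
    as effect sizes (per modality and jointly); Welch t-tests give
    per-modality p-values; a two-sample Hotelling T^2 on the joint
    (methylation, expression) sample pairs gives ``p_multi``, BH-adjusted to
    ``q_multi`` across genes.  A singular pooled covariance leaves p_multi
    missing with the univariate results retained.

    ``tumor_subsets`` optionally restricts, per gene, which tumor samples
    enter the comparison — used to test only the samples in a given CNV
    state against the normals.  ``adjust=False`` skips the BH step (for
    callers pooling several test families before adjusting).
    """
    samples = [s for s in meth.samples if s in set(expr.samples)]
    groups = {**expr.sample_groups, **meth.sample_groups}
    tumors = [s for s in samples if groups.get(s) == "tumor"]
    normals = [s for s in samples if groups.get(s) == "normal"]
    if len(tumors) < 2 or len(normals) < 2:
        raise ValueError("need >= 2 tumor and >= 2 normal samples with both modalities")
    if tumor_subsets is None:
        genes = meth.data.index.intersection(expr.data.index)
        subsets = {g: tumors for g in genes}
    else:
        shared = meth.data.index.intersection(expr.data.index)
        subsets = {
            g: [s for s in cols if s in set(tumors)]
            for g, cols in tumor_subsets.items()
            if g in shared
        }
    m_n_all = meth.data.loc[:, normals]
    e_n_all = expr.data.loc[:, normals]
    rows = []
    for gene, t_cols in subsets.items():
        empty = {
            "gene_id": gene, "n_tumor": len(t_cols), "n_normal": len(normals),
            "euclid_meth": np.nan, "euclid_expr": np.nan, "euclid_joint": np.nan,
            "p_uni_meth": np.nan, "p_uni_expr": np.nan, "t2": np.nan, "p_multi": np.nan,
        }
        if len(t_cols) < 2:
            rows.append(empty)
            continue
        mt_raw = meth.data.loc[gene, t_cols].to_numpy(dtype=float)
        et_raw = expr.data.loc[gene, t_cols].to_numpy(dtype=float)
        mn_raw = m_n_all.loc[gene].to_numpy(dtype=float)
        en_raw = e_n_all.loc[gene].to_numpy(dtype=float)
        ok_t = np.isfinite(mt_raw) & np.isfinite(et_raw)
        ok_n = np.isfinite(mn_raw) & np.isfinite(en_raw)
        if ok_t.sum() < 2 or ok_n.sum() < 2:
            rows.append(empty)
            continue
        mt, et = mt_raw[ok_t], et_raw[ok_t]
        mn, en = mn_raw[ok_n], en_raw[ok_n]
        d_m = abs(mt.mean() - mn.mean())
        d_e = abs(et.mean() - en.mean())
        p_m = float(stats.ttest_ind(mt, mn, equal_var=False).pvalue)
        p_e = float(stats.ttest_ind(et, en, equal_var=False).pvalue)
        t2, _f, p_multi = hotelling_t2_two_sample(
            np.column_stack([mt, et]), np.column_stack([mn, en])
        )
        rows.append(
            {
                "gene_id": gene,
                "n_tumor": int(ok_t.sum()),
                "n_normal": int(ok_n.sum()),
                "euclid_meth": d_m,
                "euclid_expr": d_e,
                "euclid_joint": float(np.hypot(d_m, d_e)),
                "p_uni_meth": p_m,
                "p_uni_expr": p_e,
                "t2": t2,
                "p_multi": p_multi,
            }
        )
    table = pd.DataFrame(rows)
    table["q_multi"] = np.nan
    if adjust:
        tested = table["p_multi"].notna()
        if tested.any():
            table.loc[tested, "q_multi"] = bh_adjust(table.loc[tested, "p_multi"])
    return table


def at_class_significance(
    calls: list[FeatureCall],
    meth: GeneSampleMatrix,
    expr: GeneSampleMatrix,
    cnv: GeneSampleMatrix,
    config: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Tumor-vs-normal significance restricted to each call's at-class samples.

    For every (gene, cnv_class) call, only the tumor samples whose CNV state
    matches the call's class are compared against the normals — the altered
    subpopulation carries the signal, and pooling unaltered tumors would both
    dilute the mean shift and inflate the within-group variance.  BH runs
    once across all calls.
    """
    config = config or ThresholdConfig()
    tumors = cnv.tumor_samples or cnv.samples
    states = cnv_state_matrix(cnv.subset_samples(tumors), config.extreme_state_config())
    frames = []
    for cnv_class in ("amplified", "deleted"):
        genes = sorted({c.gene_id for c in calls if c.cnv_class == cnv_class})
        genes = [g for g in genes if g in states.index]
        if not genes:
            continue
        st = states.loc[genes]
        subsets = {
            g: [s for s in tumors if st.loc[g, s] == cnv_class] for g in genes
        }
        sub = normal_vs_tumor_significance(meth, expr, subsets, adjust=False)
        sub.insert(1, "cnv_class", cnv_class)
        frames.append(sub)
    if not frames:
        return pd.DataFrame(
            columns=["gene_id", "cnv_class", "n_tumor", "n_normal", "euclid_meth",
                     "euclid_expr", "euclid_joint", "p_uni_meth", "p_uni_expr",
                     "t2", "p_multi", "q_multi"]
        )
    table = pd.concat(frames, ignore_index=True)
    table["q_multi"] = np.nan
    tested = table["p_multi"].notna()
    if tested.any():
        table.loc[tested, "q_multi"] = bh_adjust(table.loc[tested, "p_multi"])
    return table


def attach_significance(calls: list[FeatureCall], sig: pd.DataFrame) -> list[FeatureCall]:
    """Merge significance columns into the feature calls.

    Matches on (gene_id, cnv_class) when the table carries a ``cnv_class``
    column, else on gene_id alone.
    """
    keyed = "cnv_class" in sig.columns
    index = (
        sig.set_index(["gene_id", "cnv_class"]) if keyed else sig.set_index("gene_id")
    )
    for call in calls:
        key = (call.gene_id, call.cnv_class) if keyed else call.gene_id
        if key in index.index:
            row = index.loc[key]
            call.euclid_meth = float(row["euclid_meth"])
            call.euclid_expr = float(row["euclid_expr"])
            call.p_uni_meth = float(row["p_uni_meth"])
            call.p_uni_expr = float(row["p_uni_expr"])
            call.p_multi = float(row["p_multi"])
            call.q_multi = float(row["q_multi"])
    return calls


def percentile_rank_calls(
    calls: list[FeatureCall], fdr_level: float = 0.05
) -> list[FeatureCall]:
    """Percentile-rank the calls passing the FDR cut.

    Among calls with ``q_multi < fdr_level``, ascending q gives rank 1 the
    best gene and percentile ``100 * (1 - (rank-1)/(n-1))``; a single
    passing call scores 100.  Non-passing calls carry no rank.
    """
    for call in calls:
        call.percentile_rank = None
    passing = [c for c in calls if np.isfinite(c.q_multi) and c.q_multi < fdr_level]
    passing.sort(key=lambda c: (c.q_multi, c.gene_id, c.cnv_class))
    n = len(passing)
    for rank, call in enumerate(passing, start=1):
        call.percentile_rank = 100.0 if n == 1 else 100.0 * (1 - (rank - 1) / (n - 1))
    return calls


def calls_to_frame(calls: list[FeatureCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "gene_id": c.gene_id,
                "cnv_class": c.cnv_class,
                "feature_class": c.feature_class,
                "expr_ratio": c.expr_ratio,
                "meth_mean": c.meth_mean,
                "euclid_meth": c.euclid_meth,
                "euclid_expr": c.euclid_expr,
                "p_uni_meth": c.p_uni_meth,
                "p_uni_expr": c.p_uni_expr,
                "p_multi": c.p_multi,
                "q_multi": c.q_multi,
                "percentile_rank": np.nan if c.percentile_rank is None else c.percentile_rank,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "cnv_class", "feature_class", "expr_ratio", "meth_mean",
            "euclid_meth", "euclid_expr", "p_uni_meth", "p_uni_expr",
            "p_multi", "q_multi", "percentile_rank",
        ],
    )
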