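"""Segment-to-gene and probe-to-gene assignment under the inclusion rules.

The central contract: a gene receives a copy-number value for a sample only
when its locus is fully contained in exactly one CBS segment of that sample
and that segment is supported by at least ``min_num_info`` informative
markers.  Genes split across segments, uncovered genes and poorly supported
segments propagate as missing — never as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .config import ThresholdConfig, round_half_up
from .io import (
    GeneAnnotation,
    GeneSampleMatrix,
    ProbeRecord,
    SegmentRecord,
)

__all__ = [
    "assign_segments_to_genes",
    "trim_near_zero",
    "classify_cnv_state",
    "cnv_state_matrix",
    "alteration_frequency",
    "extract_breakpoints",
    "calibrate_platform_threshold",
    "CalibrationResult",
    "quantile_normalize",
    "assign_methylation_to_genes",
    "methylation_tumor_normal_ranking",
    "STATES",
]

STATES = ("amplified", "neutral", "deleted")


# ---------------------------------------------------------------------------
# segment -> gene
# ---------------------------------------------------------------------------

def _grouped_segments(segments: list[SegmentRecord]):
    """Index segments by (sample, chrom) as sorted arrays; validate layout."""
    by_key: dict[tuple[str, str], list[SegmentRecord]] = {}
    for seg in segments:
        by_key.setdefault((seg.sample_id, seg.chrom), []).append(seg)
    arrays = {}
    for key, segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.start)
        starts = np.array([s.start for s in segs])
        ends = np.array([s.end for s in segs])
        if (ends[:-1] > starts[1:]).any():
            raise ValueError(
                f"overlapping segments for sample {key[0]!r} on {key[1]}"
            )
        arrays[key] = (
            starts,
            ends,
            np.array([s.num_info for s in segs]),
            np.array([s.seg_mean for s in segs]),
        )
    return arrays


def assign_segments_to_genes(
    segments: list[SegmentRecord],
    annotation: list[GeneAnnotation],
    config: ThresholdConfig | None = None,
    sample_groups: dict[str, str] | None = None,
) -> GeneSampleMatrix:
    """Per-gene, per-sample seg.mean under full-containment inclusion.

    A cell is the seg.mean of the unique segment fully containing the gene;
    missing when the gene is uncovered, split across segments, or its segment
    has ``num_info < config.min_num_info``.
    """
    config = config or ThresholdConfig()
    arrays = _grouped_segments(segments)
    samples = sorted({s for s, _ in arrays})
    gene_ids = [g.gene_id for g in annotation]
    values = np.full((len(annotation), len(samples)), np.nan)
    for si, sample in enumerate(samples):
        for gi, gene in enumerate(annotation):
            key = (sample, gene.chrom)
            if key not in arrays:
                continue
            starts, ends, num_info, seg_mean = arrays[key]
            # candidate: last segment starting at or before the gene start
            idx = np.searchsorted(starts, gene.start, side="right") - 1
            if idx < 0:
                continue
            if ends[idx] < gene.end:
                continue  # uncovered or split across >= 2 segments
            if num_info[idx] < config.min_num_info:
                continue
            values[gi, si] = seg_mean[idx]
    data = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    groups = {s: g for s, g in (sample_groups or {}).items() if s in samples}
    return GeneSampleMatrix("cnv", data, groups)


def trim_near_zero(matrix: GeneSampleMatrix, trim_fraction: float) -> GeneSampleMatrix:
    """Mask the pooled cells closest to seg.mean 0, per sign.

    Among all strictly positive cells of the matrix, the ``trim_fraction``
    with the smallest values become missing (``ceil(trim * n)`` cells);
    symmetrically the negative cells with smallest magnitude.  Zeros are
    untouched, so 2*trim of the signed data is removed in all.
    """
    if not (0 <= trim_fraction < 0.5):
        raise ValueError("trim_fraction must lie in [0, 0.5)")
    out = matrix.copy()
    if trim_fraction == 0:
        return out
    values = out.data.to_numpy()
    flat = values.ravel()
    for sign in (+1, -1):
        idx = np.flatnonzero(np.isfinite(flat) & (np.sign(flat) == sign))
        if idx.size == 0:
            continue
        k = int(np.ceil(trim_fraction * idx.size))
        order = np.argsort(np.abs(flat[idx]), kind="stable")
        flat[idx[order[:k]]] = np.nan
    out.data = pd.DataFrame(
        flat.reshape(values.shape), index=out.data.index, columns=out.data.columns
    )
    return out


# ---------------------------------------------------------------------------
# CNV state
# ---------------------------------------------------------------------------

def classify_cnv_state(seg_mean: float, config: ThresholdConfig | None = None) -> str | float:
    """amplified iff seg.mean >= amp threshold; deleted iff < del threshold
    (strict, so a seg.mean of exactly 0.00 is neutral); missing propagates."""
    config = config or ThresholdConfig()
    if seg_mean is None or not np.isfinite(seg_mean):
        return np.nan
    if seg_mean >= config.amp_threshold:
        return "amplified"
    if seg_mean < config.del_threshold:
        return "deleted"
    return "neutral"


def cnv_state_matrix(matrix: GeneSampleMatrix, config: ThresholdConfig | None = None) -> pd.DataFrame:
    config = config or ThresholdConfig()
    vals = matrix.data.to_numpy()
    states = np.full(vals.shape, np.nan, dtype=object)
    finite = np.isfinite(vals)
    states[finite & (vals >= config.amp_threshold)] = "amplified"
    states[finite & (vals < config.del_threshold)] = "deleted"
    states[finite & (vals < config.amp_threshold) & (vals >= config.del_threshold)] = "neutral"
    return pd.DataFrame(states, index=matrix.data.index, columns=matrix.data.columns)


def alteration_frequency(states: pd.DataFrame) -> pd.DataFrame:
    """Per-gene fraction of non-missing samples in each CNV state."""
    rows = {}
    arr = states.to_numpy(dtype=object)
    for gi, gene in enumerate(states.index):
        row = arr[gi]
        observed = [s for s in row if isinstance(s, str)]
        n = len(observed)
        if n == 0:
            rows[gene] = {s: np.nan for s in STATES}
        else:
            rows[gene] = {s: observed.count(s) / n for s in STATES}
    return pd.DataFrame.from_dict(rows, orient="index").reindex(states.index)[list(STATES)]


def extract_breakpoints(
    segments: list[SegmentRecord], config: ThresholdConfig | None = None
) -> pd.DataFrame:
    """Boundaries between adjacent segments whose CNV state differs.

    Direction is 'gain'/'loss' after the state of the downstream segment when
    it is non-neutral; otherwise the transition exits the upstream non-neutral
    segment and takes its direction.
    """
    config = config or ThresholdConfig()
    arrays = _grouped_segments(segments)
    rows = []
    dir_of = {"amplified": "gain", "deleted": "loss"}
    for (sample, chrom), (starts, ends, _ni, seg_mean) in sorted(arrays.items()):
        states = [classify_cnv_state(v, config) for v in seg_mean]
        for i in range(len(starts) - 1):
            up, down = states[i], states[i + 1]
            if up == down:
                continue
            direction = dir_of.get(down) or dir_of.get(up)
            rows.append(
                {
                    "sample": sample,
                    "chrom": chrom,
                    "position": int(ends[i]),
                    "direction": direction,
                }
            )
    return pd.DataFrame(rows, columns=["sample", "chrom", "position", "direction"])


# ---------------------------------------------------------------------------
# platform threshold calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    threshold: float
    sensitivity: float
    fpr: float
    table: pd.DataFrame  # per grid value: threshold, sensitivity, fpr, objective


def calibrate_platform_threshold(
    matrix_a: GeneSampleMatrix,
    matrix_b: GeneSampleMatrix,
    shared_samples: list[str],
    reference_config: ThresholdConfig | None = None,
    grid: np.ndarray | list[float] | None = None,
) -> CalibrationResult:
    """Pick the platform-B deletion threshold that best reproduces platform A.

    Reference deletion calls are made on ``matrix_a`` with the reference
    deletion threshold; for each grid value ``t`` platform B calls a cell
    deleted when its value is ``< t``.  The returned threshold maximizes
    sensitivity-to-deleted minus the false-positive rate among amplified or
    neutral reference cells; ties go to the threshold nearest 0.
    """
    reference_config = reference_config or ThresholdConfig(del_threshold=-0.50)
    shared = list(shared_samples)
    if not shared:
        raise ValueError("calibration requires at least one shared sample")
    if grid is None:
        grid = np.round(np.arange(-1.0, 0.0001, 0.05), 10)
    genes = matrix_a.data.index.intersection(matrix_b.data.index)
    a = matrix_a.data.loc[genes, shared].to_numpy().ravel()
    b = matrix_b.data.loc[genes, shared].to_numpy().ravel()
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    ref_del = a < reference_config.del_threshold
    n_pos = int(ref_del.sum())
    n_neg = int((~ref_del).sum())
    rows = []
    for t in grid:
        pred = b < t
        sens = (pred & ref_del).sum() / n_pos if n_pos else 0.0
        fpr = (pred & ~ref_del).sum() / n_neg if n_neg else 0.0
        rows.append(
            {"threshold": float(t), "sensitivity": sens, "fpr": fpr,
             "objective": sens - fpr}
        )
    table = pd.DataFrame(rows)
    best_obj = table["objective"].max()
    tied = table[np.isclose(table["objective"], best_obj)]
    best = tied.loc[tied["threshold"].abs().idxmin()]
    return CalibrationResult(
        float(best["threshold"]), float(best["sensitivity"]), float(best["fpr"]), table
    )


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: GeneSampleMatrix) -> GeneSampleMatrix:
    """Force every sample (column) onto the common reference distribution.

    The reference is the row-wise mean of the sorted columns (for columns of
    unequal observed length, each column's sorted values are interpolated to
    the probe grid of the target column).  Within-column rank order is
    preserved; tied entries receive the mean of the reference values at their
    tied ranks; missing cells are excluded and reinserted as missing.
    """
    if matrix.data.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    values = matrix.data.to_numpy(dtype=float)
    cols = [values[:, j][np.isfinite(values[:, j])] for j in range(values.shape[1])]
    for j, c in enumerate(cols):
        if c.size < 2:
            raise ValueError(
                f"column {matrix.data.columns[j]!r} has fewer than 2 observed values"
            )
    sorted_cols = [np.sort(c) for c in cols]
    out = np.full_like(values, np.nan)
    for j in range(values.shape[1]):
        col = values[:, j]
        obs = np.isfinite(col)
        n = int(obs.sum())
        probs = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5])
        # reference vector on this column's rank grid
        ref = np.zeros(n)
        for sc in sorted_cols:
            if sc.size == n:
                ref += sc
            else:
                ref += np.quantile(sc, probs)
        ref /= len(sorted_cols)
        ranks = rankdata(col[obs], method="average")  # 1-based, ties averaged
        # map (possibly fractional) average ranks onto the reference vector
        normalized = np.empty(n)
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        frac = ranks - np.floor(ranks)
        normalized = ref[lo] * (1 - frac) + ref[hi] * frac
        # tied entries must share the mean of the reference values over the
        # whole tied run, not just the two values bracketing the average rank
        vals_obs = col[obs]
        uniq, inv, counts = np.unique(vals_obs, return_inverse=True, return_counts=True)
        if (counts > 1).any():
            order = np.argsort(vals_obs, kind="stable")
            pos = 0
            ref_mean = np.empty(len(uniq))
            for ui in range(len(uniq)):
                c = counts[ui]
                ref_mean[ui] = ref[pos:pos + c].mean()
                pos += c
            normalized = ref_mean[inv]
        out[obs, j] = normalized
    result = matrix.copy()
    result.data = pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    return result


# ---------------------------------------------------------------------------
# probe -> gene methylation
# ---------------------------------------------------------------------------

def _closest_gene(
    midpoint: float, chrom: str, annotation: list[GeneAnnotation]
) -> str | None:
    """Nearest TSS-proximal gene end to a fragment/probe midpoint.

    Ties break by smaller distance to the gene body, then lexicographic id.
    """
    best = None
    for g in annotation:
        if g.chrom != chrom:
            continue
        d_tss = abs(midpoint - g.tss)
        if g.start <= midpoint < g.end:
            d_body = 0.0
        else:
            d_body = min(abs(midpoint - g.start), abs(midpoint - g.end))
        key = (d_tss, d_body, g.gene_id)
        if best is None or key < best[0]:
            best = (key, g.gene_id)
    return best[1] if best else None


def assign_methylation_to_genes(
    probes: list[ProbeRecord],
    annotation: list[GeneAnnotation],
    dialect: str,
) -> GeneSampleMatrix:
    """Collapse probe-level methylation to a gene x sample matrix.

    moma_ratio: per fragment, the maximum probe score per sample; each
    fragment goes to the gene whose TSS is nearest its midpoint; per gene,
    the maximum over its fragments.  beta: per gene, the mean over its
    probes, missing unless the gene has >= 2 probes.
    """
    if dialect not in ("moma_ratio", "beta"):
        raise ValueError(f"unknown methylation dialect {dialect!r}")
    if not probes:
        raise ValueError("no probes given")
    samples = [s for s, _ in probes[0].values]
    gene_ids = [g.gene_id for g in annotation]
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    values = np.full((len(gene_ids), len(samples)), np.nan)

    if dialect == "moma_ratio":
        fragments: dict[str, list[ProbeRecord]] = {}
        for p in probes:
            fragments.setdefault(p.fragment_id, []).append(p)
        for fid, frag_probes in sorted(fragments.items()):
            probe_vals = np.array(
                [[v for _, v in p.values] for p in frag_probes], dtype=float
            )
            if not np.isfinite(probe_vals).any():
                warnings.warn(f"fragment {fid!r} has no observed probe values; skipped")
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
                frag_val = np.nanmax(probe_vals, axis=0)
            start = min(p.start for p in frag_probes)
            end = max(p.end for p in frag_probes)
            gene = _closest_gene(0.5 * (start + end), frag_probes[0].chrom, annotation)
            if gene is None:
                continue
            gi = gene_pos[gene]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                values[gi] = np.fmax(values[gi], frag_val)
    else:  # beta
        per_gene: dict[str, list[np.ndarray]] = {}
        for p in sorted(probes, key=lambda p: p.probe_id):
            gene = _closest_gene(0.5 * (p.start + p.end), p.chrom, annotation)
            if gene is None:
                continue
            per_gene.setdefault(gene, []).append(
                np.array([v for _, v in p.values], dtype=float)
            )
        for gene, rows in per_gene.items():
            if len(rows) < 2:
                continue  # "2 or more probes" rule
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                values[gene_pos[gene]] = np.nanmean(np.vstack(rows), axis=0)

    data = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    return GeneSampleMatrix("methylation", data, dialect=dialect)


# ---------------------------------------------------------------------------
# tumor:normal methylation ranking
# ---------------------------------------------------------------------------

def methylation_tumor_normal_ranking(
    meth: GeneSampleMatrix, extreme_fraction: float = 0.10
) -> pd.DataFrame:
    """Rank genes by mean(tumor)/mean(normal) methylation ratio.

    Genes in the top ``extreme_fraction`` of the ratio distribution are
    flagged hypermethylated, the bottom fraction hypomethylated (the study's
    10% tails of the tumor:normal ratio distribution).
    """
    tumors = meth.tumor_samples
    normals = meth.normal_samples
    if not normals:
        raise ValueError("ranking requires >= 1 normal sample")
    t_mean = meth.data[tumors].mean(axis=1, skipna=True)
    n_mean = meth.data[normals].mean(axis=1, skipna=True)
    bad = ~np.isfinite(n_mean) | (n_mean == 0) | ~np.isfinite(t_mean)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} gene(s) skipped: zero or missing normal methylation mean"
        )
    ratio = (t_mean / n_mean)[~bad]
    table = pd.DataFrame(
        {"gene_id": ratio.index, "ratio": ratio.values}
    ).sort_values("ratio", ascending=False, kind="stable").reset_index(drop=True)
    k = round_half_up(extreme_fraction * len(table))
    flags = np.array([""] * len(table), dtype=object)
    if k > 0:
        flags[:k] = "hypermethylated"
        flags[len(table) - k:] = "hypomethylated"
    table["flag"] = flags
    return table
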