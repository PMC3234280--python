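"""Synthetic tumor/normal cohort generator with planted ground truth.

The generator emits everything the pipeline consumes from disk — a SEG-style
segment table, a BED gene annotation, methylation and expression matrices and
a sample-group table — plus a per-gene truth table recording which feature
class (if any) was planted.

Model
-----
Genes are tiled without overlap on ``n_chromosomes`` simulated chromosomes,
one gene per 10 kb tile.  Per sample, each tile is one CBS-style segment, so
segments partition every chromosome and every gene lies fully inside exactly
one segment — the clean case of the assignment rules.  Edge cases (split
genes, low num.info) are injected afterwards with :func:`inject_edge_cases`.

For a planted gene, an ``altered_sample_fraction`` of tumor samples carries
the alteration; in those cells

* ``seg.mean ~ d_cnv * cnv_effect + N(0, jitter)``
* ``methylation = center + d_meth * meth_effect + noise``

and expression always follows the dosage/repression model

``log2 expr = baseline + slope * seg.mean - coupling * (meth - center) + noise``

so over-expression of an amplified hypomethylated gene (and the mirror-image
suppression of a deleted hypermethylated gene) emerges from the model rather
than being written into the expression matrix directly.  Normal samples sit at
the reference state in all modalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PLANTED_CLASSES, SimulationConfig, round_half_up
from .io import (
    GeneAnnotation,
    GeneSampleMatrix,
    SegmentRecord,
    write_bed,
    write_matrix,
    write_sample_groups,
    write_segments,
)

__all__ = ["SyntheticTruth", "Cohort", "EdgeCaseSpec", "generate_cohort",
           "inject_edge_cases", "write_cohort"]

GENE_TILE = 10_000  # bp per gene tile; the gene body occupies the middle 2 kb
GENE_BODY = (4_000, 6_000)

#: (copy-number direction, methylation direction) per planted class
CLASS_DIRECTIONS = {
    "oncogene_like": (+1, -1),
    "ts_like": (-1, +1),
    "amplified_suppressed": (+1, +1),
    "deleted_expressed": (-1, -1),
}


@dataclass
class SyntheticTruth:
    """Planted per-gene class and realized effect sizes.

    ``table`` columns: gene_id, planted_class, cnv_direction, meth_direction,
    cnv_effect, meth_effect, expr_effect (expected log2 shift in altered
    cells), altered_samples (comma-joined sample ids; empty for null genes).
    """

    table: pd.DataFrame

    def planted(self, cls: str | None = None) -> list[str]:
        t = self.table
        if cls is None:
            sel = t["planted_class"] != "null"
        else:
            sel = t["planted_class"] == cls
        return t.loc[sel, "gene_id"].tolist()

    def class_of(self, gene_id: str) -> str:
        return self.table.set_index("gene_id").loc[gene_id, "planted_class"]


@dataclass
class Cohort:
    segments: list[SegmentRecord]
    annotation: list[GeneAnnotation]
    methylation: GeneSampleMatrix
    expression: GeneSampleMatrix
    sample_groups: dict[str, str]
    truth: SyntheticTruth

    @property
    def tumor_samples(self) -> list[str]:
        return [s for s, g in self.sample_groups.items() if g == "tumor"]

    @property
    def normal_samples(self) -> list[str]:
        return [s for s, g in self.sample_groups.items() if g == "normal"]


def _planted_assignment(cfg: SimulationConfig, rng: np.random.Generator) -> list[str]:
    """Assign classes to gene indices: round-half-up counts, remainder null."""
    classes = ["null"] * cfg.n_genes
    order = rng.permutation(cfg.n_genes)
    cursor = 0
    for cls in PLANTED_CLASSES:  # fixed class order for determinism
        frac = cfg.planted_fractions.get(cls, 0.0)
        k = round_half_up(frac * cfg.n_genes)
        for idx in order[cursor:cursor + k]:
            classes[idx] = cls
        cursor += k
    return classes


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Simulate a full multi-omic cohort; deterministic given ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    tumors = [f"T{i + 1:03d}" for i in range(cfg.n_tumor)]
    normals = [f"N{i + 1:03d}" for i in range(cfg.n_normal)]
    samples = tumors + normals
    groups = {**{s: "tumor" for s in tumors}, **{s: "normal" for s in normals}}

    # --- gene layout: contiguous blocks of tiles per chromosome -------------
    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chromosomes))
    annotation: list[GeneAnnotation] = []
    gene_chrom: list[str] = []
    gene_tile: list[tuple[int, int]] = []
    for gi in range(cfg.n_genes):
        chrom = f"chr{gi // per_chrom + 1}"
        offset = (gi % per_chrom) * GENE_TILE
        annotation.append(
            GeneAnnotation(
                f"G{gi + 1:05d}", chrom, offset + GENE_BODY[0], offset + GENE_BODY[1], "+"
            )
        )
        gene_chrom.append(chrom)
        gene_tile.append((offset, offset + GENE_TILE))

    classes = _planted_assignment(cfg, rng)

    # --- per-gene, per-sample modality values -------------------------------
    n_alt = round_half_up(cfg.altered_sample_fraction * cfg.n_tumor)
    center = cfg.platform_center
    sd = cfg.noise_sd
    baseline = rng.normal(cfg.expr_baseline_mean, cfg.expr_baseline_sd, cfg.n_genes)

    seg_vals = np.empty((cfg.n_genes, len(samples)))
    meth_vals = np.empty((cfg.n_genes, len(samples)))
    truth_rows = []
    altered_lists: list[str] = []

    n_t = cfg.n_tumor
    for gi in range(cfg.n_genes):
        cls = classes[gi]
        # tumor reference state
        seg_t = rng.normal(0.0, sd["cnv"], n_t)
        meth_t = center + rng.normal(0.0, sd["methylation"], n_t)
        altered: np.ndarray = np.array([], dtype=int)
        d_cnv = d_meth = 0
        if cls != "null":
            d_cnv, d_meth = CLASS_DIRECTIONS[cls]
            altered = rng.choice(n_t, size=n_alt, replace=False)
            seg_t[altered] = d_cnv * cfg.cnv_effect + rng.normal(
                0.0, cfg.cnv_effect_jitter, n_alt
            )
            meth_t[altered] = (
                center + d_meth * cfg.meth_effect
                + rng.normal(0.0, sd["methylation"], n_alt)
            )
        seg_n = rng.normal(0.0, cfg.normal_cnv_sd, cfg.n_normal)
        meth_n = center + rng.normal(0.0, sd["methylation"], cfg.n_normal)
        seg_vals[gi] = np.concatenate([seg_t, seg_n])
        meth_vals[gi] = np.concatenate([meth_t, meth_n])
        altered_lists.append(",".join(tumors[i] for i in sorted(altered)))
        expr_effect = (
            d_cnv * cfg.cnv_effect * cfg.expr_dosage_slope
            - cfg.meth_coupling * d_meth * cfg.meth_effect
        )
        truth_rows.append(
            {
                "gene_id": annotation[gi].gene_id,
                "planted_class": cls,
                "cnv_direction": d_cnv,
                "meth_direction": d_meth,
                "cnv_effect": abs(d_cnv) * cfg.cnv_effect,
                "meth_effect": abs(d_meth) * cfg.meth_effect,
                "expr_effect": expr_effect if cls != "null" else 0.0,
            }
        )

    if cfg.methylation_dialect == "beta":
        meth_vals = np.clip(meth_vals, 0.01, 0.99)

    expr_vals = (
        baseline[:, None]
        + cfg.expr_dosage_slope * seg_vals
        - cfg.meth_coupling * (meth_vals - center)
        + rng.normal(0.0, sd["expression"], seg_vals.shape)
    )

    # --- segments: one per gene tile, partitioning each chromosome ----------
    num_info = rng.integers(10, 61, size=(cfg.n_genes, len(samples)))
    segments: list[SegmentRecord] = []
    for si, sample in enumerate(samples):
        for gi in range(cfg.n_genes):
            start, end = gene_tile[gi]
            segments.append(
                SegmentRecord(
                    sample, gene_chrom[gi], start, end,
                    int(num_info[gi, si]), float(seg_vals[gi, si]),
                )
            )

    gene_ids = pd.Index([g.gene_id for g in annotation], name="gene_id")
    meth = GeneSampleMatrix(
        "methylation",
        pd.DataFrame(meth_vals, index=gene_ids, columns=samples),
        dict(groups),
        dialect=cfg.methylation_dialect,
    )
    expr = GeneSampleMatrix(
        "expression",
        pd.DataFrame(expr_vals, index=gene_ids, columns=samples),
        dict(groups),
    )
    truth_frame = pd.DataFrame(truth_rows)
    truth_frame["altered_samples"] = altered_lists
    return Cohort(segments, annotation, meth, expr, groups, SyntheticTruth(truth_frame))


# ---------------------------------------------------------------------------
# edge-case injection
# ---------------------------------------------------------------------------

@dataclass
class EdgeCaseSpec:
    """Named (gene, sample) pairs to corrupt so exclusion rules fire.

    ``split`` splits the covering segment at the gene midpoint so the gene
    spans two segments; ``low_num_info`` drops the covering segment's marker
    count to ``num_info_value`` (below the default inclusion threshold).
    """

    split: list[tuple[str, str]] = field(default_factory=list)
    low_num_info: list[tuple[str, str]] = field(default_factory=list)
    num_info_value: int = 3


def inject_edge_cases(
    segments: list[SegmentRecord],
    spec: EdgeCaseSpec,
    annotation: list[GeneAnnotation],
) -> list[SegmentRecord]:
    """Return a new segment list with the requested corner cases planted."""
    genes = {g.gene_id: g for g in annotation}
    samples = {s.sample_id for s in segments}

    def covering_index(gene_id: str, sample: str) -> int:
        if gene_id not in genes:
            raise KeyError(f"unknown gene id {gene_id!r}")
        if sample not in samples:
            raise KeyError(f"unknown sample id {sample!r}")
        g = genes[gene_id]
        for i, seg in enumerate(out):
            if (
                seg.sample_id == sample
                and seg.chrom == g.chrom
                and seg.start <= g.start
                and seg.end >= g.end
            ):
                return i
        raise KeyError(f"no segment fully covers {gene_id!r} in sample {sample!r}")

    out = list(segments)
    for gene_id, sample in spec.split:
        i = covering_index(gene_id, sample)
        seg = out[i]
        g = genes[gene_id]
        mid = (g.start + g.end) // 2
        left_info = max(1, seg.num_info // 2)
        right_info = max(1, seg.num_info - left_info)
        out[i] = SegmentRecord(
            seg.sample_id, seg.chrom, seg.start, mid, left_info, seg.seg_mean
        )
        out.insert(
            i + 1,
            SegmentRecord(
                seg.sample_id, seg.chrom, mid, seg.end, right_info, seg.seg_mean
            ),
        )
    for gene_id, sample in spec.low_num_info:
        i = covering_index(gene_id, sample)
        seg = out[i]
        out[i] = SegmentRecord(
            seg.sample_id, seg.chrom, seg.start, seg.end,
            spec.num_info_value, seg.seg_mean,
        )
    return out


# ---------------------------------------------------------------------------
# on-disk cohort
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, outdir) -> dict[str, str]:
    """Write every pipeline input file; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "segments": outdir / "segments.seg",
        "annotation": outdir / "genes.bed",
        "methylation": outdir / "methylation.tsv",
        "expression": outdir / "expression.tsv",
        "sample_groups": outdir / "sample_groups.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_segments(cohort.segments, paths["segments"])
    write_bed(cohort.annotation, paths["annotation"])
    write_matrix(cohort.methylation, paths["methylation"])
    write_matrix(cohort.expression, paths["expression"])
    write_sample_groups(cohort.sample_groups, paths["sample_groups"])
    cohort.truth.table.to_csv(paths["truth"], sep="\t", index=False, float_format="%.6g")
    return {k: str(v) for k, v in paths.items()}
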