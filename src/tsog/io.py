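"""Readers and writers for every on-disk format the pipeline touches.

All genomic intervals are held internally as 0-based half-open ``[start, end)``.
SEG-style segment tables are assumed 1-based inclusive on disk (the convention
of CBS output); BED is 0-based half-open.  The conversion happens exactly once,
at this I/O boundary.

Missing values are explicit (``NaN`` in matrices, ``"NA"`` on disk) and are
never silently replaced by zero: a gene excluded by a coverage rule must stay
distinguishable from a copy-neutral gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "SegmentRecord",
    "GeneAnnotation",
    "GeneSampleMatrix",
    "GeneSetCollection",
    "ProbeRecord",
    "read_segments",
    "write_segments",
    "segments_to_frame",
    "read_bed",
    "write_bed",
    "read_matrix",
    "write_matrix",
    "read_gmt",
    "write_gmt",
    "read_sample_groups",
    "write_sample_groups",
    "read_probes",
    "write_probes",
]

SEG_COLUMNS = ["sample", "chrom", "loc.start", "loc.end", "num.info", "seg.mean"]

MODALITIES = ("cnv", "methylation", "expression")

#: on-disk marker for a missing cell
NA_TOKEN = "NA"

#: fixed float formatting used by every writer so that identical in-memory
#: objects always serialize byte-identically
FLOAT_FMT = "%.6g"


class FormatError(ValueError):
    """A malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass(frozen=True)
class SegmentRecord:
    """One CBS segment: a constant-copy-ratio run of probes for one sample."""

    sample_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    num_info: int  # informative marker count supporting the segment
    seg_mean: float  # mean log2 copy ratio

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"segment {self.sample_id}/{self.chrom}: start >= end")
        if self.num_info < 1:
            raise ValueError("num_info must be >= 1")
        if not np.isfinite(self.seg_mean):
            raise ValueError("seg_mean must be finite")


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start >= end")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def tss(self) -> int:
        """Transcription start position (strand-aware; '.' treated as '+')."""
        return self.start if self.strand in ("+", ".") else self.end

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class GeneSampleMatrix:
    """Genes x samples numeric matrix for one modality.

    ``data`` is a float DataFrame (rows = gene ids, columns = sample ids,
    ``NaN`` = missing).  ``sample_groups`` maps sample id -> 'tumor'/'normal'.
    """

    modality: str
    data: pd.DataFrame
    sample_groups: dict[str, str] = field(default_factory=dict)
    dialect: str | None = None  # methylation only: 'moma_ratio' or 'beta'

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise FormatError(f"duplicate gene ids: {dups[:5]}")
        if self.data.columns.duplicated().any():
            raise FormatError("duplicate sample ids")
        self.data = self.data.astype(float)
        if self.modality == "methylation" and self.dialect == "beta":
            vals = self.data.to_numpy()
            bad = vals[np.isfinite(vals)]
            if bad.size and ((bad < 0) | (bad > 1)).any():
                raise FormatError("beta-dialect methylation values must lie in [0, 1]")
        unknown = set(self.sample_groups) - set(self.data.columns)
        if unknown:
            raise FormatError(f"sample_groups mention unknown samples: {sorted(unknown)[:5]}")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.data.columns if self.sample_groups.get(s) == group]

    @property
    def tumor_samples(self) -> list[str]:
        return self.samples_in_group("tumor")

    @property
    def normal_samples(self) -> list[str]:
        return self.samples_in_group("normal")

    def subset_samples(self, samples) -> "GeneSampleMatrix":
        samples = list(samples)
        groups = {s: g for s, g in self.sample_groups.items() if s in samples}
        return replace(self, data=self.data[samples], sample_groups=groups)

    def copy(self) -> "GeneSampleMatrix":
        return replace(self, data=self.data.copy(), sample_groups=dict(self.sample_groups))


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): set id -> (description, member ids)."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self):
        for sid, (_, members) in self.sets.items():
            if not members:
                raise FormatError(f"gene set {sid!r} is empty")

    def __len__(self):
        return len(self.sets)

    def members(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id][1]


@dataclass(frozen=True)
class ProbeRecord:
    """One methylation probe with its per-sample scores.

    For the MOMA dialect several probes tile one MspI fragment
    (``fragment_id``); for the Infinium/beta dialect fragment_id may simply
    repeat the probe id.
    """

    probe_id: str
    fragment_id: str
    chrom: str
    start: int
    end: int
    values: tuple[tuple[str, float], ...]  # (sample, score); NaN = missing

    def value_dict(self) -> dict[str, float]:
        return dict(self.values)


# ---------------------------------------------------------------------------
# SEG
# ---------------------------------------------------------------------------

def read_segments(path) -> list[SegmentRecord]:
    """Parse a SEG-style tab-delimited file into :class:`SegmentRecord` list.

    On-disk coordinates are 1-based inclusive and converted to the internal
    0-based half-open convention.  Rows with non-numeric fields are rejected
    with the offending line number.
    """
    records: list[SegmentRecord] = []
    with open(path) as fh:
        header = fh.readline()
        if not header:
            raise FormatError("empty file", line=1)
        cols = header.rstrip("\n").split("\t")
        if cols != SEG_COLUMNS:
            missing = [c for c in SEG_COLUMNS if c not in cols]
            raise FormatError(f"bad SEG header; missing columns {missing}", line=1)
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != len(SEG_COLUMNS):
                raise FormatError(
                    f"expected {len(SEG_COLUMNS)} fields, got {len(parts)}", line=lineno
                )
            sample, chrom, s, e, ni, sm = parts
            try:
                start1 = int(s)
                end1 = int(e)
                num_info = int(ni)
                seg_mean = float(sm)
            except ValueError as exc:
                raise FormatError(f"non-numeric segment field: {exc}", line=lineno) from None
            if not np.isfinite(seg_mean):
                raise FormatError("seg.mean must be finite", line=lineno)
            try:
                records.append(
                    SegmentRecord(sample, chrom, start1 - 1, end1, num_info, seg_mean)
                )
            except ValueError as exc:
                raise FormatError(str(exc), line=lineno) from None
    return records


def write_segments(records: list[SegmentRecord], path) -> None:
    """Write segments back to the on-disk 1-based inclusive SEG convention."""
    with open(path, "w") as fh:
        fh.write("\t".join(SEG_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.sample_id}\t{r.chrom}\t{r.start + 1}\t{r.end}\t"
                f"{r.num_info}\t{FLOAT_FMT % r.seg_mean}\n"
            )


def segments_to_frame(records: list[SegmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [r.sample_id for r in records],
            "chrom": [r.chrom for r in records],
            "start": [r.start for r in records],
            "end": [r.end for r in records],
            "num_info": [r.num_info for r in records],
            "seg_mean": [r.seg_mean for r in records],
        }
    )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path) -> list[GeneAnnotation]:
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith(("#", "track", "browser")):
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise FormatError("BED line needs >= 4 fields (chrom start end name)", lineno)
            chrom, s, e, name = parts[:4]
            strand = parts[5] if len(parts) >= 6 else "."
            try:
                start, end = int(s), int(e)
            except ValueError:
                raise FormatError("non-integer BED coordinate", lineno) from None
            if start >= end:
                raise FormatError(f"BED interval start >= end for {name!r}", lineno)
            if name in seen:
                raise FormatError(f"duplicate gene id {name!r}", lineno)
            seen.add(name)
            try:
                genes.append(GeneAnnotation(name, chrom, start, end, strand))
            except ValueError as exc:
                raise FormatError(str(exc), lineno) from None
    return genes


def write_bed(genes: list[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def read_matrix(path, modality: str, sample_groups: dict[str, str] | None = None,
                dialect: str | None = None) -> GeneSampleMatrix:
    """Read a genes x samples TSV (first column ``gene_id``, ``NA`` = missing)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2 or header[0] != "gene_id":
            raise FormatError("matrix header must start with 'gene_id'", line=1)
        samples = header[1:]
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise FormatError(
                    f"ragged row: expected {len(header)} fields, got {len(parts)}", lineno
                )
            gene_ids.append(parts[0])
            try:
                rows.append(
                    [np.nan if v == NA_TOKEN else float(v) for v in parts[1:]]
                )
            except ValueError:
                raise FormatError("non-numeric matrix cell", lineno) from None
    data = pd.DataFrame(rows, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    if sample_groups is not None:
        unknown = set(sample_groups) - set(samples)
        if unknown:
            raise FormatError(f"groups file mentions unknown samples: {sorted(unknown)[:5]}")
    return GeneSampleMatrix(modality, data, dict(sample_groups or {}), dialect=dialect)


def write_matrix(matrix: GeneSampleMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(map(str, matrix.samples)) + "\n")
        values = matrix.data.to_numpy()
        for gene, row in zip(matrix.genes, values):
            cells = [NA_TOKEN if not np.isfinite(v) else FLOAT_FMT % v for v in row]
            fh.write(str(gene) + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# GMT / sample groups / probes
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError("GMT line needs set id, description and >=1 member", lineno)
            sid, desc = parts[0], parts[1]
            members = frozenset(m for m in parts[2:] if m)
            if not members:
                raise FormatError(f"gene set {sid!r} has no members", lineno)
            if sid in sets:
                raise FormatError(f"duplicate gene set id {sid!r}", lineno)
            sets[sid] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for sid, (desc, members) in collection.sets.items():
            fh.write(sid + "\t" + desc + "\t" + "\t".join(sorted(members)) + "\n")


def read_sample_groups(path) -> dict[str, str]:
    groups: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise FormatError("groups file needs exactly 2 columns", lineno)
            sample, group = parts
            if sample == "sample_id":  # optional header
                continue
            if group not in ("tumor", "normal"):
                raise FormatError(f"unknown sample group {group!r}", lineno)
            if sample in groups:
                raise FormatError(f"duplicate sample {sample!r}", lineno)
            groups[sample] = group
    return groups


def write_sample_groups(groups: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sample, group in groups.items():
            fh.write(f"{sample}\t{group}\n")


PROBE_FIXED = ["probe_id", "fragment_id", "chrom", "start", "end"]


def read_probes(path) -> list[ProbeRecord]:
    """Probe-level methylation TSV: fixed columns then one column per sample."""
    records: list[ProbeRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(PROBE_FIXED)] != PROBE_FIXED:
            raise FormatError(f"probe table must start with columns {PROBE_FIXED}", line=1)
        samples = header[len(PROBE_FIXED):]
        if not samples:
            raise FormatError("probe table has no sample columns", line=1)
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise FormatError("ragged probe row", lineno)
            pid, fid, chrom, s, e = parts[: len(PROBE_FIXED)]
            try:
                start, end = int(s), int(e)
                vals = tuple(
                    (smp, np.nan if v == NA_TOKEN else float(v))
                    for smp, v in zip(samples, parts[len(PROBE_FIXED):])
                )
            except ValueError:
                raise FormatError("non-numeric probe field", lineno) from None
            if start >= end:
                raise FormatError(f"probe {pid!r}: start >= end", lineno)
            records.append(ProbeRecord(pid, fid, chrom, start, end, vals))
    return records


def write_probes(records: list[ProbeRecord], path) -> None:
    if not records:
        raise ValueError("no probe records to write")
    samples = [s for s, _ in records[0].values]
    with open(path, "w") as fh:
        fh.write("\t".join(PROBE_FIXED + samples) + "\n")
        for r in records:
            vals = r.value_dict()
            cells = [
                NA_TOKEN if not np.isfinite(vals[s]) else FLOAT_FMT % vals[s] for s in samples
            ]
            fh.write(
                f"{r.probe_id}\t{r.fragment_id}\t{r.chrom}\t{r.start}\t{r.end}\t"
                + "\t".join(cells) + "\n"
            )


def _warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
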