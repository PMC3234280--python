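"""End-to-end stage orchestration with deterministic seeding and a manifest.

Stages (``simulate``, ``assign``, ``associate``, ``classify``, ``enrich``)
each read their inputs from disk, write new TSV artifacts (inputs are never
mutated) and log every filter with in/out counts — the screens' headline
numbers are filter-survivor counts, so the counts are part of the result.
A run manifest records the config, seed, package version and the SHA-256 of
every artifact; two runs with the same config and seed produce byte-identical
artifacts and manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import ConfigError, SimulationConfig, ThresholdConfig
from .io import (
    GeneSampleMatrix,
    read_bed,
    read_gmt,
    read_matrix,
    read_sample_groups,
    read_segments,
    write_matrix,
)
from .synthetic import generate_cohort, write_cohort
from .assignment import (
    alteration_frequency,
    assign_segments_to_genes,
    cnv_state_matrix,
    extract_breakpoints,
    methylation_tumor_normal_ranking,
    trim_near_zero,
)
from .associations import (
    cnv_expression_cdf_gap,
    expression_by_cnv_bins,
    normal_deviation_filter,
    per_gene_correlation,
    wilcoxon_cnv_screen,
)
from .classifier import (
    at_class_significance,
    attach_significance,
    calls_to_frame,
    class_methylation_means,
    classify_features,
    compute_quantile_thresholds,
    normal_vs_tumor_significance,
    percentile_rank_calls,
    select_extreme_cnv_genes,
    tumor_normal_expression_ratio,
)
from .enrichment import enrichment_to_frame, hypergeometric_enrichment

log = logging.getLogger("tsog")

STAGES = ("simulate", "assign", "associate", "classify", "enrich")

_FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """One config object for every stage; loadable from YAML."""

    outdir: str = "tsog_run"
    seed: int = 0
    fdr_level: float = 0.05
    quantile_q: float = 0.25
    bootstrap_reps: int = 50
    extreme_fraction: float = 0.10
    methylation_dialect: str = "beta"
    linear_ratio: bool = True
    cdf_bin_edges: list[float] = field(
        default_factory=lambda: [-2.0, -1.0, -0.5, -0.25, 0.0, 0.25, 0.5, 1.0, 2.0]
    )
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    #: input paths; filled by the simulate stage or provided by the user
    inputs: dict[str, str] = field(default_factory=dict)
    gmt_path: str | None = None

    KNOWN_KEYS = {
        "outdir", "seed", "fdr_level", "quantile_q", "bootstrap_reps",
        "extreme_fraction", "methylation_dialect", "linear_ratio",
        "cdf_bin_edges", "thresholds", "simulation", "inputs", "gmt_path",
    }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - cls.KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = dict(raw)
        if "thresholds" in kwargs:
            kwargs["thresholds"] = ThresholdConfig(**kwargs["thresholds"])
        if "simulation" in kwargs:
            kwargs["simulation"] = SimulationConfig(**kwargs["simulation"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in self.KNOWN_KEYS
            if k not in ("thresholds", "simulation")
        }
        d["thresholds"] = self.thresholds.to_dict()
        d["simulation"] = self.simulation.to_dict()
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_frame(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, na_rep="NA")


@dataclass
class Manifest:
    config: dict
    seed: int
    version: str = __version__
    artifacts: dict[str, dict] = field(default_factory=dict)
    counts: dict[str, int | float] = field(default_factory=dict)
    failed_stage: str | None = None

    def add(self, name: str, path: Path, rows: int | None = None) -> None:
        entry: dict = {"path": path.name, "sha256": _sha256(path)}
        if rows is not None:
            entry["rows"] = rows
        self.artifacts[name] = entry

    def write(self, path: Path) -> None:
        payload = {
            "version": self.version,
            "seed": self.seed,
            "config_sha256": hashlib.sha256(
                json.dumps(self.config, sort_keys=True).encode()
            ).hexdigest(),
            "config": self.config,
            "counts": self.counts,
            "artifacts": self.artifacts,
            "failed_stage": self.failed_stage,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


class PipelineRun:
    """Chains the stages over one output directory."""

    def __init__(self, config: RunConfig, outdir=None, seed: int | None = None):
        self.cfg = config
        if seed is not None:
            self.cfg.seed = seed
            self.cfg.simulation.seed = seed
        self.outdir = Path(outdir or config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest = Manifest(config=self._manifest_config(), seed=self.cfg.seed)

    def _manifest_config(self) -> dict:
        """Config as recorded in the manifest: run-location free, so reruns
        into different directories still hash identically."""
        cfg = self.cfg.to_dict()
        cfg.pop("outdir", None)
        cfg["inputs"] = {k: self._relativize(v) for k, v in cfg.get("inputs", {}).items()}
        return cfg

    def _relativize(self, path: str) -> str:
        p = Path(path)
        try:
            return str(p.resolve().relative_to(self.outdir.resolve()))
        except ValueError:
            return str(p)

    # -- inputs --------------------------------------------------------------

    def _input(self, key: str) -> Path:
        try:
            p = Path(self.cfg.inputs[key])
        except KeyError:
            raise ConfigError(f"missing input path {key!r} in config") from None
        if not p.exists():
            raise ConfigError(f"input {key!r} does not exist: {p}")
        return p

    def _load_groups(self) -> dict[str, str]:
        return read_sample_groups(self._input("sample_groups"))

    # -- stages --------------------------------------------------------------

    def simulate(self) -> dict[str, str]:
        cohort = generate_cohort(self.cfg.simulation)
        paths = write_cohort(cohort, self.outdir / "cohort")
        self.cfg.inputs.update(paths)
        for name, p in paths.items():
            self.manifest.add(f"cohort/{name}", Path(p))
        self.manifest.counts["simulated_genes"] = self.cfg.simulation.n_genes
        self.manifest.counts["simulated_segments"] = len(cohort.segments)
        log.info("simulate: %d genes, %d segments", self.cfg.simulation.n_genes,
                 len(cohort.segments))
        return paths

    def assign(self) -> None:
        thr = self.cfg.thresholds
        groups = self._load_groups()
        segments = read_segments(self._input("segments"))
        annotation = read_bed(self._input("annotation"))
        cnv = assign_segments_to_genes(segments, annotation, thr, groups)
        n_cells = cnv.data.size
        n_missing = int(cnv.data.isna().sum().sum())
        log.info("assign: %d/%d gene-sample cells missing after containment/num.info rules",
                 n_missing, n_cells)
        write_matrix(cnv, self.outdir / "cnv_matrix.tsv")
        trimmed = trim_near_zero(cnv, thr.near_zero_trim)
        n_trim = int(trimmed.data.isna().sum().sum()) - n_missing
        log.info("assign: near-zero trim masked %d cells (%.0f%% per sign)",
                 n_trim, 100 * thr.near_zero_trim)
        write_matrix(trimmed, self.outdir / "cnv_matrix_trimmed.tsv")
        states = cnv_state_matrix(trimmed, thr)
        states.to_csv(self.outdir / "cnv_states.tsv", sep="\t", na_rep="NA")
        freq = alteration_frequency(states)
        freq.index.name = "gene_id"
        freq.reset_index().pipe(_write_frame, self.outdir / "alteration_frequency.tsv")
        bp = extract_breakpoints(segments, thr)
        _write_frame(bp, self.outdir / "breakpoints.tsv")
        log.info("assign: %d breakpoints (%d gain / %d loss)", len(bp),
                 int((bp["direction"] == "gain").sum()),
                 int((bp["direction"] == "loss").sum()))
        meth = read_matrix(self._input("methylation"), "methylation", groups,
                           dialect=self.cfg.methylation_dialect)
        ranking = methylation_tumor_normal_ranking(meth, self.cfg.extreme_fraction)
        _write_frame(ranking, self.outdir / "methylation_ranking.tsv")
        n_hyper = int((ranking["flag"] == "hypermethylated").sum())
        n_hypo = int((ranking["flag"] == "hypomethylated").sum())
        log.info("assign: %d hypermethylated, %d hypomethylated at %.0f%% tails",
                 n_hyper, n_hypo, 100 * self.cfg.extreme_fraction)
        for name in ("cnv_matrix", "cnv_matrix_trimmed", "cnv_states",
                     "alteration_frequency", "breakpoints", "methylation_ranking"):
            self.manifest.add(name, self.outdir / f"{name}.tsv")
        self.manifest.counts.update(
            {
                "cnv_cells_missing": n_missing,
                "cnv_cells_trimmed": n_trim,
                "breakpoints": len(bp),
                "hypermethylated": n_hyper,
                "hypomethylated": n_hypo,
            }
        )

    def _matrices(self):
        groups = self._load_groups()
        cnv = read_matrix(self.outdir / "cnv_matrix_trimmed.tsv", "cnv", groups)
        expr = read_matrix(self._input("expression"), "expression", groups)
        meth = read_matrix(self._input("methylation"), "methylation", groups,
                           dialect=self.cfg.methylation_dialect)
        return cnv, expr, meth

    def associate(self) -> None:
        thr = self.cfg.thresholds
        cnv, expr, meth = self._matrices()
        tumors = [s for s in cnv.tumor_samples if s in set(expr.samples)]
        screen = wilcoxon_cnv_screen(expr, cnv, thr)
        _write_frame(screen, self.outdir / "wilcoxon_screen.tsv")
        n_tested = int(screen["tested"].sum())
        n_sig = int((screen["q_value"] < self.cfg.fdr_level).sum())
        log.info("associate: rank-sum screen tested %d/%d genes, %d significant at q<%.2f",
                 n_tested, len(screen), n_sig, self.cfg.fdr_level)
        corr_cnv = per_gene_correlation(
            cnv.subset_samples(tumors), expr.subset_samples(tumors)
        )
        corr_meth = per_gene_correlation(
            meth.subset_samples([s for s in meth.tumor_samples if s in set(expr.samples)]),
            expr.subset_samples([s for s in meth.tumor_samples if s in set(expr.samples)]),
            negate_x=True,
        )
        _write_frame(pd.concat([corr_cnv, corr_meth]), self.outdir / "correlations.tsv")
        bins = expression_by_cnv_bins(
            expr.subset_samples(tumors), cnv.subset_samples(tumors), self.cfg.cdf_bin_edges
        )
        _write_frame(bins, self.outdir / "expression_by_cnv_bins.tsv")
        states = cnv_state_matrix(cnv.subset_samples(tumors), thr)
        e = expr.data.loc[cnv.data.index, tumors].to_numpy()
        st = states.to_numpy(dtype=object)
        deleted_vals = e[(st == "deleted") & np.isfinite(e)]
        amplified_vals = e[(st == "amplified") & np.isfinite(e)]
        gap = (
            cnv_expression_cdf_gap(deleted_vals, amplified_vals)
            if deleted_vals.size and amplified_vals.size
            else np.nan
        )
        dev = normal_deviation_filter(expr, cnv, None, thr)
        _write_frame(dev, self.outdir / "normal_deviation.tsv")
        summary = {
            "cdf_gap": None if not np.isfinite(gap) else round(float(gap), 6),
            "wilcoxon_tested": n_tested,
            "wilcoxon_significant": n_sig,
            "deviant_genes": int(dev["retained"].sum()),
        }
        (self.outdir / "associate_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
        for name in ("wilcoxon_screen", "correlations", "expression_by_cnv_bins",
                     "normal_deviation"):
            self.manifest.add(name, self.outdir / f"{name}.tsv")
        self.manifest.add("associate_summary", self.outdir / "associate_summary.json")
        self.manifest.counts.update(summary if summary["cdf_gap"] is not None else
                                    {k: v for k, v in summary.items() if k != "cdf_gap"})

    def classify(self) -> None:
        thr = self.cfg.thresholds
        cnv, expr, meth = self._matrices()
        amp_genes, del_genes = select_extreme_cnv_genes(cnv, thr)
        log.info("classify: %d amplified-class, %d deleted-class genes at >=%.0f%% of tumors",
                 len(amp_genes), len(del_genes), 100 * thr.min_sample_fraction)
        ratios = tumor_normal_expression_ratio(
            expr, bootstrap_reps=self.cfg.bootstrap_reps, seed=self.cfg.seed,
            linear=self.cfg.linear_ratio,
        )
        meth_by_class = class_methylation_means(meth, cnv, thr)
        meth_pool = pd.concat([meth_by_class["amplified"], meth_by_class["deleted"]])
        thresholds = compute_quantile_thresholds(
            ratios.to_numpy(), meth_pool.to_numpy(), q=self.cfg.quantile_q
        )
        calls = classify_features(amp_genes, del_genes, ratios, meth_by_class, thresholds)
        sig = at_class_significance(calls, meth, expr, cnv, thr)
        _write_frame(sig, self.outdir / "normal_vs_tumor_significance.tsv")
        attach_significance(calls, sig)
        percentile_rank_calls(calls, self.cfg.fdr_level)
        frame = calls_to_frame(calls)
        _write_frame(frame, self.outdir / "feature_calls.tsv")
        n_called = int((frame["feature_class"] != "none").sum())
        log.info("classify: %d/%d calls received a non-none feature class",
                 n_called, len(frame))
        annotation = {g.gene_id: g for g in read_bed(self._input("annotation"))}
        ranked = frame[frame["percentile_rank"].notna()].copy()
        ranked["chrom"] = [annotation[g].chrom if g in annotation else "NA"
                           for g in ranked["gene_id"]]
        ranked["midpoint"] = [
            int(annotation[g].midpoint) if g in annotation else -1 for g in ranked["gene_id"]
        ]
        _write_frame(
            ranked[["gene_id", "chrom", "midpoint", "percentile_rank"]],
            self.outdir / "chromosome_ranking.tsv",
        )
        for name in ("normal_vs_tumor_significance", "feature_calls", "chromosome_ranking"):
            self.manifest.add(name, self.outdir / f"{name}.tsv")
        self.manifest.counts.update(
            {
                "amplified_class_genes": len(amp_genes),
                "deleted_class_genes": len(del_genes),
                "feature_calls": n_called,
                "ranked_calls": len(ranked),
            }
        )

    def enrich(self) -> None:
        if not self.cfg.gmt_path:
            raise ConfigError("enrich stage needs gmt_path in the config")
        gene_sets = read_gmt(self.cfg.gmt_path)
        calls = pd.read_csv(self.outdir / "feature_calls.tsv", sep="\t")
        cnv, expr, meth = self._matrices()
        # universe: genes with complete tri-modal data in this run
        tri = (
            cnv.data.notna().any(axis=1)
            & meth.data.reindex(cnv.data.index).notna().any(axis=1)
            & expr.data.reindex(cnv.data.index).notna().any(axis=1)
        )
        universe = set(cnv.data.index[tri])
        log.info("enrich: universe of %d tri-modal genes", len(universe))
        frames = []
        for cls in ("oncogene_like", "ts_like", "amplified_suppressed", "deleted_expressed"):
            members = set(calls.loc[calls["feature_class"] == cls, "gene_id"]) & universe
            if not members:
                continue
            records = hypergeometric_enrichment(members, gene_sets, universe,
                                                self.cfg.fdr_level)
            frame = enrichment_to_frame(records)
            frame.insert(0, "feature_class", cls)
            frames.append(frame)
        result = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(
                columns=["feature_class", "set_id", "description", "k", "K", "n", "N",
                         "p_value", "q_value"]
            )
        )
        _write_frame(result, self.outdir / "enrichment.tsv")
        self.manifest.add("enrichment", self.outdir / "enrichment.tsv", rows=len(result))
        self.manifest.counts["enrichment_rows"] = len(result)

    # -- driver --------------------------------------------------------------

    def run(self, stage: str) -> None:
        stages = list(STAGES) if stage == "all" else [stage]
        if self.cfg.gmt_path is None and "enrich" in stages and stage == "all":
            stages.remove("enrich")  # enrichment is optional without gene sets
        try:
            for st in stages:
                getattr(self, st)()
        except Exception:
            self.manifest.failed_stage = st
            self.manifest.config = self._manifest_config()
            self.manifest.write(self.outdir / "manifest.json")
            raise
        self.manifest.config = self._manifest_config()
        self.manifest.write(self.outdir / "manifest.json")
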