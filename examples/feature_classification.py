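"""Classify genes at extreme copy number into feature quadrants.

Runs the full feature pipeline on a planted cohort: extreme-CNV gene
selection, tumor:normal expression ratios, 25% quantile cuts on the ratio
and methylation distributions, quadrant classification, at-class Hotelling
T^2 significance vs normals, and percentile ranking of the FDR-passing
calls.
"""

import pandas as pd

from tsog import (assign_segments_to_genes, at_class_significance,
                  attach_significance, class_methylation_means,
                  classify_features, compute_quantile_thresholds,
                  generate_cohort, percentile_rank_calls,
                  select_extreme_cnv_genes, tumor_normal_expression_ratio)
from tsog.classifier import calls_to_frame
from tsog.config import SimulationConfig, ThresholdConfig

cfg = SimulationConfig(n_genes=400, n_tumor=42, n_normal=7, seed=19)
cohort = generate_cohort(cfg)
thr = ThresholdConfig()

cnv = assign_segments_to_genes(cohort.segments, cohort.annotation, thr,
                               cohort.sample_groups)
amp, dele = select_extreme_cnv_genes(cnv, thr)
print(f"extreme CNV: {len(amp)} amplified-class, {len(dele)} deleted-class genes")

ratios = tumor_normal_expression_ratio(cohort.expression)
meth_by_class = class_methylation_means(cohort.methylation, cnv, thr)
pool = pd.concat([meth_by_class["amplified"], meth_by_class["deleted"]])
cuts = compute_quantile_thresholds(ratios.to_numpy(), pool.to_numpy(), q=0.25)
print(f"ratio cuts {cuts.ratio_low:.2f}/{cuts.ratio_high:.2f}, "
      f"methylation cuts {cuts.meth_low:.3f}/{cuts.meth_high:.3f}")

calls = classify_features(amp, dele, ratios, meth_by_class, cuts)
sig = at_class_significance(calls, cohort.methylation, cohort.expression, cnv, thr)
attach_significance(calls, sig)
percentile_rank_calls(calls, fdr_level=0.05)
frame = calls_to_frame(calls)

print("\nfeature classes called:")
print(frame[frame["feature_class"] != "none"]["feature_class"]
      .value_counts().to_string())

truth = cohort.truth.table.set_index("gene_id")["planted_class"]
top = frame[frame["percentile_rank"].notna()].nlargest(6, "percentile_rank")
top = top.assign(planted=[truth[g] for g in top["gene_id"]])
print("\ntop-ranked calls (percentile by q):")
print(top[["gene_id", "cnv_class", "feature_class", "expr_ratio", "meth_mean",
           "q_multi", "percentile_rank", "planted"]].to_string(index=False))
# Oncogene-like = amplified + top-quartile expression ratio + bottom-quartile
# methylation; TS-like is the mirror image. The q-values come from Hotelling
# T^2 on (methylation, expression) of the at-class tumors vs the normals.
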