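"""Generate a synthetic methylation cohort and run the QC chain.

Builds a 1,000-probe x 200-sample cohort with planted probe-removal
categories and low-confidence entries, then applies detection-p masking,
four-category probe filtering, KNN imputation and top-variance selection.
"""

import numpy as np

from mbmetagene import (
    filter_probes,
    filter_samples,
    generate_cohort,
    knn_impute,
    mask_low_confidence,
    select_top_variance,
)

bm, sheet, truth = generate_cohort(n_probes=1000, n_samples=200, seed=11)
print(f"cohort: {bm.n_probes} probes x {bm.n_samples} samples")
frac_extreme = np.mean((bm.beta <= 0.2) | (bm.beta >= 0.8))
print(f"beta values in [0,0.2] or [0.8,1]: {frac_extreme:.1%}  (bimodal marginals)")

masked = mask_low_confidence(bm, threshold=0.05)
print(f"masked low-confidence values: {int(np.isnan(masked.beta).sum())}")

filtered, report = filter_probes(masked, truth.planted_annotation)
print("probe filter report:", report.counts())

filtered, kept_sheet = filter_samples(filtered, sheet)
imputed = knn_impute(filtered, k=10)
selected = select_top_variance(imputed, 500)
print(f"after QC: {selected.n_probes} probes x {selected.n_samples} samples, complete matrix")
# The filter counts equal the planted category sizes (the categories are
# disjoint), and the final matrix is the top-500-variance subset ready for
# factorization.
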