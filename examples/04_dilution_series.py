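"""In silico tumor-fraction dilution of a high-TF sample into healthy cfDNA.

Mixes a TF=0.5 synthetic cancer sample into a healthy sample at three
target tumor fractions (ploidy-aware read ratios), then scores each
replicate with a detection model trained on an independent synthetic
cohort. Scores rise monotonically with target TF.
"""

import numpy as np
import pandas as pd

from fatefrag import (
    AdmixtureSpec,
    CohortDesign,
    ElasticNetSpec,
    cohort_feature_matrix,
    extract_fragmentomics,
    make_mixture,
    mixing_ratio,
    simulate_fragments,
    train,
)

# detection model from an independent cohort
train_design = CohortDesign(
    n_healthy=10, n_tumor=10, tf_per_tumor=(0.05,) * 5 + (0.1,) * 5,
    n_fragments=60_000, seed=31,
)
scorer = train(cohort_feature_matrix(train_design, with_methylation=False),
               ElasticNetSpec(n_repeats=1, seed=31))

# dilution sources: one deep healthy and one deep TF=0.5 cancer sample
src = CohortDesign(n_healthy=1, n_tumor=1, tf_per_tumor=(0.5,), n_fragments=400_000, seed=37)
healthy, _ = simulate_fragments(src, 0)
cancer, _ = simulate_fragments(src, 1)
egcr, elcr = src.truth_regions()

spec = AdmixtureSpec(tf_initial=0.5, ploidy=2.0, tf_targets=(1e-3, 1e-2, 1e-1),
                     n_replicates=3, seed=41)
print("target TF   mix ratio R   realized tumor-read frac   mean score")
for tf_t in spec.tf_targets:
    r = mixing_ratio(tf_t, spec.tf_initial, spec.ploidy)
    scores, realized = [], []
    for rep in range(spec.n_replicates):
        mix = make_mixture(cancer, healthy, spec, tf_t, rep)
        feats = extract_fragmentomics(mix.fragments, egcr, elcr)
        scores.append(float(scorer.score(pd.DataFrame([feats.values]))[0]))
        realized.append(mix.realized_tumor_read_fraction)
    print(f"{tf_t:9.0e}   {r:11.4f}   {np.mean(realized):24.4f}   {np.mean(scores):10.3f}")
# the realized tumor-read fraction tracks R (= TF_T/TF_I at ploidy 2) and
# the detection score grows with the target tumor fraction
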