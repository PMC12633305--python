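"""End-to-end composition: synthetic cohort → feature matrix → scores.

Thin glue over the module APIs, used by the examples, the CLI and the
acceptance checks. Real-data workflows call the same per-module functions
with fragments loaded from BED/BAM instead of the generator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fragmentomics import FragmentomicsConfig, extract_fragmentomics
from .methylation import MethylationConfig, MethFeatures, RegionCounts, extract_methylation
from .model import FeatureMatrix
from .synthetic import CohortDesign, simulate_fragments, simulate_meth_counts


def cohort_feature_matrix(
    design: CohortDesign,
    with_methylation: bool = True,
    config: FragmentomicsConfig | None = None,
    meth_config: MethylationConfig | None = None,
) -> FeatureMatrix:
    """Simulate every sample in ``design`` and assemble the feature matrix.

    Samples are indexed healthy first (label "healthy", TF 0) then tumors
    (label "cancer", TF from the design). Fragmentomics features are
    computed against the design's ground-truth eGCR/eLCR bins; with
    ``with_methylation`` the three cfMeDIP features are appended.
    """
    config = config or FragmentomicsConfig(
        length_min=design.length_min, length_max=design.length_max
    )
    egcr, elcr = design.truth_regions()
    rows, index, labels, tfs = [], [], [], []
    n_total = design.n_healthy + design.n_tumor
    for i in range(n_total):
        healthy = i < design.n_healthy
        sid = f"{'H' if healthy else 'T'}{i:03d}"
        frags, _ = simulate_fragments(design, i)
        feats = extract_fragmentomics(frags, egcr, elcr, config, sample_id=sid)
        row = dict(feats.values)
        if with_methylation:
            ehrt_counts, ehrp_counts = simulate_meth_counts(design, i)
            meth = extract_methylation(
                RegionCounts("eHRT", ehrt_counts, sid),
                RegionCounts("eHRP", ehrp_counts, sid),
                meth_config,
            )
            row.update(meth.as_dict())
        rows.append(row)
        index.append(sid)
        labels.append("healthy" if healthy else "cancer")
        tfs.append(design.sample_tf(i))
    features = pd.DataFrame(rows, index=pd.Index(index, name="sample_id"))
    return FeatureMatrix(
        features=features,
        labels=pd.Series(labels, index=features.index, name="label"),
        cohort="synthetic",
        tf=pd.Series(tfs, index=features.index, name="tf"),
    )
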