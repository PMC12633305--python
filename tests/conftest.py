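import numpy as np
import pytest

import fatefrag as ff
from fatefrag.pipeline import cohort_feature_matrix


@pytest.fixture(scope="session")
def small_design():
    """A tiny cohort design: 2 chromosomes x 30 Mb, 20 bins, 15k fragments."""
    return ff.CohortDesign(
        n_healthy=4, n_tumor=4, tf_per_tumor=(0.1, 0.1, 0.3, 0.3),
        n_fragments=15_000, seed=11,
    )


@pytest.fixture(scope="session")
def detection_cohort():
    """The well-separated detection cohort: 40 tumors (TF >= 0.03) vs 40
    healthy, seed 7 — shared between model tests and acceptance checks."""
    design = ff.CohortDesign(
        n_healthy=40,
        n_tumor=40,
        tf_per_tumor=tuple(np.linspace(0.03, 0.15, 40)),
        n_fragments=60_000,
        seed=7,
    )
    return cohort_feature_matrix(design)


def make_titration_features(tf_levels=(0.0, 0.01, 0.03, 0.1, 0.3), n_per_level=10,
                            n_fragments=200_000, seed=23):
    """Per-TF-level fragmentomics features on fresh seeded samples.

    Returns {tf: list of FragmentomicsFeatures}. Each level reuses the
    same design truth regions; sample indices walk the tumor block.
    """
    out = {}
    for level_idx, tf in enumerate(tf_levels):
        design = ff.CohortDesign(
            n_healthy=0 if tf > 0 else n_per_level,
            n_tumor=n_per_level if tf > 0 else 0,
            tf_per_tumor=(tf,) * n_per_level if tf > 0 else (),
            n_fragments=n_fragments,
            seed=seed + level_idx,
        )
        egcr, elcr = design.truth_regions()
        feats = []
        for i in range(n_per_level):
            frags, _ = ff.simulate_fragments(design, i)
            feats.append(ff.extract_fragmentomics(frags, egcr, elcr, sample_id=f"tf{tf}_{i}"))
        out[tf] = feats
    return out


@pytest.fixture(scope="session")
def titration_features():
    return make_titration_features()
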