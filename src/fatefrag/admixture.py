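"""Ploidy-aware in silico tumor-fraction dilution.

A high-tumor-fraction plasma sample (initial fraction TF_I, tumor ploidy
PL) is digitally mixed with a healthy plasma sample to a target tumor
fraction TF_T. The fraction R of the mixture's reads drawn from the
cancer sample is

    R = TF_T · (TF_I·PL + (1 − TF_I)·2) / (TF_I·PL)

which accounts for tumor cells contributing PL genome copies per cell
against 2 for normal cells; at PL = 2 it collapses exactly to
R = TF_T / TF_I. The per-source read-keeping probabilities that also
normalize the mixture to a target depth covT are

    CancerRatio  = R · covT / covC        HealthyRatio = (1 − R) · covT / covH

Fragments are kept by independent Bernoulli thinning (the per-read
semantics of standard subsampling tools), seeded per (target, replicate)
so each replicate is individually reproducible. Healthy-only replicates
are produced by 90% subsampling of the healthy sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fragments import FragmentSet

DEFAULT_TF_TARGETS = (1e-6, 1e-5, 1e-4, 1e-3, 5e-3, 1e-2, 2e-2, 3e-2, 5e-2, 1e-1)


@dataclass
class AdmixtureSpec:
    """Dilution design: source characteristics and target grid."""

    tf_initial: float
    ploidy: float = 2.0
    tf_targets: tuple[float, ...] = DEFAULT_TF_TARGETS
    cov_cancer: float = 1.0
    cov_healthy: float = 1.0
    cov_target: float = 1.0
    n_replicates: int = 10
    healthy_subsample: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.tf_initial <= 1.0):
            raise ValueError("tf_initial must be in (0,1]")
        if self.ploidy <= 0:
            raise ValueError("ploidy must be positive")
        if any(t > self.tf_initial for t in self.tf_targets):
            raise ValueError("every target TF must be ≤ tf_initial")
        if min(self.cov_cancer, self.cov_healthy, self.cov_target) <= 0:
            raise ValueError("coverages must be positive")
        if not (0.0 < self.healthy_subsample <= 1.0):
            raise ValueError("healthy_subsample must be in (0,1]")


@dataclass
class MixedSample:
    """One admixture replicate with per-fragment provenance retained."""

    fragments: FragmentSet
    provenance: np.ndarray  # "cancer" | "healthy" per fragment
    realized_tumor_read_fraction: float
    target_tf: float
    replicate_idx: int
    mixing_ratio: float


def mixing_ratio(tf_target: float, tf_initial: float, ploidy: float) -> float:
    """Fraction of mixture reads drawn from the cancer sample for a target TF.

    Small-TF_T approximation of the exact dilution algebra: the relative
    error of the achieved tumor fraction is O(TF_T). Raises when the target
    exceeds what dilution of this source can reach (R > 1).
    """
    if not (0.0 < tf_target <= tf_initial <= 1.0):
        raise ValueError("need 0 < tf_target ≤ tf_initial ≤ 1")
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    r = tf_target * (tf_initial * ploidy + (1.0 - tf_initial) * 2.0) / (tf_initial * ploidy)
    if r > 1.0 + 1e-12:
        raise ValueError(f"target TF {tf_target} unreachable by dilution (R = {r:.4g} > 1)")
    return min(r, 1.0)


def mixture_fractions(
    r: float, cov_cancer: float, cov_healthy: float, cov_target: float
) -> tuple[float, float]:
    """Per-source read-keeping probabilities normalizing to target depth."""
    if not (0.0 <= r <= 1.0):
        raise ValueError("R must be in [0,1]")
    if min(cov_cancer, cov_healthy, cov_target) <= 0:
        raise ValueError("coverages must be positive")
    cancer_ratio = r * cov_target / cov_cancer
    healthy_ratio = (1.0 - r) * cov_target / cov_healthy
    if cancer_ratio > 1.0 or healthy_ratio > 1.0:
        raise ValueError(
            "insufficient source coverage: "
            f"cancer_ratio={cancer_ratio:.4g}, healthy_ratio={healthy_ratio:.4g}"
        )
    return cancer_ratio, healthy_ratio


def _replicate_rng(seed: int, tf_target: float, replicate_idx: int) -> np.random.Generator:
    """Independent, individually reproducible stream per (target, replicate)."""
    key = np.random.SeedSequence(
        [int(seed), int(round(tf_target * 1e9)), int(replicate_idx)]
    )
    return np.random.default_rng(key)


def make_mixture(
    cancer_fragments: FragmentSet,
    healthy_fragments: FragmentSet,
    spec: AdmixtureSpec,
    tf_target: float,
    replicate_idx: int,
) -> MixedSample:
    """One admixture replicate by independent Bernoulli thinning of both sources."""
    if tf_target == 0.0:
        r = 0.0
        cancer_ratio, healthy_ratio = 0.0, min(spec.cov_target / spec.cov_healthy, 1.0)
    else:
        r = mixing_ratio(tf_target, spec.tf_initial, spec.ploidy)
        cancer_ratio, healthy_ratio = mixture_fractions(
            r, spec.cov_cancer, spec.cov_healthy, spec.cov_target
        )
    rng = _replicate_rng(spec.seed, tf_target, replicate_idx)
    keep_c = rng.random(len(cancer_fragments)) < cancer_ratio
    keep_h = rng.random(len(healthy_fragments)) < healthy_ratio
    kept_c = cancer_fragments.subset(keep_c)
    kept_h = healthy_fragments.subset(keep_h)
    mixed = FragmentSet.concat([kept_c, kept_h])
    provenance = np.array(["cancer"] * len(kept_c) + ["healthy"] * len(kept_h), dtype=object)
    total = len(mixed)
    realized = len(kept_c) / total if total else 0.0
    return MixedSample(
        fragments=mixed,
        provenance=provenance,
        realized_tumor_read_fraction=realized,
        target_tf=tf_target,
        replicate_idx=replicate_idx,
        mixing_ratio=r,
    )


def healthy_replicates(
    healthy_fragments: FragmentSet, spec: AdmixtureSpec
) -> list[FragmentSet]:
    """Healthy-only replicates by subsampling (default 90% of reads each)."""
    out = []
    for i in range(spec.n_replicates):
        # distinct stream family from make_mixture's (tf_target, replicate) keys
        key = np.random.SeedSequence([int(spec.seed), 2**31, int(i)])
        rng = np.random.default_rng(key)
        keep = rng.random(len(healthy_fragments)) < spec.healthy_subsample
        out.append(healthy_fragments.subset(keep))
    return out


def dilution_series(
    cancer_fragments: FragmentSet, healthy_fragments: FragmentSet, spec: AdmixtureSpec
) -> list[MixedSample]:
    """The full replicate grid: every target TF × every replicate index."""
    return [
        make_mixture(cancer_fragments, healthy_fragments, spec, tf, rep)
        for tf in spec.tf_targets
        for rep in range(spec.n_replicates)
    ]
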