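"""Shared fixtures: synthetic cohorts at two signal levels.

Heavier artifacts (the strong-signal study and its full-face shape space)
are session-scoped so matching, trait and acceptance tests reuse them.
"""

import numpy as np
import pytest

from sibface.matching import run_identification
from sibface.preprocess import project_to_reference, symmetrize
from sibface.segmentation import align_to_segment, build_segment_space
from sibface.synthetic import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """Small, cheap cohort for structural / preprocessing tests."""
    cfg = SimulationConfig(
        n_landmarks=40,
        n_families=30,
        n_unrelated=120,
        n_snps=60,
        n_causal=6,
        seed=101,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def strong_study():
    """Cohort with strong familial facial signal (high heritability, low
    noise) used for identification and trait-selection checks."""
    cfg = SimulationConfig(
        n_landmarks=100,
        n_families=200,
        n_unrelated=500,
        n_snps=80,
        n_causal=0,
        genetic_variance_fraction=0.7,
        factor_scale=3.0,
        noise_sd=0.3,
        seed=202,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def strong_symmetric(strong_study):
    _, ref_sym = symmetrize(
        strong_study["reference"].configurations, strong_study["pairing"]
    )
    _, sib_sym = symmetrize(
        strong_study["sib"].configurations, strong_study["pairing"]
    )
    return ref_sym, sib_sym


@pytest.fixture(scope="session")
def fullface_space(strong_symmetric):
    ref_sym, _ = strong_symmetric
    return build_segment_space(
        ref_sym, np.arange(ref_sym.shape[1]), n_permutations=50, seed=7
    )


@pytest.fixture(scope="session")
def sib_scores(strong_symmetric, fullface_space):
    _, sib_sym = strong_symmetric
    return project_to_reference(
        align_to_segment(fullface_space, sib_sym), fullface_space
    )


@pytest.fixture(scope="session")
def sib_identification(strong_study, fullface_space, sib_scores):
    sib = strong_study["sib"]
    return run_identification(
        sib_scores,
        sib.individual_ids,
        sib.family_id,
        metric="MA",
        sigma=fullface_space.sigma,
        label="1",
    )
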