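"""Shared fixtures: templates, small cohort configs, calibrated defaults."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from memnet.connectome import apply_mask, build_population_mask, symmetrize, tally_to_probability
from memnet.metrics import weighted_clustering
from memnet.synthetic import (
    CohortConfig,
    calibrate_effects,
    cohort_to_frame,
    generate_cohort,
    make_template,
)


def small_cohort_config(**overrides) -> CohortConfig:
    """A scaled-down cohort for fast tests: fewer subjects, nodes, streamlines."""
    defaults = dict(
        n_subjects=80, n_nodes=16, n_blocks=4, waytotal=800, seed=7,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return small_cohort_config()


@pytest.fixture(scope="session")
def small_model(small_config):
    return make_template(
        small_config.n_nodes, small_config.n_blocks, small_config.w_within,
        small_config.w_between, jitter=small_config.template_jitter,
        rng=np.random.default_rng(np.random.SeedSequence([small_config.seed, 0x7E3])),
    )


@pytest.fixture(scope="session")
def small_coefficients(small_config, small_model):
    return calibrate_effects(small_config, n_pilot=30_000, model=small_model, n_noise=400)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_model, small_coefficients):
    """One generated small cohort: (subjects, tallies)."""
    return generate_cohort(small_config, model=small_model,
                           coefficients=small_coefficients)


def cohort_transitivity(subjects, tallies) -> pd.DataFrame:
    """Covariate table plus pipeline-measured weighted transitivity."""
    mats = [symmetrize(tally_to_probability(t)) for t in tallies]
    mask = build_population_mask(mats)
    t = np.array([weighted_clustering(apply_mask(m, mask))[3] for m in mats])
    df = cohort_to_frame(subjects)
    df["transitivity"] = t
    return df


@pytest.fixture(scope="session")
def default_config() -> CohortConfig:
    """The full-scale study conditions (n = 655, R = 82)."""
    return CohortConfig(seed=1)


@pytest.fixture(scope="session")
def default_model(default_config):
    cfg = default_config
    return make_template(
        cfg.n_nodes, cfg.n_blocks, cfg.w_within, cfg.w_between,
        jitter=cfg.template_jitter,
        rng=np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7E3])),
    )


@pytest.fixture(scope="session")
def default_coefficients(default_config, default_model):
    return calibrate_effects(default_config, model=default_model)


def replicate(config: CohortConfig, seed: int) -> CohortConfig:
    return dataclasses.replace(config, seed=seed)
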