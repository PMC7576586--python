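"""Shared fixtures: ideal (noise-free) presets, synthetic cohorts and the
dense-grid support oracle used to cross-check the event sweep."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import settings

import equigait as eg
from equigait.simulate import BreedCohort, CohortConfig, generate_cohort
from equigait.types import Breed, HorseProfile

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

SEED = 101


def make_ideal(preset: eg.GaitPreset, duty: float | None = None) -> eg.GaitPreset:
    """Strip all stochasticity from a preset (zero SDs, zero jitter)."""
    kwargs = dict(
        stride_duration_sd=0.0,
        duty_factor_sd=0.0,
        phase_jitter_sd=0.0,
        duty_limb_sd=0.0,
    )
    if duty is not None:
        kwargs["duty_factor_mean"] = duty
    return dataclasses.replace(preset, **kwargs)


def dense_support_pcts(window, n_grid: int = 10_000) -> dict:
    """Brute-force support-category percentages: sample ``n_grid`` points
    over the window and count limbs in stance at each."""
    t = window.start + (np.arange(n_grid) + 0.5) / n_grid * window.duration
    count = np.zeros(n_grid, dtype=int)
    for iv in window.intervals:
        count += (t >= iv.on_time) & (t < iv.off_time)
    return {k: 100.0 * np.mean(count == k) for k in range(5)}


@pytest.fixture(scope="session")
def presets():
    return eg.builtin_presets()


@pytest.fixture(scope="session")
def neutral_horse():
    return HorseProfile(horse_id="ref")


@pytest.fixture(scope="session")
def cohort_table():
    """Feature table of the default synthetic cohort (33 horses, 8 gaits,
    study-proportioned stride counts, uncontrolled trial speed)."""
    pairs = generate_cohort(CohortConfig(), rng_seed=SEED, with_signals=False)
    return eg.feature_table([tl for tl, _ in pairs])


@pytest.fixture(scope="session")
def signal_blocks():
    """Reduced signal cohort (all 8 gaits across 11 horses) for the
    raw-signal classification path."""
    cfg = CohortConfig(
        breeds={
            Breed.icelandic: BreedCohort(n_horses=6),
            Breed.colombian_criollo: BreedCohort(n_horses=5),
        },
        total_strides=500,
        trials_per_gait=1,
    )
    return [b for _, b in generate_cohort(cfg, rng_seed=SEED, with_signals=True)]
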