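"""Stride segmentation, support profiles, feature computation and the
Hildebrand projection."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import equigait as eg
from equigait.features import (
    FEATURE_COLUMNS,
    OVERLAP_PAIRS,
    compute_features,
    feature_table,
    footfall_order,
    segment_strides,
    support_profile,
)
from equigait.types import FootfallTimeline, Gait, HorseProfile, Limb, StanceInterval
from conftest import make_ideal

HORSE = HorseProfile(horse_id="h")


def ideal_timeline(presets, gait, n=6, duty=None):
    return eg.generate_timeline(make_ideal(presets[gait], duty=duty), HORSE, n, rng_seed=0)


# --- segmentation -----------------------------------------------------------


def test_window_count_is_onsets_minus_one(presets):
    tl = ideal_timeline(presets, Gait.walk, n=11)
    assert len(tl.onsets(Limb.LH)) == 11
    assert len(segment_strides(tl)) == 10


def test_windows_tile_the_reference_span(presets, neutral_horse):
    tl = eg.generate_timeline(presets[Gait.tolt], neutral_horse, 15, rng_seed=9)
    windows = segment_strides(tl)
    onsets = tl.onsets(Limb.LH)
    total = sum(w.duration for w in windows)
    assert total == pytest.approx(onsets[-1] - onsets[0], abs=1e-9)


def test_ideal_trot_windows_all_complete(presets):
    tl = ideal_timeline(presets, Gait.trot, n=8)
    assert all(w.complete for w in segment_strides(tl))


def test_too_few_reference_onsets_yields_empty(presets):
    tl = ideal_timeline(presets, Gait.trot, n=1)
    assert segment_strides(tl) == []


def test_alternative_reference_limb(presets):
    tl = ideal_timeline(presets, Gait.walk, n=6)
    for limb in Limb:
        ws = segment_strides(tl, reference_limb=limb)
        assert len(ws) == 5
        assert all(w.reference_limb is limb for w in ws)


# --- support profile --------------------------------------------------------


def test_ideal_trot_support_profile_closed_form(presets):
    """Duty d < 50 with synchronous diagonal pairs: support alternates
    between 2 limbs (2d of the stride) and suspension (100 - 2d)."""
    d = 44.2
    tl = ideal_timeline(presets, Gait.trot, n=6)
    w = segment_strides(tl)[2]
    bounds, counts = support_profile(w)
    assert set(counts) == {0, 2}
    f = compute_features(w)
    assert f.pct_suspension == pytest.approx(100 - 2 * d, abs=1e-9)
    assert f.pct_bipedal == pytest.approx(2 * d, abs=1e-9)
    assert (f.min_limbs, f.max_limbs, f.median_limbs) == (0, 2, 2)


def test_ideal_walk_support_profile_closed_form(presets):
    tl = ideal_timeline(presets, Gait.walk, n=6, duty=60.0)
    w = segment_strides(tl)[2]
    _, counts = support_profile(w)
    assert set(counts) == {2, 3}
    f = compute_features(w)
    assert f.pct_tripedal == pytest.approx(40.0, abs=1e-9)
    assert f.pct_bipedal == pytest.approx(60.0, abs=1e-9)


@given(gait=st.sampled_from(list(Gait)), seed=st.integers(0, 10_000))
def test_support_coverage_conservation(gait, seed):
    """Sum of (count x segment length) equals total clipped stance time."""
    presets = eg.builtin_presets()
    tl = eg.generate_timeline(presets[gait], HORSE, 4, rng_seed=seed)
    for w in segment_strides(tl):
        bounds, counts = support_profile(w)
        assert bounds[0] == pytest.approx(w.start) and bounds[-1] == pytest.approx(w.end)
        seg = np.diff(bounds)
        total_stance = sum(iv.off_time - iv.on_time for iv in w.intervals)
        assert float(seg @ counts) == pytest.approx(total_stance, abs=1e-9)


def test_overlapping_same_limb_intervals_rejected(presets):
    tl = ideal_timeline(presets, Gait.walk, n=4)
    w = segment_strides(tl)[1]
    w.intervals.append(
        StanceInterval(limb=Limb.LF, on_time=w.start + 0.01, off_time=w.end - 0.01)
    )
    with pytest.raises(ValueError):
        support_profile(w)


# --- features ---------------------------------------------------------------


def test_feature_invariants_on_jittered_cohort(presets, neutral_horse):
    tl = eg.generate_timeline(presets[Gait.trocha], neutral_horse, 30, rng_seed=2)
    for w in segment_strides(tl):
        if not w.complete:
            continue
        f = compute_features(w)
        total = (
            f.pct_quadrupedal + f.pct_tripedal + f.pct_bipedal + f.pct_single + f.pct_suspension
        )
        assert total == pytest.approx(100.0, abs=1e-6)
        assert f.min_limbs <= f.median_limbs <= f.max_limbs
        assert f.stride_frequency == pytest.approx(1 / f.stride_duration, abs=1e-9)
        for limb in Limb:
            assert f.duty_by_limb[limb] == pytest.approx(
                f.stance_by_limb[limb] / w.limb_cycles[limb] * 100, abs=1e-9
            )
        for pair in OVERLAP_PAIRS:
            assert 0.0 <= f.overlaps[pair] <= 100.0


def test_features_invariant_to_time_translation(presets, neutral_horse):
    tl = eg.generate_timeline(presets[Gait.pace], neutral_horse, 8, rng_seed=3)
    shifted = FootfallTimeline(
        horse_id=tl.horse_id,
        gait=tl.gait,
        intervals=[
            StanceInterval(limb=iv.limb, on_time=iv.on_time + 13.7, off_time=iv.off_time + 13.7)
            for iv in tl.intervals
        ],
        total_duration=tl.total_duration + 13.7,
    )
    rows_a = feature_table([tl])[FEATURE_COLUMNS].to_numpy()
    rows_b = feature_table([shifted])[FEATURE_COLUMNS].to_numpy()
    np.testing.assert_allclose(rows_a, rows_b, atol=1e-8)


@pytest.mark.parametrize(
    "gait,dap,lap",
    [(Gait.trot, 0.0, 50.0), (Gait.pace, 50.0, 0.0), (Gait.walk, -25.0, 25.0)],
)
def test_advanced_placements_canonical_gaits(presets, gait, dap, lap):
    tl = ideal_timeline(presets, gait, n=6)
    w = segment_strides(tl)[2]
    got_dap, got_lap = eg.advanced_placements(w)
    assert got_dap == pytest.approx(dap, abs=1e-9)
    assert got_lap == pytest.approx(lap, abs=1e-9)
    f = compute_features(w)
    assert eg.hildebrand_coordinates(f) == (
        pytest.approx(dap, abs=1e-9),
        pytest.approx(lap, abs=1e-9),
    )


def test_mirroring_swaps_canter_leads(presets):
    """Left-right mirroring of the limbs maps one canter lead onto the
    other; the (dap, lap) pair is preserved by the pairwise averaging."""
    mirror = {Limb.LF: Limb.RF, Limb.RF: Limb.LF, Limb.LH: Limb.RH, Limb.RH: Limb.LH}
    tl = ideal_timeline(presets, Gait.rcanter, n=6)
    mirrored = FootfallTimeline(
        horse_id=tl.horse_id,
        gait=Gait.lcanter,
        intervals=[
            StanceInterval(limb=mirror[iv.limb], on_time=iv.on_time, off_time=iv.off_time)
            for iv in tl.intervals
        ],
        total_duration=tl.total_duration,
    )
    tl_l = ideal_timeline(presets, Gait.lcanter, n=6)
    f_m = compute_features(segment_strides(mirrored)[2])
    f_l = compute_features(segment_strides(tl_l)[2])
    assert f_m.diagonal_advanced_placement == pytest.approx(
        f_l.diagonal_advanced_placement, abs=1e-9
    )
    assert f_m.lateral_advanced_placement == pytest.approx(
        f_l.lateral_advanced_placement, abs=1e-9
    )


@pytest.mark.parametrize("duty", [30.0, 38.5, 44.2, 49.0])
def test_trot_suspension_closed_form_across_duties(presets, duty):
    tl = ideal_timeline(presets, Gait.trot, n=5, duty=duty)
    f = compute_features(segment_strides(tl)[1])
    assert f.pct_suspension == pytest.approx(100 - 2 * duty, abs=1e-9)


def test_ideal_walk_limb_pair_overlap(presets):
    """LF stance [0.25, 0.85] overlaps LH stance [0, 0.6] for 35 % of the
    stride at duty 60 with 25 % spacing."""
    tl = ideal_timeline(presets, Gait.walk, n=6, duty=60.0)
    f = compute_features(segment_strides(tl)[2])
    assert f.overlaps[(Limb.LF, Limb.LH)] == pytest.approx(35.0, abs=1e-9)
    # hind pair: direct overlap [0.5, 0.6] plus the wrapped tail [0, 0.1]
    assert f.overlaps[(Limb.LH, Limb.RH)] == pytest.approx(20.0, abs=1e-9)


def test_round_trip_ideal_presets_recovered_exactly(presets):
    """With zero jitter and zero SDs the extracted features equal the
    generating parameters exactly."""
    for gait in (Gait.trot, Gait.walk, Gait.tolt, Gait.rcanter):
        p = make_ideal(presets[gait])
        tl = eg.generate_timeline(p, HORSE, 5, rng_seed=0)
        f = compute_features(segment_strides(tl)[2])
        assert f.stride_duration == pytest.approx(p.stride_duration_mean, abs=1e-9)
        assert f.duty_factor == pytest.approx(p.duty_factor_mean, abs=1e-9)
        assert f.duty_factor_hind == pytest.approx(p.duty_factor_mean, abs=1e-9)


def test_feature_table_shape_and_columns(presets):
    tls = [ideal_timeline(presets, g, n=11) for g in (Gait.walk, Gait.trot, Gait.pace)]
    tab = feature_table(tls)
    assert len(tab) == 30
    assert list(tab.columns) == FEATURE_COLUMNS + ["gait_label", "horse_id"]
    assert len(FEATURE_COLUMNS) == 21


def test_feature_table_requires_input_and_complete_strides(presets):
    with pytest.raises(ValueError):
        feature_table([])
    tl = ideal_timeline(presets, Gait.trot, n=1)
    with pytest.raises(ValueError):
        feature_table([tl])


def test_tolt_centroid_between_pace_and_trot(cohort_table):
    """In Hildebrand space the four-beat lateral tölt lies between the
    lateral (pace) and diagonal (trot) two-beat extremes in |LAP|."""
    lap = cohort_table.groupby("gait_label")["lateral_advanced_placement"].apply(
        lambda s: s.abs().mean()
    )
    assert lap["pace"] < lap["tolt"] < lap["trot"]


def test_footfall_order_groups_simultaneous_onsets(presets):
    tl = ideal_timeline(presets, Gait.trot, n=4)
    order = footfall_order(segment_strides(tl)[1])
    assert order[0] == ("LH", "RF")
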