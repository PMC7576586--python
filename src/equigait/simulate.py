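"""Synthetic gait data generation.

Produces ground-truth footfall timelines (hoof-on/hoof-off per limb) and
IMU-like multichannel signal streams for cohorts of horses.  The signal
model is deliberately simple plumbing — an exponentially decaying impact
transient at each hoof-on, a swing-phase oscillation, a stride-locked
vertical harmonic on the upper-body sensors and additive Gaussian noise —
it exercises the raw-signal classification path, it is not a biomechanical
simulation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .presets import builtin_presets
from .types import (
    Breed,
    FootfallTimeline,
    Gait,
    GaitPreset,
    HorseProfile,
    Limb,
    SignalBlock,
    default_channel_names,
)

__all__ = [
    "generate_timeline",
    "generate_signals",
    "generate_cohort",
    "CohortConfig",
    "BreedCohort",
    "BREED_GAITS",
    "BREED_STRIDE_MULTIPLIER",
    "child_rng",
]

#: Minimum admissible stride duration (s); the stride-duration normal is
#: truncated below at this value.
MIN_STRIDE_DURATION = 0.2

#: Which gaits each breed displays.
BREED_GAITS: Mapping[Breed, Tuple[Gait, ...]] = {
    Breed.warmblood: (Gait.walk, Gait.trot, Gait.lcanter, Gait.rcanter),
    Breed.icelandic: (
        Gait.walk,
        Gait.trot,
        Gait.pace,
        Gait.tolt,
        Gait.lcanter,
        Gait.rcanter,
    ),
    Breed.franches_montagnes: (Gait.walk, Gait.trot),
    Breed.colombian_criollo: (Gait.paso, Gait.trot, Gait.trocha),
}

#: Breed-level stride-duration multiplier (conformation/size effect).  The
#: Colombian criollo multiplier is well below 1 so that breed's trot sits in
#: the high-stride-frequency range adjacent to trocha.
BREED_STRIDE_MULTIPLIER: Mapping[Breed, float] = {
    Breed.warmblood: 1.08,
    Breed.icelandic: 0.97,
    Breed.franches_montagnes: 1.02,
    Breed.colombian_criollo: 0.82,
}

#: Per-horse SD of the stride-duration multiplier around the breed base.
HORSE_MULTIPLIER_SD = 0.06


def child_rng(root_seed: int, *tokens: str) -> np.random.Generator:
    """Derive a child generator from a root seed and string identifiers.

    Uses CRC32 of each token as spawn-key material so that adding a horse to
    a cohort does not reshuffle the data of the others.
    """
    keys = [zlib.crc32(t.encode()) for t in tokens]
    return np.random.default_rng(np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF, *keys]))


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lower: float, size: int
) -> np.ndarray:
    if sd == 0:
        return np.full(size, max(mean, lower))
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def generate_timeline(
    preset: GaitPreset,
    horse: HorseProfile,
    n_strides: int,
    rng_seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> FootfallTimeline:
    """Generate a footfall timeline of ``n_strides`` complete stride cycles.

    Per-stride duration is drawn from a Normal truncated below at 0.2 s,
    with mean ``preset.stride_duration_mean * horse.stride_duration_multiplier``.
    Each limb's hoof-on is placed at its phase offset plus Gaussian jitter;
    hoof-off follows at ``duty/100 * stride_duration``.  The duty factor is
    drawn once per stride (shared by all limbs) plus small per-limb noise,
    so stance and stride durations co-vary as in real locomotion.
    Deterministic given the seed.
    """
    if n_strides < 1:
        raise ValueError("n_strides must be >= 1")
    if preset.duty_factor_mean >= 100.0:
        raise ValueError("duty factor must be < 100 %")
    if rng is None:
        rng = np.random.default_rng(rng_seed)

    mean_T = preset.stride_duration_mean * horse.stride_duration_multiplier
    durations = _truncated_normal(
        rng, mean_T, preset.stride_duration_sd, MIN_STRIDE_DURATION, n_strides
    )
    starts = np.concatenate([[0.0], np.cumsum(durations)])[:-1]

    # Shared stride-level duty draw + small per-limb noise, clipped to a
    # physical range.
    duty_stride = rng.normal(preset.duty_factor_mean, preset.duty_factor_sd, n_strides)
    duty = duty_stride[:, None] + rng.normal(0.0, preset.limb_duty_sd, (n_strides, 4))
    duty = np.clip(duty, 5.0, 98.0)

    jitter = (
        rng.normal(0.0, preset.phase_jitter_sd, (n_strides, 4))
        if preset.phase_jitter_sd > 0
        else np.zeros((n_strides, 4))
    )

    limbs = list(Limb)
    intervals = []
    for j, limb in enumerate(limbs):
        phi = preset.phase_offset[limb]
        on = starts + (phi + jitter[:, j]) * durations
        off = on + duty[:, j] / 100.0 * durations
        # Repair rare jitter-induced overlaps of consecutive stances.
        for i in range(1, n_strides):
            if on[i] < off[i - 1]:
                off[i - 1] = on[i] - 1e-9
        intervals.extend(
            _mk_interval(limb, float(a), float(b)) for a, b in zip(on, off)
        )

    # Jitter can push the very first onset below t=0; translate the whole
    # timeline so it starts at 0 (all downstream features are
    # translation-invariant).
    shift = -min(0.0, min(iv.on_time for iv in intervals))
    if shift > 0:
        intervals = [
            _mk_interval(iv.limb, iv.on_time + shift, iv.off_time + shift)
            for iv in intervals
        ]
    total = max(iv.off_time for iv in intervals) + 0.05
    tl = FootfallTimeline(
        horse_id=horse.horse_id,
        gait=preset.gait,
        intervals=sorted(intervals, key=lambda iv: iv.on_time),
        total_duration=total,
    )
    tl.validate()
    return tl


def _mk_interval(limb, on, off):
    from .types import StanceInterval

    return StanceInterval(limb=limb, on_time=on, off_time=off)


# --- signal synthesis -------------------------------------------------------

#: Impact-transient decay time constant (s).
_TRANSIENT_TAU = 0.03
#: Transient amplitude scale: amplitude = _IMPACT_SCALE / stance_duration,
#: so faster gaits (shorter stance) produce larger peaks.
_IMPACT_SCALE = 0.5
#: Attenuation of limb transients as seen by the upper-body sensors,
#: per (site, limb-group) — fore-mounted sensors see fore impacts better.
_UPPER_ATTEN = {
    "poll": {"fore": 0.40, "hind": 0.12},
    "withers": {"fore": 0.35, "hind": 0.20},
    "pelvis": {"fore": 0.12, "hind": 0.40},
}
_AXIS_WEIGHT = {"acc_x": 1.0, "acc_y": 0.6, "acc_z": 0.8}
_GYR_WEIGHT = {"gyr_x": 1.0, "gyr_y": 0.7, "gyr_z": 0.5}
#: Gaits whose footfall pattern contains a synchronous limb pair; their
#: upper-body vertical harmonic runs at two beats per stride.
_TWO_BEAT = {Gait.trot, Gait.pace, Gait.lcanter, Gait.rcanter}


def _transient_train(t: np.ndarray, onsets: np.ndarray, amps: np.ndarray) -> np.ndarray:
    out = np.zeros_like(t)
    for t0, a in zip(onsets, amps):
        m = t >= t0
        out[m] += a * np.exp(-(t[m] - t0) / _TRANSIENT_TAU)
    return out


def _stride_phase(t: np.ndarray, ref_onsets: np.ndarray) -> np.ndarray:
    """Piecewise-linear stride phase: 0 at each reference hoof-on, advancing
    by 1 per stride; extrapolated at the edges with the adjacent rate."""
    if len(ref_onsets) < 2:
        return np.zeros_like(t)
    idx = np.arange(len(ref_onsets), dtype=float)
    return np.interp(t, ref_onsets, idx, left=0.0, right=float(idx[-1]))


def generate_signals(
    timeline: FootfallTimeline,
    sample_rate: float = 200.0,
    rng_seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    noise_sd: Optional[float] = None,
) -> SignalBlock:
    """Synthesize a 42-channel (7 sites x 6 axes) IMU-like stream.

    Limb sensors carry an impact transient at each of their hoof-on events
    (amplitude inversely proportional to stance duration) plus a
    swing-phase oscillation on the gyroscope axes.  Upper-body sensors
    (poll, withers, pelvis) carry the attenuated sum of limb transients and
    a vertical harmonic locked to stride phase — fundamental two beats per
    stride for gaits with a synchronous limb pair, one otherwise — plus
    Gaussian noise.  Deterministic given the seed.
    """
    if not timeline.intervals:
        raise ValueError("cannot synthesize signals from an empty timeline")
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    if noise_sd is None:
        noise_sd = 0.0

    n = int(round(timeline.total_duration * sample_rate))
    t = np.arange(n) / sample_rate
    names = default_channel_names()
    values = np.zeros((n, len(names)))

    limb_base: Dict[Limb, np.ndarray] = {}
    limb_swing: Dict[Limb, np.ndarray] = {}
    for limb in Limb:
        ivs = timeline.limb_intervals(limb)
        onsets = np.array([iv.on_time for iv in ivs])
        amps = np.array([_IMPACT_SCALE / iv.duration for iv in ivs])
        limb_base[limb] = _transient_train(t, onsets, amps)
        # Swing-phase oscillation: one protraction cycle per swing window.
        swing = np.zeros_like(t)
        for a, b in zip(ivs, ivs[1:]):
            m = (t >= a.off_time) & (t < b.on_time)
            dur = b.on_time - a.off_time
            if dur > 0:
                swing[m] = np.sin(np.pi * (t[m] - a.off_time) / dur)
        limb_swing[limb] = swing

    ref_onsets = timeline.onsets(Limb.LH)
    phase = _stride_phase(t, ref_onsets)
    n_beats = 2 if timeline.gait in _TWO_BEAT else 1
    harmonic = np.sin(2 * np.pi * n_beats * phase)
    mean_amp = float(np.mean([_IMPACT_SCALE / iv.duration for iv in timeline.intervals]))

    col = {c: i for i, c in enumerate(names)}
    for limb in Limb:
        base, swing = limb_base[limb], limb_swing[limb]
        for axis, w in _AXIS_WEIGHT.items():
            values[:, col[f"{limb.value}.{axis}"]] = w * base
        for axis, w in _GYR_WEIGHT.items():
            values[:, col[f"{limb.value}.{axis}"]] = (
                0.2 * w * base + 0.3 * mean_amp * w * swing
            )

    fore = (Limb.LF, Limb.RF)
    for site in ("poll", "withers", "pelvis"):
        att = _UPPER_ATTEN[site]
        mix = sum(
            (att["fore"] if limb in fore else att["hind"]) * limb_base[limb]
            for limb in Limb
        )
        for axis, w in _AXIS_WEIGHT.items():
            values[:, col[f"{site}.{axis}"]] = w * mix
        values[:, col[f"{site}.acc_z"]] += 0.6 * mean_amp * harmonic
        for axis, w in _GYR_WEIGHT.items():
            values[:, col[f"{site}.{axis}"]] = 0.3 * w * mix + 0.25 * mean_amp * w * np.sin(
                2 * np.pi * phase
            )

    if noise_sd > 0:
        values += rng.normal(0.0, noise_sd, values.shape)

    return SignalBlock(
        horse_id=timeline.horse_id,
        gait=timeline.gait,
        sample_rate=sample_rate,
        channel_names=names,
        values=values,
        meta={"n_strides": int(len(ref_onsets))},
    )


# --- cohorts ----------------------------------------------------------------


@dataclass
class BreedCohort:
    """Number of horses of one breed and the gaits they are recorded in."""

    n_horses: int
    gaits: Optional[Sequence[Gait]] = None  # None = all breed-legal gaits


@dataclass
class CohortConfig:
    """Composition of a synthetic study cohort.

    Defaults mirror the reference data set: breed -> gait availability
    (warmbloods and Franches-Montagnes show the standard gaits only,
    Icelandic horses add tölt and pace, Colombian criollos add paso fino
    and trocha), per-gait stride totals proportional to the study's stride
    counts (walk and trot dominate; pace is rarest), and uncontrolled
    locomotion speed: every trial draws a lognormal speed multiplier
    (``trial_speed_sd``) on top of the horse's own multiplier, while the
    within-trial stride-duration SD is shrunk to
    ``within_trial_sd_fraction`` of the per-gait population SD, so pooled
    per-gait spreads still approximate the population statistics.
    """

    breeds: Dict[Breed, BreedCohort] = field(
        default_factory=lambda: {
            Breed.warmblood: BreedCohort(n_horses=10),
            Breed.icelandic: BreedCohort(n_horses=10),
            Breed.franches_montagnes: BreedCohort(n_horses=5),
            Breed.colombian_criollo: BreedCohort(n_horses=8),
        }
    )
    total_strides: int = 2000
    trials_per_gait: int = 2
    trial_speed_sd: float = 0.15
    within_trial_sd_fraction: float = 0.4
    signal_sample_rate: float = 200.0
    signal_noise_sd: float = 0.3
    #: Trocha sits on a continuum with the trot (clean diagonal
    #: dissociation at one end, trot-like timing at the other).  Each
    #: trocha trial draws a cleanness factor c ~ U(min_cleanness, 1) and
    #: its generative parameters interpolate between the trot (c=0) and
    #: trocha (c=1) presets.  Set to 1.0 for ideal trocha only.
    trocha_min_cleanness: float = 0.4
    walk_printed_duration: bool = False
    allow_illegal_gaits: bool = False

    def resolved_gaits(self, breed: Breed) -> Sequence[Gait]:
        spec = self.breeds[breed]
        gaits = tuple(spec.gaits) if spec.gaits is not None else BREED_GAITS[breed]
        if not self.allow_illegal_gaits:
            for g in gaits:
                if g not in BREED_GAITS[breed]:
                    raise ValueError(
                        f"gait {g.value} is not displayed by breed {breed.value}; "
                        "set allow_illegal_gaits to override"
                    )
        return gaits


_BREED_PREFIX = {
    Breed.warmblood: "wb",
    Breed.icelandic: "is",
    Breed.franches_montagnes: "fm",
    Breed.colombian_criollo: "cc",
}


def cohort_profiles(config: CohortConfig, rng_seed: int) -> List[HorseProfile]:
    """Draw one profile per horse; the stride-duration multiplier is drawn
    once per horse (breed base + individual variation) and reused across all
    of that horse's trials."""
    profiles: List[HorseProfile] = []
    for breed, spec in config.breeds.items():
        for i in range(spec.n_horses):
            horse_id = f"{_BREED_PREFIX[breed]}{i + 1:02d}"
            rng = child_rng(rng_seed, "horse", horse_id)
            mult = BREED_STRIDE_MULTIPLIER[breed] + rng.normal(0.0, HORSE_MULTIPLIER_SD)
            profiles.append(
                HorseProfile(
                    horse_id=horse_id,
                    breed=breed,
                    stride_duration_multiplier=float(max(mult, 0.5)),
                    signal_noise_sd=config.signal_noise_sd,
                )
            )
    return profiles


def _gait_stride_quota(config: CohortConfig, profiles: List[HorseProfile]) -> Dict[Gait, int]:
    """Strides per (horse, gait, trial), sized so per-gait totals follow the
    reference stride-count proportions."""
    from .presets import STRIDE_COUNTS

    horses_per_gait: Dict[Gait, int] = {}
    for p in profiles:
        for g in config.resolved_gaits(p.breed):
            horses_per_gait[g] = horses_per_gait.get(g, 0) + 1
    total_share = sum(STRIDE_COUNTS[g] for g in horses_per_gait)
    quota: Dict[Gait, int] = {}
    for g, n_horses in horses_per_gait.items():
        share = STRIDE_COUNTS[g] / total_share
        per_trial = config.total_strides * share / (n_horses * config.trials_per_gait)
        quota[g] = max(4, int(round(per_trial)))
    return quota


def _blend_presets(a: GaitPreset, b: GaitPreset, w: float) -> GaitPreset:
    """Linear interpolation of two presets (w=0 -> a, w=1 -> b); the gait
    label is taken from b."""
    from dataclasses import replace

    lerp = lambda x, y: (1.0 - w) * x + w * y  # noqa: E731
    return replace(
        b,
        phase_offset={l: lerp(a.phase_offset[l], b.phase_offset[l]) for l in Limb},
        duty_factor_mean=lerp(a.duty_factor_mean, b.duty_factor_mean),
        duty_factor_sd=lerp(a.duty_factor_sd, b.duty_factor_sd),
        stride_duration_mean=lerp(a.stride_duration_mean, b.stride_duration_mean),
        stride_duration_sd=lerp(a.stride_duration_sd, b.stride_duration_sd),
        phase_jitter_sd=lerp(a.phase_jitter_sd, b.phase_jitter_sd),
    )


def generate_cohort(
    config: CohortConfig,
    rng_seed: int,
    with_signals: bool = True,
) -> List[Tuple[FootfallTimeline, Optional[SignalBlock]]]:
    """Generate ``trials_per_gait`` trials per (horse, breed-legal gait).

    Each trial gets its own lognormal speed multiplier (uncontrolled
    speed across trials) and a within-trial stride-duration SD shrunk per
    the config.  Returns (timeline, signal_block) pairs;
    ``with_signals=False`` skips signal synthesis (signal slot is None)
    for feature-only pipelines.
    """
    from dataclasses import replace

    presets = builtin_presets(walk_printed_duration=config.walk_printed_duration)
    profiles = cohort_profiles(config, rng_seed)
    quota = _gait_stride_quota(config, profiles)
    out: List[Tuple[FootfallTimeline, Optional[SignalBlock]]] = []
    for profile in profiles:
        for gait in config.resolved_gaits(profile.breed):
            preset = replace(
                presets[gait],
                stride_duration_sd=presets[gait].stride_duration_sd
                * config.within_trial_sd_fraction,
            )
            for trial in range(config.trials_per_gait):
                trial_id = f"t{trial + 1}"
                rng = child_rng(rng_seed, "trial", profile.horse_id, gait.value, trial_id)
                speed = float(np.exp(rng.normal(0.0, config.trial_speed_sd)))
                trial_profile = replace(
                    profile,
                    stride_duration_multiplier=profile.stride_duration_multiplier * speed,
                )
                trial_preset = preset
                if gait is Gait.trocha and config.trocha_min_cleanness < 1.0:
                    c = float(rng.uniform(config.trocha_min_cleanness, 1.0))
                    trot = replace(
                        presets[Gait.trot],
                        stride_duration_sd=presets[Gait.trot].stride_duration_sd
                        * config.within_trial_sd_fraction,
                    )
                    trial_preset = _blend_presets(trot, preset, c)
                tl = generate_timeline(trial_preset, trial_profile, quota[gait], rng=rng)
                tl.trial = trial_id
                block = None
                if with_signals:
                    block = generate_signals(
                        tl,
                        sample_rate=config.signal_sample_rate,
                        rng=child_rng(
                            rng_seed, "signal", profile.horse_id, gait.value, trial_id
                        ),
                        noise_sd=profile.signal_noise_sd,
                    )
                    block.meta["trial"] = trial_id
                out.append((tl, block))
    return out
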