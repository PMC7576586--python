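"""Core domain types for quadruped gait analysis.

The vocabulary follows standard equine biomechanics: a *stride* is one
complete limb-movement cycle (reference hoof contact to the next contact of
the same hoof); the *stance phase* is the weight-bearing part of a limb's
stride; the *duty factor* is stance duration as a percentage of stride
duration.  Hind limbs are labelled LH/RH (left/right hind), fore limbs
LF/RF.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "Limb",
    "Gait",
    "Breed",
    "GaitPreset",
    "HorseProfile",
    "StanceInterval",
    "FootfallTimeline",
    "SignalBlock",
    "SENSOR_SITES",
    "SENSOR_AXES",
    "default_channel_names",
]


class Limb(str, enum.Enum):
    """The four limbs of a quadruped."""

    LF = "LF"
    RF = "RF"
    LH = "LH"
    RH = "RH"


class Gait(str, enum.Enum):
    """The eight gait classes: the three standard gaits (walk, trot, the two
    canter leads) plus the gaited-breed gaits tölt, pace, paso fino and
    trocha."""

    walk = "walk"
    trot = "trot"
    lcanter = "lcanter"
    rcanter = "rcanter"
    tolt = "tolt"
    pace = "pace"
    paso = "paso"
    trocha = "trocha"


class Breed(str, enum.Enum):
    warmblood = "warmblood"
    icelandic = "icelandic"
    franches_montagnes = "franches_montagnes"
    colombian_criollo = "colombian_criollo"


@dataclass(frozen=True)
class GaitPreset:
    """Generative parameterization of one gait.

    Parameters
    ----------
    phase_offset
        Hoof-on time of each limb as a fraction of the stride, in [0, 1).
        Encodes the footfall ordering (e.g. trot = synchronous diagonal
        pairs at 0 and 0.5).
    duty_factor_mean, duty_factor_sd
        Stance duration as percent of stride (population mean and SD).
    stride_duration_mean, stride_duration_sd
        Seconds.
    phase_jitter_sd
        SD of per-stride, per-limb Gaussian jitter on the phase offset,
        as a fraction of the stride.
    duty_limb_sd
        SD of the additional per-limb duty-factor noise on top of the
        shared stride-level draw; defaults to 0.1 * duty_factor_sd so that
        a zero-SD preset yields exactly reproducible duty factors.
    """

    gait: Gait
    phase_offset: Mapping[Limb, float]
    duty_factor_mean: float
    duty_factor_sd: float
    stride_duration_mean: float
    stride_duration_sd: float
    phase_jitter_sd: float = 0.01
    duty_limb_sd: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.duty_factor_mean < 100.0:
            raise ValueError("duty_factor_mean must lie in (0, 100)")
        if self.stride_duration_mean <= 0:
            raise ValueError("stride_duration_mean must be positive")
        if self.stride_duration_sd < 0 or self.duty_factor_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if set(self.phase_offset) != set(Limb):
            raise ValueError("phase_offset must cover all four limbs")
        for limb, phi in self.phase_offset.items():
            if not 0.0 <= phi < 1.0:
                raise ValueError(f"phase offset of {limb} outside [0, 1)")

    @property
    def limb_duty_sd(self) -> float:
        return 0.1 * self.duty_factor_sd if self.duty_limb_sd is None else self.duty_limb_sd


@dataclass(frozen=True)
class HorseProfile:
    """One animal in a cohort.

    ``stride_duration_multiplier`` scales the preset stride-duration mean
    for this horse (conformation/breed effect); ``signal_noise_sd`` is the
    SD of the additive Gaussian sensor noise, in signal units.
    """

    horse_id: str
    breed: Breed = Breed.warmblood
    stride_duration_multiplier: float = 1.0
    signal_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.stride_duration_multiplier <= 0:
            raise ValueError("stride_duration_multiplier must be positive")
        if self.signal_noise_sd < 0:
            raise ValueError("signal_noise_sd must be non-negative")


@dataclass(frozen=True)
class StanceInterval:
    """Period of ground contact (weight bearing) of an individual limb."""

    limb: Limb
    on_time: float
    off_time: float

    def __post_init__(self) -> None:
        if not self.on_time < self.off_time:
            raise ValueError(
                f"stance interval for {self.limb.value} has on_time "
                f"{self.on_time} >= off_time {self.off_time}"
            )

    @property
    def duration(self) -> float:
        return self.off_time - self.on_time


@dataclass
class FootfallTimeline:
    """Ground-truth hoof-on/hoof-off events for one trial.

    Per-limb stance intervals must be pairwise disjoint, time-sorted and
    contained in [0, total_duration].
    """

    horse_id: str
    gait: Gait
    intervals: List[StanceInterval]
    total_duration: float
    trial: str = ""

    def limb_intervals(self, limb: Limb) -> List[StanceInterval]:
        return sorted(
            (iv for iv in self.intervals if iv.limb == limb),
            key=lambda iv: iv.on_time,
        )

    def validate(self) -> None:
        if self.total_duration <= 0:
            raise ValueError("total_duration must be positive")
        for limb in Limb:
            ivs = self.limb_intervals(limb)
            for a, b in zip(ivs, ivs[1:]):
                if b.on_time < a.off_time:
                    raise ValueError(
                        f"overlapping stance intervals for limb {limb.value} "
                        f"at t={a.off_time:.4f}/{b.on_time:.4f}"
                    )
        for iv in self.intervals:
            if iv.on_time < 0 or iv.off_time > self.total_duration:
                raise ValueError(
                    f"stance interval [{iv.on_time}, {iv.off_time}] outside "
                    f"[0, {self.total_duration}]"
                )

    def onsets(self, limb: Limb) -> np.ndarray:
        return np.array([iv.on_time for iv in self.limb_intervals(limb)])


SENSOR_SITES: Sequence[str] = ("poll", "withers", "pelvis", "LF", "RF", "LH", "RH")
SENSOR_AXES: Sequence[str] = ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")


def default_channel_names() -> List[str]:
    """The 42 canonical channel names, ``site.axis`` (7 sites x 6 axes)."""
    return [f"{site}.{axis}" for site in SENSOR_SITES for axis in SENSOR_AXES]


@dataclass
class SignalBlock:
    """Multichannel fixed-rate sensor stream for one trial.

    ``values`` is an [n_samples x n_channels] float matrix; channels are
    named ``site.axis`` (accelerometer and gyroscope triplets for the seven
    sensor sites: poll, withers, pelvis and the four limbs).
    """

    horse_id: str
    gait: Gait
    sample_rate: float
    channel_names: List[str]
    values: np.ndarray
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.values.ndim != 2 or self.values.shape[1] != len(self.channel_names):
            raise ValueError("values must be [n_samples x n_channels]")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, self.channel_names.index(name)]

    def select_sites(self, sites: Sequence[str]) -> "SignalBlock":
        """Restrict the block to the channels of the given sensor sites."""
        keep = [i for i, c in enumerate(self.channel_names) if c.split(".")[0] in sites]
        if not keep:
            raise ValueError(f"no channels for sites {sites!r}")
        return SignalBlock(
            horse_id=self.horse_id,
            gait=self.gait,
            sample_rate=self.sample_rate,
            channel_names=[self.channel_names[i] for i in keep],
            values=self.values[:, keep].copy(),
            meta=dict(self.meta),
        )
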