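"""Built-in generative presets for the eight gait classes.

Stride-duration and duty-factor moments come from published descriptive
statistics for 7576 strides of 120 horses of four breeds; phase offsets
encode the canonical footfall orderings of each gait:

* trot  — two-beat, synchronous diagonal pairs (LH+RF, RH+LF) at 0 and 0.5;
* pace  — two-beat, synchronous lateral pairs (LH+LF, RH+RF) at 0 and 0.5;
* walk, tölt, paso fino — lateral-sequence four-beat, equally spaced
  (LH, LF, RH, RF at 0, 0.25, 0.5, 0.75);
* trocha — diagonal-sequence four-beat: a trot whose diagonal partners are
  dissociated by a small fraction ``delta`` of the stride;
* canters — three-beat with one synchronous diagonal pair; the two leads
  are mirror images.

The walk row of the source statistics is internally inconsistent: the
printed stride duration (1.80 s) disagrees with the printed stride
frequency (0.95 Hz) and with stance 0.65 s at duty 60.6 % (both imply
~1.05-1.07 s).  The default walk preset therefore uses the derived 1.07 s;
pass ``walk_printed_duration=True`` to use the printed 1.80 s instead.
"""

from __future__ import annotations

from typing import Dict, Mapping

from .types import Gait, GaitPreset, Limb

__all__ = [
    "builtin_presets",
    "TABLE_STATS",
    "STRIDE_COUNTS",
    "TROCHA_DELTA",
]

#: Per-gait descriptive statistics: (stride_duration_mean, sd,
#: stride_frequency_mean, sd, stance_duration_mean, sd, duty_mean, duty_sd).
TABLE_STATS: Mapping[Gait, tuple] = {
    Gait.walk: (1.80, 0.17, 0.95, 0.14, 0.65, 0.12, 60.60, 1.85),
    Gait.trot: (0.63, 0.12, 1.64, 0.32, 0.28, 0.05, 44.20, 4.76),
    Gait.lcanter: (0.50, 0.05, 2.03, 0.22, 0.19, 0.02, 39.10, 3.58),
    Gait.rcanter: (0.49, 0.04, 2.05, 0.18, 0.20, 0.02, 40.00, 3.28),
    Gait.tolt: (0.42, 0.04, 2.39, 0.19, 0.15, 0.02, 36.10, 2.63),
    Gait.pace: (0.54, 0.04, 1.87, 0.13, 0.24, 0.03, 44.20, 3.78),
    Gait.paso: (0.39, 0.03, 2.55, 0.15, 0.21, 0.01, 53.70, 2.49),
    Gait.trocha: (0.39, 0.04, 2.56, 0.20, 0.20, 0.03, 51.00, 3.34),
}

#: Stride counts per gait in the reference data set (used for
#: imbalance-realistic cohort sizing and reporting).
STRIDE_COUNTS: Mapping[Gait, int] = {
    Gait.walk: 1966,
    Gait.trot: 1932,
    Gait.lcanter: 519,
    Gait.rcanter: 483,
    Gait.tolt: 1572,
    Gait.pace: 277,
    Gait.paso: 401,
    Gait.trocha: 426,
}

#: Diagonal dissociation of the trocha, fraction of stride.
TROCHA_DELTA = 0.08

#: Derived walk stride duration (stance 0.65 s / duty 60.6 %).
_WALK_DERIVED_DURATION = 1.07

_LATERAL_SEQUENCE: Dict[Limb, float] = {
    Limb.LH: 0.0,
    Limb.LF: 0.25,
    Limb.RH: 0.5,
    Limb.RF: 0.75,
}

_PHASES: Dict[Gait, Dict[Limb, float]] = {
    Gait.walk: dict(_LATERAL_SEQUENCE),
    Gait.tolt: dict(_LATERAL_SEQUENCE),
    Gait.paso: dict(_LATERAL_SEQUENCE),
    Gait.trot: {Limb.LH: 0.0, Limb.RF: 0.0, Limb.RH: 0.5, Limb.LF: 0.5},
    Gait.pace: {Limb.LH: 0.0, Limb.LF: 0.0, Limb.RH: 0.5, Limb.RF: 0.5},
    Gait.trocha: {
        Limb.LH: 0.0,
        Limb.RF: TROCHA_DELTA,
        Limb.RH: 0.5,
        Limb.LF: 0.5 + TROCHA_DELTA,
    },
    # Transverse canter, three-beat: trailing hind, then the synchronous
    # diagonal pair, then the leading fore.
    Gait.rcanter: {Limb.LH: 0.0, Limb.RH: 0.3, Limb.LF: 0.3, Limb.RF: 0.45},
    Gait.lcanter: {Limb.RH: 0.0, Limb.LH: 0.3, Limb.RF: 0.3, Limb.LF: 0.45},
}

#: Trocha footfall timing is notoriously irregular; its jitter default is
#: raised relative to the other gaits.
_JITTER: Dict[Gait, float] = {g: 0.01 for g in Gait}
_JITTER[Gait.trocha] = 0.025


def builtin_presets(walk_printed_duration: bool = False) -> Dict[Gait, GaitPreset]:
    """Return the eight built-in gait presets.

    Parameters
    ----------
    walk_printed_duration
        If True, the walk preset uses the printed 1.80 s stride duration
        instead of the internally consistent derived 1.07 s (see module
        docstring).
    """
    presets: Dict[Gait, GaitPreset] = {}
    for gait, (sd_mean, sd_sd, _f, _fs, _st, _sts, duty, duty_sd) in TABLE_STATS.items():
        if gait is Gait.walk and not walk_printed_duration:
            sd_mean = _WALK_DERIVED_DURATION
        presets[gait] = GaitPreset(
            gait=gait,
            phase_offset=dict(_PHASES[gait]),
            duty_factor_mean=duty,
            duty_factor_sd=duty_sd,
            stride_duration_mean=sd_mean,
            stride_duration_sd=sd_sd,
            phase_jitter_sd=_JITTER[gait],
        )
    return presets
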