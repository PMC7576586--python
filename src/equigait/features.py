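"""Stride segmentation and stride/interlimb feature extraction.

From a :class:`~equigait.types.FootfallTimeline` this module derives, per
stride, the standard temporal gait variables: stride duration and
frequency, per-limb stance durations and duty factors, diagonal and
lateral advanced placement (DAP/LAP, the Hildebrand-diagram coordinates),
the support-phase statistics (min/max/median number of limbs on the
ground, percentage of the stride spent in quadrupedal / tripedal /
bipedal / single-limb support and in suspension) and the six limb-pair
stance-overlap percentages.

Conventions
-----------
* A stride runs from one reference-limb hoof-on to the next; the default
  reference limb is the left hind (LH), consistent with hind-centric gait
  formulas.
* Advanced placements are signed circular differences
  ``(fore hoof-on - hind hoof-on) / stride * 100`` mapped to (-50, 50],
  averaged over the left and right pairs; positive means the fore contact
  follows the hind contact.  The fore limb is ipsilateral for LAP and
  contralateral (diagonal) for DAP.
* Support-phase statistics are computed by an exact event sweep over the
  stance on/off boundaries clipped to the stride window.
* Per-limb stance durations (hence duty factors) use the full, unclipped
  stance interval that starts inside the window, and limb-pair overlaps
  are measured on the stride circle (wrapping across the window edge), so
  a stance phase split by the window boundary is not undercounted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import FootfallTimeline, Gait, Limb, StanceInterval

__all__ = [
    "StrideWindow",
    "StrideFeatures",
    "segment_strides",
    "support_profile",
    "compute_features",
    "advanced_placements",
    "hildebrand_coordinates",
    "feature_table",
    "FEATURE_COLUMNS",
    "OVERLAP_PAIRS",
]

log = logging.getLogger(__name__)

#: The six limb pairs whose stance overlap is reported, in canonical order.
OVERLAP_PAIRS: Sequence[Tuple[Limb, Limb]] = (
    (Limb.LF, Limb.RF),
    (Limb.LH, Limb.RH),
    (Limb.LF, Limb.LH),
    (Limb.RF, Limb.RH),
    (Limb.LF, Limb.RH),
    (Limb.RF, Limb.LH),
)

#: Fixed column order of the feature table (21 variables).
FEATURE_COLUMNS: List[str] = [
    "stride_duration",
    "stance_duration",
    "stride_frequency",
    "duty_factor",
    "duty_factor_hind",
    "diagonal_advanced_placement",
    "lateral_advanced_placement",
    "min_limbs",
    "max_limbs",
    "median_limbs",
    "pct_quadrupedal",
    "pct_tripedal",
    "pct_bipedal",
    "pct_single",
    "pct_suspension",
    "overlap_lf_rf",
    "overlap_lh_rh",
    "overlap_lf_lh",
    "overlap_rf_rh",
    "overlap_lf_rh",
    "overlap_rf_lh",
]

#: Onsets closer than this (s) are displayed as simultaneous in footfall
#: ordering summaries; they are never merged in arithmetic.
SIMULTANEITY_TOL = 1e-3


@dataclass
class StrideWindow:
    """One stride: reference hoof-on to the next reference hoof-on.

    ``intervals`` are the stance intervals of all limbs clipped to
    ``[start, end)``; ``onset_intervals`` maps each limb to its first
    *unclipped* stance interval whose onset lies inside the window (absent
    for limbs without an onset, making the window incomplete).
    """

    start: float
    end: float
    reference_limb: Limb
    intervals: List[StanceInterval]
    onset_intervals: Dict[Limb, StanceInterval]
    #: Per limb, the reference stride cycle its anchored stance belongs to
    #: (this window's duration, or the next reference cycle when the onset
    #: was borrowed from just past the window edge).
    limb_cycles: Dict[Limb, float] = field(default_factory=dict)
    horse_id: str = ""
    gait: Optional[Gait] = None

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError("stride window must have end > start")

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def complete(self) -> bool:
        return set(self.onset_intervals) == set(Limb)


def segment_strides(
    timeline: FootfallTimeline, reference_limb: Limb = Limb.LH
) -> List[StrideWindow]:
    """Cut a timeline into stride windows at reference-limb hoof-on events.

    Returns one window per consecutive pair of reference onsets.  With
    fewer than two reference onsets an empty list is returned and a
    warning logged.  Windows missing any limb's onset are flagged
    incomplete (``window.complete``); feature tables exclude them.
    """
    ref_onsets = timeline.onsets(reference_limb)
    if len(ref_onsets) < 2:
        log.warning(
            "timeline %s/%s has %d %s onsets; no strides segmented",
            timeline.horse_id,
            timeline.gait.value,
            len(ref_onsets),
            reference_limb.value,
        )
        return []

    by_limb = {limb: timeline.limb_intervals(limb) for limb in Limb}
    windows: List[StrideWindow] = []
    for w_idx, (start, end) in enumerate(zip(ref_onsets, ref_onsets[1:])):
        clipped: List[StanceInterval] = []
        onset_ivs: Dict[Limb, StanceInterval] = {}
        # A limb synchronous with the reference (e.g. the trot's diagonal
        # partner) jitters across the window edge; anchoring each limb to
        # its first onset at or after the window start — allowing a small
        # slack past the end, handled circularly downstream — keeps such
        # strides instead of discarding them with a duration-selection
        # bias.
        slack = end + 0.1 * (end - start)
        cycles: Dict[Limb, float] = {}
        for limb, ivs in by_limb.items():
            for iv in ivs:
                if iv.off_time <= start or iv.on_time >= end:
                    continue
                clipped.append(
                    StanceInterval(
                        limb=limb,
                        on_time=max(iv.on_time, start),
                        off_time=min(iv.off_time, end),
                    )
                )
            for iv in ivs:
                if start <= iv.on_time < slack:
                    onset_ivs[limb] = iv
                    # duty divides the stance by the reference cycle it
                    # belongs to: this window, or the next one when the
                    # onset was borrowed from past the window edge
                    if iv.on_time < end or w_idx + 2 >= len(ref_onsets):
                        cycles[limb] = float(end - start)
                    else:
                        cycles[limb] = float(ref_onsets[w_idx + 2] - end)
                    break
        windows.append(
            StrideWindow(
                start=float(start),
                end=float(end),
                reference_limb=reference_limb,
                intervals=clipped,
                onset_intervals=onset_ivs,
                limb_cycles=cycles,
                horse_id=timeline.horse_id,
                gait=timeline.gait,
            )
        )
    return windows


def support_profile(window: StrideWindow) -> Tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant limbs-in-stance count over the stride.

    Returns ``(bounds, counts)`` where ``bounds`` is the increasing array
    of segment boundaries covering ``[start, end)`` and ``counts[i]`` is
    the number of limbs in stance on ``[bounds[i], bounds[i+1])``.
    Computed by an event sweep over the sorted on/off boundaries; segment
    lengths sum to the stride duration exactly.
    """
    _check_disjoint(window)
    events: List[Tuple[float, int]] = []
    for iv in window.intervals:
        events.append((iv.on_time, +1))
        events.append((iv.off_time, -1))
    events.sort()

    bounds = [window.start]
    counts: List[int] = []
    cur = 0
    prev = window.start
    for t, delta in events:
        if t > prev:
            bounds.append(t)
            counts.append(cur)
            prev = t
        cur += delta
    if prev < window.end:
        bounds.append(window.end)
        counts.append(cur)
    arr_counts = np.array(counts, dtype=int)
    if arr_counts.min(initial=0) < 0 or arr_counts.max(initial=0) > 4:
        raise ValueError("support count outside 0..4; invalid window intervals")
    return np.array(bounds), arr_counts


def _check_disjoint(window: StrideWindow) -> None:
    for limb in Limb:
        ivs = sorted(
            (iv for iv in window.intervals if iv.limb == limb),
            key=lambda iv: iv.on_time,
        )
        for a, b in zip(ivs, ivs[1:]):
            if b.on_time < a.off_time:
                raise ValueError(f"overlapping same-limb intervals for {limb.value}")


def _circular_pct(delta_pct: float) -> float:
    """Map a percent-of-stride difference to the circular range (-50, 50].

    A small tolerance keeps a difference of exactly half a stride (the
    trot/pace synchrony cases) from being flipped to -50 by floating-point
    noise.
    """
    m = delta_pct % 100.0
    return min(m, 50.0) if m <= 50.0 + 1e-9 else m - 100.0


def _circular_mean_pct(values) -> float:
    """Circular mean of percent-of-stride phase differences.

    A plain arithmetic mean misbehaves at the wrap point: two jittered
    trot pairs at +49 and -49 (which are 2 % apart on the stride circle)
    would average to 0 instead of (+/-)50.
    """
    ang = np.asarray(values) / 100.0 * 2.0 * np.pi
    mean_ang = float(np.arctan2(np.mean(np.sin(ang)), np.mean(np.cos(ang))))
    return _circular_pct(mean_ang / (2.0 * np.pi) * 100.0)


def advanced_placements(window: StrideWindow) -> Tuple[float, float]:
    """Diagonal and lateral advanced placement, percent of stride.

    For each hind limb the signed circular hoof-on difference
    (fore - hind) / stride * 100 is mapped to (-50, 50]; DAP pairs each
    hind with its contralateral fore, LAP with its ipsilateral fore.  The
    returned values are circular means over the left and right pairs.
    """
    if not window.complete:
        raise ValueError("advanced placements require a complete stride window")
    on = {limb: window.onset_intervals[limb].on_time for limb in Limb}
    D = window.duration
    dap_pairs = [(Limb.LH, Limb.RF), (Limb.RH, Limb.LF)]
    lap_pairs = [(Limb.LH, Limb.LF), (Limb.RH, Limb.RF)]
    dap = _circular_mean_pct(
        [_circular_pct((on[f] - on[h]) / D * 100.0) for h, f in dap_pairs]
    )
    lap = _circular_mean_pct(
        [_circular_pct((on[f] - on[h]) / D * 100.0) for h, f in lap_pairs]
    )
    return dap, lap


def _circle_arcs(a: float, length: float, D: float) -> List[Tuple[float, float]]:
    """Arc [a, a+length) on a circle of circumference D, as linear segments."""
    a %= D
    if a + length <= D:
        return [(a, a + length)]
    return [(a, D), (0.0, a + length - D)]


def _pair_overlap_pct(window: StrideWindow, a: Limb, b: Limb) -> float:
    """Stance overlap of limbs a and b, percent of stride, measured on the
    stride circle using the unclipped onset-anchored stance intervals."""
    D = window.duration
    total = 0.0
    iva = window.onset_intervals[a]
    ivb = window.onset_intervals[b]
    arcs_a = _circle_arcs(iva.on_time - window.start, min(iva.duration, D), D)
    arcs_b = _circle_arcs(ivb.on_time - window.start, min(ivb.duration, D), D)
    for s1, e1 in arcs_a:
        for s2, e2 in arcs_b:
            total += max(0.0, min(e1, e2) - max(s1, s2))
    return total / D * 100.0


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Lower weighted median: smallest value whose cumulative weight reaches
    half the total."""
    order = np.argsort(values)
    v = values[order]
    cw = np.cumsum(weights[order])
    return float(v[np.searchsorted(cw, 0.5 * cw[-1])])


@dataclass
class StrideFeatures:
    """All 21 per-stride variables (plus provenance labels)."""

    horse_id: str
    gait_label: Optional[Gait]
    stride_duration: float
    stride_frequency: float
    stance_by_limb: Dict[Limb, float]
    duty_by_limb: Dict[Limb, float]
    diagonal_advanced_placement: float
    lateral_advanced_placement: float
    min_limbs: int
    max_limbs: int
    median_limbs: float
    pct_quadrupedal: float
    pct_tripedal: float
    pct_bipedal: float
    pct_single: float
    pct_suspension: float
    overlaps: Dict[Tuple[Limb, Limb], float]

    @property
    def stance_duration(self) -> float:
        """Four-limb mean stance duration (s)."""
        return float(np.mean(list(self.stance_by_limb.values())))

    @property
    def duty_factor(self) -> float:
        """Four-limb mean duty factor (%)."""
        return float(np.mean(list(self.duty_by_limb.values())))

    @property
    def duty_factor_hind(self) -> float:
        """Hind-limb mean duty factor (%), Hildebrand's convention."""
        return float(
            np.mean([self.duty_by_limb[Limb.LH], self.duty_by_limb[Limb.RH]])
        )

    def to_row(self) -> Dict[str, float]:
        row = {
            "stride_duration": self.stride_duration,
            "stance_duration": self.stance_duration,
            "stride_frequency": self.stride_frequency,
            "duty_factor": self.duty_factor,
            "duty_factor_hind": self.duty_factor_hind,
            "diagonal_advanced_placement": self.diagonal_advanced_placement,
            "lateral_advanced_placement": self.lateral_advanced_placement,
            "min_limbs": self.min_limbs,
            "max_limbs": self.max_limbs,
            "median_limbs": self.median_limbs,
            "pct_quadrupedal": self.pct_quadrupedal,
            "pct_tripedal": self.pct_tripedal,
            "pct_bipedal": self.pct_bipedal,
            "pct_single": self.pct_single,
            "pct_suspension": self.pct_suspension,
        }
        for (a, b), v in self.overlaps.items():
            row[f"overlap_{a.value.lower()}_{b.value.lower()}"] = v
        return row


def compute_features(window: StrideWindow) -> StrideFeatures:
    """Compute the full per-stride feature vector for a complete window."""
    if not window.complete:
        raise ValueError("cannot compute features for an incomplete stride window")

    D = window.duration
    stance = {limb: window.onset_intervals[limb].duration for limb in Limb}
    # duty factor per limb = stance over that limb's own cycle duration
    # ("proportion of the total limb cycle"), which stays unbiased when a
    # limb synchronous with the reference jitters across the window edge
    duty = {
        limb: stance[limb] / window.limb_cycles.get(limb, D) * 100.0
        for limb in Limb
    }

    bounds, counts = support_profile(window)
    seg = np.diff(bounds)
    pct = {
        k: float(seg[counts == k].sum() / D * 100.0) for k in range(5)
    }
    dap, lap = advanced_placements(window)

    overlaps = {
        (a, b): _pair_overlap_pct(window, a, b) for a, b in OVERLAP_PAIRS
    }

    return StrideFeatures(
        horse_id=window.horse_id,
        gait_label=window.gait,
        stride_duration=D,
        stride_frequency=1.0 / D,
        stance_by_limb=stance,
        duty_by_limb=duty,
        diagonal_advanced_placement=dap,
        lateral_advanced_placement=lap,
        min_limbs=int(counts.min()),
        max_limbs=int(counts.max()),
        median_limbs=_weighted_median(counts.astype(float), seg),
        pct_quadrupedal=pct[4],
        pct_tripedal=pct[3],
        pct_bipedal=pct[2],
        pct_single=pct[1],
        pct_suspension=pct[0],
        overlaps=overlaps,
    )


def hildebrand_coordinates(features: StrideFeatures) -> Tuple[float, float]:
    """The Hildebrand-diagram projection of a stride: x = diagonal advanced
    placement, y = lateral advanced placement (both percent of stride)."""
    return features.diagonal_advanced_placement, features.lateral_advanced_placement


def feature_table(
    timelines: Iterable[FootfallTimeline],
    reference_limb: Limb = Limb.LH,
) -> pd.DataFrame:
    """One row per complete stride across the given timelines.

    Columns: the 21 feature columns (:data:`FEATURE_COLUMNS`, fixed order)
    plus ``gait_label`` and ``horse_id``.  Incomplete strides are dropped,
    not imputed.
    """
    rows: List[Dict[str, object]] = []
    n_timelines = 0
    for tl in timelines:
        n_timelines += 1
        for w in segment_strides(tl, reference_limb):
            if not w.complete:
                continue
            f = compute_features(w)
            row = f.to_row()
            row["gait_label"] = f.gait_label.value if f.gait_label else ""
            row["horse_id"] = f.horse_id
            rows.append(row)
    if n_timelines == 0:
        raise ValueError("feature_table requires at least one timeline")
    if not rows:
        raise ValueError("no complete strides found in any timeline")
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS + ["gait_label", "horse_id"])


def footfall_order(window: StrideWindow) -> List[Tuple[str, ...]]:
    """The footfall sequence of a stride as groups of limbs, limbs whose
    onsets fall within the simultaneity tolerance grouped together.
    Display helper only; arithmetic never merges onsets."""
    onsets = sorted(
        ((window.onset_intervals[l].on_time, l.value) for l in Limb)
    )
    groups: List[List[Tuple[float, str]]] = [[onsets[0]]]
    for t, name in onsets[1:]:
        if t - groups[-1][-1][0] <= SIMULTANEITY_TOL:
            groups[-1].append((t, name))
        else:
            groups.append([(t, name)])
    return [tuple(sorted(name for _, name in g)) for g in groups]
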