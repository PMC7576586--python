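"""Readers and writers for the pipeline's interchange formats.

* footfall events — CSV with columns ``horse_id, gait, limb, on_time_s,
  off_time_s`` (times in seconds, six decimal places);
* feature tables — CSV, column names exactly the feature field names;
* signal blocks — HDF5 container (one group per block, ``values`` dataset,
  metadata as attributes, format version in the root attrs) with a CSV
  fallback writer for small blocks;
* configuration — YAML, lossless round-trip of the resolved config.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Iterable, List, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .features import FEATURE_COLUMNS
from .simulate import BreedCohort, CohortConfig
from .types import Breed, FootfallTimeline, Gait, Limb, SignalBlock, StanceInterval

__all__ = [
    "write_events_csv",
    "read_events_csv",
    "write_features_csv",
    "read_features_csv",
    "write_signals_h5",
    "read_signals_h5",
    "write_signals_csv",
    "load_cohort_config",
    "dump_cohort_config",
    "config_hash",
]

log = logging.getLogger(__name__)

EVENT_COLUMNS = ["horse_id", "gait", "limb", "on_time_s", "off_time_s"]
#: Optional 6th column distinguishing repeat trials of one (horse, gait).
TRIAL_COLUMN = "trial"
SIGNALS_FORMAT_VERSION = 1


# --- footfall events --------------------------------------------------------


def write_events_csv(timelines: Iterable[FootfallTimeline], path) -> None:
    rows = []
    for tl in timelines:
        for iv in sorted(tl.intervals, key=lambda iv: (iv.limb.value, iv.on_time)):
            rows.append(
                {
                    "horse_id": tl.horse_id,
                    "gait": tl.gait.value,
                    "limb": iv.limb.value,
                    "on_time_s": f"{iv.on_time:.6f}",
                    "off_time_s": f"{iv.off_time:.6f}",
                    TRIAL_COLUMN: tl.trial,
                }
            )
    pd.DataFrame(rows, columns=EVENT_COLUMNS + [TRIAL_COLUMN]).to_csv(path, index=False)


def read_events_csv(path) -> List[FootfallTimeline]:
    """Load timelines, validating invariants; rows are grouped by
    (horse_id, gait, trial) — the trial column is optional.  Raises with
    the offending line number on malformed rows and names the limb on
    interval violations."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events file missing columns {missing}")
    if TRIAL_COLUMN not in df.columns:
        df[TRIAL_COLUMN] = ""
    df[TRIAL_COLUMN] = df[TRIAL_COLUMN].fillna("")
    timelines: List[FootfallTimeline] = []
    if df.empty:
        return timelines
    for (horse, gait, trial), grp in df.groupby(
        ["horse_id", "gait", TRIAL_COLUMN], sort=False
    ):
        intervals = []
        for idx, row in grp.iterrows():
            line = idx + 2  # header + 1-based
            try:
                limb = Limb(row["limb"])
                on = float(row["on_time_s"])
                off = float(row["off_time_s"])
            except (ValueError, KeyError) as exc:
                raise ValueError(f"malformed events row at line {line}: {exc}") from exc
            if not on < off:
                raise ValueError(
                    f"line {line}: limb {row['limb']} has off_time <= on_time"
                )
            intervals.append(StanceInterval(limb=limb, on_time=on, off_time=off))
        tl = FootfallTimeline(
            horse_id=str(horse),
            gait=Gait(gait),
            intervals=sorted(intervals, key=lambda iv: iv.on_time),
            total_duration=max(iv.off_time for iv in intervals) + 1e-6,
            trial=str(trial),
        )
        tl.validate()
        timelines.append(tl)
    return timelines


# --- feature tables ---------------------------------------------------------


def write_features_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_features_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS + ["gait_label", "horse_id"] if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing columns {missing}")
    return df


# --- signal blocks ----------------------------------------------------------


def write_signals_h5(blocks: Sequence[SignalBlock], path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = SIGNALS_FORMAT_VERSION
        for i, b in enumerate(blocks):
            g = f.create_group(f"block_{i:04d}")
            g.attrs["horse_id"] = b.horse_id
            g.attrs["gait"] = b.gait.value
            g.attrs["sample_rate"] = b.sample_rate
            g.attrs["channel_names"] = np.array(b.channel_names, dtype="S")
            g.create_dataset("values", data=b.values, compression="gzip", compression_opts=4)


def read_signals_h5(path) -> List[SignalBlock]:
    blocks: List[SignalBlock] = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            blocks.append(
                SignalBlock(
                    horse_id=g.attrs["horse_id"],
                    gait=Gait(g.attrs["gait"]),
                    sample_rate=float(g.attrs["sample_rate"]),
                    channel_names=[c.decode() for c in g.attrs["channel_names"]],
                    values=g["values"][...],
                )
            )
    return blocks


def write_signals_csv(block: SignalBlock, path) -> None:
    """CSV fallback for small blocks: a time column plus one column per
    ``site.axis`` channel."""
    df = pd.DataFrame(block.values, columns=block.channel_names)
    df.insert(0, "time_s", np.arange(block.n_samples) / block.sample_rate)
    df.to_csv(path, index=False, float_format="%.6g")


# --- configuration ----------------------------------------------------------


def dump_cohort_config(config: CohortConfig, path=None) -> str:
    doc = {
        "breeds": {
            breed.value: {
                "n_horses": spec.n_horses,
                "gaits": [g.value for g in spec.gaits] if spec.gaits else None,
            }
            for breed, spec in config.breeds.items()
        },
        "total_strides": config.total_strides,
        "trials_per_gait": config.trials_per_gait,
        "trial_speed_sd": config.trial_speed_sd,
        "within_trial_sd_fraction": config.within_trial_sd_fraction,
        "trocha_min_cleanness": config.trocha_min_cleanness,
        "signal_sample_rate": config.signal_sample_rate,
        "signal_noise_sd": config.signal_noise_sd,
        "walk_printed_duration": config.walk_printed_duration,
        "allow_illegal_gaits": config.allow_illegal_gaits,
    }
    text = yaml.safe_dump(doc, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def load_cohort_config(path) -> CohortConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    breeds = {}
    for name, spec in (doc.get("breeds") or {}).items():
        breeds[Breed(name)] = BreedCohort(
            n_horses=int(spec["n_horses"]),
            gaits=[Gait(g) for g in spec["gaits"]] if spec.get("gaits") else None,
        )
    kwargs = {}
    if breeds:
        kwargs["breeds"] = breeds
    for key in (
        "total_strides",
        "trials_per_gait",
        "trial_speed_sd",
        "within_trial_sd_fraction",
        "trocha_min_cleanness",
        "signal_sample_rate",
        "signal_noise_sd",
        "walk_printed_duration",
        "allow_illegal_gaits",
    ):
        if key in doc:
            kwargs[key] = doc[key]
    return CohortConfig(**kwargs)


def config_hash(config: CohortConfig) -> str:
    return hashlib.sha256(dump_cohort_config(config).encode()).hexdigest()[:12]
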