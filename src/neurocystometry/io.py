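"""Recording container and table serialization.

No standard interchange format exists for dual-rate cystometry +
electroneurogram data, so recordings are stored as a plain-text trio
sharing one stem: ``<stem>.meta.yaml`` (channel names, per-channel rates,
units, condition, infusion rate, seed provenance), ``<stem>.pressure.csv``
and ``<stem>.nerve.csv``.  Values are written with 17 significant digits
so a write/read round-trip is bit-exact.  Annotations, summaries, ground
truth and comparison tables are ordinary CSV files.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .model import MeasurementSummary
from .processing import RawRecording
from .segmentation import PhaseAnnotation

__all__ = [
    "write_recording",
    "read_recording",
    "write_truth_table",
    "write_annotations",
    "summaries_to_frame",
    "write_summaries",
    "IOError_",
    "FormatError",
]


class FormatError(ValueError):
    """Raised for malformed or inconsistent container files."""


IOError_ = FormatError  # historical alias


_META_VERSION = 1


def _trace_path(stem: Path, channel: str) -> Path:
    return stem.with_name(stem.name + f".{channel}.csv")


def _meta_path(stem: Path) -> Path:
    return stem.with_name(stem.name + ".meta.yaml")


def write_recording(rec: RawRecording, stem: str | Path) -> None:
    """Write one recording as a meta/pressure/nerve file trio."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": _META_VERSION,
        "condition": rec.condition,
        "infusion_rate_ml_min": float(rec.infusion_rate),
        "t0_is_fill_start": bool(rec.t0_is_fill_start),
        "channels": {
            "pressure": {"rate_hz": float(rec.pressure_rate_hz),
                         "units": "cmH2O", "n_samples": len(rec.pressure)},
            "nerve": {"rate_hz": float(rec.nerve_rate_hz),
                      "units": "V", "n_samples": len(rec.nerve)},
        },
        "meta": {k: v for k, v in rec.meta.items()},
    }
    with open(_meta_path(stem), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    for channel, trace in (("pressure", rec.pressure), ("nerve", rec.nerve)):
        np.savetxt(_trace_path(stem, channel), trace, fmt="%.17g",
                   header=channel, comments="# ")


def read_recording(stem: str | Path) -> RawRecording:
    """Read a recording written by :func:`write_recording`.

    Validates the header (positive rates, required condition tag) and the
    consistency of declared sample counts with the stored traces; the two
    channels must share one duration to within one envelope sample.
    """
    stem = Path(stem)
    meta_path = _meta_path(stem)
    if not meta_path.exists():
        raise FormatError(f"missing header file {meta_path}")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    if not isinstance(meta, dict) or "channels" not in meta:
        raise FormatError(f"malformed header in {meta_path}")
    if "condition" not in meta or meta["condition"] in (None, ""):
        raise FormatError("header lacks required 'condition' tag")

    channels = meta["channels"]
    traces: dict[str, np.ndarray] = {}
    rates: dict[str, float] = {}
    for channel in ("pressure", "nerve"):
        if channel not in channels:
            raise FormatError(f"header lacks channel '{channel}'")
        info = channels[channel]
        rate = float(info.get("rate_hz", 0.0))
        if rate <= 0:
            raise FormatError(f"non-positive rate for channel '{channel}'")
        trace = np.loadtxt(_trace_path(stem, channel), ndmin=1)
        declared = int(info.get("n_samples", -1))
        if declared != len(trace):
            raise FormatError(
                f"channel '{channel}': declared {declared} samples, "
                f"file has {len(trace)}"
            )
        traces[channel] = trace
        rates[channel] = rate

    dur_p = len(traces["pressure"]) / rates["pressure"]
    dur_n = len(traces["nerve"]) / rates["nerve"]
    if abs(dur_p - dur_n) > 1.0 / rates["pressure"] + 1e-9:
        raise FormatError(
            f"channel durations inconsistent: pressure {dur_p:.3f} s vs "
            f"nerve {dur_n:.3f} s"
        )
    return RawRecording(
        pressure=traces["pressure"],
        nerve=traces["nerve"],
        pressure_rate_hz=rates["pressure"],
        nerve_rate_hz=rates["nerve"],
        infusion_rate=float(meta.get("infusion_rate_ml_min", 0.05)),
        condition=str(meta["condition"]),
        t0_is_fill_start=bool(meta.get("t0_is_fill_start", True)),
        meta=dict(meta.get("meta", {}) or {}),
    )


def write_truth_table(truths: Iterable, path: str | Path) -> None:
    """Ground-truth side-car table (one row per generated recording)."""
    pd.DataFrame([asdict(t) for t in truths]).to_csv(path, index=False)


def write_annotations(annotations: Iterable[PhaseAnnotation],
                      path: str | Path,
                      names: Sequence[str] | None = None) -> None:
    """Annotation CSV: one row per recording, times in s, pressures in cmH2O."""
    frame = pd.DataFrame([asdict(a) for a in annotations])
    if names is not None:
        frame.insert(0, "recording", list(names))
    frame.to_csv(path, index=False)


def summaries_to_frame(summaries: Iterable[MeasurementSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_dict() for s in summaries])


def write_summaries(summaries: Iterable[MeasurementSummary],
                    path: str | Path,
                    names: Sequence[str] | None = None) -> None:
    """Cohort-level summary CSV, one row per measurement."""
    frame = summaries_to_frame(summaries)
    if names is not None:
        frame.insert(0, "recording", list(names))
    frame.to_csv(path, index=False)
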