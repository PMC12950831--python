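"""Reading, writing and validation of sampled ventilator waveform tables.

A waveform record holds five synchronously sampled channels — time, airway
pressure (Paw), flow, volume and esophageal pressure (Pes) — on a strictly
uniform time grid, typically at 200 samples/s.  Files are plain CSV with a
``# key=value`` metadata preamble, so they are diffable and self-describing:

    # patient_id=P01
    # sampling_rate=200.0
    time_s,paw_mbar,flow_lps,vol_ml,pes_mbar
    0,8,0,0,7.9
    0.005,8,0,0,8.1

Maneuver annotations (occlusion / P0.1 windows) use a companion CSV with
header ``patient_id,kind,start_time_s,end_time_s`` and an optional
``maneuver_id`` column.  All pressures are in mbar, flow in L/s, volume in
mL; time is 0-based seconds from the start of the record.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "WaveformRecord",
    "ManeuverAnnotation",
    "WaveformFormatError",
    "SamplingGridError",
    "read_waveform_table",
    "write_waveform_table",
    "read_annotations",
    "write_annotations",
]

#: column order of the on-disk waveform dialect
WAVEFORM_COLUMNS = ("time_s", "paw_mbar", "flow_lps", "vol_ml", "pes_mbar")

ANNOTATION_COLUMNS = ("patient_id", "kind", "start_time_s", "end_time_s")

MANEUVER_KINDS = ("occlusion", "p01")


class WaveformFormatError(ValueError):
    """A waveform or annotation file does not conform to the dialect."""


class SamplingGridError(ValueError):
    """The time channel is not a uniform grid consistent with the stated rate."""


@dataclass
class WaveformRecord:
    """Uniformly sampled multi-channel pressure/flow/volume trace.

    Parameters
    ----------
    patient_id
        Identifier of the patient the trace belongs to.
    sampling_rate
        Samples per second (200 for the ventilator export emulated here).
    time
        Seconds, strictly increasing uniform grid, 0-based.
    paw
        Airway pressure, mbar.
    flow
        Airway flow, L/s (inspiratory positive).
    volume
        Tidal volume above end-expiration, mL.
    pes
        Esophageal pressure, mbar.
    """

    patient_id: str
    sampling_rate: float
    time: np.ndarray
    paw: np.ndarray
    flow: np.ndarray
    volume: np.ndarray
    pes: np.ndarray

    def __post_init__(self) -> None:
        for name in ("time", "paw", "flow", "volume", "pes"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        n = self.time.size
        if n < 2:
            raise WaveformFormatError("record must contain at least 2 samples")
        for name in ("paw", "flow", "volume", "pes"):
            if getattr(self, name).size != n:
                raise WaveformFormatError(
                    f"channel {name!r} has length {getattr(self, name).size}, "
                    f"expected {n}"
                )
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            idx = int(np.argmax(dt <= 0))
            raise SamplingGridError(f"time not strictly increasing at index {idx + 1}")
        dt0 = float(dt[0])
        bad = np.abs(dt - dt0) > 1e-9 * max(abs(dt0), 1.0)
        if np.any(bad):
            raise SamplingGridError(
                f"non-uniform time grid at index {int(np.argmax(bad)) + 1}"
            )
        if abs(self.sampling_rate * dt0 - 1.0) > 1e-6:
            raise SamplingGridError(
                f"sampling_rate {self.sampling_rate} inconsistent with grid "
                f"spacing {dt0!r}"
            )

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def index_at(self, t: float) -> int:
        """Index of the sample nearest to time ``t`` (clipped to the record)."""
        i = int(round((t - self.time[0]) * self.sampling_rate))
        return min(max(i, 0), self.time.size - 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "paw_mbar": self.paw,
                "flow_lps": self.flow,
                "vol_ml": self.volume,
                "pes_mbar": self.pes,
            }
        )

    def equals(self, other: "WaveformRecord") -> bool:
        return (
            self.patient_id == other.patient_id
            and self.sampling_rate == other.sampling_rate
            and all(
                np.array_equal(getattr(self, c), getattr(other, c))
                for c in ("time", "paw", "flow", "volume", "pes")
            )
        )


@dataclass(frozen=True)
class ManeuverAnnotation:
    """Time window of one recorded maneuver on a record's 0-based clock."""

    patient_id: str
    kind: str  # "occlusion" | "p01"
    start_time: float
    end_time: float
    maneuver_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in MANEUVER_KINDS:
            raise WaveformFormatError(f"unknown maneuver kind {self.kind!r}")
        if not self.start_time < self.end_time:
            raise WaveformFormatError(
                f"annotation start {self.start_time} must precede end {self.end_time}"
            )

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


# ---------------------------------------------------------------------------
# waveform CSV dialect


def _channel_map() -> dict[str, str]:
    return {
        "time_s": "time",
        "paw_mbar": "paw",
        "flow_lps": "flow",
        "vol_ml": "volume",
        "pes_mbar": "pes",
    }


def read_waveform_table(path: str | Path) -> WaveformRecord:
    """Read one waveform CSV (``# key=value`` preamble + channel table)."""
    path = Path(path)
    meta: dict[str, str] = {}
    body = io.StringIO()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if "=" in stripped:
                    key, _, value = stripped.partition("=")
                    meta[key.strip()] = value.strip()
            else:
                body.write(line)
    body.seek(0)
    try:
        df = pd.read_csv(body, float_precision="round_trip")
    except Exception as exc:  # malformed CSV body
        raise WaveformFormatError(f"{path}: unparseable table: {exc}") from exc
    for col in WAVEFORM_COLUMNS:
        if col not in df.columns:
            raise WaveformFormatError(f"{path}: missing channel column {col!r}")
    if "patient_id" not in meta:
        raise WaveformFormatError(f"{path}: missing 'patient_id' metadata line")
    if "sampling_rate" not in meta:
        raise WaveformFormatError(f"{path}: missing 'sampling_rate' metadata line")
    kwargs = {attr: df[col].to_numpy(float) for col, attr in _channel_map().items()}
    return WaveformRecord(
        patient_id=meta["patient_id"],
        sampling_rate=float(meta["sampling_rate"]),
        **kwargs,
    )


def write_waveform_table(record: WaveformRecord, path: str | Path) -> None:
    """Write ``record`` losslessly (``%.17g``, exact float round-trip)."""
    record.validate()
    path = Path(path)
    df = record.to_frame()
    with open(path, "w") as fh:
        fh.write(f"# patient_id={record.patient_id}\n")
        fh.write(f"# sampling_rate={record.sampling_rate!r}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# annotation CSV


def read_annotations(path: str | Path) -> list[ManeuverAnnotation]:
    df = pd.read_csv(path)
    for col in ANNOTATION_COLUMNS:
        if col not in df.columns:
            raise WaveformFormatError(f"{path}: missing annotation column {col!r}")
    has_id = "maneuver_id" in df.columns
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ManeuverAnnotation(
                patient_id=str(row.patient_id),
                kind=str(row.kind),
                start_time=float(row.start_time_s),
                end_time=float(row.end_time_s),
                maneuver_id=str(row.maneuver_id) if has_id else None,
            )
        )
    return out


def write_annotations(
    annotations: Iterable[ManeuverAnnotation], path: str | Path
) -> None:
    rows = [
        {
            "patient_id": a.patient_id,
            "kind": a.kind,
            "start_time_s": a.start_time,
            "end_time_s": a.end_time,
            "maneuver_id": a.maneuver_id,
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS) + ["maneuver_id"]).to_csv(
        path, index=False, float_format="%.17g"
    )
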