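"""Maneuver detection and measurement on ventilator waveforms.

Quantities extracted per maneuver:

* ``delta_paw`` / ``delta_pes`` — signed airway / esophageal pressure
  deflections during the occluded inspiratory effort (negative for an
  inspiratory effort).  For the prolonged occlusion maneuver the deflection
  is taken at the Paw nadir; Pes is sampled at the *same* time, because the
  validity criterion is a synchronous swing in both channels (independent
  nadirs would inflate ratios under cardiac artifact).
* ``ratio`` — delta_pes / delta_paw, the balloon validity index.
* ``p01`` — the Paw deflection 100 ms after effort onset of a P0.1
  maneuver (signed; around -1 to -5 mbar for normal-to-high drive).
* ``pes_end_exp`` — end-expiratory Pes, a 50 ms mean centred 0.5 s before
  effort onset, used to check that the balloon state was comparable between
  a P0.1 maneuver and its reference occlusion.

Detection is signature-based (zero flow plus a sustained Paw deflection) so
the pipeline can run without device annotations; when annotations are
available they are used directly as windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .waveform_io import ManeuverAnnotation, WaveformRecord

__all__ = [
    "ManeuverWindow",
    "ManeuverMeasurement",
    "ManeuverError",
    "OnsetNotFoundError",
    "detect_occlusion_windows",
    "detect_effort_onset",
    "measure_occlusion_deltas",
    "measure_p01",
    "end_expiratory_pes",
    "measure_maneuver",
    "analyze_record",
    "measurements_to_frame",
    "frame_to_measurements",
]

# detection / measurement constants (see docs/methods.md for rationale)
BASELINE_WINDOW_S = 0.25  # pre-window mean used as the pressure baseline
ONSET_DROP_MBAR = 0.2  # sustained Paw drop defining effort onset
ONSET_SUSTAIN_S = 0.05  # how long the drop must persist
WINDOW_DROP_MBAR = 0.5  # Paw deflection identifying a maneuver window
WINDOW_EDGE_MBAR = 0.05  # deflection level used to trim window edges
P01_TIME_S = 0.100  # the P0.1 sampling point after onset
P01_MIN_OCCLUDED_S = 0.075  # minimum occluded time after onset for a valid P0.1
END_EXP_OFFSET_S = 0.5  # end-expiratory Pes reference point before onset
END_EXP_HALF_WIDTH_S = 0.025  # 50 ms averaging window around that point
P01_DURATION_RANGE_S = (0.08, 0.15)  # detected window lengths labelled p01
OCC_MIN_DURATION_S = 0.3  # detected window lengths labelled occlusion


class ManeuverError(ValueError):
    """A maneuver window cannot be measured."""


class OnsetNotFoundError(ManeuverError):
    """No qualifying effort onset inside the window (maneuver unusable)."""


@dataclass(frozen=True)
class ManeuverWindow:
    """Half-open-ish maneuver time window ``[start, end]`` on the record clock."""

    start_time: float
    end_time: float
    kind: str  # "occlusion" | "p01"

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time

    @classmethod
    def from_annotation(cls, ann: ManeuverAnnotation) -> "ManeuverWindow":
        return cls(ann.start_time, ann.end_time, ann.kind)


@dataclass
class ManeuverMeasurement:
    """Extracted quantities of one occlusion or P0.1 maneuver."""

    patient_id: str
    maneuver_id: str
    kind: str
    onset_time: float
    baseline_paw: float
    baseline_pes: float
    delta_paw: float  # signed, nadir (or 100 ms point) minus baseline
    delta_pes: float  # signed, sampled synchronously with delta_paw
    ratio: float  # delta_pes / delta_paw
    p01: float  # signed Paw deflection at 100 ms; NaN for occlusion kind
    pes_end_exp: float  # Pes 0.5 s before onset

    def __post_init__(self) -> None:
        if self.kind == "p01" and not np.isfinite(self.p01):
            raise ManeuverError("p01 must be finite for a P0.1 measurement")


# ---------------------------------------------------------------------------
# detection


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of ``mask`` as (start, stop) index pairs (stop excl.)."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def detect_occlusion_windows(
    record: WaveformRecord,
    flow_epsilon: float = 0.02,
    min_duration: float = 0.08,
) -> list[ManeuverWindow]:
    """Find occluded-effort windows: no flow plus a sustained Paw deflection.

    Within each maximal zero-flow interval (|flow| < ``flow_epsilon`` for at
    least ``min_duration``), samples where Paw falls more than 0.5 mbar
    below the local pre-interval baseline mark a maneuver; the window is
    trimmed outward to where the deflection vanishes (0.05 mbar), which
    anchors its start at the effort onset.  Windows of 0.08-0.15 s are
    labelled ``p01``, windows of at least 0.3 s ``occlusion``; other
    durations are discarded.
    """
    fs = record.sampling_rate
    n_min = max(2, int(round(min_duration * fs)))
    n_base = int(round(BASELINE_WINDOW_S * fs))
    quiet = np.abs(record.flow) < flow_epsilon
    windows: list[ManeuverWindow] = []
    for i0, i1 in _runs(quiet):
        if i1 - i0 < n_min:
            continue
        pre = record.paw[max(0, i0 - n_base) : i0]
        if pre.size == 0:  # run starts the record; use its own quiet head
            pre = record.paw[i0 : min(i1, i0 + n_base)]
        baseline = float(np.mean(pre))
        deflected = record.paw[i0:i1] < baseline - WINDOW_DROP_MBAR
        for j0, j1 in _runs(deflected):
            a, b = i0 + j0, i0 + j1
            # trim outward to the edge of the deflection; the window starts
            # at the last baseline-level sample (the effort onset itself)
            # and ends at the last deflected sample (the release/valve-open
            # boundary for a P0.1 maneuver)
            edge = baseline - WINDOW_EDGE_MBAR
            while a > i0 and record.paw[a - 1] < edge:
                a -= 1
            if a > i0:
                a -= 1
            while b < i1 and record.paw[b] < edge:
                b += 1
            b = max(a + 1, b - 1)
            start, end = record.time[a], record.time[min(b, record.time.size - 1)]
            dur = end - start
            if P01_DURATION_RANGE_S[0] <= dur <= P01_DURATION_RANGE_S[1]:
                windows.append(ManeuverWindow(start, end, "p01"))
            elif dur >= OCC_MIN_DURATION_S:
                windows.append(ManeuverWindow(start, end, "occlusion"))
    return windows


def _baseline(record: WaveformRecord, channel: np.ndarray, t_end: float) -> float:
    """Mean of ``channel`` over the 0.25 s immediately preceding ``t_end``."""
    i1 = record.index_at(t_end)
    i0 = max(0, i1 - int(round(BASELINE_WINDOW_S * record.sampling_rate)))
    if i1 - i0 < 2:
        raise ManeuverError("insufficient pre-window data for a baseline")
    return float(np.mean(channel[i0:i1]))


def detect_effort_onset(record: WaveformRecord, window: ManeuverWindow) -> float:
    """First time in the window where Paw drops 0.2 mbar below baseline for 50 ms.

    The baseline is the mean Paw over the 0.25 s immediately preceding the
    window.  Raises :class:`OnsetNotFoundError` when no sample qualifies
    (the maneuver is unusable).
    """
    baseline = _baseline(record, record.paw, window.start_time)
    i0 = record.index_at(window.start_time)
    i1 = record.index_at(window.end_time)
    n_sustain = max(1, int(round(ONSET_SUSTAIN_S * record.sampling_rate)))
    below = record.paw[i0 : i1 + 1] < baseline - ONSET_DROP_MBAR
    if below.size >= n_sustain:
        # first index where `below` holds for n_sustain consecutive samples
        kernel = np.ones(n_sustain, dtype=int)
        counts = np.convolve(below.astype(int), kernel, mode="valid")
        hits = np.flatnonzero(counts == n_sustain)
        if hits.size:
            return float(record.time[i0 + int(hits[0])])
    raise OnsetNotFoundError(
        f"no sustained Paw drop > {ONSET_DROP_MBAR} mbar in window "
        f"[{window.start_time:.3f}, {window.end_time:.3f}]"
    )


# ---------------------------------------------------------------------------
# measurement


def measure_occlusion_deltas(
    record: WaveformRecord, window: ManeuverWindow, onset_time: float
) -> tuple[float, float]:
    """Signed (delta_paw, delta_pes) of a prolonged occlusion maneuver.

    delta_paw is the Paw nadir over [onset, window end] minus the pre-window
    Paw baseline; delta_pes is Pes *at the Paw-nadir time* minus the
    pre-window Pes baseline (synchronous-swing convention).
    """
    i0 = record.index_at(onset_time)
    i1 = record.index_at(window.end_time)
    if i1 - i0 < 2:
        raise ManeuverError("window shorter than 2 samples after onset")
    baseline_paw = _baseline(record, record.paw, window.start_time)
    baseline_pes = _baseline(record, record.pes, window.start_time)
    seg = record.paw[i0 : i1 + 1]
    k = int(np.argmin(seg))
    delta_paw = float(seg[k] - baseline_paw)
    delta_pes = float(record.pes[i0 + k] - baseline_pes)
    return delta_paw, delta_pes


def measure_p01(
    record: WaveformRecord, window: ManeuverWindow, onset_time: float
) -> tuple[float, float]:
    """Signed (p01, delta_pes) of a P0.1 maneuver.

    p01 is the Paw deflection 100 ms after effort onset; for ratio purposes
    delta_paw equals p01 and delta_pes is the Pes deflection at the same
    sample.  Because the valve reopens 100 ms after the *true* effort onset
    while onset detection has a small threshold delay, the sampling point is
    clamped to the window end (the release boundary — physically where the
    ventilator reads P0.1).  Fewer than 75 ms of occluded signal after the
    detected onset is a measurement error.
    """
    if window.end_time < onset_time + P01_MIN_OCCLUDED_S:
        raise ManeuverError(
            "occlusion released less than 75 ms after detected effort onset"
        )
    t_sample = min(onset_time + P01_TIME_S, window.end_time)
    i = record.index_at(t_sample)
    baseline_paw = _baseline(record, record.paw, window.start_time)
    baseline_pes = _baseline(record, record.pes, window.start_time)
    p01 = float(record.paw[i] - baseline_paw)
    delta_pes = float(record.pes[i] - baseline_pes)
    return p01, delta_pes


def end_expiratory_pes(record: WaveformRecord, onset_time: float) -> float:
    """Mean Pes over a 50 ms window centred 0.5 s before effort onset."""
    t0 = onset_time - END_EXP_OFFSET_S - END_EXP_HALF_WIDTH_S
    t1 = onset_time - END_EXP_OFFSET_S + END_EXP_HALF_WIDTH_S
    if t0 < record.time[0]:
        raise ManeuverError(
            "record does not extend 0.525 s before effort onset"
        )
    i0, i1 = record.index_at(t0), record.index_at(t1)
    return float(np.mean(record.pes[i0 : i1 + 1]))


def measure_maneuver(
    record: WaveformRecord,
    window: ManeuverWindow,
    *,
    maneuver_id: str = "",
) -> ManeuverMeasurement:
    """Full measurement of one maneuver window (onset, deltas, ratio, P0.1)."""
    onset = detect_effort_onset(record, window)
    baseline_paw = _baseline(record, record.paw, window.start_time)
    baseline_pes = _baseline(record, record.pes, window.start_time)
    if window.kind == "p01":
        p01, delta_pes = measure_p01(record, window, onset)
        delta_paw = p01
    else:
        delta_paw, delta_pes = measure_occlusion_deltas(record, window, onset)
        p01 = float("nan")
    ratio = delta_pes / delta_paw if delta_paw != 0 else float("nan")
    return ManeuverMeasurement(
        patient_id=record.patient_id,
        maneuver_id=maneuver_id,
        kind=window.kind,
        onset_time=onset,
        baseline_paw=baseline_paw,
        baseline_pes=baseline_pes,
        delta_paw=delta_paw,
        delta_pes=delta_pes,
        ratio=ratio,
        p01=p01,
        pes_end_exp=end_expiratory_pes(record, onset),
    )


def analyze_record(
    record: WaveformRecord,
    annotations: Sequence[ManeuverAnnotation] | None = None,
    *,
    on_error: str = "skip",
) -> list[ManeuverMeasurement]:
    """Measure every maneuver of a record.

    Windows come from ``annotations`` when given, otherwise from
    :func:`detect_occlusion_windows`.  Unusable maneuvers (no onset, too
    little occluded time) are skipped by default; ``on_error='raise'``
    propagates instead.
    """
    if annotations is not None:
        items = [
            (ManeuverWindow.from_annotation(a), a.maneuver_id or f"{record.patient_id}-M{k + 1:02d}")
            for k, a in enumerate(annotations)
            if a.patient_id == record.patient_id
        ]
    else:
        items = [
            (w, f"{record.patient_id}-D{k + 1:02d}")
            for k, w in enumerate(detect_occlusion_windows(record))
        ]
    out = []
    for window, mid in items:
        try:
            out.append(measure_maneuver(record, window, maneuver_id=mid))
        except ManeuverError:
            if on_error == "raise":
                raise
    return out


# ---------------------------------------------------------------------------
# tabular export

MEASUREMENT_COLUMNS = (
    "patient_id",
    "maneuver_id",
    "kind",
    "onset_time_s",
    "delta_paw_mbar",
    "delta_pes_mbar",
    "ratio",
    "p01_mbar",
    "pes_end_exp_mbar",
)


def measurements_to_frame(
    measurements: Iterable[ManeuverMeasurement],
) -> pd.DataFrame:
    rows = [
        {
            "patient_id": m.patient_id,
            "maneuver_id": m.maneuver_id,
            "kind": m.kind,
            "onset_time_s": m.onset_time,
            "delta_paw_mbar": m.delta_paw,
            "delta_pes_mbar": m.delta_pes,
            "ratio": m.ratio,
            "p01_mbar": m.p01,
            "pes_end_exp_mbar": m.pes_end_exp,
        }
        for m in measurements
    ]
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def frame_to_measurements(df: pd.DataFrame) -> list[ManeuverMeasurement]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ManeuverMeasurement(
                patient_id=str(row.patient_id),
                maneuver_id=str(row.maneuver_id),
                kind=str(row.kind),
                onset_time=float(row.onset_time_s),
                baseline_paw=float("nan"),
                baseline_pes=float("nan"),
                delta_paw=float(row.delta_paw_mbar),
                delta_pes=float(row.delta_pes_mbar),
                ratio=float(row.ratio),
                p01=float(row.p01_mbar),
                pes_end_exp=float(row.pes_end_exp_mbar),
            )
        )
    return out
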