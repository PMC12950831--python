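"""Synthetic assisted-ventilation waveforms with embedded validation maneuvers.

The generator emulates pressure-support breaths of a spontaneously breathing
ICU patient instrumented with an esophageal balloon catheter, together with
the two airway-occlusion maneuvers used to check the validity of the
esophageal pressure (Pes) signal:

* an **expiratory occlusion maneuver** — the valve stays closed for a full
  inspiratory effort, so the entire pleural pressure swing appears in the
  airway pressure (Paw) trace; and
* a **P0.1 maneuver** — the occlusion is released 100 ms after the onset of
  effort, so only the first 100 ms of the drive is seen at the airway.

Mechanics follow a single-compartment equation of motion integrated by
forward Euler at the ventilator's 200 Hz export rate.  Muscle pressure is a
half-sine pulse, Pmus(t) = p_max * sin(pi * t / t_insp) (deflection
magnitude), the standard lung-simulator convention; it makes the P0.1 of a
noise-free breath available in closed form, -p_max * sin(0.1 * pi / t_insp).

The quality of balloon placement/filling is condensed into a transmission
factor ``lambda``: the measured Pes swing is ``lambda`` times the true
pleural swing, plus a static offset, a cardiac-oscillation artifact and
additive sensor noise.  ``lambda == 1`` is an ideally placed, ideally filled
balloon; values far below 1 emulate a deflated or malpositioned balloon and
values above 1 over-transmission.  Because the downstream validity rule is a
pure ratio threshold (0.75 < dPes/dPaw < 1.25), ``lambda`` is a sufficient
ground-truth parameter for correct-vs-incorrect placement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .waveform_io import ManeuverAnnotation, WaveformRecord

__all__ = [
    "RespiratorySystem",
    "EffortProfile",
    "BalloonModel",
    "VentilatorConfig",
    "GroundTruth",
    "LambdaSpec",
    "EffortSpec",
    "CohortConfig",
    "SimulatedCohort",
    "SimulationError",
    "ConfigurationError",
    "simulate_breath",
    "generate_cohort",
]

SAMPLING_RATE = 200.0  # Hz, ventilator export rate
P01_OCCLUSION_S = 0.100  # duration of the P0.1 occlusion after effort onset


class SimulationError(RuntimeError):
    """Integration produced a non-finite state."""


class ConfigurationError(ValueError):
    """A cohort/parameter specification is empty or inconsistent."""


@dataclass(frozen=True)
class RespiratorySystem:
    """Passive single-compartment respiratory mechanics.

    resistance      mbar*s/L
    compliance_rs   mL/mbar  (respiratory system)
    elastance_cw    mbar/L   (chest wall; drives the volume-dependent part
                              of the pleural pressure)
    peep            mbar
    """

    resistance: float = 10.0
    compliance_rs: float = 45.0
    elastance_cw: float = 7.0
    peep: float = 7.0

    def __post_init__(self) -> None:
        if self.resistance <= 0:
            raise ConfigurationError("resistance must be > 0")
        if self.compliance_rs <= 0:
            raise ConfigurationError("compliance_rs must be > 0")
        if self.elastance_cw < 0:
            raise ConfigurationError("elastance_cw must be >= 0")


@dataclass(frozen=True)
class EffortProfile:
    """Inspiratory muscle effort: half-sine of amplitude p_max over t_insp."""

    p_max: float = 10.0  # mbar, peak muscle pressure (deflection magnitude)
    t_insp: float = 1.0  # s, effort duration
    respiratory_rate: float = 18.0  # breaths/min

    def __post_init__(self) -> None:
        if self.p_max < 0:
            raise ConfigurationError("p_max must be >= 0")
        if not 0.3 <= self.t_insp < 60.0 / self.respiratory_rate:
            raise ConfigurationError(
                "t_insp must be within [0.3 s, breath period)"
            )


@dataclass(frozen=True)
class BalloonModel:
    """Esophageal balloon transfer: Pes = offset + lambda * Ppl + artifacts."""

    lambda_transmission: float = 1.0  # dPes/dPpl; 1 = ideal placement/filling
    pes_offset: float = 8.0  # mbar, static end-expiratory esophageal pressure
    cardiac_amplitude: float = 0.0  # mbar, cardiac-oscillation artifact
    cardiac_rate: float = 80.0  # beats/min
    noise_sd: float = 0.0  # mbar, additive white sensor noise

    def __post_init__(self) -> None:
        if self.lambda_transmission < 0:
            raise ConfigurationError("lambda_transmission must be >= 0")
        if self.cardiac_amplitude < 0 or self.noise_sd < 0:
            raise ConfigurationError("artifact amplitudes must be >= 0")


@dataclass(frozen=True)
class VentilatorConfig:
    """Pressure-support settings of the simulated ventilator."""

    pressure_support: float = 10.0  # mbar above PEEP
    trigger_flow: float = 0.05  # L/s, flow trigger threshold
    cycle_fraction: float = 0.25  # support cycles off at this fraction of peak flow
    rise_time: float = 0.15  # s, pressurization ramp

    def __post_init__(self) -> None:
        if self.pressure_support < 0:
            raise ConfigurationError("pressure_support must be >= 0")
        if not 0 < self.cycle_fraction < 1:
            raise ConfigurationError("cycle_fraction must be in (0, 1)")


@dataclass(frozen=True)
class GroundTruth:
    """Simulator-side truth for one generated maneuver."""

    patient_id: str
    maneuver_id: str
    kind: str  # "occlusion" | "p01"
    lambda_true: float
    p_max: float
    true_p01: float  # model-implied Paw deflection at 100 ms (NaN for occlusion)


def _pmus(t: np.ndarray, onset: float, effort: EffortProfile) -> np.ndarray:
    """Half-sine muscle pressure (deflection magnitude, >= 0)."""
    tau = t - onset
    active = (tau >= 0) & (tau <= effort.t_insp)
    out = np.zeros_like(t)
    out[active] = effort.p_max * np.sin(np.pi * tau[active] / effort.t_insp)
    return out


def true_p01(effort: EffortProfile) -> float:
    """Closed-form Paw deflection 100 ms into a half-sine effort (signed)."""
    return -effort.p_max * math.sin(math.pi * P01_OCCLUSION_S / effort.t_insp)


def simulate_breath(
    system: RespiratorySystem,
    effort: EffortProfile,
    vent: VentilatorConfig,
    balloon: BalloonModel,
    maneuver: str = "none",
    seed: int | np.random.Generator = 0,
    *,
    onset_time: float = 1.0,
    duration: float | None = None,
    patient_id: str = "sim",
    sampling_rate: float = SAMPLING_RATE,
) -> tuple[WaveformRecord, ManeuverAnnotation | None]:
    """Simulate one breath, optionally containing an occlusion or P0.1 maneuver.

    The record starts ``onset_time`` seconds before the inspiratory effort
    (quiet end-expiration at PEEP), long enough for the end-expiratory Pes
    reference point 0.5 s before effort onset.  During an occlusion the
    airway valve is closed: flow is identically zero, volume constant, and
    the measured Paw equals ``peep - Pmus(t)`` (a complete occlusion
    transmits the full pleural swing to the airway).  For ``maneuver='p01'``
    the valve reopens 0.100 s after effort onset and the breath continues as
    a normal supported breath.

    Returns the waveform record and the maneuver window annotation (``None``
    for an unoccluded breath).
    """
    if maneuver not in ("none", "occlusion", "p01"):
        raise ConfigurationError(f"unknown maneuver {maneuver!r}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    dt = 1.0 / sampling_rate
    if duration is None:
        duration = onset_time + effort.t_insp + 2.0
    n = int(round(duration * sampling_rate))
    t = np.arange(n) * dt
    pmus = _pmus(t, onset_time, effort)

    if maneuver == "occlusion":
        occluded = (t >= onset_time) & (t <= onset_time + effort.t_insp)
    elif maneuver == "p01":
        occluded = (t >= onset_time) & (t <= onset_time + P01_OCCLUSION_S)
    else:
        occluded = np.zeros(n, dtype=bool)

    paw = np.empty(n)
    flow = np.zeros(n)
    volume = np.zeros(n)

    vol = 0.0  # mL above end-expiration
    triggered = False
    support_on = False
    t_trigger = math.inf
    peak_flow = 0.0
    for i in range(n):
        if occluded[i]:
            paw[i] = system.peep - pmus[i]
            flow[i] = 0.0
            volume[i] = vol
            continue
        if support_on:
            ramp = min(1.0, (t[i] - t_trigger) / max(vent.rise_time, dt))
            paw_applied = system.peep + vent.pressure_support * ramp
        else:
            paw_applied = system.peep
        f = (
            paw_applied - vol / system.compliance_rs - system.peep + pmus[i]
        ) / system.resistance
        if not triggered and f > vent.trigger_flow:
            triggered = True
            support_on = True
            t_trigger = t[i]
            # re-evaluate with support beginning to ramp this sample
        if support_on:
            peak_flow = max(peak_flow, f)
            if (
                t[i] - t_trigger > vent.rise_time
                and f < vent.cycle_fraction * peak_flow
            ):
                support_on = False
                paw_applied = system.peep
        paw[i] = paw_applied
        flow[i] = f
        volume[i] = vol
        vol = vol + f * 1000.0 * dt  # L/s -> mL
        if not math.isfinite(vol) or abs(vol) > 1e9:
            raise SimulationError(
                "non-finite state during integration (check that the "
                "respiratory time constant is resolvable at 200 Hz)"
            )

    # pleural swing relative to end-expiration: effort pulls it down,
    # lung inflation pushes the chest wall out and it back up
    ppl = -pmus + volume * system.elastance_cw / 1000.0
    phase = rng.uniform(0.0, 2.0 * np.pi)
    cardiac = balloon.cardiac_amplitude * np.sin(
        2.0 * np.pi * balloon.cardiac_rate / 60.0 * t + phase
    )
    noise = (
        rng.normal(0.0, balloon.noise_sd, n) if balloon.noise_sd > 0 else 0.0
    )
    pes = balloon.pes_offset + balloon.lambda_transmission * ppl + cardiac + noise

    for arr in (paw, flow, volume, pes):
        if not np.all(np.isfinite(arr)):
            raise SimulationError("non-finite state during integration")

    record = WaveformRecord(
        patient_id=patient_id,
        sampling_rate=sampling_rate,
        time=t,
        paw=paw,
        flow=flow,
        volume=volume,
        pes=pes,
    )
    annotation = None
    if maneuver != "none":
        end = onset_time + (
            P01_OCCLUSION_S if maneuver == "p01" else effort.t_insp
        )
        annotation = ManeuverAnnotation(
            patient_id=patient_id,
            kind=maneuver,
            start_time=onset_time,
            end_time=end,
        )
    return record, annotation


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class LambdaSpec:
    """Distribution of the true balloon transmission factor across patients.

    A fraction of patients get a "correct" balloon (lambda drawn from
    ``correct_range``); the rest draw from one of the ``incorrect_ranges``
    with the paired weights.  Defaults model clearly correct placements
    against frank failures — a deflated/malpositioned balloon
    (under-transmission, the common mode) or over-transmission.
    """

    fraction_correct: float = 0.6
    correct_range: tuple[float, float] = (0.90, 1.10)
    incorrect_ranges: tuple[tuple[float, float], ...] = ((0.10, 0.50), (1.40, 1.60))
    incorrect_weights: tuple[float, ...] = (0.8, 0.2)

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_correct <= 1.0:
            raise ConfigurationError("fraction_correct must be in [0, 1]")
        if not self.incorrect_ranges:
            raise ConfigurationError("incorrect_ranges must be non-empty")
        if len(self.incorrect_weights) != len(self.incorrect_ranges):
            raise ConfigurationError("one weight per incorrect range required")
        for lo, hi in (self.correct_range, *self.incorrect_ranges):
            if not lo <= hi:
                raise ConfigurationError(f"empty range ({lo}, {hi})")


@dataclass(frozen=True)
class EffortSpec:
    """Across-patient effort variability and within-patient jitter."""

    p_max_range: tuple[float, float] = (5.0, 15.0)
    t_insp_range: tuple[float, float] = (0.8, 1.2)
    respiratory_rate_range: tuple[float, float] = (12.0, 25.0)
    jitter_sd: float = 0.05  # multiplicative N(1, sd^2) on p_max per maneuver

    def __post_init__(self) -> None:
        for lo, hi in (
            self.p_max_range,
            self.t_insp_range,
            self.respiratory_rate_range,
        ):
            if not lo <= hi:
                raise ConfigurationError(f"empty range ({lo}, {hi})")


@dataclass(frozen=True)
class CohortConfig:
    """Patient-level parameter ranges (adult ICU plausibility)."""

    resistance_range: tuple[float, float] = (5.0, 15.0)  # mbar*s/L
    compliance_range: tuple[float, float] = (30.0, 60.0)  # mL/mbar
    elastance_cw_range: tuple[float, float] = (4.0, 10.0)  # mbar/L
    peep_range: tuple[float, float] = (5.0, 10.0)  # mbar
    pes_offset_range: tuple[float, float] = (5.0, 12.0)  # mbar
    cardiac_rate_range: tuple[float, float] = (60.0, 100.0)  # /min
    cardiac_amplitude_range: tuple[float, float] = (0.0, 2.0)  # mbar
    noise_sd_range: tuple[float, float] = (0.0, 0.3)  # mbar
    pressure_support_range: tuple[float, float] = (8.0, 14.0)  # mbar
    p01_per_occlusion: int = 3  # acquisition protocol: 3 P0.1 per occlusion
    inter_maneuver_gap: float = 1.0  # s of quiet baseline between breaths


@dataclass
class SimulatedCohort:
    """Output bundle of :func:`generate_cohort`.

    ``ground_truth`` rows align one-to-one with ``annotations``.
    ``covariates`` carries per-patient synthetic baseline characteristics
    (age, sex, BMI, admission category, pulmonary comorbidity) for subgroup
    analyses.
    """

    records: list[WaveformRecord] = field(default_factory=list)
    annotations: list[ManeuverAnnotation] = field(default_factory=list)
    ground_truth: list[GroundTruth] = field(default_factory=list)
    covariates: "pd.DataFrame | None" = None

    def __iter__(self):
        # allow `records, annotations, truth = cohort`
        return iter((self.records, self.annotations, self.ground_truth))


def _draw(rng: np.random.Generator, rng_pair: tuple[float, float]) -> float:
    lo, hi = rng_pair
    return float(rng.uniform(lo, hi)) if hi > lo else float(lo)


def _draw_lambda(rng: np.random.Generator, spec: LambdaSpec) -> tuple[float, bool]:
    correct = bool(rng.uniform() < spec.fraction_correct)
    if correct:
        return _draw(rng, spec.correct_range), True
    w = np.asarray(spec.incorrect_weights, dtype=float)
    k = int(rng.choice(len(spec.incorrect_ranges), p=w / w.sum()))
    return _draw(rng, spec.incorrect_ranges[k]), False


def generate_cohort(
    n_patients: int = 25,
    maneuvers_per_patient: tuple[int, int] = (1, 6),
    lambda_distribution: LambdaSpec | None = None,
    effort_distribution: EffortSpec | None = None,
    seed: int = 0,
    *,
    config: CohortConfig | None = None,
    cardiac_amplitude: float | None = None,
    noise_sd: float | None = None,
) -> SimulatedCohort:
    """Generate a synthetic study cohort with known ground truth.

    Per patient: one balloon transmission factor ``lambda`` and one effort
    parameterization are drawn (p_max gets a small multiplicative jitter per
    maneuver); ``n_pairs`` P0.1/occlusion measurement pairs are drawn
    uniformly from ``maneuvers_per_patient``.  Following the acquisition
    protocol, maneuvers come in episodes of up to three P0.1 maneuvers
    followed by one reference occlusion, all on one continuous per-patient
    record.  ``cardiac_amplitude``/``noise_sd`` override the per-patient
    draws (e.g. to fix the artifact level of a study arm).

    Deterministic given ``seed``.
    """
    if n_patients < 1:
        raise ConfigurationError("n_patients must be >= 1")
    lo, hi = maneuvers_per_patient
    if not 1 <= lo <= hi:
        raise ConfigurationError("maneuvers_per_patient range must satisfy 1 <= lo <= hi")
    lam_spec = lambda_distribution or LambdaSpec()
    eff_spec = effort_distribution or EffortSpec()
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)

    cohort = SimulatedCohort()
    cov_rows = []
    for p in range(n_patients):
        pid = f"P{p + 1:02d}"
        lam, lam_correct = _draw_lambda(rng, lam_spec)
        system = RespiratorySystem(
            resistance=_draw(rng, cfg.resistance_range),
            compliance_rs=_draw(rng, cfg.compliance_range),
            elastance_cw=_draw(rng, cfg.elastance_cw_range),
            peep=_draw(rng, cfg.peep_range),
        )
        rr = _draw(rng, eff_spec.respiratory_rate_range)
        t_insp = min(_draw(rng, eff_spec.t_insp_range), 60.0 / rr - 0.05)
        effort_base = EffortProfile(
            p_max=_draw(rng, eff_spec.p_max_range),
            t_insp=t_insp,
            respiratory_rate=rr,
        )
        balloon = BalloonModel(
            lambda_transmission=lam,
            pes_offset=_draw(rng, cfg.pes_offset_range),
            cardiac_amplitude=(
                _draw(rng, cfg.cardiac_amplitude_range)
                if cardiac_amplitude is None
                else cardiac_amplitude
            ),
            cardiac_rate=_draw(rng, cfg.cardiac_rate_range),
            noise_sd=(
                _draw(rng, cfg.noise_sd_range) if noise_sd is None else noise_sd
            ),
        )
        vent = VentilatorConfig(
            pressure_support=_draw(rng, cfg.pressure_support_range)
        )

        n_pairs = int(rng.integers(lo, hi + 1))
        # acquisition order per episode: P0.1 maneuvers first, then the
        # reference occlusion; up to `p01_per_occlusion` P0.1 per episode
        kinds: list[str] = []
        remaining = n_pairs
        while remaining > 0:
            k = min(cfg.p01_per_occlusion, remaining)
            kinds.extend(["p01"] * k)
            kinds.append("occlusion")
            remaining -= k

        segments: list[WaveformRecord] = []
        offset = 0.0
        m_idx = 0
        for kind in kinds:
            m_idx += 1
            mid = f"{pid}-M{m_idx:02d}"
            jitter = float(rng.normal(1.0, eff_spec.jitter_sd))
            effort = EffortProfile(
                p_max=max(0.0, effort_base.p_max * jitter),
                t_insp=effort_base.t_insp,
                respiratory_rate=effort_base.respiratory_rate,
            )
            rec, ann = simulate_breath(
                system,
                effort,
                vent,
                balloon,
                maneuver=kind,
                seed=rng,
                onset_time=1.0,
                duration=1.0 + effort.t_insp + 2.0 + cfg.inter_maneuver_gap,
                patient_id=pid,
            )
            assert ann is not None
            cohort.annotations.append(
                ManeuverAnnotation(
                    patient_id=pid,
                    kind=kind,
                    start_time=ann.start_time + offset,
                    end_time=ann.end_time + offset,
                    maneuver_id=mid,
                )
            )
            cohort.ground_truth.append(
                GroundTruth(
                    patient_id=pid,
                    maneuver_id=mid,
                    kind=kind,
                    lambda_true=lam,
                    p_max=effort.p_max,
                    true_p01=(
                        true_p01(effort) if kind == "p01" else float("nan")
                    ),
                )
            )
            segments.append(rec)
            offset += rec.time.size * rec.dt

        dt = segments[0].dt
        cohort.records.append(
            WaveformRecord(
                patient_id=pid,
                sampling_rate=segments[0].sampling_rate,
                time=np.arange(sum(s.time.size for s in segments)) * dt,
                paw=np.concatenate([s.paw for s in segments]),
                flow=np.concatenate([s.flow for s in segments]),
                volume=np.concatenate([s.volume for s in segments]),
                pes=np.concatenate([s.pes for s in segments]),
            )
        )
        cov_rows.append(
            {
                "patient_id": pid,
                "age": int(rng.integers(36, 86)),
                "sex": "male" if rng.uniform() < 0.64 else "female",
                "bmi": float(np.round(rng.uniform(21.0, 43.0), 1)),
                "primary_resp_failure": bool(rng.uniform() < 0.24),
                "pulm_comorbidity": bool(rng.uniform() < 0.20),
                "lambda_true": lam,
                "lambda_correct": lam_correct,
            }
        )

    import pandas as pd  # deferred; only needed for the covariate table

    cohort.covariates = pd.DataFrame(cov_rows)
    return cohort
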