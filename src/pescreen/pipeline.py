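"""End-to-end orchestration: simulate -> measure -> screen -> agreement.

This is the programmatic counterpart of the command-line workflow and the
entry point used by the reproduction script: it generates a synthetic
cohort, measures every annotated maneuver, applies the screening cascade,
and produces one JSON-ready report with the diagnostic 2x2, the agreement
statistics, and ground-truth recovery diagnostics (possible only on
synthetic data, where the true balloon transmission factor is known).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import agreement_stats, maneuvers, screening, simulate
from .maneuvers import ManeuverMeasurement
from .screening import PairedMeasurement
from .simulate import SimulatedCohort
from .waveform_io import ManeuverAnnotation, WaveformRecord

__all__ = [
    "analyze_cohort",
    "pairs_to_frame",
    "lambda_recovery",
    "run_synthetic_study",
]


def analyze_cohort(
    records: Sequence[WaveformRecord],
    annotations: Sequence[ManeuverAnnotation] | None = None,
) -> list[ManeuverMeasurement]:
    """Measure every maneuver of every record (annotation-driven when
    annotations are given, detection-driven otherwise)."""
    out: list[ManeuverMeasurement] = []
    for rec in records:
        out.extend(maneuvers.analyze_record(rec, annotations))
    return out


def pairs_to_frame(pairs: Sequence[PairedMeasurement]) -> pd.DataFrame:
    """Pair-level table with ratios, filter flags and classifications."""
    rows = []
    for p in pairs:
        rows.append(
            {
                "patient_id": p.patient_id,
                "p01_maneuver_id": p.p01_measurement.maneuver_id,
                "occ_maneuver_id": p.occ_measurement.maneuver_id,
                "ratio_p01": p.p01_measurement.ratio,
                "ratio_occ": p.occ_measurement.ratio,
                "p01_mbar": p.p01_measurement.p01,
                "pes_deviation": p.pes_deviation,
                "excluded_reason": p.excluded_reason,
                "class_p01": p.class_p01,
                "class_occ": p.class_occ,
            }
        )
    return pd.DataFrame(rows)


def lambda_recovery(
    measurements: Sequence[ManeuverMeasurement],
    ground_truth: Sequence[simulate.GroundTruth],
) -> pd.DataFrame:
    """Join measured ratios to the simulator's true transmission factor."""
    truth = {g.maneuver_id: g for g in ground_truth}
    rows = []
    for m in measurements:
        g = truth.get(m.maneuver_id)
        if g is None:
            continue
        rows.append(
            {
                "patient_id": m.patient_id,
                "maneuver_id": m.maneuver_id,
                "kind": m.kind,
                "ratio": m.ratio,
                "lambda_true": g.lambda_true,
                "error": m.ratio - g.lambda_true,
                "class_measured": screening.classify_placement(m.ratio),
                "class_true": screening.classify_placement(g.lambda_true),
            }
        )
    return pd.DataFrame(rows)


def run_synthetic_study(
    seed: int,
    n_patients: int = 25,
    maneuvers_per_patient: tuple[int, int] = (1, 6),
    *,
    cardiac_amplitude: float | None = None,
    noise_sd: float | None = None,
    lambda_distribution: simulate.LambdaSpec | None = None,
) -> dict:
    """Full synthetic study: cohort, measurements, screening and agreement.

    Returns a JSON-ready dict with the screening report (2x2 counts,
    sensitivity/specificity/PPV/NPV, Fisher p, exclusion ledger), the
    continuous agreement statistics on the retained pairs (regression,
    Bland-Altman, GEE, subgroup R-squared), and the ground-truth recovery
    of the occlusion classification.
    """
    cohort: SimulatedCohort = simulate.generate_cohort(
        n_patients=n_patients,
        maneuvers_per_patient=maneuvers_per_patient,
        lambda_distribution=lambda_distribution,
        seed=seed,
        cardiac_amplitude=cardiac_amplitude,
        noise_sd=noise_sd,
    )
    measurements = analyze_cohort(cohort.records, cohort.annotations)
    pairs = screening.apply_filters(screening.pair_maneuvers(measurements))
    report = screening.screening_report(pairs)

    df = pairs_to_frame(pairs)
    retained = df[df["excluded_reason"] == screening.REASON_NONE]
    agreement: dict = {}
    if len(retained) >= 3 and retained["ratio_occ"].nunique() > 1:
        reg = agreement_stats.linear_regression(
            retained["ratio_occ"], retained["ratio_p01"]
        )
        ba = agreement_stats.bland_altman(
            retained["ratio_occ"], retained["ratio_p01"]
        )
        agreement["regression"] = {
            "slope": reg.slope,
            "intercept": reg.intercept,
            "r_squared": reg.r_squared,
            "p_value": reg.p_value,
            "n": reg.n,
        }
        agreement["bland_altman"] = {
            "bias": ba.bias,
            "bias_ci": list(ba.bias_ci),
            "loa": list(ba.loa),
            "n_outside": ba.n_outside,
            "n": ba.n,
        }
        cluster_sizes = retained.groupby("patient_id").size()
        if len(cluster_sizes) >= 2:
            gee = agreement_stats.gee_gaussian_exchangeable(
                retained["ratio_p01"].to_numpy(),
                retained["ratio_occ"].to_numpy(),
                retained["patient_id"].to_numpy(),
            )
            agreement["gee"] = {
                "beta": gee.beta,
                "robust_se": gee.robust_se,
                "ci95": list(gee.ci95),
                "alpha_exch": gee.alpha_exch,
                "n_clusters": gee.n_clusters,
                "converged": gee.converged,
            }
        if cohort.covariates is not None:
            subgroups = agreement_stats.subgroup_regressions(
                retained, cohort.covariates
            )
            agreement["subgroup_r2"] = {
                grouping: {
                    str(g): (
                        res.r_squared
                        if isinstance(res, agreement_stats.RegressionResult)
                        else None
                    )
                    for g, res in table.items()
                }
                for grouping, table in subgroups.items()
            }

    rec = lambda_recovery(measurements, cohort.ground_truth)
    occ = rec[rec["kind"] == "occlusion"]
    recovery = {
        "n_occlusions_measured": int(len(occ)),
        "occ_classification_accuracy": (
            float((occ["class_measured"] == occ["class_true"]).mean())
            if len(occ)
            else None
        ),
        "occ_ratio_mae": float(occ["error"].abs().mean()) if len(occ) else None,
    }
    return {
        "seed": seed,
        "n_patients": n_patients,
        "n_maneuvers": len(cohort.annotations),
        "n_measurements": len(measurements),
        "screening": report,
        "agreement": agreement,
        "ground_truth_recovery": recovery,
    }
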