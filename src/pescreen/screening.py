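"""Screening logic: pair P0.1 maneuvers with reference occlusions, filter,
classify balloon validity, and tabulate diagnostic accuracy.

The screening question is framed with the prolonged occlusion maneuver as
the reference standard: "positive" means the occlusion says the esophageal
pressure measurement is *incorrect* (ratio outside 0.75-1.25), and
"test-positive" means the P0.1 maneuver also flags it as incorrect.
Sensitivity is therefore the ability of the quick P0.1 screen to catch a
bad balloon, and the negative predictive value quantifies how safely a
normal screening result rules one out.

Filter cascade applied to each P0.1/occlusion pair before classification
(each filter is a pure predicate, so the retained set is order-invariant;
the recorded exclusion reason follows the canonical order below):

1. comparability — end-expiratory Pes must deviate by no more than 20 %
   between the P0.1 maneuver and its reference occlusion (similar balloon
   filling and position at both times);
2. respiratory drive — P0.1 values above -1 mbar indicate drive too weak
   to produce a measurable deflection and are removed;
3. plausibility — negative dPes/dPaw ratios are physiologically
   implausible and are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom

from .maneuvers import ManeuverMeasurement

__all__ = [
    "PairedMeasurement",
    "ContingencyTable",
    "pair_maneuvers",
    "comparability_filter",
    "drive_filter",
    "plausibility_filter",
    "classify_placement",
    "apply_filters",
    "build_contingency",
    "fisher_exact_p",
    "diagnostic_metrics",
    "screening_report",
]

logger = logging.getLogger(__name__)

RATIO_LOWER = 0.75  # validity band (both bounds strict)
RATIO_UPPER = 1.25
PES_DEVIATION_MAX = 0.20  # comparability: max end-expiratory Pes deviation
DRIVE_CUTOFF_MBAR = -1.0  # P0.1 above this (weaker drive) is removed
MIN_REFERENCE_PES_MBAR = 0.5  # |end-exp Pes| below this -> indeterminate 20 % rule

# exclusion reasons, in cascade order
REASON_NONE = "none"
REASON_INDETERMINATE = "indeterminate_denominator"
REASON_PES_DEVIATION = "pes_deviation_gt_20pct"
REASON_LOW_DRIVE = "low_drive"
REASON_NEGATIVE_RATIO = "negative_ratio"
EXCLUSION_REASONS = (
    REASON_INDETERMINATE,
    REASON_PES_DEVIATION,
    REASON_LOW_DRIVE,
    REASON_NEGATIVE_RATIO,
)


@dataclass
class PairedMeasurement:
    """One P0.1 measurement matched to its reference occlusion."""

    patient_id: str
    p01_measurement: ManeuverMeasurement
    occ_measurement: ManeuverMeasurement
    pes_deviation: float = float("nan")
    excluded_reason: str = REASON_NONE
    class_p01: str | None = None  # "correct" | "incorrect", retained pairs only
    class_occ: str | None = None

    @property
    def retained(self) -> bool:
        return self.excluded_reason == REASON_NONE


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 diagnostic table; positive = occlusion-incorrect, test = P0.1."""

    tp: int  # occlusion incorrect, P0.1 incorrect
    fn: int  # occlusion incorrect, P0.1 correct
    fp: int  # occlusion correct, P0.1 incorrect
    tn: int  # occlusion correct, P0.1 correct

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def pair_maneuvers(
    measurements: Sequence[ManeuverMeasurement],
) -> list[PairedMeasurement]:
    """Pair each P0.1 measurement with the nearest subsequent occlusion of
    the same patient (the acquisition protocol records P0.1 maneuvers before
    their reference occlusion).  P0.1 measurements with no subsequent
    occlusion are dropped with a logged warning.
    """
    pairs: list[PairedMeasurement] = []
    by_patient: dict[str, list[ManeuverMeasurement]] = {}
    for m in measurements:
        by_patient.setdefault(m.patient_id, []).append(m)
    for pid, ms in by_patient.items():
        occs = sorted(
            (m for m in ms if m.kind == "occlusion"), key=lambda m: m.onset_time
        )
        for p in sorted(
            (m for m in ms if m.kind == "p01"), key=lambda m: m.onset_time
        ):
            following = [o for o in occs if o.onset_time > p.onset_time]
            if not following:
                logger.warning(
                    "P0.1 maneuver %s (patient %s) has no subsequent occlusion; dropped",
                    p.maneuver_id,
                    pid,
                )
                continue
            ref = min(following, key=lambda o: o.onset_time - p.onset_time)
            pairs.append(
                PairedMeasurement(
                    patient_id=pid, p01_measurement=p, occ_measurement=ref
                )
            )
    return pairs


# ---------------------------------------------------------------------------
# filters (pure predicates; apply_filters records the first failing reason)


def comparability_filter(pair: PairedMeasurement) -> PairedMeasurement:
    """20 % end-expiratory Pes rule, anchored on the reference occlusion.

    Near-zero reference end-expiratory Pes makes the relative deviation
    indeterminate; such pairs are excluded with a distinct reason.
    """
    ref = pair.occ_measurement.pes_end_exp
    if abs(ref) < MIN_REFERENCE_PES_MBAR:
        logger.warning(
            "pair %s/%s: |end-expiratory Pes| of the reference occlusion "
            "< %.1f mbar; 20%% rule indeterminate",
            pair.p01_measurement.maneuver_id,
            pair.occ_measurement.maneuver_id,
            MIN_REFERENCE_PES_MBAR,
        )
        return replace(pair, excluded_reason=REASON_INDETERMINATE)
    deviation = abs(pair.p01_measurement.pes_end_exp - ref) / abs(ref)
    reason = (
        REASON_PES_DEVIATION if deviation > PES_DEVIATION_MAX else pair.excluded_reason
    )
    return replace(pair, pes_deviation=deviation, excluded_reason=reason)


def drive_filter(measurement: ManeuverMeasurement) -> bool:
    """Retain only P0.1 maneuvers with adequate drive (P0.1 <= -1 mbar)."""
    if measurement.kind != "p01":
        raise ValueError("drive_filter applies to P0.1 measurements")
    return measurement.p01 <= DRIVE_CUTOFF_MBAR


def plausibility_filter(measurement: ManeuverMeasurement) -> bool:
    """Retain only non-negative dPes/dPaw ratios (negative is implausible)."""
    return measurement.ratio >= 0


def classify_placement(ratio: float) -> str:
    """'correct' iff 0.75 < ratio < 1.25 (both bounds strict)."""
    return "correct" if RATIO_LOWER < ratio < RATIO_UPPER else "incorrect"


def apply_filters(pairs: Iterable[PairedMeasurement]) -> list[PairedMeasurement]:
    """Run the cascade (comparability -> drive -> plausibility) and classify
    the retained pairs by both maneuvers' ratios."""
    out = []
    for pair in pairs:
        pair = comparability_filter(pair)
        if pair.retained and not drive_filter(pair.p01_measurement):
            pair = replace(pair, excluded_reason=REASON_LOW_DRIVE)
        if pair.retained and not plausibility_filter(pair.p01_measurement):
            pair = replace(pair, excluded_reason=REASON_NEGATIVE_RATIO)
        if pair.retained:
            pair = replace(
                pair,
                class_p01=classify_placement(pair.p01_measurement.ratio),
                class_occ=classify_placement(pair.occ_measurement.ratio),
            )
        else:
            logger.info(
                "pair %s/%s excluded: %s",
                pair.p01_measurement.maneuver_id,
                pair.occ_measurement.maneuver_id,
                pair.excluded_reason,
            )
        out.append(pair)
    return out


def build_contingency(pairs: Iterable[PairedMeasurement]) -> ContingencyTable:
    """2x2 counts over retained, classified pairs."""
    tp = fn = fp = tn = 0
    for pair in pairs:
        if not pair.retained:
            continue
        if pair.class_p01 is None or pair.class_occ is None:
            raise ValueError(
                f"retained pair {pair.p01_measurement.maneuver_id} is unclassified"
            )
        occ_bad = pair.class_occ == "incorrect"
        p01_bad = pair.class_p01 == "incorrect"
        if occ_bad and p01_bad:
            tp += 1
        elif occ_bad:
            fn += 1
        elif p01_bad:
            fp += 1
        else:
            tn += 1
    return ContingencyTable(tp=tp, fn=fn, fp=fp, tn=tn)


# ---------------------------------------------------------------------------
# diagnostic accuracy


def fisher_exact_p(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of all
    tables with the observed margins that are no more probable than the
    observed one (with the customary 1 + 1e-7 relative tie tolerance)."""
    row1 = table.tp + table.fn
    col1 = table.tp + table.fp
    n = table.total
    if n == 0:
        return float("nan")
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = hypergeom.pmf(support, n, row1, col1)
    p_obs = hypergeom.pmf(table.tp, n, row1, col1)
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + 1e-7)].sum()))


def _safe_div(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def diagnostic_metrics(table: ContingencyTable) -> dict[str, float | None]:
    """Sensitivity / specificity / PPV / NPV (fractions) and Fisher p.

    Metrics with a zero denominator are reported as ``None`` (undefined),
    never as 0.
    """
    return {
        "sensitivity": _safe_div(table.tp, table.tp + table.fn),
        "specificity": _safe_div(table.tn, table.tn + table.fp),
        "ppv": _safe_div(table.tp, table.tp + table.fp),
        "npv": _safe_div(table.tn, table.tn + table.fn),
        "fisher_p": fisher_exact_p(table),
    }


def screening_report(pairs: Sequence[PairedMeasurement]) -> dict:
    """JSON-ready summary: counts, metrics, and the exclusion ledger."""
    table = build_contingency(pairs)
    excluded = {reason: 0 for reason in EXCLUSION_REASONS}
    for pair in pairs:
        if not pair.retained:
            excluded[pair.excluded_reason] += 1
    metrics = diagnostic_metrics(table)
    return {
        "n_pairs": len(pairs),
        "n_retained": sum(p.retained for p in pairs),
        "excluded": excluded,
        "counts": {
            "tp": table.tp,
            "fn": table.fn,
            "fp": table.fp,
            "tn": table.tn,
            "total": table.total,
        },
        "metrics": metrics,
    }
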