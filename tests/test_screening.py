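"""Pairing, filter cascade, validity classification and 2x2 diagnostics."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from pescreen import screening as scr
from pescreen.maneuvers import ManeuverMeasurement


def meas(kind, onset, pid="P01", ratio=1.0, p01=-2.0, pes_end_exp=10.0, mid=None):
    return ManeuverMeasurement(
        patient_id=pid,
        maneuver_id=mid or f"{pid}-{kind}-{onset}",
        kind=kind,
        onset_time=onset,
        baseline_paw=5.0,
        baseline_pes=8.0,
        delta_paw=-2.0,
        delta_pes=ratio * -2.0,
        ratio=ratio,
        p01=p01 if kind == "p01" else float("nan"),
        pes_end_exp=pes_end_exp,
    )


class TestPairing:
    def test_three_p01_share_one_subsequent_occlusion(self):
        ms = [meas("p01", t) for t in (1.0, 10.0, 20.0)] + [meas("occlusion", 30.0)]
        pairs = scr.pair_maneuvers(ms)
        assert len(pairs) == 3
        assert all(p.occ_measurement.onset_time == 30.0 for p in pairs)

    def test_occlusion_preceding_all_p01s_yields_no_pairs(self, caplog):
        ms = [meas("occlusion", 1.0)] + [meas("p01", t) for t in (10.0, 20.0, 30.0)]
        with caplog.at_level("WARNING", logger="pescreen.screening"):
            pairs = scr.pair_maneuvers(ms)
        assert pairs == []
        assert sum("no subsequent occlusion" in r.message for r in caplog.records) == 3

    def test_nearest_subsequent_occlusion_brute_force(self):
        rng = np.random.default_rng(0)
        times_p01 = sorted(rng.uniform(0, 100, 12))
        times_occ = sorted(rng.uniform(0, 100, 4))
        ms = [meas("p01", t) for t in times_p01] + [meas("occlusion", t) for t in times_occ]
        pairs = scr.pair_maneuvers(ms)
        expected = {}
        for tp in times_p01:
            later = [to for to in times_occ if to > tp]
            if later:
                expected[tp] = min(later)
        assert len(pairs) == len(expected)
        for p in pairs:
            assert p.occ_measurement.onset_time == expected[p.p01_measurement.onset_time]

    def test_pairs_never_cross_patients(self):
        ms = [meas("p01", 1.0, pid="A"), meas("occlusion", 5.0, pid="B")]
        assert scr.pair_maneuvers(ms) == []


class TestFilters:
    @pytest.mark.parametrize(
        "pes_p01,pes_occ,excluded",
        [(10.0, 10.0, False), (12.5, 10.0, True), (11.9, 10.0, False)],
    )
    def test_comparability_20_percent_rule(self, pes_p01, pes_occ, excluded):
        pair = scr.PairedMeasurement(
            "P01",
            meas("p01", 1.0, pes_end_exp=pes_p01),
            meas("occlusion", 5.0, pes_end_exp=pes_occ),
        )
        out = scr.comparability_filter(pair)
        assert (out.excluded_reason == scr.REASON_PES_DEVIATION) == excluded
        if not excluded:
            assert out.pes_deviation == pytest.approx(abs(pes_p01 - pes_occ) / pes_occ)

    def test_near_zero_reference_is_indeterminate(self):
        pair = scr.PairedMeasurement(
            "P01", meas("p01", 1.0), meas("occlusion", 5.0, pes_end_exp=0.2)
        )
        assert scr.comparability_filter(pair).excluded_reason == scr.REASON_INDETERMINATE

    @pytest.mark.parametrize(
        "p01,retained", [(-3.1, True), (-0.5, False), (-1.0, True)]
    )
    def test_drive_filter_boundary(self, p01, retained):
        assert scr.drive_filter(meas("p01", 1.0, p01=p01)) is retained

    @pytest.mark.parametrize("ratio,retained", [(-0.3, False), (0.0, True), (1.1, True)])
    def test_plausibility_filter(self, ratio, retained):
        assert scr.plausibility_filter(meas("p01", 1.0, ratio=ratio)) is retained

    def test_cascade_is_order_invariant(self):
        """Each filter is a pure predicate, so the retained set does not
        depend on the order in which the rules are applied."""
        rng = np.random.default_rng(1)
        pairs = [
            scr.PairedMeasurement(
                "P01",
                meas(
                    "p01",
                    float(i),
                    ratio=float(rng.normal(0.9, 0.6)),
                    p01=float(rng.uniform(-4, 0.5)),
                    pes_end_exp=float(rng.uniform(7, 14)),
                ),
                meas("occlusion", 100.0, pes_end_exp=10.0),
            )
            for i in range(50)
        ]
        canonical = {
            p.p01_measurement.maneuver_id
            for p in scr.apply_filters(pairs)
            if p.retained
        }
        predicates = [
            lambda p: scr.comparability_filter(p).retained,
            lambda p: scr.drive_filter(p.p01_measurement),
            lambda p: scr.plausibility_filter(p.p01_measurement),
        ]
        for order in itertools.permutations(predicates):
            kept = {
                p.p01_measurement.maneuver_id
                for p in pairs
                if all(pred(p) for pred in order)
            }
            assert kept == canonical

    def test_filters_never_increase_retained_count(self):
        pairs = [
            scr.PairedMeasurement("P01", meas("p01", 1.0, ratio=-0.1), meas("occlusion", 5.0))
        ]
        assert sum(p.retained for p in scr.apply_filters(pairs)) <= len(pairs)


class TestClassification:
    @pytest.mark.parametrize(
        "ratio,expected",
        [(1.00, "correct"), (0.75, "incorrect"), (1.25, "incorrect"), (1.40, "incorrect"), (0.76, "correct")],
    )
    def test_strict_validity_band(self, ratio, expected):
        assert scr.classify_placement(ratio) == expected


def pairs_with_classes(spec):
    """Build classified pairs from (occ_class, p01_class, count) triples."""
    out = []
    t = 0.0
    for occ_c, p01_c, n in spec:
        for _ in range(n):
            r_occ = 1.0 if occ_c == "correct" else 1.5
            r_p01 = 1.0 if p01_c == "correct" else 1.5
            pair = scr.PairedMeasurement(
                "P01", meas("p01", t, ratio=r_p01), meas("occlusion", t + 1, ratio=r_occ)
            )
            out.append(pair)
            t += 2
    return scr.apply_filters(out)


class TestContingency:
    def test_study_counts_build_the_printed_table(self):
        # 38 occlusion-correct (27 concordant), 27 occlusion-incorrect (25 concordant)
        pairs = pairs_with_classes(
            [
                ("correct", "correct", 27),
                ("correct", "incorrect", 11),
                ("incorrect", "incorrect", 25),
                ("incorrect", "correct", 2),
            ]
        )
        table = scr.build_contingency(pairs)
        assert (table.tp, table.fn, table.fp, table.tn) == (25, 2, 11, 27)
        assert table.total == 65

    def test_all_concordant_correct(self):
        table = scr.build_contingency(pairs_with_classes([("correct", "correct", 7)]))
        assert (table.tp, table.fn, table.fp, table.tn) == (0, 0, 0, 7)

    def test_totals_conserved_and_margins_match(self):
        pairs = pairs_with_classes(
            [("correct", "correct", 4), ("incorrect", "correct", 3), ("incorrect", "incorrect", 5)]
        )
        table = scr.build_contingency(pairs)
        assert table.total == sum(p.retained for p in pairs)
        n_occ_bad = sum(p.class_occ == "incorrect" for p in pairs if p.retained)
        assert table.tp + table.fn == n_occ_bad

    def test_unclassified_retained_pair_is_a_contract_violation(self):
        pair = scr.PairedMeasurement("P01", meas("p01", 1.0), meas("occlusion", 2.0))
        with pytest.raises(ValueError, match="unclassified"):
            scr.build_contingency([pair])


def fisher_oracle(tp, fn, fp, tn):
    """Exhaustive two-sided Fisher p with exact rational arithmetic."""
    n, r, c = tp + fn + fp + tn, tp + fn, tp + fp

    def pmf(k):
        return (
            Fraction(math.comb(r, k) * math.comb(n - r, c - k), math.comb(n, c))
        )

    p_obs = pmf(tp)
    total = sum(
        p for k in range(max(0, r + c - n), min(r, c) + 1)
        if (p := pmf(k)) <= p_obs
    )
    return float(total)


class TestDiagnostics:
    def test_study_table_metrics(self):
        m = scr.diagnostic_metrics(scr.ContingencyTable(25, 2, 11, 27))
        assert m["sensitivity"] == pytest.approx(25 / 27)
        assert m["specificity"] == pytest.approx(27 / 38)
        assert m["ppv"] == pytest.approx(25 / 36)
        assert m["npv"] == pytest.approx(27 / 29)

    def test_perfect_table(self):
        m = scr.diagnostic_metrics(scr.ContingencyTable(1, 0, 0, 1))
        assert m["sensitivity"] == m["specificity"] == m["ppv"] == m["npv"] == 1.0

    def test_zero_denominator_reported_as_undefined(self):
        m = scr.diagnostic_metrics(scr.ContingencyTable(0, 0, 3, 5))
        assert m["sensitivity"] is None and m["ppv"] is not None

    @pytest.mark.parametrize(
        "table", [(25, 2, 11, 27), (1, 0, 0, 1), (5, 5, 5, 5), (0, 10, 3, 2), (8, 1, 0, 12)]
    )
    def test_fisher_matches_enumeration_oracle(self, table):
        p = scr.fisher_exact_p(scr.ContingencyTable(*table))
        assert p == pytest.approx(fisher_oracle(*table), abs=1e-12)

    @pytest.mark.parametrize("table", [(25, 2, 11, 27), (3, 7, 2, 9), (12, 0, 1, 4)])
    def test_fisher_matches_scipy(self, table):
        tp, fn, fp, tn = table
        p = scr.fisher_exact_p(scr.ContingencyTable(tp, fn, fp, tn))
        assert p == pytest.approx(scipy_fisher([[tp, fn], [fp, tn]])[1], rel=1e-9)


def test_screening_report_excluded_ledger():
    pairs = [
        scr.PairedMeasurement("P01", meas("p01", 1.0, ratio=-0.5), meas("occlusion", 2.0)),
        scr.PairedMeasurement("P01", meas("p01", 3.0, p01=-0.2), meas("occlusion", 4.0)),
        scr.PairedMeasurement("P01", meas("p01", 5.0, pes_end_exp=14.0), meas("occlusion", 6.0, pes_end_exp=10.0)),
        scr.PairedMeasurement("P01", meas("p01", 7.0), meas("occlusion", 8.0)),
    ]
    report = scr.screening_report(scr.apply_filters(pairs))
    assert report["excluded"][scr.REASON_NEGATIVE_RATIO] == 1
    assert report["excluded"][scr.REASON_LOW_DRIVE] == 1
    assert report["excluded"][scr.REASON_PES_DEVIATION] == 1
    assert report["n_retained"] == 1
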