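"""Maneuver detection and dPes/dPaw measurement against simulator truth."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pescreen import maneuvers as mv
from pescreen import simulate as sim
from pescreen.waveform_io import WaveformRecord
from .conftest import make_balloon


def flat_record(n=600, peep=5.0, pes=8.0):
    return WaveformRecord(
        patient_id="F",
        sampling_rate=200.0,
        time=np.arange(n) / 200.0,
        paw=np.full(n, peep),
        flow=np.zeros(n),
        volume=np.zeros(n),
        pes=np.full(n, pes),
    )


class TestDetection:
    def test_occlusion_breath_yields_one_occlusion_window(self, system, effort, vent, clean_balloon):
        rec, ann = sim.simulate_breath(system, effort, vent, clean_balloon, "occlusion", seed=0)
        wins = mv.detect_occlusion_windows(rec)
        assert len(wins) == 1 and wins[0].kind == "occlusion"
        assert wins[0].start_time == pytest.approx(ann.start_time, abs=0.01)

    def test_p01_breath_yields_one_p01_window_of_100ms(self, system, effort, vent, clean_balloon):
        rec, _ = sim.simulate_breath(system, effort, vent, clean_balloon, "p01", seed=0)
        wins = mv.detect_occlusion_windows(rec)
        assert len(wins) == 1 and wins[0].kind == "p01"
        assert wins[0].duration == pytest.approx(0.100, abs=0.005)

    def test_flat_record_yields_nothing(self):
        assert mv.detect_occlusion_windows(flat_record()) == []

    def test_unoccluded_breath_yields_nothing(self, system, effort, vent, clean_balloon):
        rec, _ = sim.simulate_breath(system, effort, vent, clean_balloon, "none", seed=0)
        assert mv.detect_occlusion_windows(rec) == []


class TestOnset:
    def test_onset_close_to_true_effort_start(self, system, effort, vent, clean_balloon):
        rec, ann = sim.simulate_breath(system, effort, vent, clean_balloon, "occlusion", seed=0)
        win = mv.ManeuverWindow(ann.start_time, ann.end_time, ann.kind)
        onset = mv.detect_effort_onset(rec, win)
        assert abs(onset - ann.start_time) <= 0.025

    def test_zero_deflection_raises_onset_not_found(self):
        rec = flat_record()
        with pytest.raises(mv.OnsetNotFoundError):
            mv.detect_effort_onset(rec, mv.ManeuverWindow(1.0, 2.0, "occlusion"))

    def test_onset_robust_to_sensor_noise(self, system, effort, vent):
        """Onset shifts by <= 50 ms in >= 95 % of noisy replicates."""
        rng = np.random.default_rng(8)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            rec, ann = sim.simulate_breath(
                system, effort, vent, make_balloon(), "occlusion", seed=rng
            )
            rec.paw = rec.paw + rng.normal(0, 0.05, rec.paw.size)
            onset = mv.detect_effort_onset(
                rec, mv.ManeuverWindow(ann.start_time, ann.end_time, ann.kind)
            )
            hits += abs(onset - ann.start_time) <= 0.05
        assert hits >= 95


class TestMeasurement:
    @pytest.mark.parametrize(
        "lam,expected", [(1.0, (-10.0, -10.0)), (0.5, (-10.0, -5.0))]
    )
    def test_occlusion_deltas_closed_form(self, system, effort, vent, lam, expected):
        rec, _ = sim.simulate_breath(system, effort, vent, make_balloon(lam=lam), "occlusion", seed=0)
        win = mv.detect_occlusion_windows(rec)[0]
        onset = mv.detect_effort_onset(rec, win)
        d_paw, d_pes = mv.measure_occlusion_deltas(rec, win, onset)
        assert d_paw == pytest.approx(expected[0], abs=0.05)
        assert d_pes == pytest.approx(expected[1], abs=0.05)

    def test_no_transmission_gives_zero_ratio(self, system, effort, vent):
        rec, _ = sim.simulate_breath(system, effort, vent, make_balloon(lam=0.0), "occlusion", seed=0)
        m = mv.measure_maneuver(rec, mv.detect_occlusion_windows(rec)[0])
        assert m.delta_pes == pytest.approx(0.0, abs=1e-9)
        assert m.ratio == pytest.approx(0.0, abs=1e-9)

    def test_p01_closed_form(self, system, effort, vent, clean_balloon):
        rec, _ = sim.simulate_breath(system, effort, vent, clean_balloon, "p01", seed=0)
        win = mv.detect_occlusion_windows(rec)[0]
        onset = mv.detect_effort_onset(rec, win)
        p01, d_pes = mv.measure_p01(rec, win, onset)
        expected = -10.0 * math.sin(0.1 * math.pi)
        assert p01 == pytest.approx(expected, abs=0.16)  # one sample of Pmus slope
        assert d_pes / p01 == pytest.approx(1.0, abs=0.02)

    def test_zero_effort_p01_is_zero(self):
        rec = flat_record()
        p01, d_pes = mv.measure_p01(rec, mv.ManeuverWindow(1.0, 1.1, "p01"), 1.0)
        assert p01 == 0.0 and d_pes == 0.0

    def test_too_little_occluded_time_is_an_error(self):
        rec = flat_record()
        with pytest.raises(mv.ManeuverError):
            mv.measure_p01(rec, mv.ManeuverWindow(1.0, 1.05, "p01"), 1.0)

    def test_end_expiratory_pes_constant_signal(self):
        assert mv.end_expiratory_pes(flat_record(pes=8.0), 1.0) == pytest.approx(8.0)

    def test_end_expiratory_pes_from_simulated_breath(self, system, effort, vent, clean_balloon):
        rec, ann = sim.simulate_breath(system, effort, vent, clean_balloon, "occlusion", seed=0)
        assert mv.end_expiratory_pes(rec, ann.start_time) == pytest.approx(8.0, abs=1e-9)

    def test_end_expiratory_pes_needs_pre_onset_data(self):
        with pytest.raises(mv.ManeuverError):
            mv.end_expiratory_pes(flat_record(), 0.3)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(scale=st.floats(0.2, 5.0))
def test_ratio_scale_invariance(scale):
    """Scaling both pressure deflections by c > 0 leaves the ratio unchanged."""
    system = sim.RespiratorySystem(resistance=10, compliance_rs=45, elastance_cw=0, peep=5)
    effort = sim.EffortProfile(p_max=8.0, t_insp=1.0, respiratory_rate=18)
    vent = sim.VentilatorConfig()
    rec, ann = sim.simulate_breath(system, effort, vent, make_balloon(lam=0.8), "occlusion", seed=0)
    win = mv.ManeuverWindow(ann.start_time, ann.end_time, ann.kind)
    base = mv.measure_maneuver(rec, win)
    rec.paw = 5.0 + scale * (rec.paw - 5.0)
    rec.pes = 8.0 + scale * (rec.pes - 8.0)
    scaled = mv.measure_maneuver(rec, win)
    assert scaled.ratio == pytest.approx(base.ratio, abs=1e-9)


def test_detection_matches_annotation_oracle(system, vent):
    """Detect->measure equals annotation-driven measurement on clean breaths."""
    rng = np.random.default_rng(3)
    for p_max, t_insp, lam, kind in [
        (6, 0.8, 0.4, "occlusion"),
        (12, 1.2, 1.0, "occlusion"),
        (9, 1.0, 1.2, "p01"),
        (14, 0.9, 0.7, "p01"),
    ]:
        effort = sim.EffortProfile(p_max=p_max, t_insp=t_insp, respiratory_rate=18)
        rec, ann = sim.simulate_breath(
            system, effort, vent, make_balloon(lam=lam), kind, seed=rng
        )
        detected = mv.detect_occlusion_windows(rec)
        assert len(detected) == 1 and detected[0].kind == kind
        m_det = mv.measure_maneuver(rec, detected[0])
        m_ann = mv.measure_maneuver(rec, mv.ManeuverWindow(ann.start_time, ann.end_time, kind))
        assert m_det.delta_paw == pytest.approx(m_ann.delta_paw, abs=0.05)
        assert m_det.delta_pes == pytest.approx(m_ann.delta_pes, abs=0.05)


def test_measurement_frame_round_trip(system, effort, vent, clean_balloon):
    rec, ann = sim.simulate_breath(system, effort, vent, clean_balloon, "occlusion", seed=0)
    ms = [mv.measure_maneuver(rec, mv.ManeuverWindow(ann.start_time, ann.end_time, ann.kind), maneuver_id="A-1")]
    df = mv.measurements_to_frame(ms)
    back = mv.frame_to_measurements(df)
    assert back[0].ratio == ms[0].ratio
    assert back[0].maneuver_id == "A-1"
    assert back[0].pes_end_exp == ms[0].pes_end_exp
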