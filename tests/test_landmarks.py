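"""Landmark extraction against minimum-jerk closed forms; aggregation."""

import numpy as np
import pandas as pd
import pytest

from motorequiv.conventions import PEAK_ACC_FACTOR, PEAK_SPEED_FACTOR
from motorequiv.exceptions import CompletenessError, ExtractionError
from motorequiv.io import Recording
from motorequiv.kinematics import compute_kinematics
from motorequiv.landmarks import (
    LandmarkRecord,
    LandmarkTable,
    aggregate,
    extract_landmarks,
)
from motorequiv.segmentation import detect_cycles, select_cycles


def record(value, pid="P01", tool="hammer", eff="right_hand", ordinal=6):
    return LandmarkRecord(
        participant_id=pid, tool=tool, effector=eff, cycle_ordinal=ordinal,
        cycle_duration=value, vertical_amplitude=value,
        max_velocity_forth=value, peak_acceleration_forth=value,
        peak_deceleration_forth=value,
    )


@pytest.fixture(scope="module")
def clean_landmarks(clean_hammer_sim):
    ser = compute_kinematics(clean_hammer_sim.recording)
    kept = select_cycles(detect_cycles(ser, "hammer"))
    return extract_landmarks(ser, kept, "P01", "hammer", "right_hand")


class TestExtractLandmarks:
    def test_peak_speed_within_2pct_of_closed_form(self, clean_landmarks):
        """A = 300 mm, forth d = 0.4 s -> 1.875 A/d = 1406.25 mm/s."""
        expected = PEAK_SPEED_FACTOR * 300.0 / 0.4
        for rec in clean_landmarks:
            assert rec.max_velocity_forth == pytest.approx(expected, rel=0.02)

    def test_peak_acceleration_within_5pct_of_closed_form(self, clean_landmarks):
        """(10/sqrt(3)) A/d^2 = 10825.3 mm/s^2; deceleration symmetric."""
        expected = PEAK_ACC_FACTOR * 300.0 / 0.4**2
        for rec in clean_landmarks:
            assert rec.peak_acceleration_forth == pytest.approx(expected, rel=0.05)
            assert rec.peak_deceleration_forth == pytest.approx(expected, rel=0.05)

    def test_cycle_duration_and_amplitude(self, clean_landmarks, clean_hammer_sim):
        truth = clean_hammer_sim.cycle_truth.set_index("cycle_ordinal")
        for rec in clean_landmarks:
            t = truth.loc[rec.cycle_ordinal]
            assert rec.cycle_duration == pytest.approx(t["cycle_duration"],
                                                       abs=1.0 / 200.0)
            assert rec.vertical_amplitude == pytest.approx(
                t["vertical_amplitude"], rel=0.01
            )

    def test_scale_equivariance(self, clean_hammer_sim):
        """Scaling positions by c scales spatial landmarks by c, leaves
        duration unchanged."""
        rec = clean_hammer_sim.recording
        c = 2.5
        scaled = Recording(rec.participant_id, rec.tool, rec.effector,
                           rec.sample_rate,
                           {m: xyz * c for m, xyz in rec.markers.items()},
                           endpoint_marker=rec.endpoint_marker)
        base = extract_landmarks(
            *_pipeline(rec), "P01", "hammer", "right_hand")
        scl = extract_landmarks(
            *_pipeline(scaled), "P01", "hammer", "right_hand")
        for b, s in zip(base, scl):
            assert s.cycle_duration == pytest.approx(b.cycle_duration, abs=1e-12)
            assert s.vertical_amplitude == pytest.approx(c * b.vertical_amplitude)
            assert s.max_velocity_forth == pytest.approx(c * b.max_velocity_forth)
            assert s.peak_acceleration_forth == pytest.approx(
                c * b.peak_acceleration_forth)

    def test_time_dilation(self, clean_config, hammer_signature):
        """Half-speed movement: duration x2, peak speed /2, peak acc /4."""
        from dataclasses import replace

        from motorequiv.simulate import synthesize_recording, EffectorModulation

        slow_sig = replace(hammer_signature,
                           cycle_duration=2 * hammer_signature.cycle_duration)
        mod = EffectorModulation("right_hand")
        fast = synthesize_recording(hammer_signature, "hammer", "right_hand",
                                    mod, clean_config)
        slow = synthesize_recording(slow_sig, "hammer", "right_hand",
                                    mod, clean_config)
        rf = extract_landmarks(*_pipeline(fast.recording), "P", "hammer",
                               "right_hand")
        rs = extract_landmarks(*_pipeline(slow.recording), "P", "hammer",
                               "right_hand")
        mf = pd.DataFrame([r.__dict__ for r in rf]).mean(numeric_only=True)
        ms = pd.DataFrame([r.__dict__ for r in rs]).mean(numeric_only=True)
        assert ms["cycle_duration"] == pytest.approx(2 * mf["cycle_duration"],
                                                     rel=0.02)
        assert ms["max_velocity_forth"] == pytest.approx(
            mf["max_velocity_forth"] / 2, rel=0.02)
        assert ms["peak_acceleration_forth"] == pytest.approx(
            mf["peak_acceleration_forth"] / 4, rel=0.05)

    def test_nonfinite_landmark_rejected(self):
        with pytest.raises(ExtractionError):
            record(float("nan"))


def _pipeline(recording):
    ser = compute_kinematics(recording)
    kept = select_cycles(detect_cycles(ser, recording.tool))
    return ser, kept


class TestAggregate:
    def test_mean_of_identical_values(self):
        records = [record(5.0, ordinal=i) for i in range(6, 20)]
        table = aggregate(records)
        assert (table.data["value"] == 5.0).all()
        assert (table.data["n_cycles"] == 14).all()

    def test_arithmetic_mean(self):
        records = [record(float(v), ordinal=v) for v in range(1, 15)]
        table = aggregate(records)
        assert np.allclose(table.data["value"], 7.5)

    def test_missing_cell_raises(self):
        records = [record(1.0, eff="right_hand"), record(1.0, eff="left_hand"),
                   record(1.0, pid="P02", eff="right_hand")]
        with pytest.raises(CompletenessError, match="P02"):
            aggregate(records)

    def test_cohort_table_matches_generator_truth(self, clean_config):
        """Noise-free cohort: extracted means equal analytic ground truth."""
        from dataclasses import replace

        from motorequiv.reporting import extract_cohort
        from motorequiv.simulate import generate_cohort

        cfg = replace(clean_config, n_participants=2, rng_seed=21)
        cohort = generate_cohort(cfg)
        table, _ = extract_cohort(cohort.recordings)
        merged = table.data.merge(
            cohort.ground_truth.data,
            on=["participant", "tool", "effector", "parameter"],
            suffixes=("", "_truth"),
        )
        assert len(merged) == len(table.data)
        tol = {"cycle_duration": 0.02, "vertical_amplitude": 0.02,
               "max_velocity_forth": 0.02, "peak_acceleration_forth": 0.05,
               "peak_deceleration_forth": 0.05}
        for _, row in merged.iterrows():
            assert row["value"] == pytest.approx(
                row["value_truth"], rel=tol[row["parameter"]]
            ), row["parameter"]


def test_values_matrix_completeness_check():
    df = pd.DataFrame({
        "participant": ["P01", "P01", "P02"],
        "tool": ["hammer"] * 3,
        "effector": ["right_hand", "left_hand", "right_hand"],
        "parameter": ["cycle_duration"] * 3,
        "value": [1.0, 1.1, 0.9],
    })
    with pytest.raises(CompletenessError):
        LandmarkTable(df).values_matrix("hammer", "cycle_duration")
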