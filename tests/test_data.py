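"""Cohort I/O, lab imputation, covariate encoding and feature building."""

import numpy as np
import pytest

from tacdose.data import (
    LabSeries,
    STATIC_FEATURE_NAMES,
    build_lag_features,
    build_sequences,
    encode_static,
    impute_labs,
    lag_matrix,
    pad_batch,
    read_cohort,
)
from tacdose.pk_core import (
    DoseEvent,
    TroughObservation,
    empirical_alpha,
    remaining_drug_amount,
)
from tacdose.synthdata import CohortConfig, simulate_cohort, write_cohort_csvs

from conftest import make_labs, make_patient, make_static


class TestReadCohort:
    def test_round_trip_of_simulated_cohort(self, tmp_path, small_cohort):
        records, truths = small_cohort
        write_cohort_csvs(records, truths, tmp_path)
        back = read_cohort(
            tmp_path / "doses.csv", tmp_path / "troughs.csv",
            tmp_path / "labs.csv", tmp_path / "static.csv",
        )
        assert len(back) == len(records)
        by_id = {r.patient_id: r for r in back}
        for r in records:
            b = by_id[r.patient_id]
            assert [d.time for d in b.doses] == [d.time for d in r.doses]
            assert [o.concentration for o in b.troughs] == pytest.approx(
                [o.concentration for o in r.troughs]
            )
            # event times come back sorted
            assert all(
                t1.time < t2.time for t1, t2 in zip(b.troughs, b.troughs[1:])
            )

    def test_single_trough_patient_excluded_with_log(self, tmp_path, caplog):
        records, truths = simulate_cohort(CohortConfig(n_patients=5, seed=3))
        write_cohort_csvs(records, truths, tmp_path)
        import pandas as pd
        troughs = pd.read_csv(tmp_path / "troughs.csv")
        victim = records[0].patient_id
        troughs = troughs[
            ~((troughs.patient_id == victim)
              & (troughs.time_h > troughs[troughs.patient_id == victim].time_h.min()))
        ]
        troughs.to_csv(tmp_path / "troughs.csv", index=False)
        with caplog.at_level("WARNING"):
            back = read_cohort(
                tmp_path / "doses.csv", tmp_path / "troughs.csv",
                tmp_path / "labs.csv", tmp_path / "static.csv",
            )
        assert victim not in {r.patient_id for r in back}
        assert any(
            victim in m and "fewer than two" in m for m in caplog.messages
        )

    def test_trough_before_first_dose_is_error(self, tmp_path, small_cohort):
        records, truths = small_cohort
        write_cohort_csvs(records, truths, tmp_path)
        import pandas as pd
        troughs = pd.read_csv(tmp_path / "troughs.csv")
        troughs.loc[troughs.index[0], "time_h"] = -5.0
        troughs.to_csv(tmp_path / "troughs.csv", index=False)
        with pytest.raises(ValueError, match="precedes the first dose"):
            read_cohort(
                tmp_path / "doses.csv", tmp_path / "troughs.csv",
                tmp_path / "labs.csv", tmp_path / "static.csv",
            )

    def test_duplicate_dose_rows_rejected(self, tmp_path, small_cohort):
        records, truths = small_cohort
        write_cohort_csvs(records, truths, tmp_path)
        import pandas as pd
        doses = pd.read_csv(tmp_path / "doses.csv")
        doses = pd.concat([doses, doses.iloc[[0]]])
        doses.to_csv(tmp_path / "doses.csv", index=False)
        with pytest.raises(ValueError, match="duplicated"):
            read_cohort(
                tmp_path / "doses.csv", tmp_path / "troughs.csv",
                tmp_path / "labs.csv", tmp_path / "static.csv",
            )

    def test_missing_column_names_file(self, tmp_path, small_cohort):
        records, truths = small_cohort
        write_cohort_csvs(records, truths, tmp_path)
        import pandas as pd
        doses = pd.read_csv(tmp_path / "doses.csv").drop(columns=["dose_mg"])
        doses.to_csv(tmp_path / "doses.csv", index=False)
        with pytest.raises(ValueError, match="dose_mg"):
            read_cohort(
                tmp_path / "doses.csv", tmp_path / "troughs.csv",
                tmp_path / "labs.csv", tmp_path / "static.csv",
            )


class TestImputeLabs:
    def test_midpoint_interpolation(self):
        s = LabSeries("hematocrit", [0.0, 48.0], [30.0, 34.0])
        assert impute_labs(s, [24.0])[0] == pytest.approx(32.0)

    def test_edges_carry_nearest_value(self):
        s = LabSeries("hematocrit", [0.0, 48.0], [30.0, 34.0])
        assert impute_labs(s, [60.0])[0] == pytest.approx(34.0)
        assert impute_labs(s, [-5.0])[0] == pytest.approx(30.0)

    def test_single_point_series(self):
        s = LabSeries("albumin", [24.0], [3.5])
        assert impute_labs(s, [0.0, 24.0, 100.0]) == pytest.approx([3.5] * 3)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            LabSeries("alt", [], [])


class TestEncodeStatic:
    def test_deterministic_and_one_hot(self):
        s = make_static(race="Other")
        v1, v2 = encode_static(s), encode_static(s)
        assert np.array_equal(v1, v2)
        race_block = v1[-3:]
        assert race_block.sum() == 1.0
        assert v1[STATIC_FEATURE_NAMES.index("race_other") ] == 1.0

    def test_unknown_race_rejected(self):
        with pytest.raises(ValueError, match="race"):
            make_static(race="Martian")

    def test_zscoring_maps_mean_to_zero(self):
        s = make_static(age=52.0)
        mean = np.array([52.0, 172.0, 87.0, 29.4, 2.03])
        std = np.ones(5)
        v = encode_static(s, stats=(mean, std))
        assert v[:5] == pytest.approx(np.zeros(5))


class TestBuildSequences:
    def test_sample_count_is_troughs_minus_one(self):
        p2 = make_patient(trough_times=(23.9, 47.9), trough_concs=(8.0, 10.0))
        assert len(build_sequences(p2)) == 1
        times = tuple(24.0 * k - 0.1 for k in range(1, 7))
        p6 = make_patient(trough_times=times, trough_concs=(8, 9, 10, 11, 10, 9))
        assert len(build_sequences(p6)) == 5

    def test_histories_strictly_nested(self):
        times = tuple(24.0 * k - 0.1 for k in range(1, 5))
        p = make_patient(trough_times=times, trough_concs=(8, 9, 10, 11))
        samples = build_sequences(p)
        for a, b in zip(samples, samples[1:]):
            assert b.n_steps == a.n_steps + 1
            assert np.array_equal(b.features[: a.n_steps], a.features)

    def test_first_trough_never_a_target(self):
        p = make_patient()
        assert all(s.target_index >= 1 for s in build_sequences(p))

    def test_doses_attached_up_to_target_only(self):
        p = make_patient()
        s = build_sequences(p)[0]
        assert all(d.time < s.target_time for d in s.doses)

    def test_no_information_after_target_time(self):
        """Leakage sentinel: perturbing any post-target dose, trough or lab
        leaves the sample's features and attached doses unchanged."""
        times = tuple(24.0 * k - 0.1 for k in range(1, 4))
        p = make_patient(trough_times=times, trough_concs=(8.0, 9.0, 10.0))
        s = build_sequences(p)[0]  # target = trough 2 at 47.9 h
        # perturb: change late doses, late trough, late labs
        doses = [
            DoseEvent(d.time, d.amount * 3 if d.time > s.target_time else d.amount)
            for d in p.doses
        ]
        troughs = list(p.troughs[:2]) + [TroughObservation(71.9, 25.0)]
        labs = make_labs()
        for series in labs.values():
            series.values[series.times >= 48.0] *= 5.0
        p_perturbed = type(p)(p.patient_id, doses, troughs, labs, p.static)
        s2 = build_sequences(p_perturbed)[0]
        assert np.array_equal(s.features, s2.features)
        assert [(d.time, d.amount) for d in s.doses] == [
            (d.time, d.amount) for d in s2.doses
        ]


class TestPadBatch:
    def test_equal_lengths_no_padding(self):
        p = make_patient()
        s = build_sequences(p)[0]
        X, mask, lengths = pad_batch([s, s])
        assert mask.all() and X.shape[1] == s.n_steps

    def test_mixed_lengths(self):
        times = tuple(24.0 * k - 0.1 for k in range(1, 5))
        p = make_patient(trough_times=times, trough_concs=(8, 9, 10, 11))
        samples = build_sequences(p)
        X, mask, lengths = pad_batch([samples[0], samples[2]])
        assert X.shape[1] == 3
        assert lengths.tolist() == [1, 3]
        assert mask[0].tolist() == [True, False, False]
        # padded steps are exactly zero
        assert np.all(X[0, 1:] == 0.0)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            pad_batch([])


class TestBuildLagFeatures:
    def test_two_trough_patient_has_flagged_lag2(self):
        p = make_patient()
        rows = build_lag_features(p, 0.0578)
        assert len(rows) == 1
        assert rows[0].values["lag2_missing"] == 1.0
        assert rows[0].values["lag2_remaining_mg"] == 0.0

    def test_time_interval_feature(self):
        times = tuple(24.0 * k - 0.1 for k in range(1, 4))
        p = make_patient(trough_times=times, trough_concs=(8.0, 9.0, 10.0))
        rows = build_lag_features(p, 0.0578)
        assert rows[1].values["time_interval"] == pytest.approx(24.0)

    def test_lag_blocks_reproduce_pk_core(self):
        p = make_patient()
        ke = 0.0578
        row = build_lag_features(p, ke)[0]
        lag1 = p.troughs[0]
        doses = p.doses_until(lag1.time)
        assert row.values["lag1_remaining_mg"] == pytest.approx(
            remaining_drug_amount(doses, lag1.time, ke)
        )
        assert row.values["lag1_empirical_alpha"] == pytest.approx(
            empirical_alpha(lag1, doses, ke)
        )

    def test_sample_count_matches_sequences(self, small_cohort):
        records, _ = small_cohort
        for p in records[:20]:
            assert len(build_sequences(p)) == len(build_lag_features(p, 0.0578))

    def test_matrix_layouts(self):
        p = make_patient()
        rows = build_lag_features(p, 0.0578)
        Xm, names_m = lag_matrix(rows, mechanism=True)
        Xd, names_d = lag_matrix(rows, mechanism=False)
        assert Xm.shape == (1, len(names_m))
        assert "lag1_empirical_alpha" in names_m
        assert "lag1_empirical_alpha" not in names_d
        assert "daily_dose" in names_d
        assert Xd[0, names_d.index("daily_dose")] == pytest.approx(row_daily(p))


def row_daily(p):
    target = p.troughs[1]
    return sum(
        d.amount for d in p.doses if target.time - 24.0 <= d.time < target.time
    )
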