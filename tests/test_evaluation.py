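"""Metric suite, fold construction, cross-validation protocol,
target-attainment stratification and feature importance."""

import math

import numpy as np
import pandas as pd
import pytest

from tacdose.data import build_lag_features
from tacdose.evaluation import (
    compute_metrics,
    crossvalidate,
    gain_importance,
    make_folds,
    permutation_importance,
    predictions_frame,
    target_attainment,
)
from tacdose.gru import PredictionResult
from tacdose.xgb import MechanismXgb, XgbConfig


def _brute_force_metrics(pairs):
    """Independent loop-based recomputation (no numpy vectorization)."""
    n = len(pairs)
    se = sum((p - o) ** 2 for p, o in pairs)
    ae = sum(abs(p - o) for p, o in pairs)
    mean_o = sum(o for _, o in pairs) / n
    sst = sum((o - mean_o) ** 2 for _, o in pairs)
    rel = [(p - o) / o for p, o in pairs]
    return {
        "mse": se / n,
        "mae": ae / n,
        "r2": 1 - se / sst if n > 1 and sst > 0 else None,
        "mpe": 100 * sum(rel) / n,
        "rmsrpe": 100 * math.sqrt(sum(r * r for r in rel) / n),
        "p10": 100 * sum(abs(r) <= 0.10 for r in rel) / n,
        "p20": 100 * sum(abs(r) <= 0.20 for r in rel) / n,
        "p30": 100 * sum(abs(r) <= 0.30 for r in rel) / n,
    }


class TestComputeMetrics:
    def test_perfect_predictions(self):
        m = compute_metrics([(5.0, 5.0), (10.0, 10.0), (8.0, 8.0)])
        assert m.mse == 0 and m.mae == 0 and m.r2 == 1.0
        assert m.mpe == 0 and m.p10 == 100.0

    def test_symmetric_ten_percent_errors(self):
        m = compute_metrics([(11.0, 10.0), (9.0, 10.0)])
        assert m.mpe == pytest.approx(0.0)
        assert m.rmsrpe == pytest.approx(10.0)
        assert m.p10 == pytest.approx(100.0)

    def test_constant_mean_prediction_has_zero_r2(self):
        y = [8.0, 10.0, 12.0]
        m = compute_metrics([(10.0, o) for o in y])
        assert m.r2 == pytest.approx(0.0)

    def test_agrees_with_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(123)
        y = rng.uniform(2.0, 20.0, size=1000)
        yhat = y * (1 + rng.normal(0, 0.2, size=1000))
        pairs = list(zip(yhat, y))
        got = compute_metrics(pairs)
        want = _brute_force_metrics(pairs)
        for key, val in want.items():
            assert getattr(got, key) == pytest.approx(val, rel=1e-10)

    def test_nonpositive_observed_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([(5.0, 0.0)])

    def test_single_pair_r2_missing(self):
        assert compute_metrics([(5.0, 6.0)]).r2 is None


class TestMakeFolds:
    def test_partition_properties(self, small_cohort):
        records, _ = small_cohort
        folds = make_folds(records, k=5, seed=0)
        assert set(folds) == {p.patient_id for p in records}
        sizes = np.bincount(list(folds.values()), minlength=5)
        assert sizes.sum() == len(records)
        assert sizes.max() - sizes.min() <= len(set(
            min(len(p.troughs), 4) for p in records
        ))  # balanced within one per stratification bin

    def test_deterministic_given_seed(self, small_cohort):
        records, _ = small_cohort
        assert make_folds(records, 5, seed=9) == make_folds(records, 5, seed=9)
        assert make_folds(records, 5, seed=9) != make_folds(records, 5, seed=10)

    def test_k_larger_than_cohort_rejected(self, small_cohort):
        records, _ = small_cohort
        with pytest.raises(ValueError):
            make_folds(records[:3], k=5)

    def test_stratification_balances_trough_bins(self, small_cohort):
        records, _ = small_cohort
        folds = make_folds(records, k=5, seed=1)
        by_id = {p.patient_id: p for p in records}
        for b, sel in (
            (2, lambda n: n <= 2), (3, lambda n: n == 3), (4, lambda n: n >= 4)
        ):
            counts = np.zeros(5, int)
            for pid, f in folds.items():
                if sel(len(by_id[pid].troughs)):
                    counts[f] += 1
            if counts.sum():
                assert counts.max() - counts.min() <= 1


class TestCrossvalidate:
    def test_perfect_oracle_model_scores_ideally(self, small_cohort):
        records, _ = small_cohort

        def oracle(train, test):
            out = []
            for p in test:
                for k in range(1, len(p.troughs)):
                    out.append(PredictionResult(
                        p.patient_id, k, p.troughs[k].concentration,
                        p.troughs[k].concentration, model_name="oracle",
                    ))
            return out

        res = crossvalidate(oracle, records, k=5, seed=0)
        assert res["pooled"].mse == 0.0 and res["pooled"].r2 == 1.0
        assert all(m.mse == 0.0 for m in res["per_fold"])

    def test_metrics_recomputable_from_predictions_table(self, small_cohort):
        records, _ = small_cohort

        def noisy(train, test):
            rng = np.random.default_rng(0)
            return [
                PredictionResult(
                    p.patient_id, k,
                    p.troughs[k].concentration * (1 + rng.normal(0, 0.1)),
                    p.troughs[k].concentration,
                )
                for p in test
                for k in range(1, len(p.troughs))
            ]

        res = crossvalidate(noisy, records, k=3, seed=2)
        frame = predictions_frame(res["predictions"], res["fold_assignment"])
        recomputed = _brute_force_metrics(
            list(zip(frame["predicted"], frame["observed"]))
        )
        assert res["pooled"].mse == pytest.approx(recomputed["mse"], rel=1e-10)
        assert res["pooled"].rmsrpe == pytest.approx(recomputed["rmsrpe"], rel=1e-10)

    def test_training_never_sees_test_fold(self, small_cohort):
        records, _ = small_cohort
        seen: list[set] = []

        def spy(train, test):
            seen.append(({p.patient_id for p in train}, {p.patient_id for p in test}))
            return [
                PredictionResult(p.patient_id, 1, 10.0,
                                 p.troughs[1].concentration)
                for p in test
            ]

        crossvalidate(spy, records, k=4, seed=5)
        for train_ids, test_ids in seen:
            assert not (train_ids & test_ids)
        all_test = set().union(*(t for _, t in seen))
        assert all_test == {p.patient_id for p in records}


class TestTargetAttainment:
    def test_all_within_target(self):
        t = pd.DataFrame({
            "observed": [10.0] * 6,
            "category": ["within", "below", "above"] * 2,
            "measurement_index": [2, 2, 2, 3, 3, 3],
        })
        out = target_attainment(t)
        for cat in ("all", "within", "below", "above"):
            assert out[cat]["within_pct"] == 100.0

    def test_boundary_counts_as_within(self):
        t = pd.DataFrame({
            "observed": [8.0, 12.0, 7.999, 12.001],
            "category": ["within"] * 4,
            "measurement_index": [2] * 4,
        })
        out = target_attainment(t)
        assert out["within"]["within_pct"] == pytest.approx(50.0)
        assert out["within"]["below_pct"] == pytest.approx(25.0)
        assert out["within"]["above_pct"] == pytest.approx(25.0)

    def test_percentages_sum_to_100_and_match_brute_force(self):
        rng = np.random.default_rng(4)
        t = pd.DataFrame({
            "observed": rng.uniform(3, 20, 200),
            "category": rng.choice(["within", "below", "above"], 200),
            "measurement_index": rng.integers(2, 7, 200),
        })
        out = target_attainment(t)
        for cat in ("all", "within", "below", "above"):
            s = out[cat]
            assert s["below_pct"] + s["within_pct"] + s["above_pct"] == pytest.approx(100.0)
        # brute force on one stratum
        sub = t[t.category == "within"]["observed"]
        assert out["within"]["within_pct"] == pytest.approx(
            100.0 * ((sub >= 8) & (sub <= 12)).mean()
        )

    def test_empty_stratum_reported_without_division(self):
        t = pd.DataFrame({
            "observed": [10.0], "category": ["within"], "measurement_index": [2],
        })
        out = target_attainment(t)
        assert out["below"]["n"] == 0 and out["below"]["within_pct"] is None


class TestPermutationImportance:
    def test_constant_feature_scores_zero(self):
        X = np.c_[np.ones(50), np.linspace(0, 1, 50)]
        y = 3.0 * X[:, 1]

        def mse(Xp):
            return float(np.mean((3.0 * Xp[:, 1] - y) ** 2))

        imp = permutation_importance(mse, X, ["const", "signal"], seed=0)
        assert imp["const"] == 0.0
        assert imp["signal"] > 0.0

    def test_unused_feature_scores_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 2))
        y = 2.0 * X[:, 0]

        def mse(Xp):
            return float(np.mean((2.0 * Xp[:, 0] - y) ** 2))

        imp = permutation_importance(mse, X, ["used", "unused"], seed=0)
        assert imp["unused"] == pytest.approx(0.0, abs=1e-12)
        assert imp["used"] > 1.0

    def test_planted_dose_signal_outranks_labs(self, small_cohort):
        """Troughs are driven by dose history and alpha; permuting the
        trough/dose sequence features must hurt more than permuting labs."""
        from tacdose.data import SEQUENCE_FEATURE_NAMES, build_sequences, pad_batch
        from tacdose.gru import GruConfig, train_gru

        records, _ = small_cohort
        samples = [s for p in records for s in build_sequences(p)]
        model, _ = train_gru(samples, GruConfig(seed=0, max_epochs=10))
        X, mask, lengths = pad_batch(samples)
        y = np.array([s.target_conc for s in samples])
        import copy

        def mse(Xp):
            mcopy = copy.copy(model)
            hs, _ = model.core.forward(model._normalize(Xp, mask), mask)
            h_last = hs[np.arange(len(samples)), lengths - 1, :]
            alpha, ke, _, _ = model._params_from_h(h_last)
            from tacdose.gru import _dose_tensors
            D, DT = _dose_tensors(samples)
            pred = alpha * np.sum(D * np.exp(-ke[:, None] * DT), axis=1)
            return float(np.mean((pred - y) ** 2))

        imp = permutation_importance(mse, X, SEQUENCE_FEATURE_NAMES, seed=0,
                                     n_repeats=3)
        trough_imp = imp["trough_conc"]
        lab_imp = max(imp[a] for a in ("alt", "ast", "albumin"))
        assert trough_imp > lab_imp


class TestGainImportance:
    def test_shares_sum_to_100(self, small_cohort):
        records, _ = small_cohort
        rows = [r for p in records for r in build_lag_features(p, 0.0578)]
        model = MechanismXgb(XgbConfig(), {"n_estimators": 50, "max_depth": 3}).fit(rows)
        shares = gain_importance(model)
        assert sum(shares.values()) == pytest.approx(100.0, abs=1e-6)
        assert all(v >= 0 for v in shares.values())

    def test_planted_alpha_signal_ranks_first(self, small_cohort):
        """With a mechanism target, the lag-1 empirical alpha is the single
        most informative feature (echoing its dominant gain share)."""
        records, _ = small_cohort
        rows = [r for p in records for r in build_lag_features(p, 0.0578)]
        model = MechanismXgb(XgbConfig(), {"n_estimators": 100, "max_depth": 3}).fit(rows)
        shares = gain_importance(model)
        top = max(shares, key=shares.get)
        assert top == "lag1_empirical_alpha"
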