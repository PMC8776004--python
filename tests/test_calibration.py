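import numpy as np
import pandas as pd
import pytest

import simscreen as ss
from simscreen.calibration import ProbabilityCurve
from simscreen.errors import CalibrationError, SamplingError


def make_table(rows):
    return pd.DataFrame(rows, columns=["compound_id", "target_id"])


class TestBuildPairDataset:
    def test_unique_targets_cannot_yield_positives(self):
        table = make_table([("a", "t1"), ("b", "t2"), ("c", "t3")])
        with pytest.raises(SamplingError):
            ss.build_pair_dataset(table, n_pos=1, n_rand=5, seed=0)

    def test_forced_single_positive_pair(self):
        table = make_table([("a", "t1"), ("b", "t1")])
        ds = ss.build_pair_dataset(table, n_pos=1, n_rand=3, seed=0)
        assert ds.positive_pairs == [("a", "b")]
        assert ds.n_random == 3

    def test_same_seed_reproducible(self):
        table = make_table(
            [(f"c{i}", f"t{i % 5}") for i in range(40)]
        )
        a = ss.build_pair_dataset(table, n_pos=20, n_rand=50, seed=9)
        b = ss.build_pair_dataset(table, n_pos=20, n_rand=50, seed=9)
        assert a.positive_pairs == b.positive_pairs
        assert a.random_pairs == b.random_pairs

    def test_positive_pairs_share_a_target(self):
        table = make_table([(f"c{i}", f"t{i % 7}") for i in range(50)])
        ds = ss.build_pair_dataset(table, n_pos=30, n_rand=10, seed=2)
        by_compound = table.groupby("compound_id")["target_id"].apply(set)
        for a, b in ds.positive_pairs:
            assert by_compound[a] & by_compound[b]

    def test_positive_pairs_distinct(self):
        table = make_table([(f"c{i}", "t0") for i in range(30)])
        ds = ss.build_pair_dataset(table, n_pos=100, n_rand=10, seed=3)
        assert len(set(ds.positive_pairs)) == 100


class TestProbabilityCurve:
    def test_all_positive_bins_estimate_one(self):
        table = make_table([(f"c{i}", "t0") for i in range(30)])
        ds = ss.build_pair_dataset(table, n_pos=50, n_rand=1, seed=1)
        rng = np.random.default_rng(0)
        sims = {}

        def sim(a, b):
            return sims.setdefault((a, b), float(rng.random()))

        # every sampled random pair also shares t0 here, so every occupied
        # bin carries positives; where randoms are absent P must be 1
        curve = ss.probability_curve(ds, sim, isotonic=False)
        occupied_pos_only = (curve.positive_counts > 0) & (curve.random_counts == 0)
        assert np.all(curve.probability[occupied_pos_only] == 1.0)

    def test_identical_distributions_balance_to_half(self):
        # positives and randoms drawn from the same similarity distribution:
        # with the class-balancing weight, P in occupied bins ~ 0.5
        rng = np.random.default_rng(4)
        table = make_table([(f"c{i}", "t0") for i in range(200)])
        ds = ss.build_pair_dataset(table, n_pos=2000, n_rand=8000, seed=4)

        def sim(a, b):
            return float(rng.random())

        curve = ss.probability_curve(ds, sim, isotonic=False)
        probs = curve.probability[curve.occupied]
        assert abs(np.nanmean(probs) - 0.5) < 0.05

    def test_prevalence_correction_scales_weight(self):
        table = make_table([(f"c{i}", "t0") for i in range(30)])
        ds = ss.build_pair_dataset(table, n_pos=10, n_rand=100, seed=0)
        curve = ss.probability_curve(
            ds, lambda a, b: 0.5, prevalence_correction=0.1
        )
        assert curve.weight == pytest.approx(1.0)

    def test_isotonic_pass_is_monotone(self):
        table = make_table([(f"c{i}", "t0") for i in range(100)])
        ds = ss.build_pair_dataset(table, n_pos=500, n_rand=2000, seed=7)
        pos_set = set(map(tuple, ds.positive_pairs))

        def sim(a, b):
            # deterministic per pair: positives high, randoms low
            return self._deterministic_sim(a, b, (a, b) in pos_set)

        curve = ss.probability_curve(ds, sim)
        est = curve.smoothed[curve.occupied]
        assert np.all(np.diff(est) >= -1e-12)

    @staticmethod
    def _deterministic_sim(a, b, high):
        from simscreen.hashing import hash_str

        u = (hash_str(f"{a}|{b}") % 1000) / 1000
        return 0.5 + 0.5 * u if high else 0.5 * u


class TestThresholdAt:
    def _curve(self, edges, pos, rand):
        pos, rand = np.asarray(pos), np.asarray(rand)
        w = rand.sum() / max(pos.sum(), 1)
        total = w * pos + rand
        prob = np.full(len(pos), np.nan)
        occ = (pos + rand) > 0
        prob[occ] = w * pos[occ] / total[occ]
        return ProbabilityCurve(
            bin_edges=np.asarray(edges), positive_counts=pos,
            random_counts=rand, probability=prob, weight=w,
        )

    def test_step_curve_crossing(self):
        # P = 0 below 0.4 and 1 at or above
        curve = self._curve(
            [0.0, 0.2, 0.4, 0.6, 0.8, 1.0],
            pos=[0, 0, 10, 10, 10],
            rand=[10, 10, 0, 0, 0],
        )
        assert ss.threshold_at(curve, 0.5) == pytest.approx(0.4)

    def test_flat_low_curve_has_no_threshold(self):
        curve = self._curve(
            [0.0, 0.5, 1.0], pos=[3, 3], rand=[7, 7]
        )
        # both bins at weighted P != sustained 0.5 crossing when corrected
        curve.probability[:] = 0.3
        with pytest.raises(CalibrationError):
            ss.threshold_at(curve, 0.5)

    def test_dip_after_crossing_moves_threshold_up(self):
        curve = self._curve(
            [0.0, 0.2, 0.4, 0.6, 0.8, 1.0],
            pos=[0, 10, 0, 10, 10],
            rand=[10, 0, 10, 0, 0],
        )
        # crossing at 0.2 is not sustained (dip at [0.4, 0.6))
        assert ss.threshold_at(curve, 0.5) == pytest.approx(0.6)


class TestCombinedLogisticFit:
    def test_null_model_recovers_balanced_intercept(self):
        rng = np.random.default_rng(11)
        n = 20_000
        s1, s2 = rng.random(n), rng.random(n)
        y = (rng.random(n) < 0.1).astype(int)  # labels independent of sims
        fit = ss.fit_combined_logistic(s1, s2, y)
        # class balancing makes the effective prevalence 1:1 -> logit ~ 0
        assert abs(fit.model.coef_fp2) < 3 * fit.std_errors[1]
        assert abs(fit.model.coef_es5d) < 3 * fit.std_errors[2]
        assert abs(fit.model.intercept) < 3 * fit.std_errors[0]

    def test_duplicated_dataset_identical_fit(self):
        rng = np.random.default_rng(12)
        n = 2000
        s1, s2 = rng.random(n), rng.random(n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-1 + 2 * s1)))).astype(int)
        f1 = ss.fit_combined_logistic(s1, s2, y)
        f2 = ss.fit_combined_logistic(
            np.tile(s1, 2), np.tile(s2, 2), np.tile(y, 2)
        )
        assert f1.model.intercept == pytest.approx(f2.model.intercept, abs=1e-4)
        assert f1.model.coef_fp2 == pytest.approx(f2.model.coef_fp2, abs=1e-4)

    def test_perfect_separation_flagged_and_refit(self):
        s1 = np.concatenate([np.zeros(200), np.ones(200)])
        s2 = np.zeros(400)
        y = np.concatenate([np.zeros(200, int), np.ones(200, int)])
        fit = ss.fit_combined_logistic(s1, s2, y)
        assert fit.separation_flagged
        assert np.isfinite(fit.model.coef_fp2)

    def test_single_class_rejected(self):
        with pytest.raises(CalibrationError):
            ss.fit_combined_logistic(
                np.r_[0.1, 0.2], np.r_[0.3, 0.4], np.r_[1, 1]
            )
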