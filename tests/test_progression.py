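"""Rapid-progressor labelling, CV harness, Wilcoxon comparison and PPV tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from glycoprog.progression import (
    ModelConfiguration, ProgressionError, compare_with_without_glycans,
    default_zoo, disparate_subset, label_five_year_crc_death,
    label_rapid_progressors, ppv_at_threshold, run_cv,
)
from glycoprog.synthetic import simulate_progression_cohort


def _records(times, crc_flags, stage=4):
    n = len(times)
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)], "stage": stage,
        "time": times, "event_all": crc_flags, "event_crc": crc_flags,
    })


class TestRapidProgressorLabels:
    def test_tertile_cutoff_type7(self):
        rec = _records([1, 2, 3, 4, 5, 6], [1] * 6)
        lab = label_rapid_progressors(rec, 4)
        assert lab.cutoff_years == pytest.approx(2.6667, abs=1e-3)
        assert lab.labels.sum() == 2
        assert set(rec.loc[lab.labels == 1, "time"]) == {1, 2}

    def test_too_few_crc_deaths_skipped(self):
        rec = _records([1.0, 2.0, 5.0], [1, 1, 0])
        with pytest.raises(ProgressionError, match="2 CRC deaths"):
            label_rapid_progressors(rec, 4)

    def test_censored_patient_never_rapid(self):
        rec = _records([1, 2, 3, 4, 5, 0.5], [1, 1, 1, 1, 1, 0])
        lab = label_rapid_progressors(rec, 4)
        assert lab.labels.iloc[-1] == 0  # short follow-up but no CRC death

    def test_other_stage_patients_excluded(self):
        rec = pd.concat([_records([1, 2, 3, 4], [1] * 4, stage=4),
                         _records([0.1], [1], stage=2)], ignore_index=True)
        lab = label_rapid_progressors(rec, 4)
        assert len(lab.labels) == 4


class TestFiveYearLabels:
    def test_crc_death_within_horizon_positive(self):
        rec = _records([3.0], [1])
        labels, eligible = label_five_year_crc_death(rec)
        assert labels.iloc[0] == 1 and eligible.iloc[0]

    def test_early_censoring_excluded(self):
        rec = _records([4.0], [0])
        labels, eligible = label_five_year_crc_death(rec)
        assert not eligible.iloc[0]

    def test_other_cause_death_is_negative(self):
        rec = _records([2.0], [1])
        rec["event_crc"] = 0  # died of another cause
        labels, eligible = label_five_year_crc_death(rec)
        assert labels.iloc[0] == 0 and eligible.iloc[0]


class TestPPV:
    def test_forced_arithmetic(self):
        assert ppv_at_threshold([0.9, 0.8, 0.2], [1, 0, 0], 0.5) == 0.5

    def test_all_positives_correct(self):
        assert ppv_at_threshold([0.9, 0.8, 0.2], [1, 1, 0], 0.5) == 1.0

    def test_no_predicted_positives_error(self):
        with pytest.raises(ProgressionError):
            ppv_at_threshold([0.9, 0.8], [1, 0], threshold=1.1)


class TestWilcoxonComparison:
    @staticmethod
    def _cv_results(diffs):
        """Fabricate paired CVResult-like inputs from given AUC differences."""
        from glycoprog.progression import CVResult

        res = []
        for i, d in enumerate(diffs):
            cfg = ModelConfiguration(f"m{i}", "l1_logistic")
            base = 0.6
            res.append(CVResult(cfg, "clinical", np.array([base]),
                                pd.DataFrame()))
            res.append(CVResult(cfg, "clinical_glycans", np.array([base + d]),
                                pd.DataFrame()))
        return res

    def test_seven_positive_pairs_exact_p(self):
        comp = compare_with_without_glycans(
            self._cv_results([0.1, 0.09, 0.08, 0.07, 0.06, 0.05, 0.04])
        )
        assert comp.p_w == pytest.approx(2 / 2**7)

    def test_identical_vectors_p_one_with_warning(self):
        comp = compare_with_without_glycans(self._cv_results([0.0] * 5))
        assert comp.p_w == 1.0
        assert comp.warning

    def test_symmetric_pair_p_one(self):
        comp = compare_with_without_glycans(self._cv_results([0.1, -0.1]))
        assert comp.p_w == pytest.approx(1.0)

    def test_exact_p_matches_full_enumeration(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 11))
            d = rng.normal(size=n)
            got = compare_with_without_glycans(self._cv_results(d)).p_w
            # enumerate all sign assignments of |d| ranks
            ranks = stats.rankdata(np.abs(d))
            w_obs = ranks[d > 0].sum()
            total = ranks.sum()
            ws = [sum(r for r, s in zip(ranks, signs) if s)
                  for signs in itertools.product([0, 1], repeat=n)]
            ws = np.array(ws)
            p_lo = np.mean(ws <= w_obs)
            p_hi = np.mean(ws >= w_obs)
            expected = min(1.0, 2 * min(p_lo, p_hi))
            assert got == pytest.approx(expected)

    def test_median_gain_over_same_pairs(self):
        comp = compare_with_without_glycans(self._cv_results([0.2, 0.0, -0.1]))
        assert comp.median_gain == pytest.approx(0.0)

    def test_disparate_subset_one_per_class(self):
        zoo = default_zoo(extended=True)
        sub = disparate_subset(zoo)
        assert len(sub) == 7
        assert sum(c.model_class.startswith("svm") for c in sub) == 1
        assert sub[[c.model_class for c in sub].index("svm_linear")]


class TestCVHarness:
    def test_perfectly_determined_labels_give_auc_one(self, rng):
        n = 200
        x = rng.normal(size=n)
        y = (x > 0).astype(int)
        feats = pd.DataFrame({"clin": rng.normal(size=n), "G01": x})
        cv = run_cv(default_zoo(), feats, y, ["clin"], ["G01"],
                    n_runs=1, n_folds=5, seed=0)
        for r in cv:
            if r.feature_set == "clinical_glycans":
                assert r.merged_auc > 0.97, r.configuration.name

    def test_null_features_give_chance_auc(self, rng):
        n = 600
        feats = pd.DataFrame(rng.normal(size=(n, 6)),
                             columns=["clin"] + [f"G{j}" for j in range(5)])
        y = (rng.uniform(size=n) < 0.3).astype(int)
        cv = run_cv(default_zoo(), feats, y, ["clin"],
                    [c for c in feats.columns if c.startswith("G")],
                    n_runs=1, n_folds=10, seed=1)
        for r in cv:
            assert 0.4 < r.merged_auc < 0.6, r.configuration.name

    def test_identical_seed_bitwise_identical(self):
        feats, rec = simulate_progression_cohort(n=80, seed=3)
        lab = label_rapid_progressors(rec, 4)
        zoo = default_zoo()[:2]
        kw = dict(n_runs=2, n_folds=5, seed=5)
        cv1 = run_cv(zoo, feats, lab.labels.to_numpy(), ["age"], ["G01"], **kw)
        cv2 = run_cv(zoo, feats, lab.labels.to_numpy(), ["age"], ["G01"], **kw)
        for a, b in zip(cv1, cv2):
            np.testing.assert_array_equal(a.run_aucs, b.run_aucs)
            pd.testing.assert_frame_equal(a.predictions, b.predictions)

    def test_single_class_rejected(self):
        feats = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(ProgressionError):
            run_cv(default_zoo()[:1], feats, [1, 1, 1], ["a"], [], seed=0)

    def test_leakage_guard_label_shuffle_kills_auc(self, rng):
        # with strong signal the merged AUC is high, but scoring the same
        # predictions against shuffled labels must fall back to chance
        feats, rec = simulate_progression_cohort(n=150, glycan_signal=1.5,
                                                 seed=9)
        lab = label_rapid_progressors(rec, 4)
        y = lab.labels.to_numpy()
        cv = run_cv(default_zoo()[:3], feats, y, ["age", "crp_gt10"],
                    [c for c in feats.columns if c.startswith("G")],
                    n_runs=1, n_folds=10, seed=2)
        shuffled = rng.permutation(y)
        for r in cv:
            if r.feature_set != "clinical_glycans":
                continue
            assert r.merged_auc > 0.65
            scores = r.predictions["score"].to_numpy()
            assert abs(roc_auc_score(shuffled, scores) - 0.5) < 0.12
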