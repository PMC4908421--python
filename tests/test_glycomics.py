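"""Glycomics unit tests: normalization, derived traits, robustness, transforms."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtri

from glycoprog.glycomics import (
    PEAKS, GlycomicsError, TraitMatrix, derive_traits, filter_robust,
    normalize_total_area, qc_trait_matrix, rank_normal_transform, robustness,
)

from conftest import make_peak_row, peak_frame


class TestNormalization:
    def test_already_percent_scale_is_unchanged(self):
        df = peak_frame([make_peak_row({"GP1": 25.0, "GP2": 25.0, "GP3": 50.0})])
        out = normalize_total_area(df)
        assert out.iloc[0][["GP1", "GP2", "GP3"]].tolist() == [25.0, 25.0, 50.0]

    def test_rescales_to_percent(self):
        df = peak_frame([make_peak_row({"GP1": 2.0, "GP2": 3.0, "GP3": 5.0})])
        out = normalize_total_area(df)
        assert out.iloc[0][["GP1", "GP2", "GP3"]].tolist() == [20.0, 30.0, 50.0]

    def test_zero_sum_row_excluded_with_warning(self, caplog):
        df = peak_frame([make_peak_row({}, sample_id="BAD"),
                         make_peak_row({"GP1": 1.0}, sample_id="OK")])
        with caplog.at_level("WARNING"):
            out = normalize_total_area(df)
        assert list(out["sample_id"]) == ["OK"]
        assert "BAD" in caplog.text

    def test_idempotence_and_scale_invariance(self, rng):
        areas = rng.uniform(0.1, 50.0, size=(20, 24))
        rows = [make_peak_row(dict(zip(PEAKS, a)), sample_id=f"S{i}")
                for i, a in enumerate(areas)]
        df = peak_frame(rows)
        once = normalize_total_area(df)
        twice = normalize_total_area(once)
        np.testing.assert_allclose(once[list(PEAKS)], twice[list(PEAKS)],
                                   rtol=1e-12)
        scaled = df.copy()
        scaled[list(PEAKS)] = scaled[list(PEAKS)].to_numpy() * rng.uniform(
            0.5, 20.0, size=(20, 1)
        )
        np.testing.assert_allclose(
            normalize_total_area(scaled)[list(PEAKS)], once[list(PEAKS)],
            rtol=1e-12,
        )

    def test_negative_area_rejected(self):
        df = peak_frame([make_peak_row({"GP1": -1.0, "GP2": 2.0})])
        with pytest.raises(GlycomicsError):
            normalize_total_area(df)


class TestDerivedTraits:
    def test_four_peak_oracle(self, trait_defs):
        # FA2 (F,G0), FA2G1 (F,G1), FA2G2 (F,G2), FA2G2S1 (F,G2,S1)
        df = peak_frame([make_peak_row(
            {"GP4": 40.0, "GP8": 30.0, "GP14": 20.0, "GP18": 10.0})])
        out = derive_traits(normalize_total_area(df), trait_defs).iloc[0]
        assert out["G0n"] == pytest.approx(100 * 40 / 90)
        assert out["G1n"] == pytest.approx(100 * 30 / 90)
        assert out["G2n"] == pytest.approx(100 * 20 / 90)
        assert out["FGS/(F+FG+FGS)"] == pytest.approx(10.0)
        assert out["FGS/(FG+FGS)"] == pytest.approx(100 * 10 / 60)
        assert out["Fn"] == pytest.approx(100.0)
        assert out["GP4n"] == pytest.approx(100 * 40 / 90)
        assert out["GP4"] == pytest.approx(40.0)

    def test_galactosylation_partitions_neutral_fraction(self, small_cohort,
                                                         trait_defs):
        traits = derive_traits(normalize_total_area(small_cohort.peak_table),
                               trait_defs)
        total = traits["G0n"] + traits["G1n"] + traits["G2n"]
        np.testing.assert_allclose(total, 100.0, atol=1e-9)

    def test_bisected_sialylated_ratio_identity(self, small_cohort, trait_defs):
        # FBS1/(FS1+FBS1) == r/(1+r) with r = FBS1/FS1
        traits = derive_traits(normalize_total_area(small_cohort.peak_table),
                               trait_defs)
        r = traits["FBS1/FS1"]
        np.testing.assert_allclose(traits["FBS1/(FS1+FBS1)"], r / (1 + r),
                                   rtol=1e-10)

    def test_percentage_traits_bounded(self, small_cohort, trait_defs):
        traits = derive_traits(normalize_total_area(small_cohort.peak_table),
                               trait_defs)
        for d in trait_defs:
            if d.scale == 100.0:
                assert traits[d.name].between(-1e-9, 100 + 1e-9).all(), d.name

    def test_zero_denominator_marked_missing(self, trait_defs):
        df = peak_frame([make_peak_row({"GP4": 50.0, "GP8": 50.0})])  # no S peaks
        out = derive_traits(normalize_total_area(df), trait_defs)
        assert np.isnan(out.iloc[0]["FBS1/FS1"])

    def test_scale_invariance_of_traits(self, trait_defs, rng):
        areas = rng.uniform(0.5, 30.0, size=24)
        df1 = peak_frame([make_peak_row(dict(zip(PEAKS, areas)))])
        df2 = peak_frame([make_peak_row(dict(zip(PEAKS, 7.3 * areas)))])
        t1 = derive_traits(normalize_total_area(df1), trait_defs)
        t2 = derive_traits(normalize_total_area(df2), trait_defs)
        np.testing.assert_allclose(
            t1.drop(columns=["sample_id", "plate_id", "is_standard"]),
            t2.drop(columns=["sample_id", "plate_id", "is_standard"]),
            rtol=1e-12,
        )


class TestRobustness:
    @staticmethod
    def _frames(std_values, cohort_values):
        return (pd.DataFrame({"t": std_values}),
                pd.DataFrame({"t": cohort_values}))

    def test_variance_ratio_formula(self):
        # Var(stand)=1, Var(cohort)=20 -> 5%
        s = np.array([-1.0, 1.0, -1.0, 1.0]) * np.sqrt(3.0 / 4.0)
        assert np.var(s, ddof=1) == pytest.approx(1.0)
        c = s * np.sqrt(20.0)
        std, coh = self._frames(s, c)
        assert robustness(std, coh)["t"] == pytest.approx(5.0)

    def test_identical_variance_gives_100(self, rng):
        v = rng.normal(size=50)
        std, coh = self._frames(v, v.copy())
        assert robustness(std, coh)["t"] == pytest.approx(100.0)

    def test_shift_invariance(self, rng):
        s, c = rng.normal(size=20), rng.normal(size=200) * 3
        r1 = robustness(*self._frames(s, c))["t"]
        r2 = robustness(*self._frames(s + 5.0, c + 5.0))["t"]
        assert r1 == pytest.approx(r2)

    def test_zero_cohort_variance_undefined(self):
        std, coh = self._frames([0.0, 1.0], [2.0, 2.0, 2.0])
        assert np.isnan(robustness(std, coh)["t"])

    def test_boundary_strictness_on_planted_ratio(self, rng):
        # planted variance ratios 0.199 and 0.201 under threshold 20%
        base = rng.normal(size=500)
        base = (base - base.mean()) / base.std(ddof=1)
        std = rng.normal(size=40)
        std = (std - std.mean()) / std.std(ddof=1)
        values = pd.DataFrame({"in_": base, "out_": base})
        stands = pd.DataFrame({"in_": std * np.sqrt(0.199),
                               "out_": std * np.sqrt(0.201)})
        rob = robustness(stands, values)
        matrix = filter_robust(TraitMatrix(values, rob))
        assert matrix.retained["in_"] and not matrix.retained["out_"]


class TestFilter:
    @staticmethod
    def _matrix(rob: dict) -> TraitMatrix:
        values = pd.DataFrame({k: [0.0, 1.0] for k in rob})
        return TraitMatrix(values, pd.Series(rob))

    def test_strict_threshold(self):
        m = filter_robust(self._matrix({"a": 5, "b": 19.99, "c": 20, "d": 25}))
        assert m.retained_names == ["a", "b"]

    def test_threshold_100_retains_all_finite(self):
        m = filter_robust(self._matrix({"a": 5, "b": 99.9}), threshold=100)
        assert m.retained_names == ["a", "b"]

    def test_empty_matrix(self):
        m = filter_robust(TraitMatrix(pd.DataFrame(), pd.Series(dtype=float)))
        assert m.retained_names == []


class TestRankNormal:
    def test_blom_oracle(self):
        out = rank_normal_transform([3.0, 1.0, 2.0])
        expected = ndtri((np.array([3, 1, 2]) - 0.375) / 3.25)
        np.testing.assert_allclose(out, expected)
        assert out[0] == pytest.approx(0.86942, abs=1e-4)
        assert out[2] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_input_keeps_order_and_sign(self):
        out = rank_normal_transform([-1.0, 0.0, 1.0])
        assert out[0] < out[1] < out[2]
        assert out[1] == pytest.approx(0.0, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=40)
        np.testing.assert_allclose(rank_normal_transform(x),
                                   rank_normal_transform(np.exp(x)))

    def test_ties_get_average_ranks(self):
        out = rank_normal_transform([1.0, 1.0, 2.0])
        assert out[0] == out[1] < out[2]

    def test_constant_trait_rejected(self):
        with pytest.raises(GlycomicsError):
            rank_normal_transform([2.0, 2.0, 2.0])

    def test_missing_values_stay_missing(self):
        out = rank_normal_transform([1.0, np.nan, 2.0])
        assert np.isnan(out[1]) and np.isfinite(out[0])


def test_qc_pipeline_counts(small_cohort):
    matrix = qc_trait_matrix(small_cohort.peak_table)
    assert len(matrix.trait_names) == 61
    assert 0 < len(matrix.retained_names) < 61
    # standards never appear among cohort rows
    assert not matrix.values["is_standard"].astype(bool).any()
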