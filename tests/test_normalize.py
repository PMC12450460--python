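"""Normalization pipeline and the Wilcoxon rank-sum test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import blotquant as bq
from blotquant.normalize import apply_background
from blotquant.plate_io import PlateMap, PlateMapEntry
from oracles import enumerate_rank_sum_p


def _map_entries(spec):
    """spec: list of (well, sample, role, bca)."""
    return PlateMap(
        [PlateMapEntry(w, s, f"{s}_{w}", role, bca) for w, s, role, bca in spec]
    )


def _measurements(medians):
    rows = [
        {"well": w, "median": m, "mean": m, "sd": 0.0, "mode": m, "min": m,
         "max": m, "n_pixels": 10}
        for w, m in medians.items()
    ]
    return pd.DataFrame(rows)


class TestNormalizeBca:
    def test_division(self):
        assert bq.normalize_bca(100.0, 2.0) == 50.0
        assert bq.normalize_bca(3.7, 1.0) == 3.7

    def test_non_positive_bca_rejected(self):
        with pytest.raises(ValueError):
            bq.normalize_bca(1.0, 0.0)

    def test_homogeneity_in_bca(self, rng):
        medians = rng.uniform(1, 100, 20)
        bcas = rng.uniform(0.5, 2.0, 20)
        base = [bq.normalize_bca(m, b) for m, b in zip(medians, bcas)]
        scaled = [bq.normalize_bca(m, 4.0 * b) for m, b in zip(medians, bcas)]
        np.testing.assert_allclose(scaled, np.array(base) / 4.0, rtol=1e-12)


class TestControlBackground:
    def _records(self, buffer_vals, untagged_vals):
        recs = []
        for i, v in enumerate(buffer_vals):
            r = bq.SampleRecord(f"buf{i}", [f"A{i+1}"], "buffer_only", None)
            r.normalized = [v]
            recs.append(r)
        for i, v in enumerate(untagged_vals):
            r = bq.SampleRecord(f"wt{i}", [f"B{i+1}"], "untagged", None)
            r.normalized = [v]
            recs.append(r)
        return recs

    def test_mean_of_two(self):
        assert bq.control_background(self._records([2.0], [4.0])) == 3.0

    def test_all_zero_controls(self):
        recs = self._records([0.0, 0.0], [0.0])
        assert bq.control_background(recs) == 0.0
        assert bq.subtract_background([5.0, 7.0], 0.0) == [5.0, 7.0]

    def test_pooled_per_well_weighting(self):
        # buffer {1,1} + untagged {3} pooled per-well -> 5/3
        assert bq.control_background(self._records([1.0, 1.0], [3.0])) == pytest.approx(5 / 3)

    def test_missing_control_role_rejected(self):
        with pytest.raises(ValueError, match="untagged"):
            bq.control_background(self._records([1.0], []))


class TestSubtractAggregate:
    def test_subtract_retains_negatives(self):
        assert bq.subtract_background([5.0, 7.0], 3.0) == [2.0, 4.0]
        assert bq.subtract_background([1.0], 3.0) == [-2.0]

    def test_subtract_then_add_restores(self, rng):
        values = list(rng.uniform(-5, 50, 9))
        out = bq.subtract_background(values, 3.25)
        assert [v + 3.25 for v in out] == pytest.approx(values, abs=1e-12)

    def test_aggregate_hand_values(self):
        mean, sd, sem = bq.aggregate([2.0, 4.0, 6.0])
        assert mean == 4.0
        assert sd == pytest.approx(2.0)
        assert sem == pytest.approx(2.0 / np.sqrt(3))

    def test_single_replicate_sd_undefined(self):
        mean, sd, sem = bq.aggregate([5.0])
        assert mean == 5.0
        assert np.isnan(sd) and np.isnan(sem)

    def test_identical_replicates_sd_zero(self):
        assert bq.aggregate([3.3, 3.3, 3.3])[1] == pytest.approx(0.0, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bq.aggregate([])


class TestRankSamples:
    def _records(self, intensities):
        recs = []
        for sid, vals in intensities.items():
            r = bq.SampleRecord(sid, [], "sample", 1.0)
            r.background_subtracted = list(vals)
            recs.append(r)
        return recs

    def test_ascending_order(self):
        table = bq.rank_samples(self._records({"B": [3.0], "A": [1.0], "C": [2.0]}))
        assert list(table["sample"]) == ["A", "C", "B"]
        assert list(table["rank"]) == [1, 2, 3]

    def test_tie_broken_lexicographically(self):
        table = bq.rank_samples(self._records({"Z": [2.0], "M": [2.0], "A": [5.0]}))
        assert list(table["sample"]) == ["M", "Z", "A"]

    def test_invariant_under_input_permutation(self, rng):
        intensities = {f"S{i}": [float(v)] for i, v in enumerate(rng.uniform(0, 10, 12))}
        recs = self._records(intensities)
        base = bq.rank_samples(recs)
        for _ in range(5):
            shuffled = list(recs)
            rng.shuffle(shuffled)
            pd.testing.assert_frame_equal(bq.rank_samples(shuffled), base)


class TestPlatePipeline:
    def _small_plate(self):
        pm = _map_entries(
            [
                ("A1", "S1", "sample", 2.0),
                ("A2", "S1", "sample", 2.0),
                ("B1", "S2", "sample", 1.0),
                ("B2", "S2", "sample", 1.0),
                ("H1", "buffer", "buffer_only", None),
                ("H2", "wt", "untagged", None),
            ]
        )
        meas = _measurements(
            {"A1": 40.0, "A2": 44.0, "B1": 9.0, "B2": 11.0, "H1": 1.5, "H2": 4.5}
        )
        return pm, meas

    def test_hand_computed_integrated_intensities(self):
        pm, meas = self._small_plate()
        table = bq.process_plate(pm, meas)
        # plate-median BCA = 1.5; controls normalized {1, 3} -> background 2
        # S1 normalized {20, 22} -> subtracted {18, 20} -> integrated 19
        # S2 normalized {9, 11} -> subtracted {7, 9} -> integrated 8
        s1 = table.set_index("sample").loc["S1"]
        s2 = table.set_index("sample").loc["S2"]
        assert s1["integrated_intensity"] == pytest.approx(19.0)
        assert s2["integrated_intensity"] == pytest.approx(8.0)
        assert list(table["sample"]) == ["S2", "S1"]

    def test_homogeneity_in_gain(self):
        pm, meas = self._small_plate()
        base = bq.process_plate(pm, meas)
        scaled_meas = meas.copy()
        scaled_meas["median"] = scaled_meas["median"] * 7.0
        scaled = bq.process_plate(pm, scaled_meas)
        assert list(scaled["sample"]) == list(base["sample"])
        np.testing.assert_allclose(
            scaled["integrated_intensity"], 7.0 * base["integrated_intensity"], rtol=1e-12
        )

    def test_pairwise_tests_table(self):
        pm, meas = self._small_plate()
        records = bq.build_sample_records(pm, meas)
        apply_background(records, bq.control_background(records))
        tests = bq.pairwise_tests(records)
        assert list(tests.columns) == ["sample_a", "sample_b", "U", "p"]
        assert len(tests) == 1  # one pair
        assert 0.0 < tests["p"].iloc[0] <= 1.0


class TestWilcoxonRankSum:
    def test_separated_samples_one_sided(self):
        u, p = bq.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], alternative="less")
        assert u == 0.0
        assert p == pytest.approx(1 / 20)  # 1 of C(6,3)=20 rank splits

    def test_identical_samples_two_sided(self):
        u, p = bq.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            bq.wilcoxon_rank_sum([], [1.0])

    @pytest.mark.parametrize("n,m", [(n, m) for n in range(1, 6) for m in range(1, 6)])
    def test_exact_path_equals_enumeration(self, rng, n, m):
        values = rng.permutation(np.arange(1.0, n + m + 1.0))
        x, y = list(values[:n]), list(values[n:])
        for alternative in ("two-sided", "less", "greater"):
            _, p = bq.wilcoxon_rank_sum(x, y, alternative)
            assert p == pytest.approx(enumerate_rank_sum_p(x, y, alternative), abs=1e-12)

    def test_exact_path_matches_scipy_exact(self, rng):
        # independent cross-check against scipy's exact method
        for _ in range(20):
            values = rng.permutation(np.arange(1.0, 11.0))
            x, y = values[:4], values[4:]
            u, p = bq.wilcoxon_rank_sum(list(x), list(y))
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert u == res.statistic
            assert p == pytest.approx(res.pvalue, abs=1e-12)

    def test_approximation_close_to_exact_at_n12(self, rng):
        # tie-free n = m = 12: normal approximation within 0.01 of exact
        values = rng.permutation(np.arange(1.0, 25.0))
        x, y = list(values[:12]), list(values[12:])
        _, p_approx = bq.wilcoxon_rank_sum(x, y)  # n+m=24 -> approximate path
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert abs(p_approx - res.pvalue) < 0.01

    def test_tie_correction_matches_scipy(self, rng):
        x = [1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 7.0]
        y = [2.0, 4.0, 5.0, 5.0, 6.0, 8.0, 8.0]
        u, p = bq.wilcoxon_rank_sum(x, y)
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert u == res.statistic
        assert p == pytest.approx(res.pvalue, rel=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        n=st.integers(1, 5),
        m=st.integers(1, 5),
        seed=st.integers(0, 2**31 - 1),
        alternative=st.sampled_from(["two-sided", "less", "greater"]),
    )
    def test_exact_enumeration_property(self, n, m, seed, alternative):
        rng = np.random.default_rng(seed)
        values = rng.permutation(np.arange(1.0, n + m + 1.0))
        x, y = list(values[:n]), list(values[n:])
        _, p = bq.wilcoxon_rank_sum(x, y, alternative)
        assert p == pytest.approx(enumerate_rank_sum_p(x, y, alternative), abs=1e-12)
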