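"""Recombination fractions, Kosambi maps, Marey rates, PCoA."""

import numpy as np
import pandas as pd
import pytest

from tetrameio import mapping
from tetrameio import synthdata as sd
from conftest import simple_windows, truth_matrix


class TestPairwiseRf:
    def test_identical_columns_zero(self):
        m = pd.DataFrame({"a": [1.0] * 30, "b": [1.0] * 30})
        assert mapping.pairwise_rf(m, "a", "b") == 0.0

    def test_single_change_among_fifty(self):
        a = np.ones(50)
        b = np.ones(50)
        b[7] = 0.0
        m = pd.DataFrame({"a": a, "b": b})
        assert mapping.pairwise_rf(m, "a", "b") == pytest.approx(0.01)

    def test_insufficient_overlap_missing(self):
        m = pd.DataFrame({"a": [1.0] * 10, "b": [0.0] * 10})
        assert np.isnan(mapping.pairwise_rf(m, "a", "b", min_overlap=20))

    def test_unlinked_windows_reach_saturation(self):
        # analytic saturation of the dose-difference estimator for
        # independent duplex doses at tau = 1: E|di - dj| / 2 = 5/18
        genome = sd.default_genome(2, 2_000_000, 1.0)
        mat, _ = truth_matrix(genome, 1.0, 2000, seed=41, per_chrom=1)
        r = mapping.pairwise_rf(mat, mat.columns[0], mat.columns[1])
        assert r == pytest.approx(5 / 18, abs=0.02)

    def test_matrix_agrees_with_pairwise(self):
        rng = np.random.default_rng(42)
        m = pd.DataFrame(rng.choice([0, 1, 2], size=(40, 5)).astype(float),
                         columns=list("abcde"))
        m.iloc[rng.random((40, 5)) < 0.1] = np.nan
        full = mapping.rf_matrix(m, min_overlap=5)
        for i in "abc":
            for j in "de":
                expect = mapping.pairwise_rf(m, i, j, min_overlap=5)
                assert full.loc[i, j] == pytest.approx(expect, nan_ok=True)


class TestLinkageGroups:
    def test_two_chromosomes_two_groups(self):
        genome = sd.default_genome(2, 5_000_000, 1.0)
        mat, _ = truth_matrix(genome, 1.0, 300, seed=43)
        lg = mapping.linkage_groups(mapping.rf_matrix(mat))
        assert lg.nunique() == 2
        chroms = pd.Series([c.split("_")[1] for c in lg.index], index=lg.index)
        assert (lg.groupby(chroms).nunique() == 1).all()

    def test_zero_threshold_isolates_every_window(self):
        genome = sd.default_genome(1, 5_000_000, 1.0)
        mat, _ = truth_matrix(genome, 1.0, 100, seed=44)
        lg = mapping.linkage_groups(mapping.rf_matrix(mat), threshold=0.0)
        assert lg.nunique() == len(lg)


class TestKosambi:
    def test_zero_r_zero_distance(self):
        assert mapping.kosambi_cm(0.0) == 0.0

    @pytest.mark.parametrize("r,cm", [(0.1, 10.137), (0.25, 27.465)])
    def test_closed_form_values(self, r, cm):
        assert mapping.kosambi_cm(r) == pytest.approx(cm, abs=0.01)

    def test_strictly_increasing_and_above_r(self):
        rs = np.linspace(0.0, 0.49, 50)
        cms = np.array([mapping.kosambi_cm(r) for r in rs])
        assert np.all(np.diff(cms) > 0)
        assert np.all(cms >= 100 * rs - 1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mapping.kosambi_cm(0.5)


class TestBuildMap:
    def test_no_recombination_zero_length(self):
        m = pd.DataFrame(np.ones((30, 4)),
                         columns=[f"w_C1_{i:02d}" for i in range(4)])
        w = simple_windows(list(m.columns))
        gmap = mapping.build_map(m, w)
        assert gmap["cm"].max() == 0.0

    def test_uniform_intervals_closed_form(self):
        # 10 intervals of r = 0.01 -> 10 * 25 ln(1.02/0.98)
        n = 100
        cols = [f"w_C1_{i:02d}" for i in range(11)]
        vals = np.ones((n, 11))
        for j in range(1, 11):
            # two gametes switch 1 -> 0 at column j: sum |delta| = 2,
            # so each adjacent interval has r = 2 / (2n) = 0.01
            vals[2 * (j - 1), j:] = 0.0
            vals[2 * (j - 1) + 1, j:] = 0.0
        m = pd.DataFrame(vals, columns=cols)
        w = simple_windows(cols)
        gmap = mapping.build_map(m, w)
        r = 1.0 / n
        expected = 10 * mapping.kosambi_cm(r)
        assert gmap["cm"].max() == pytest.approx(expected, rel=1e-6)

    def test_disomic_cohort_maps_to_zero(self):
        genome = sd.default_genome(1, 5_000_000, 1.0)
        mat, windows = truth_matrix(genome, 0.0, 100, seed=45)
        gmap = mapping.build_map(mat, windows)
        assert gmap["cm"].max() == 0.0

    def test_missing_interval_warns_and_skips(self):
        cols = [f"w_C1_{i:02d}" for i in range(3)]
        m = pd.DataFrame(np.ones((30, 3)), columns=cols)
        m.iloc[:, 1] = np.nan
        w = simple_windows(cols)
        with pytest.warns(UserWarning, match="missing rf"):
            gmap = mapping.build_map(m, w)
        assert gmap["cm"].max() == 0.0

    def test_summary_totals(self):
        genome = sd.default_genome(2, 5_000_000, 1.0)
        mat, windows = truth_matrix(genome, 1.0, 200, seed=46)
        gmap = mapping.build_map(mat, windows)
        summ = mapping.map_summary(gmap)
        assert summ.loc["total", "n_markers"] == len(gmap)
        assert summ.loc["total", "length_cm"] == pytest.approx(
            summ.drop("total")["length_cm"].sum())


class TestMareyRate:
    def _linear_map(self, rate_cm_per_mb=2.0, n=30):
        bp = np.linspace(0, 20e6, n)
        return pd.DataFrame({"chrom": "C1",
                             "window_id": [f"w{i}" for i in range(n)],
                             "bp": bp, "cm": rate_cm_per_mb * bp / 1e6})

    def test_linear_map_constant_rate(self):
        prof = mapping.marey_rate(self._linear_map(2.0))
        assert np.allclose(prof["rate_cm_per_mb"], 2.0, atol=1e-6)

    def test_plateau_rate_zero(self):
        gmap = self._linear_map(2.0)
        mid = (gmap["bp"] > 6e6) & (gmap["bp"] < 14e6)
        gmap.loc[mid, "cm"] = gmap.loc[mid, "cm"].iloc[0]
        gmap["cm"] = np.maximum.accumulate(gmap["cm"])
        prof = mapping.marey_rate(gmap)
        inner = prof[(prof["bp"] > 8e6) & (prof["bp"] < 12e6)]
        assert (inner["rate_cm_per_mb"] < 0.2).all()

    def test_centromeric_suppression_minimum_at_centromere(self):
        # crossovers suppressed around the centromere leave a rate dip
        genome = sd.default_genome(1, 20_000_000, 1.0)
        mat, windows = truth_matrix(genome, 1.0, 400, seed=47, per_chrom=14)
        cen = genome.centromeres["C1"]
        # thin out apparent recombination near the centromere by copying
        # the nearest flanking calls (emulating a cold region)
        cols = list(mat.columns)
        pos = windows.set_index("window_id")["rep_pos"]
        cold = [c for c in cols if abs(pos[c] - cen) < 3e6]
        anchor = min(cols, key=lambda c: abs(pos[c] - (cen - 3.5e6)))
        for c in cold:
            mat[c] = mat[anchor]
        gmap = mapping.build_map(mat, windows)
        prof = mapping.marey_rate(gmap)
        near = prof[(prof["bp"] - cen).abs() < 2.5e6]["rate_cm_per_mb"]
        far = prof[(prof["bp"] - cen).abs() > 5e6]["rate_cm_per_mb"]
        assert near.mean() < far.mean()

    def test_too_few_markers_rejected(self):
        with pytest.raises(ValueError, match="markers"):
            mapping.marey_rate(self._linear_map(n=5))

    def test_degenerate_positions_rejected(self):
        gmap = self._linear_map(n=12)
        gmap["bp"] = 5.0
        with pytest.raises(ValueError, match="degenerate"):
            mapping.marey_rate(gmap)


class TestManhattan:
    def test_identical_rows_zero(self):
        assert mapping.manhattan_dissimilarity([1, 2, 0], [1, 2, 0]) == 0.0

    def test_hand_value(self):
        assert mapping.manhattan_dissimilarity([0, 1], [2, 1]) == 1.0

    def test_symmetric(self):
        rng = np.random.default_rng(48)
        a, b = rng.choice([0, 1, 2], 20), rng.choice([0, 1, 2], 20)
        assert mapping.manhattan_dissimilarity(a, b) == \
            mapping.manhattan_dissimilarity(b, a)

    def test_no_shared_loci_missing(self):
        assert np.isnan(
            mapping.manhattan_dissimilarity([np.nan, 1], [2, np.nan]))


class TestFactorialCoordinates:
    def test_collinear_points_one_axis(self):
        x = np.arange(6, dtype=float)
        m = pd.DataFrame({"w1": x, "w2": x})
        d = mapping.dissimilarity_matrix(m)
        coords, pct = mapping.factorial_coordinates(d)
        assert pct.iloc[0] > 99.0

    def test_planted_clusters_separated_on_axis_one(self):
        rng = np.random.default_rng(49)
        a = rng.choice([0, 1], size=(20, 30), p=[0.9, 0.1])
        b = rng.choice([1, 2], size=(20, 30), p=[0.1, 0.9])
        m = pd.DataFrame(np.vstack([a, b]).astype(float))
        m.columns = [f"w{i}" for i in range(30)]
        d = mapping.dissimilarity_matrix(m)
        coords, _ = mapping.factorial_coordinates(d)
        ax1 = coords["axis1"].to_numpy()
        assert (ax1[:20].mean() < ax1[20:].mean()) != \
            (ax1[:20].mean() > ax1[20:].mean())
        lo, hi = sorted([ax1[:20].mean(), ax1[20:].mean()])
        assert hi - lo > 3 * (ax1[:20].std() + ax1[20:].std()) / 2

    def test_asymmetric_rejected(self):
        d = pd.DataFrame([[0, 1], [2, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            mapping.factorial_coordinates(d)


class TestMapPpRelation:
    def test_map_length_decreases_with_pp(self):
        genome = sd.default_genome(2, 5_000_000, 1.0)
        lengths = []
        for pp in (0.0, 0.5, 1.0):
            mat, windows = truth_matrix(genome, 1.0 - pp, 300, seed=50)
            gmap = mapping.build_map(mat, windows)
            lengths.append(mapping.map_summary(gmap).loc["total", "length_cm"])
        assert lengths[0] > lengths[1] > lengths[2] == 0.0
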