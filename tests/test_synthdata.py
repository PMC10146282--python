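"""Generator correctness: parent structures, meiosis model, hybrids,
read counts, phenotypes."""

import numpy as np
import pandas as pd
import pytest

from tetrameio import synthdata as sd


@pytest.fixture(scope="module")
def genome():
    return sd.default_genome(n_chromosomes=2, chrom_length=1_000_000,
                             map_length=1.0)


@pytest.fixture(scope="module")
def parents(genome):
    return sd.build_parent_karyotypes(genome)


class TestParentKaryotypes:
    def test_volkamer_is_reticulata_medica_everywhere(self, genome, parents):
        volk, _ = parents
        pos = np.linspace(1, 999_999, 50)
        for chrom in genome.names:
            assert np.all(volk.ancestor_dose(chrom, pos, sd.RETICULATA) == 2)
            assert np.all(volk.ancestor_dose(chrom, pos, sd.MEDICA) == 2)

    def test_citrumelo_trifoliata_dose_two_everywhere(self, genome, parents):
        _, citru = parents
        pos = np.linspace(1, 999_999, 50)
        for chrom in genome.names:
            assert np.all(citru.ancestor_dose(chrom, pos, sd.TRIFOLIATA) == 2)

    def test_citrumelo_mosaic_alternates(self, genome, parents):
        _, citru = parents
        # default: one breakpoint at mid-chromosome
        before = citru.ancestor_dose("C1", np.array([100.0]), sd.RETICULATA)
        after = citru.ancestor_dose("C1", np.array([999_000.0]), sd.RETICULATA)
        assert {int(before[0]), int(after[0])} == {0, 2}

    def test_zero_breakpoints_single_ancestor(self, genome):
        _, citru = sd.build_parent_karyotypes(
            genome, citrumelo_breakpoints={c: [] for c in genome.names})
        pos = np.linspace(1, 999_999, 20)
        for chrom in genome.names:
            doses = citru.ancestor_dose(chrom, pos, sd.RETICULATA)
            assert len(np.unique(doses)) == 1

    def test_breakpoint_outside_chromosome_raises(self, genome):
        with pytest.raises(ValueError, match="breakpoint"):
            sd.build_parent_karyotypes(genome,
                                       citrumelo_breakpoints={"C1": [2e6]})

    def test_unknown_ancestor_label_raises(self):
        with pytest.raises(ValueError, match="unknown ancestor"):
            sd.ParentKaryotype("bad", {"C1": ([(100.0, "martian")],
                                              [(100.0, sd.MEDICA)])})


class TestMeiosis:
    def test_tau_zero_all_gametes_heterozygous(self, genome, parents):
        # identical homologs pair; crossovers are invisible
        volk, _ = parents
        gams = sd.simulate_meiosis(volk, genome, sd.MeiosisParams(0.0), 40,
                                   np.random.default_rng(0))
        pos = np.linspace(1, 999_999, 25)
        for g in gams:
            for chrom in genome.names:
                assert np.all(g.ancestor_dose(chrom, pos, sd.MEDICA) == 1)

    def test_tau_one_centromeric_class_frequencies(self):
        # no crossovers: classes must hit (1/6, 1/6, 4/6) within 3 SD
        g = sd.default_genome(1, 1_000_000, map_length=0.0)
        volk, _ = sd.build_parent_karyotypes(g)
        n = 60_000
        gams = sd.simulate_meiosis(volk, g, sd.MeiosisParams(1.0), n,
                                   np.random.default_rng(1))
        cen = np.array([g.centromeres["C1"]])
        d = np.array([x.ancestor_dose("C1", cen, sd.MEDICA)[0] for x in gams])
        for cls, p in ((2, 1 / 6), (0, 1 / 6), (1, 4 / 6)):
            sdv = np.sqrt(p * (1 - p) / n)
            assert abs((d == cls).mean() - p) < 3 * sdv

    @pytest.mark.parametrize("tau", [0.0, 0.3, 0.6, 1.0])
    def test_heterozygosity_invariant_any_locus(self, genome, parents, tau):
        # E[het] = 1 - tau/3 at every locus, crossovers on
        volk, _ = parents
        n = 3000
        gams = sd.simulate_meiosis(volk, genome, sd.MeiosisParams(tau), n,
                                   np.random.default_rng(2))
        pos = np.array([123_456.0, 700_001.0])
        het = np.mean([g.ancestor_dose("C1", pos, sd.MEDICA) == 1
                       for g in gams], axis=0)
        p = 1 - tau / 3
        assert np.all(np.abs(het - p) < 3 * np.sqrt(p * (1 - p) / n) + 1e-12)

    def test_seeded_runs_identical(self, genome, parents):
        volk, _ = parents
        a = sd.simulate_meiosis(volk, genome, sd.MeiosisParams(0.5), 10,
                                np.random.default_rng(42))
        b = sd.simulate_meiosis(volk, genome, sd.MeiosisParams(0.5), 10,
                                np.random.default_rng(42))
        for x, y in zip(a, b):
            assert x.chromatids == y.chromatids
            assert x.pairing == y.pairing

    def test_tau_out_of_range_raises(self, genome, parents):
        volk, _ = parents
        with pytest.raises(ValueError, match="tau"):
            sd.simulate_meiosis(volk, genome, sd.MeiosisParams(1.5), 1,
                                np.random.default_rng(0))

    def test_double_reduction_flag_rejected(self):
        with pytest.raises(ValueError, match="double reduction"):
            sd.MeiosisParams(0.5, double_reduction=True)

    def test_chromatids_tile_chromosome(self, genome, parents):
        volk, _ = parents
        gams = sd.simulate_meiosis(volk, genome, sd.MeiosisParams(1.0), 20,
                                   np.random.default_rng(3))
        for g in gams:
            for chrom, length in genome.chromosomes:
                for track in g.chromatids[chrom]:
                    assert track[-1][0] == length
                    ends = [e for e, _ in track]
                    assert all(a < b for a, b in zip(ends, ends[1:]))


class TestHybrids:
    def test_dose_conservation(self, genome, parents):
        volk, citru = parents
        rng = np.random.default_rng(4)
        ov = sd.simulate_meiosis(volk, genome, sd.MeiosisParams(0.7), 15, rng)
        po = sd.simulate_meiosis(citru, genome, sd.MeiosisParams(0.4), 15, rng)
        hybs = sd.form_hybrids(ov, po)
        pos = np.linspace(1, 999_999, 11)
        for h in hybs:
            for chrom in genome.names:
                for anc in sd.ANCESTORS:
                    assert np.all(
                        h.ancestor_dose(chrom, pos, anc)
                        == h.ovule.ancestor_dose(chrom, pos, anc)
                        + h.pollen.ancestor_dose(chrom, pos, anc))

    def test_trifoliata_only_from_pollen(self, genome, parents):
        volk, citru = parents
        rng = np.random.default_rng(5)
        ov = sd.simulate_meiosis(volk, genome, sd.MeiosisParams(0.5), 5, rng)
        po = sd.simulate_meiosis(citru, genome, sd.MeiosisParams(0.0), 5, rng)
        hybs = sd.form_hybrids(ov, po)
        pos = np.linspace(1, 999_999, 9)
        for h in hybs:
            assert np.all(h.ancestor_dose("C1", pos, sd.TRIFOLIATA)
                          == h.pollen.ancestor_dose("C1", pos, sd.TRIFOLIATA))

    def test_requested_cohort_size(self, genome, parents):
        volk, citru = parents
        rng = np.random.default_rng(6)
        ov = sd.simulate_meiosis(volk, genome, sd.MeiosisParams(0.5), 30, rng)
        po = sd.simulate_meiosis(citru, genome, sd.MeiosisParams(0.5), 20, rng)
        hybs = sd.form_hybrids(ov, po, rng=rng, n=95)
        assert len(hybs) == 95
        assert all(len(h.ovule.chromatids["C1"])
                   + len(h.pollen.chromatids["C1"]) == 4 for h in hybs)

    def test_empty_gamete_list_raises(self):
        with pytest.raises(ValueError, match="empty"):
            sd.form_hybrids([], [])


@pytest.fixture(scope="module")
def dose2_hybrid(genome, parents):
    # two tau=0 ovules -> medica dose exactly 2 everywhere
    volk, _ = parents
    rng = np.random.default_rng(7)
    g1 = sd.simulate_meiosis(volk, genome, sd.MeiosisParams(0.0), 1, rng)
    g2 = sd.simulate_meiosis(volk, genome, sd.MeiosisParams(0.0), 1, rng)
    return sd.form_hybrids(g1, g2)


class TestReadCounts:
    def test_full_dose_zero_error_all_reads_diagnostic(self, genome, parents):
        volk, _ = parents
        rng = np.random.default_rng(8)
        g1 = sd.simulate_meiosis(volk, genome, sd.MeiosisParams(0.0), 1, rng)
        hyb = sd.form_hybrids(g1, g1)  # medica dose 2... use reticulata d=4? no
        panel = pd.DataFrame({"chrom": "C1",
                              "pos": np.linspace(10, 999_990, 200).astype(int),
                              "taxon": sd.RETICULATA, "diag_allele": "alt"})
        counts = sd.simulate_read_counts(
            hyb, panel, sd.ReadCountModel(30, 0.0, 0.0),
            np.random.default_rng(9))
        # reticulata dose is 2 (ovule 1 + pollen 1): f = 0.5; instead check
        # dose-0 taxon gives zero diagnostic reads
        panel0 = panel.assign(taxon=sd.TRIFOLIATA)
        counts0 = sd.simulate_read_counts(
            hyb, panel0, sd.ReadCountModel(30, 0.0, 0.0),
            np.random.default_rng(9))
        assert (counts0["diag_reads"] == 0).all()
        assert (counts["total_reads"] > 0).mean() > 0.9

    def test_duplex_dose_fraction_near_half(self, dose2_hybrid):
        panel = pd.DataFrame({"chrom": "C1",
                              "pos": np.linspace(10, 999_990, 1000).astype(int),
                              "taxon": sd.MEDICA, "diag_allele": "alt"})
        counts = sd.simulate_read_counts(
            dose2_hybrid, panel, sd.ReadCountModel(1000, 0.01, 0.0),
            np.random.default_rng(10))
        frac = counts["diag_reads"].sum() / counts["total_reads"].sum()
        n = counts["total_reads"].sum()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_missing_sites_have_zero_total(self, dose2_hybrid):
        panel = pd.DataFrame({"chrom": "C1",
                              "pos": np.linspace(10, 999_990, 500).astype(int),
                              "taxon": sd.MEDICA, "diag_allele": "alt"})
        counts = sd.simulate_read_counts(
            dose2_hybrid, panel, sd.ReadCountModel(20, 0.01, 0.3),
            np.random.default_rng(11))
        frac_zero = (counts["total_reads"] == 0).mean()
        assert 0.2 < frac_zero < 0.4

    def test_model_invariants(self):
        with pytest.raises(ValueError):
            sd.ReadCountModel(eps=0.6)
        with pytest.raises(ValueError):
            sd.ReadCountModel(depth=-1)
        with pytest.raises(ValueError):
            sd.ReadCountModel(missing_rate=1.5)


class TestPhenotypes:
    def test_no_effect_no_noise_equals_intercept(self):
        doses = pd.DataFrame({"w1": [0, 1, 2], "w2": [1, 1, 1]},
                             index=["a", "b", "c"])
        ph = sd.simulate_phenotypes(doses, [("w1", 0.0)], noise_sd=0.0,
                                    intercept=5.0)
        assert (ph.iloc[:, 0] == 5.0).all()

    def test_noiseless_differences_equal_dose_differences(self):
        doses = pd.DataFrame({"w1": [0.0, 1.0, 2.0]}, index=list("abc"))
        ph = sd.simulate_phenotypes(doses, [("w1", 1.0)], noise_sd=0.0)
        v = ph.iloc[:, 0].to_numpy()
        assert np.allclose(np.diff(v), np.diff(doses["w1"]))

    def test_seeded_repeat_identical(self):
        doses = pd.DataFrame({"w1": np.arange(10) % 3})
        a = sd.simulate_phenotypes(doses, [("w1", 0.5)], 1.0,
                                   rng=np.random.default_rng(3))
        b = sd.simulate_phenotypes(doses, [("w1", 0.5)], 1.0,
                                   rng=np.random.default_rng(3))
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_window_raises(self):
        doses = pd.DataFrame({"w1": [0, 1]})
        with pytest.raises(KeyError, match="unknown window"):
            sd.simulate_phenotypes(doses, [("nope", 1.0)])
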