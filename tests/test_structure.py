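"""Population structure: FST, Nei distance, classical MDS, neighbor joining."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

import oracles
from conftest import make_table
from forensicstr.markers import AlleleFrequencySpectrum, MarkerDef
from forensicstr.simulate import SimConfig, simulate_autosomal_table
from forensicstr.structure import (
    DistanceMatrix,
    classical_mds,
    group_small_populations,
    nei_distance_matrix,
    nei_standard_distance,
    neighbor_joining,
    pairwise_fst,
    tree_tip_distances,
    weir_cockerham_theta,
)

L = MarkerDef("L1")


class TestWeirCockerham:
    def test_random_split_of_one_population_is_near_zero(self):
        cfg = SimConfig(seed=9, n_loci_autosomal=20, alleles_min_autosomal=5,
                        alleles_max_autosomal=10,
                        subpopulations=(("P", 200, 0.001),))
        tab = simulate_autosomal_table(cfg)
        half = tab.data.index < 100
        theta = weir_cockerham_theta([tab.subset(half), tab.subset(~half)])
        assert abs(theta) < 0.01

    def test_fixed_differences_give_one(self):
        rows = [(f"a{i}", "female", "A", {"L1": ("10", "10")})
                for i in range(20)]
        rows += [(f"b{i}", "female", "B", {"L1": ("12", "12")})
                 for i in range(20)]
        t = make_table([L], rows)
        theta = weir_cockerham_theta(
            [t.subset(t.data.Population == "A"),
             t.subset(t.data.Population == "B")], ["L1"])
        assert theta == pytest.approx(1.0)

    @pytest.mark.parametrize("F", [0.01, 0.05, 0.15])
    def test_balding_nichols_recovery(self, F):
        cfg = SimConfig(seed=17, n_loci_autosomal=20, alleles_min_autosomal=6,
                        alleles_max_autosomal=12,
                        subpopulations=(("P1", 100, F), ("P2", 100, F)))
        tab = simulate_autosomal_table(cfg)
        theta = weir_cockerham_theta(
            [tab.subset(tab.data.Population == "P1"),
             tab.subset(tab.data.Population == "P2")])
        assert theta == pytest.approx(F, abs=max(0.02, 0.4 * F))

    def test_pairwise_matrix_shape_and_small_group_nan(self):
        rows = [(f"a{i}", "female", "A", {"L1": ("10", "11")})
                for i in range(10)]
        rows += [(f"b{i}", "female", "B", {"L1": ("10", "12")})
                 for i in range(10)]
        rows += [("c0", "female", "C", {"L1": ("10", "10")})]
        t = make_table([L], rows)
        with pytest.warns(UserWarning):
            dm, _ = pairwise_fst(t, loci=["L1"], min_size=2)
        assert dm.labels == ["A", "B", "C"]
        assert np.isnan(dm.values[0, 2]) and np.isnan(dm.values[1, 2])
        assert np.isfinite(dm.values[0, 1])


class TestNei:
    def two_spectra(self, ca, cb):
        return ({"L1": AlleleFrequencySpectrum("L1", ca)},
                {"L1": AlleleFrequencySpectrum("L1", cb)})

    def test_identical_spectra_zero(self):
        fa, fb = self.two_spectra({"A": 7, "B": 3}, {"A": 7, "B": 3})
        assert nei_standard_distance(fa, fb) == pytest.approx(0.0, abs=1e-15)

    def test_hand_value(self):
        fa, fb = self.two_spectra({"A": 7, "B": 3}, {"A": 3, "B": 7})
        # Jxy = 0.42, Jx = Jy = 0.58
        assert nei_standard_distance(fa, fb) == pytest.approx(
            -math.log(0.42 / 0.58), abs=1e-12)
        assert nei_standard_distance(fa, fb) == pytest.approx(0.3228,
                                                              abs=5e-4)

    def test_disjoint_alleles_infinite(self):
        fa, fb = self.two_spectra({"A": 1}, {"B": 1})
        assert math.isinf(nei_standard_distance(fa, fb))

    def test_symmetry(self):
        fa, fb = self.two_spectra({"A": 5, "B": 2, "C": 3}, {"A": 1, "B": 9})
        assert nei_standard_distance(fa, fb) == pytest.approx(
            nei_standard_distance(fb, fa), abs=1e-15)

    def test_matrix_builder(self):
        pops = {
            "P1": {"L1": AlleleFrequencySpectrum("L1", {"A": 7, "B": 3})},
            "P2": {"L1": AlleleFrequencySpectrum("L1", {"A": 3, "B": 7})},
            "P3": {"L1": AlleleFrequencySpectrum("L1", {"A": 5, "B": 5})},
        }
        dm = nei_distance_matrix(pops)
        assert dm.labels == ["P1", "P2", "P3"]
        assert dm.values[0, 1] > dm.values[0, 2] > 0


class TestMDS:
    def test_equilateral_triangle(self):
        dm = DistanceMatrix(["a", "b", "c"], 1.0 - np.eye(3), "d")
        coords, evals = classical_mds(dm, 2)
        rec = squareform(pdist(coords))
        assert np.allclose(rec, dm.values, atol=1e-9)

    def test_euclidean_inputs_reconstructed(self, rng):
        pts = rng.normal(size=(6, 3))
        d = squareform(pdist(pts))
        dm = DistanceMatrix([f"p{i}" for i in range(6)], d, "d")
        coords, evals = classical_mds(dm, 5)
        rec = squareform(pdist(coords))
        assert np.allclose(rec, d, atol=1e-9)

    def test_collinear_points_have_rank_one(self):
        x = np.array([0.0, 1.0, 3.0, 6.0])
        d = np.abs(x[:, None] - x[None, :])
        dm = DistanceMatrix(list("abcd"), d, "d")
        with pytest.warns(UserWarning):
            coords, evals = classical_mds(dm, 2)
        assert coords.shape[1] == 1
        assert abs(evals[1]) < 1e-9 * evals[0]

    def test_agrees_with_skbio_pcoa(self, rng):
        pts = rng.normal(size=(7, 2))
        d = squareform(pdist(pts))
        dm = DistanceMatrix([f"p{i}" for i in range(7)], d, "d")
        coords, _ = classical_mds(dm, 2)
        from skbio import DistanceMatrix as SkDM
        from skbio.stats.ordination import pcoa
        ref = pcoa(SkDM(d, ids=dm.labels), number_of_dimensions=2)
        rec_mine = squareform(pdist(coords))
        rec_ref = squareform(pdist(ref.samples.values))
        assert np.allclose(rec_mine, rec_ref, atol=1e-8)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        dm = DistanceMatrix(["A", "B", "C"], d, "d")
        td = tree_tip_distances(neighbor_joining(dm))
        idx = {lab: i for i, lab in enumerate(td.labels)}
        for a, b, want in (("A", "B", 3), ("A", "C", 4), ("B", "C", 5)):
            assert td.values[idx[a], idx[b]] == pytest.approx(want, abs=1e-9)

    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,C:3,D:1)
        d = np.array([
            [0, 3, 5, 3],
            [3, 0, 6, 4],
            [5, 6, 0, 4],
            [3, 4, 4, 0]], float)
        dm = DistanceMatrix(list("ABCD"), d, "d")
        td = tree_tip_distances(neighbor_joining(dm))
        idx = {lab: i for i, lab in enumerate(td.labels)}
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                assert td.values[idx[a], idx[b]] == pytest.approx(
                    d[i, j], abs=1e-9)

    def test_random_additive_matrices_recovered(self, rng):
        for _ in range(20):
            labels, d = oracles.random_additive_matrix(rng, 8)
            dm = DistanceMatrix(labels, d, "d")
            td = tree_tip_distances(neighbor_joining(dm))
            idx = {lab: i for i, lab in enumerate(td.labels)}
            for i, a in enumerate(labels):
                for j, b in enumerate(labels):
                    assert td.values[idx[a], idx[b]] == pytest.approx(
                        d[i, j], abs=1e-9)

    def test_infinite_distance_rejected_with_guidance(self):
        d = np.array([[0, 1, np.inf], [1, 0, 1], [np.inf, 1, 0]])
        dm = DistanceMatrix(list("abc"), d, "d")
        with pytest.raises(ValueError, match="cap"):
            neighbor_joining(dm)


def test_group_small_populations():
    rows = [(f"a{i}", "female", "Big", {"L1": ("10", "11")})
            for i in range(12)]
    rows += [("b0", "female", "Tiny", {"L1": ("10", "11")})]
    t = make_table([L], rows)
    g = group_small_populations(t, threshold=10)
    assert g.populations() == ["Big", "Other"]


def test_distance_matrix_writers(tmp_path):
    dm = DistanceMatrix(["a", "b", "c"],
                        np.array([[0, .1, .2], [.1, 0, .3], [.2, .3, 0]]),
                        "fst")
    dm.to_csv(tmp_path / "m.csv")
    dm.to_phylip(tmp_path / "m.phy")
    assert (tmp_path / "m.phy").read_text().startswith("3\n")
    neg = DistanceMatrix(["a", "b"], np.array([[0, -.01], [-.01, 0]]), "fst")
    assert neg.clamped().values[0, 1] == 0.0
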