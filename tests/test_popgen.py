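"""Diversity/identity statistics, similarity, Mantel, PCoA and trees."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import pi_genotype_enumeration, pic_double_sum
from ssrkit.genotypes import GenotypeTable
from ssrkit.popgen import (
    allele_freqs,
    build_tree,
    diversity,
    geo_distance,
    gs_matrix,
    identity_stats,
    mantel,
    multilocus_match,
    pcoa,
    shared_allele_distance,
)


def table_from_freqs(p, n=4000, seed=0, locus="L1"):
    """Diploid table drawn exactly from allele frequencies *p* (sizes
    100, 102, ...)."""
    rng = np.random.default_rng(seed)
    sizes = [100 + 2 * i for i in range(len(p))]
    inds = [f"i{k}" for k in range(n)]
    draws = rng.choice(sizes, size=(n, 2), p=p)
    cells = {(ind, locus): tuple(map(int, draws[k])) for k, ind in
             enumerate(inds)}
    return GenotypeTable(inds, [locus], cells)


class TestAlleleFreqs:
    def test_heterozygote_panel(self, two_allele_table):
        assert allele_freqs(two_allele_table, "L1") == {180: 0.5, 184: 0.5}

    def test_homozygote_mix(self):
        cells = {(f"i{k}", "L1"): (180, 180) for k in range(4)}
        cells[("i4", "L1")] = (184, 184)
        t = GenotypeTable([f"i{k}" for k in range(5)], ["L1"], cells)
        assert allele_freqs(t, "L1") == {180: 0.8, 184: 0.2}

    def test_single_size_counts_as_homozygote(self):
        t = GenotypeTable(["a", "b"], ["L1"],
                          {("a", "L1"): (150,), ("b", "L1"): (150, 154)})
        assert allele_freqs(t, "L1") == {150: 0.75, 154: 0.25}

    def test_matches_brute_force_tally(self, rng):
        sizes = rng.integers(100, 140, size=(30, 2)) * 2
        inds = [f"i{k}" for k in range(30)]
        t = GenotypeTable(inds, ["L"], {(i, "L"): tuple(map(int, s))
                                        for i, s in zip(inds, sizes)})
        tally = {}
        for s in sizes.ravel():
            tally[int(s)] = tally.get(int(s), 0) + 1
        expected = {a: c / 60 for a, c in tally.items()}
        assert allele_freqs(t, "L") == pytest.approx(expected)

    def test_all_missing_locus_rejected(self):
        t = GenotypeTable(["a"], ["L1", "L2"], {("a", "L1"): (100,)})
        with pytest.raises(ValueError, match="L2"):
            allele_freqs(t, "L2")


class TestDiversity:
    def test_two_equifrequent_alleles_closed_form(self, two_allele_table):
        row = diversity(two_allele_table).loc["L1"]
        assert row["Na"] == 2
        assert row["Ne"] == pytest.approx(2.0)
        assert row["He"] == pytest.approx(0.5)
        assert row["I"] == pytest.approx(math.log(2))
        assert row["PIC"] == pytest.approx(0.375)
        assert row["Ho"] == 1.0

    def test_monomorphic_locus(self):
        t = GenotypeTable(["a", "b"], ["L"],
                          {("a", "L"): (90, 90), ("b", "L"): (90,)})
        row = diversity(t).loc["L"]
        assert (row["Na"], row["Ne"], row["He"], row["I"], row["PIC"]) == \
            (1, 1.0, 0.0, 0.0, 0.0)

    def test_four_equifrequent_alleles(self):
        inds = [f"i{k}" for k in range(2)]
        t = GenotypeTable(inds, ["L"], {("i0", "L"): (100, 102),
                                        ("i1", "L"): (104, 106)})
        row = diversity(t).loc["L"]
        assert row["Ne"] == pytest.approx(4.0)
        assert row["He"] == pytest.approx(0.75)
        assert row["I"] == pytest.approx(math.log(4))

    @given(st.lists(st.floats(0.05, 1.0), min_size=2, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_pic_equals_double_sum_and_bounds(self, weights):
        p = np.array(weights) / np.sum(weights)
        sum2, sum4 = float(np.sum(p**2)), float(np.sum(p**4))
        pic = 1 - sum2 - sum2**2 + sum4
        assert pic == pytest.approx(pic_double_sum(p), abs=1e-12)
        he = 1 - sum2
        assert pic <= he + 1e-12
        assert he <= 1 - 1 / len(p) + 1e-12
        assert 1 / sum2 <= len(p) + 1e-9

    def test_parameter_recovery_from_simulated_table(self):
        p = [0.5, 0.3, 0.2]
        t = table_from_freqs(p, n=2000, seed=1)
        row = diversity(t).loc["L1"]
        assert row["He"] == pytest.approx(1 - sum(x * x for x in p),
                                          abs=0.01)

    def test_unbiased_toggle_scales_he(self, two_allele_table):
        he = diversity(two_allele_table, unbiased_he=True).loc["L1", "He"]
        assert he == pytest.approx(0.5 * 20 / 19)


class TestIdentity:
    def test_two_equifrequent_alleles_closed_form(self, two_allele_table):
        row = identity_stats(two_allele_table).loc["L1"]
        assert row["PI"] == pytest.approx(0.375)
        assert row["PIsibs"] == pytest.approx(0.59375)

    def test_single_allele_is_certain_identity(self):
        t = GenotypeTable(["a", "b"], ["L"],
                          {("a", "L"): (90,), ("b", "L"): (90,)})
        row = identity_stats(t).loc["L"]
        assert row["PI"] == 1.0 and row["PIsibs"] == 1.0

    @given(st.lists(st.floats(0.05, 1.0), min_size=1, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_pi_matches_genotype_enumeration(self, weights):
        p = np.array(weights) / np.sum(weights)
        sum2, sum4 = float(np.sum(p**2)), float(np.sum(p**4))
        pi = 2 * sum2**2 - sum4
        assert pi == pytest.approx(pi_genotype_enumeration(p), abs=1e-12)

    def test_cumulative_product_non_increasing(self, panel105):
        df = identity_stats(panel105.table)
        assert (np.diff(df["cum_PI"]) <= 1e-15).all()
        assert (np.diff(df["cum_PIsibs"]) <= 1e-15).all()
        assert df["PI"].is_monotonic_increasing  # ascending-PI order


class TestMultilocusMatch:
    def _table(self):
        cells = {
            ("a", "L1"): (100, 102), ("a", "L2"): (200, 200),
            ("b", "L1"): (102, 100), ("b", "L2"): (200,),
            ("c", "L1"): (100, 104), ("c", "L2"): (200, 202),
        }
        return GenotypeTable(["a", "b", "c"], ["L1", "L2"], cells)

    def test_duplicated_genotype_reported_order_free(self):
        assert multilocus_match(self._table()) == [("a", "b")]

    def test_distinct_rows_empty(self, panel105):
        assert multilocus_match(panel105.table) == []

    def test_planted_duplicates_recovered(self, panel105):
        t = panel105.table
        cells = {(i, l): t.alleles(i, l) for i, l in
                 ((i, l) for i in t.individuals for l in t.loci)
                 if t.alleles(i, l)}
        clone = "S_clone"
        for l in t.loci:
            if t.alleles("S001", l):
                cells[(clone, l)] = t.alleles("S001", l)
        t2 = GenotypeTable(t.individuals + [clone], t.loci, cells)
        assert multilocus_match(t2) == [("S001", clone)]


class TestGSMatrix:
    def test_identical_individuals_have_unit_similarity(self):
        cells = {(i, "L"): (100, 104) for i in ("a", "b")}
        gs = gs_matrix(GenotypeTable(["a", "b"], ["L"], cells))
        assert gs.loc["a", "b"] == 1.0

    def test_disjoint_single_band_profiles_simple_matching_zero(self):
        t = GenotypeTable(["a", "b"], ["L"],
                          {("a", "L"): (100,), ("b", "L"): (110,)})
        gs = gs_matrix(t, "simple_matching")
        assert gs.loc["a", "b"] == 0.0

    def test_matches_brute_force_band_comparison(self, panel105):
        t = panel105.table
        gs = gs_matrix(t, "dice")
        bands = sorted({(l, s) for i in t.individuals for l in t.loci
                        for s in t.alleles(i, l)})
        a, b = t.individuals[3], t.individuals[17]
        pa = {bd for bd in bands if bd[1] in t.alleles(a, bd[0])}
        pb = {bd for bd in bands if bd[1] in t.alleles(b, bd[0])}
        shared = len(pa & pb)
        expected = 2 * shared / (2 * shared + len(pa - pb) + len(pb - pa))
        assert gs.loc[a, b] == pytest.approx(expected)

    def test_symmetric_unit_diagonal_and_pair_count(self, panel105):
        gs = gs_matrix(panel105.table)
        arr = gs.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 1.0)
        n = arr.shape[0]
        assert n * (n - 1) // 2 == 5460  # C(105, 2) unordered pairs


class TestMantel:
    def test_perfect_correlation(self, rng):
        pts = rng.normal(size=(12, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = mantel(d, d.copy(), n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_fixed_seed_reproducible(self, rng):
        a = rng.random((10, 10))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        b = rng.random((10, 10))
        b = (b + b.T) / 2
        np.fill_diagonal(b, 0)
        r1 = mantel(a, b, n_perm=199, seed=7)
        r2 = mantel(a, b, n_perm=199, seed=7)
        assert (r1.r, r1.p) == (r2.r, r2.p)

    def test_null_calibration(self):
        rng = np.random.default_rng(123)
        ps, rs = [], []
        for _ in range(200):
            pts1 = rng.normal(size=(10, 2))
            pts2 = rng.normal(size=(10, 2))
            d1 = np.sqrt(((pts1[:, None] - pts1[None]) ** 2).sum(-1))
            d2 = np.sqrt(((pts2[:, None] - pts2[None]) ** 2).sum(-1))
            res = mantel(d1, d2, n_perm=49,
                         seed=int(rng.integers(2**31)))
            ps.append(res.p)
            rs.append(res.r)
        assert abs(np.mean(rs)) < 0.05
        assert 0.35 < np.mean(ps) < 0.65  # uniform null p-values

    def test_joint_reordering_invariance(self, rng):
        a = rng.random((9, 9)); a = (a + a.T) / 2; np.fill_diagonal(a, 0)
        b = rng.random((9, 9)); b = (b + b.T) / 2; np.fill_diagonal(b, 0)
        perm = rng.permutation(9)
        r1 = mantel(a, b, n_perm=0, seed=0).r
        r2 = mantel(a[np.ix_(perm, perm)], b[np.ix_(perm, perm)],
                    n_perm=0, seed=0).r
        assert r1 == pytest.approx(r2)

    def test_order_mismatch_rejected(self):
        a = pd.DataFrame(np.zeros((3, 3)), index=list("abc"),
                         columns=list("abc"))
        b = pd.DataFrame(np.zeros((3, 3)), index=list("acb"),
                         columns=list("acb"))
        with pytest.raises(ValueError, match="order"):
            mantel(a, b, n_perm=9)


class TestGeoDistance:
    def test_identical_points_zero(self):
        c = pd.DataFrame({"lat": [10.0, 10.0], "lon": [20.0, 20.0]},
                         index=["a", "b"])
        assert geo_distance(c).loc["a", "b"] == 0.0

    def test_equatorial_antipodes(self):
        c = pd.DataFrame({"lat": [0.0, 0.0], "lon": [0.0, 180.0]},
                         index=["a", "b"])
        assert geo_distance(c).loc["a", "b"] == \
            pytest.approx(math.pi * 6371.0)

    def test_matches_spherical_law_of_cosines(self, rng):
        lat = rng.uniform(-80, 80, size=8)
        lon = rng.uniform(-170, 170, size=8)
        c = pd.DataFrame({"lat": lat, "lon": lon},
                         index=[f"p{i}" for i in range(8)])
        d = geo_distance(c).to_numpy()
        phi, lam = np.radians(lat), np.radians(lon)
        for i in range(8):
            for j in range(i + 1, 8):
                cosd = (np.sin(phi[i]) * np.sin(phi[j])
                        + np.cos(phi[i]) * np.cos(phi[j])
                        * np.cos(lam[i] - lam[j]))
                ref = 6371.0 * np.arccos(np.clip(cosd, -1, 1))
                assert d[i, j] == pytest.approx(ref, rel=1e-6, abs=1e-6)

    def test_invalid_latitude_rejected(self):
        c = pd.DataFrame({"lat": [95.0], "lon": [0.0]}, index=["a"])
        with pytest.raises(ValueError):
            geo_distance(c)


class TestPCoA:
    def test_two_points_closed_form(self):
        res = pcoa(np.array([[0.0, 4.0], [4.0, 0.0]]))
        coords = res.coordinates.to_numpy().ravel()
        assert sorted(coords) == pytest.approx([-2.0, 2.0])
        assert res.percent_variance == pytest.approx([100.0])

    def test_recovers_planted_configuration(self, rng):
        pts = rng.normal(size=(15, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = pcoa(d)
        rec = res.coordinates.to_numpy()[:, :2]
        from scipy.spatial import procrustes

        _, _, disparity = procrustes(pts, rec)
        assert disparity < 1e-8
        assert res.percent_variance.sum() == pytest.approx(100.0)

    def test_axis_sign_convention(self, rng):
        pts = rng.normal(size=(10, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        coords = pcoa(d).coordinates.to_numpy()
        for k in range(coords.shape[1]):
            assert coords[np.argmax(np.abs(coords[:, k])), k] > 0

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            pcoa(np.array([[0.0, 1.0], [2.0, 0.0]]))


def _tree_distances(newick):
    import io as _io

    from skbio import TreeNode

    t = TreeNode.read(_io.StringIO(newick))
    return t.tip_tip_distances()


class TestTrees:
    def test_upgma_three_taxa_closed_form(self):
        d = pd.DataFrame([[0, 2, 4], [2, 0, 4], [4, 4, 0]],
                         index=list("ABC"), columns=list("ABC"), dtype=float)
        assert build_tree(d, "upgma") == "((A:1,B:1):1,C:2);"

    def test_upgma_reproduces_ultrametric_input(self, rng):
        # build an ultrametric matrix from a random UPGMA-like hierarchy
        d = pd.DataFrame(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 4], [6, 6, 4, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float)
        td = _tree_distances(build_tree(d, "upgma"))
        for a in "ABCD":
            for b in "ABCD":
                if a != b:
                    assert td[a, b] == pytest.approx(d.loc[a, b])

    def test_nj_recovers_additive_topology(self):
        # additive distances from tree ((A:1,B:2):1,(C:3,D:1):1)
        d = pd.DataFrame(
            [[0, 3, 6, 4], [3, 0, 7, 5], [6, 7, 0, 4], [4, 5, 4, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float)
        td = _tree_distances(build_tree(d, "nj"))
        for a in "ABCD":
            for b in "ABCD":
                if a != b:
                    assert td[a, b] == pytest.approx(d.loc[a, b])

    def test_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            build_tree(np.zeros((2, 2)), "upgma")

    def test_shared_allele_distance_bounds(self, panel105):
        d = shared_allele_distance(panel105.table)
        arr = d.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0.0)
        assert ((arr >= 0) & (arr <= 1)).all()
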