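"""Heterozygosity, Weir-Cockerham F_ST, distances, Mantel IBD."""

import itertools

import numpy as np
import pytest

from stepstone.stats import (
    DistanceMatrix,
    geographic_distances,
    linearize_fst,
    linearize_fst_matrix,
    mantel_test,
    observed_heterozygosity,
    pairwise_fst,
    wc_fst,
)


class TestHeterozygosity:
    def test_all_het_and_all_hom(self):
        G = np.array([[1, 1, 1], [0, 2, 0]], dtype=np.int8)
        ho = observed_heterozygosity(G, ["a", "b"])
        assert ho["a"] == 1.0 and ho["b"] == 0.0

    def test_missing_excluded_from_denominator(self):
        G = np.array([[1, -1, 0, 1]], dtype=np.int8)
        ho = observed_heterozygosity(G)
        assert ho.iloc[0] == pytest.approx(2 / 3)

    def test_all_missing_individual_raises(self):
        G = np.array([[-1, -1]], dtype=np.int8)
        with pytest.raises(ValueError, match="no non-missing"):
            observed_heterozygosity(G)

    def test_hwe_binomial_oracle(self):
        """At allele frequency 0.5 in HWE, Ho ~ 0.5 within 3 SE."""
        rng = np.random.default_rng(8)
        n_sites = 4000
        G = (rng.random((1, n_sites)) < 0.5).astype(np.int8)
        G += (rng.random((1, n_sites)) < 0.5).astype(np.int8)
        ho = observed_heterozygosity(G).iloc[0]
        se = np.sqrt(0.25 / n_sites)
        assert abs(ho - 0.5) < 3 * se


class TestFst:
    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.2, 0.8, 10_000)
        G1 = ((rng.random((8, 10_000)) < p).astype(np.int8)
              + (rng.random((8, 10_000)) < p).astype(np.int8))
        G2 = ((rng.random((8, 10_000)) < p).astype(np.int8)
              + (rng.random((8, 10_000)) < p).astype(np.int8))
        assert abs(wc_fst(G1, G2)) < 0.01

    def test_reciprocally_fixed_difference_is_one(self):
        G1 = np.zeros((4, 50), dtype=np.int8)
        G2 = np.full((4, 50), 2, dtype=np.int8)
        assert wc_fst(G1, G2) == pytest.approx(1.0)

    def test_invariant_to_allele_label_swap_and_row_order(self):
        rng = np.random.default_rng(2)
        G1 = rng.integers(0, 3, size=(6, 500)).astype(np.int8)
        G2 = rng.integers(0, 3, size=(5, 500)).astype(np.int8)
        f = wc_fst(G1, G2)
        assert wc_fst(2 - G1, 2 - G2) == pytest.approx(f, rel=1e-12)
        perm = rng.permutation(6)
        assert wc_fst(G1[perm], G2) == pytest.approx(f, rel=1e-12)

    def test_fewer_than_two_individuals_rejected(self):
        with pytest.raises(ValueError, match="two individuals"):
            wc_fst(np.zeros((1, 5), dtype=np.int8), np.zeros((3, 5), dtype=np.int8))

    def test_symmetric_island_model_matches_coalescent_expectation(self):
        """Two demes exchanging Nm migrants per generation: F_ST matches
        the coalescence-time expectation (T_b - T_w)/T_b = 1/(1 + 8Nm)
        (T_w = 4N, T_b = 4N + 1/2m) within Monte-Carlo tolerance."""
        from stepstone.demography import DemeConfig, Demography
        from stepstone.genotypes import simulate_genotype_matrix

        Nm = 1.0
        N = 2000.0
        m = Nm / N
        d = Demography(
            demes=(DemeConfig("X", N), DemeConfig("Y", N)),
            migration0=((0.0, m), (m, 0.0)),
            mu=1e-8,
        )
        gm = simulate_genotype_matrix(d, {"X": 10, "Y": 10}, n_sites=4000, seed=77)
        f = wc_fst(gm.genotypes[:10], gm.genotypes[10:])
        expected = 1.0 / (1.0 + 8 * Nm)
        assert f == pytest.approx(expected, abs=0.03)

    def test_pairwise_matrix_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(3)
        G = rng.integers(0, 3, size=(12, 300)).astype(np.int8)
        pops = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        d = pairwise_fst(G, pops, ["A", "B", "C"])
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0.0)


class TestLinearize:
    @pytest.mark.parametrize("f,expected", [(0.0, 0.0), (0.5, 1.0), (0.2, 0.25)])
    def test_values(self, f, expected):
        assert linearize_fst(f) == pytest.approx(expected)

    def test_negative_clamped_and_monotone(self):
        assert linearize_fst(-0.05) == 0.0
        grid = np.linspace(0.0, 0.99, 50)
        out = linearize_fst(grid)
        assert (np.diff(out) > 0).all()

    def test_one_rejected(self):
        with pytest.raises(ValueError, match="infinite"):
            linearize_fst(1.0)


class TestGeographicDistances:
    def test_identical_points_zero(self):
        d = geographic_distances({"a": (27.0, 99.0), "b": (27.0, 99.0), "c": (28.0, 99.0)})
        assert d.values[0, 1] == 0.0

    def test_antipodal_half_circumference(self):
        d = geographic_distances({"a": (0.0, 0.0), "b": (0.0, 180.0), "c": (1.0, 1.0)})
        assert d.values[0, 1] == pytest.approx(20_015.1, abs=1.0)

    def test_one_degree_latitude(self):
        d = geographic_distances({"a": (27.0, 99.0), "b": (28.0, 99.0), "c": (0.0, 0.0)})
        assert d.values[0, 1] == pytest.approx(111.2, abs=0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            geographic_distances({"a": (95.0, 0.0)})


class TestMantel:
    def rand_dm(self, n, seed, kind="generic"):
        rng = np.random.default_rng(seed)
        v = rng.random((n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0.0)
        return DistanceMatrix([f"l{i}" for i in range(n)], v, kind)

    def test_identical_matrices_min_p(self):
        d = self.rand_dm(10, 1)
        res = mantel_test(d, d, n_perm=999, seed=5)
        assert res["r"] == pytest.approx(1.0)
        assert res["p"] == pytest.approx(1.0 / 1000.0)

    def test_exact_matches_independent_enumeration(self):
        """4-label exact p equals a from-scratch enumeration over all 4!
        permutations using numpy's corrcoef."""
        a = self.rand_dm(4, 2)
        b = self.rand_dm(4, 3)
        res = mantel_test(a, b, method="exact")
        iu = np.triu_indices(4, 1)
        x = a.values[iu]
        r_obs = np.corrcoef(x, b.values[iu])[0, 1]
        count = sum(
            np.corrcoef(x, b.values[np.ix_(p, p)][iu])[0, 1] >= r_obs - 1e-12
            for p in itertools.permutations(range(4))
        )
        assert res["p"] == pytest.approx(count / 24.0)
        assert res["R2"] == pytest.approx(res["r"] ** 2)

    def test_null_p_roughly_uniform(self):
        """Independent random matrices: p exceeds 0.05 in most replicates
        and spreads over (0, 1]."""
        ps = []
        for rep in range(20):
            a = self.rand_dm(8, 100 + rep)
            b = self.rand_dm(8, 200 + rep)
            ps.append(mantel_test(a, b, n_perm=199, seed=rep)["p"])
        ps = np.array(ps)
        assert (ps > 0.05).mean() >= 0.8
        assert ps.std() > 0.1

    def test_constant_matrix_rejected(self):
        labels = ["a", "b", "c", "d"]
        v = np.ones((4, 4)) - np.eye(4)
        flat = DistanceMatrix(labels, v)
        with pytest.raises(ValueError, match="constant"):
            mantel_test(flat, flat)

    def test_label_mismatch_rejected(self):
        a = self.rand_dm(4, 1)
        b = DistanceMatrix(["x0", "x1", "x2", "x3"], a.values)
        with pytest.raises(ValueError, match="labels"):
            mantel_test(a, b)

    def test_skbio_cross_check(self):
        """Same r as scikit-bio's Mantel on the same matrices."""
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        a = self.rand_dm(7, 11)
        b = self.rand_dm(7, 12)
        ours = mantel_test(a, b, n_perm=999, seed=1)
        theirs_r, theirs_p, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(a.values, a.labels),
            skbio_distance.DistanceMatrix(b.values, b.labels),
            method="pearson", permutations=999, alternative="greater",
        )
        assert ours["r"] == pytest.approx(theirs_r, abs=1e-12)
        assert abs(ours["p"] - theirs_p) < 0.05


class TestIBDLattice:
    def test_stepping_stone_shows_isolation_by_distance(self):
        """A linear stepping-stone demography yields a significant positive
        Mantel correlation between linearized F_ST and chain distance in
        most replicates.  Five demes: with fewer, the chain's reversal
        symmetry plus the small permutation group bounds p above 0.05."""
        from stepstone.demography import DemeConfig, Demography
        from stepstone.genotypes import simulate_genotype_matrix

        k = 5
        m = 2e-4
        mig = np.zeros((k, k))
        for i in range(k - 1):
            mig[i, i + 1] = mig[i + 1, i] = m
        labels = [f"P{i}" for i in range(k)]
        demes = tuple(DemeConfig(lab, 1000.0) for lab in labels)
        coords = {lab: (25.0 + i, 99.0) for i, lab in enumerate(labels)}
        geo = geographic_distances(coords)
        hits = 0
        reps = 5
        for rep in range(reps):
            d = Demography(demes=demes, migration0=tuple(map(tuple, mig)), mu=1e-8)
            gm = simulate_genotype_matrix(
                d, {lab: 6 for lab in labels}, n_sites=1500, seed=400 + rep
            )
            fst = pairwise_fst(
                gm.genotypes, list(gm.individuals["cluster"]), labels
            )
            res = mantel_test(
                linearize_fst_matrix(fst), geo, n_perm=199, seed=rep
            )
            hits += res["p"] < 0.05
        assert hits >= int(0.8 * reps)
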