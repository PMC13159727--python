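"""Hard filters, Hardy-Weinberg exact test, KING kinship, panel design."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stepstone.demography import DemeConfig, Demography
from stepstone.genotypes import GenotypeMatrix, simulate_genotype_matrix
from stepstone.qc import (
    FilterReport,
    SiteFilterThresholds,
    design_panel,
    filter_individuals,
    filter_sites,
    hwe_exact_test,
    king_kinship,
    merge_intervals,
    prune_first_degree,
)


def make_gm(sites: pd.DataFrame, genotypes=None, depth=20.0) -> GenotypeMatrix:
    n_sites = len(sites)
    if genotypes is None:
        genotypes = np.tile(np.array([0, 1, 1, 2], dtype=np.int8), (n_sites, 1)).T
    individuals = pd.DataFrame(
        {
            "id": [f"i{k}" for k in range(genotypes.shape[0])],
            "group": "g",
            "cluster": "c",
            "mean_depth": depth,
        }
    )
    return GenotypeMatrix(np.asarray(genotypes, dtype=np.int8), sites, individuals)


def passing_sites(n) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": ["chr1"] * n,
            "pos": np.arange(1, n + 1) * 100,
            "ref": "A",
            "alt": "C",
            "QUAL": 200.0,
            "FS": 1.0,
            "QD": 20.0,
            "MQ": 55.0,
            "MQRankSum": 0.0,
            "ReadPosRankSum": 0.0,
        }
    )


class TestSiteFilters:
    def test_qd_failure_attributed(self):
        sites = passing_sites(2)
        sites.loc[1, "QD"] = 1.5
        kept, rep = filter_sites(make_gm(sites))
        assert len(kept.sites) == 1
        assert rep.removed["QD"] == 1

    def test_boundary_values_pass(self):
        sites = passing_sites(1)
        sites.loc[0, ["QUAL", "FS", "QD", "MQ"]] = [60.0, 60.0, 2.0, 40.0]
        sites.loc[0, ["MQRankSum", "ReadPosRankSum"]] = [-20.0, -8.0]
        kept, rep = filter_sites(make_gm(sites))
        assert len(kept.sites) == 1

    def test_missing_annotation_skips_rule(self):
        sites = passing_sites(1)
        sites.loc[0, "MQRankSum"] = np.nan
        kept, rep = filter_sites(make_gm(sites))
        assert len(kept.sites) == 1
        assert rep.skipped_annotations["MQRankSum"] == 1

    def test_ten_record_hand_count(self):
        """Hand-enumerated mixed failures: first-failing-rule attribution."""
        sites = passing_sites(10)
        sites.loc[0, "QUAL"] = 10.0                    # QUAL
        sites.loc[1, "FS"] = 80.0                      # FS
        sites.loc[2, ["QUAL", "QD"]] = [10.0, 1.0]     # QUAL (first in order)
        sites.loc[3, "MQ"] = 39.9                      # MQ
        sites.loc[4, "ReadPosRankSum"] = -9.0          # ReadPosRankSum
        sites.loc[5, "MQRankSum"] = -25.0              # MQRankSum
        # 6..9 pass
        G = np.tile(np.array([0, 1, 1, 2], dtype=np.int8), (10, 1)).T
        G[:, 7] = [0, 0, 0, 0]   # monomorphic -> MAF rule
        G[0, 8] = -1
        G[1, 8] = -1             # 50% missing -> site_missing rule
        kept, rep = filter_sites(make_gm(sites, G))
        assert len(kept.sites) == 2
        assert rep.removed == {
            "QUAL": 2, "FS": 1, "QD": 0, "MQ": 1, "MQRankSum": 1,
            "ReadPosRankSum": 1, "site_missing": 1, "MAF": 1,
        }

    def test_filter_idempotent(self):
        sites = passing_sites(6)
        sites.loc[2, "QUAL"] = 5.0
        gm1, rep1 = filter_sites(make_gm(sites))
        gm2, rep2 = filter_sites(gm1)
        assert len(gm2.sites) == len(gm1.sites)
        assert sum(rep2.removed.values()) == 0

    def test_report_conservation(self):
        with pytest.raises(ValueError, match="sum"):
            FilterReport(stage="x", n_input=5, n_output=3, removed={"a": 1})


class TestIndividualFilters:
    @pytest.mark.parametrize(
        "depth,miss,kept",
        [(10.0, 0.29, True), (3.9, 0.0, False), (10.0, 0.31, False), (4.0, 0.30, True)],
    )
    def test_depth_and_missingness_rules(self, depth, miss, kept):
        n_sites = 100
        G = np.ones((1, n_sites), dtype=np.int8)
        G[0, : int(round(miss * n_sites))] = -1
        sites = passing_sites(n_sites)
        gm = make_gm(sites, G, depth=depth)
        out, rep = filter_individuals(gm)
        assert (len(out.individuals) == 1) is kept

    def test_planted_failures_recovered(self):
        d = Demography(demes=(DemeConfig("A", 2000.0),), mu=1e-8)
        gm = simulate_genotype_matrix(
            d, {"A": 24}, n_sites=300, seed=5, missing_rate=0.01,
            n_low_depth=3, n_high_missing=2,
        )
        kept, rep = filter_individuals(gm)
        planted = set(
            gm.individuals.loc[
                gm.individuals.truth_low_depth | gm.individuals.truth_high_missing, "id"
            ]
        )
        assert set(gm.ids) - set(kept.ids) == planted


class TestHWE:
    def test_monomorphic_p_is_one(self):
        assert hwe_exact_test(100, 0, 0) == 1.0

    def test_extreme_het_deficit(self):
        assert hwe_exact_test(50, 0, 50) < 1e-10

    def test_invalid_input(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 1)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60))
    def test_matches_enumeration_oracle(self, n_aa, n_ab, n_bb):
        from conftest import hwe_enumeration_oracle

        if n_aa + n_ab + n_bb == 0:
            return
        ours = hwe_exact_test(n_aa, n_ab, n_bb)
        theirs = hwe_enumeration_oracle(n_aa, n_ab, n_bb)
        assert ours == pytest.approx(theirs, rel=1e-9, abs=1e-300)


@pytest.fixture(scope="module")
def cohort():
    """Coalescent cohort from one deme with a planted parent-offspring pair."""
    d = Demography(demes=(DemeConfig("A", 5000.0),), mu=1e-8)
    return simulate_genotype_matrix(
        d, {"A": 12}, n_sites=10_000, seed=9, relative_pairs=1
    )


class TestKinship:
    def test_duplicated_individual_phi_half(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=2000).astype(np.int8)
        K = king_kinship(np.stack([g, g]), ids=["a", "b"])
        assert K.values[0, 1] == pytest.approx(0.5)

    def test_symmetry_bit_exact(self, cohort):
        K = king_kinship(cohort)
        assert np.array_equal(K.values, K.values.T)

    def test_planted_parent_offspring_and_unrelated(self, cohort):
        """Coalescent cohort: the planted pair stands far above everyone
        else (the rare-allele-heavy spectrum makes unrelated phi noisier
        than under common-frequency HWE draws, hence the 0.05 band)."""
        K = king_kinship(cohort)
        child = cohort.individuals.truth_parent.notna()
        cid = cohort.individuals.loc[child, "id"].iloc[0]
        pid = cohort.individuals.loc[child, "truth_parent"].iloc[0]
        i, j = cohort.ids.index(cid), cohort.ids.index(pid)
        assert 0.177 < K.values[i, j] < 0.35
        others = [
            (a, b)
            for a in range(len(cohort.ids))
            for b in range(a + 1, len(cohort.ids))
            if {a, b} != {i, j}
        ]
        vals = np.array([K.values[a, b] for a, b in others])
        assert np.abs(vals).max() < 0.05

    def test_hwe_cohort_unrelated_tight_and_po_recovered(self):
        """HWE cohort at uniform(0.1, 0.9) frequencies: unrelated pairs sit
        within |phi| < 0.02 at 1e4 sites (the KING estimator's Monte-Carlo
        SD is ~0.009 there, so the band holds only for a handful of
        simultaneous pairs); Mendelian pairs near 0.25."""
        from conftest import hwe_cohort

        G, pairs = hwe_cohort(4, 10_000, seed=0, po_pairs=1)
        K = king_kinship(G)
        (pi, ci) = pairs[0]
        assert 0.177 < K.values[pi, ci] < 0.35
        mask = np.triu(np.ones_like(K.values, dtype=bool), 1)
        mask[pi, ci] = False
        assert np.abs(K.values[mask]).max() < 0.02

    def test_zero_overlap_pair_is_nan(self):
        G = np.array([[1, 1, -1, -1], [-1, -1, 1, 1]], dtype=np.int8)
        K = king_kinship(G, ids=["a", "b"])
        assert np.isnan(K.values[0, 1])


class TestPruning:
    def kin(self, ids, pairs):
        n = len(ids)
        v = np.zeros((n, n))
        np.fill_diagonal(v, 0.5)
        for a, b, phi in pairs:
            i, j = ids.index(a), ids.index(b)
            v[i, j] = v[j, i] = phi
        from stepstone.qc import KinshipMatrix

        return KinshipMatrix(ids=ids, values=v)

    def test_no_flagged_pairs_keeps_all(self):
        K = self.kin(["a", "b", "c"], [("a", "b", 0.1)])
        assert prune_first_degree(K) == ["a", "b", "c"]

    def test_chain_removes_middle_only(self):
        K = self.kin(["a", "b", "c"], [("a", "b", 0.3), ("b", "c", 0.3)])
        assert prune_first_degree(K) == ["a", "c"]

    def test_disjoint_pairs_remove_one_each(self):
        ids = ["a", "b", "c", "d", "e", "f"]
        K = self.kin(ids, [("a", "b", 0.3), ("c", "d", 0.3), ("e", "f", 0.3)])
        kept = prune_first_degree(K)
        assert len(kept) == 3
        for x, y in [("a", "b"), ("c", "d"), ("e", "f")]:
            assert (x in kept) != (y in kept)

    def test_tie_broken_by_missingness(self):
        K = self.kin(["a", "b"], [("a", "b", 0.3)])
        kept = prune_first_degree(K, missingness={"a": 0.1, "b": 0.4})
        assert kept == ["a"]

    def test_post_pruning_sound(self):
        rng = np.random.default_rng(3)
        ids = [f"i{k}" for k in range(12)]
        v = np.zeros((12, 12))
        pairs = [(0, 1), (1, 2), (3, 4), (5, 6), (6, 7), (7, 5)]
        for i, j in pairs:
            v[i, j] = v[j, i] = 0.2 + 0.1 * rng.random()
        np.fill_diagonal(v, 0.5)
        from stepstone.qc import KinshipMatrix

        K = KinshipMatrix(ids=ids, values=v)
        kept = prune_first_degree(K)
        idx = [ids.index(i) for i in kept]
        off = v[np.ix_(idx, idx)].copy()
        np.fill_diagonal(off, 0.0)
        assert off.max() <= 0.177


class TestPanelDesign:
    def test_interval_merge(self):
        merged, n = merge_intervals([("chr1", 10, 30), ("chr1", 20, 40), ("chr2", 0, 5)])
        assert n == 1
        np.testing.assert_array_equal(merged["chr1"][0], [10])
        np.testing.assert_array_equal(merged["chr1"][1], [40])

    def test_thirty_site_hand_derivation(self):
        """30 constructed sites; survivors derived by hand, rule by rule."""
        rows = []
        for k in range(30):
            rows.append({"chrom": "chr1", "pos": 1000 * k + 1, "ref": "A", "alt": "C"})
        sites = pd.DataFrame(rows)
        # sites 0,1 on chrX -> non-autosomal; site 2 multiallelic
        sites.loc[0, "chrom"] = "chrX"
        sites.loc[1, "chrom"] = "chrX"
        sites.loc[2, "alt"] = "C,T"
        # gene mask covers pos 3001-5000 (0-based 3000..5000): sites 3,4
        gene_mask = [("chr1", 3000, 5000)]
        # cpg mask covers site 5 (pos 5001; 0-based 5000..5100)
        cpg_mask = [("chr1", 5000, 5100)]
        # genotypes: 20 individuals, HWE-ish at freq 0.5 except planted:
        rng = np.random.default_rng(1)
        G = rng.integers(0, 2, size=(20, 30)).astype(np.int8)
        G += rng.integers(0, 2, size=(20, 30)).astype(np.int8)
        G[0, 6] = -1                     # site 6 incomplete
        G[:, 7] = 0
        G[0, 7] = 1                      # site 7 MAF = 1/40 < 0.05
        G[:10, 8] = 0
        G[10:, 8] = 2                    # site 8: hard HWE violation
        keep, rep = design_panel(
            make_gm(sites, G), gene_mask=gene_mask, cpg_mask=cpg_mask
        )
        # survivors: 9..29 minus thinning; window = 10kb, pos 9001..29001:
        # windows: site 9 (pos 9001, win 0)! sites 10-19 (win 1..) ...
        # hand calc: pos 9001 -> win 0; 10001..19001 -> win 1; 20001..29001 -> win 2
        assert 9 in keep
        kept_pos = sites.loc[keep, "pos"].tolist()
        assert kept_pos == [9001, 10001, 20001]
        assert rep.removed["non_autosomal"] == 2
        assert rep.removed["non_biallelic"] == 1
        assert rep.removed["gene_mask"] == 2
        assert rep.removed["cpg_mask"] == 1
        assert rep.removed["incomplete_genotyping"] == 1
        assert rep.removed["MAF"] == 1
        assert rep.removed["HWE"] == 1
        assert rep.n_output == 3

    def test_two_passing_snps_within_10kb_thin_to_one(self):
        sites = passing_sites(2)
        sites.loc[0, "pos"] = 1000
        sites.loc[1, "pos"] = 6000
        rng = np.random.default_rng(2)
        G = rng.integers(0, 3, size=(20, 2)).astype(np.int8)
        keep, rep = design_panel(make_gm(sites, G))
        assert len(keep) == 1 and sites.loc[keep[0], "pos"] == 1000
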