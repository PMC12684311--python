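"""Pool-seq statistics: parsing, filtering, diversity, Fst, IBD, UPGMA."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gfchrono.pool_stats import (SiteFilterConfig, filter_sites, folded_sfs,
                                 haversine_km, ibd_regression, joint_2dsfs,
                                 nei_pi_site, pairwise_fst, parse_pooled_vcf,
                                 population_pi, upgma_tree, FstMatrix)

from conftest import (DIRTY_MASK, DIRTY_SURVIVOR_POSITIONS, DIRTY_TALLIES,
                      VCF_HEADER, make_table, vcf_line)


class TestParsing:
    def test_three_record_echo(self):
        text = VCF_HEADER + "".join([
            vcf_line(100, "A", "G", 400, 100),
            vcf_line(250, "C", "T", 450, 0),
            vcf_line(900, "G", "A", 500, 500),
        ])
        table = parse_pooled_vcf(text, pool_n=100, population_id="p1")
        assert list(table.sites["pos"]) == [100, 250, 900]
        assert table.population_id == "p1"
        assert table.n_chromosomes == 100

    def test_alt_freq_from_allele_depths(self):
        text = VCF_HEADER + vcf_line(100, "A", "G", 300, 180)  # AD=120,180
        table = parse_pooled_vcf(text, pool_n=100)
        assert table.sites.loc[0, "alt_freq"] == pytest.approx(0.6)
        assert table.sites.loc[0, "depth"] == 300

    def test_multiallelic_allele_count(self):
        text = VCF_HEADER + vcf_line(100, "A", "G,T", 400, 100, extra_ad=50)
        table = parse_pooled_vcf(text, pool_n=100)
        assert table.sites.loc[0, "n_alleles"] == 3

    def test_missing_depth_field_errors(self):
        text = VCF_HEADER + "chr1\t100\t.\tA\tG\t.\tPASS\t.\n"
        with pytest.raises(ValueError, match="record #1"):
            parse_pooled_vcf(text, pool_n=100)


class TestFiltering:
    def test_dirty_fixture_survivors_and_tallies(self, dirty_vcf_text):
        table = parse_pooled_vcf(dirty_vcf_text, pool_n=100)
        cfg = SiteFilterConfig(mask_regions=DIRTY_MASK)
        out, tally = filter_sites(table, cfg)
        assert list(out.sites["pos"]) == DIRTY_SURVIVOR_POSITIONS
        assert tally == DIRTY_TALLIES

    def test_tallies_sum_to_removed_count(self, dirty_vcf_text):
        table = parse_pooled_vcf(dirty_vcf_text, pool_n=100)
        out, tally = filter_sites(table, SiteFilterConfig(mask_regions=DIRTY_MASK))
        assert sum(tally.values()) == len(table) - len(out)

    def test_depth_bounds_inclusive(self):
        text = VCF_HEADER + vcf_line(100, "A", "G", 300, 50)
        table = parse_pooled_vcf(text, pool_n=100)
        out, tally = filter_sites(table, SiteFilterConfig())
        assert len(out) == 0 and tally["depth"] == 1

    def test_flank_rule_inclusive_at_five_bp(self, dirty_vcf_text):
        # 1025 is exactly 5 bp from the indel at 1030 and is removed
        table = parse_pooled_vcf(dirty_vcf_text, pool_n=100)
        out, _ = filter_sites(table, SiteFilterConfig(mask_regions=DIRTY_MASK))
        assert 1025 not in set(out.sites["pos"])


class TestDiversity:
    @pytest.mark.parametrize("p,n,expected", [
        (0.0, 100, 0.0),
        (0.5, 100, 2 * 0.25 * 100 / 99),
        (0.1, 100, 2 * 0.09 * 100 / 99),
    ])
    def test_nei_pi_site_values(self, p, n, expected):
        assert nei_pi_site(p, n) == pytest.approx(expected)

    def test_nei_pi_requires_two_chromosomes(self):
        with pytest.raises(ValueError):
            nei_pi_site(0.5, 1)

    @settings(derandomize=True, max_examples=50)
    @given(p=st.floats(0, 1))
    def test_nei_pi_symmetric_and_bounded(self, p):
        n = 100
        assert nei_pi_site(p, n) == pytest.approx(nei_pi_site(1 - p, n))
        assert nei_pi_site(p, n) <= nei_pi_site(0.5, n) + 1e-12

    def test_population_pi_mean_with_monomorphic(self):
        table = make_table([0.0, 0.5], n=100)
        assert population_pi(table) == pytest.approx(
            0.5 * (0 + 2 * 0.25 * 100 / 99))

    def test_population_pi_matches_site_loop(self):
        rng = np.random.default_rng(0)
        freqs = rng.uniform(0, 1, 100)
        table = make_table(freqs, n=100)
        manual = sum(2 * p * (1 - p) * 100 / 99 for p in freqs) / 100
        assert population_pi(table) == pytest.approx(manual, rel=1e-12)

    def test_population_pi_empty_errors(self):
        with pytest.raises(ValueError):
            population_pi(make_table([]))


class TestFst:
    def test_identical_pools_zero(self):
        a = make_table([0.1, 0.5, 0.9], population_id="a")
        b = make_table([0.1, 0.5, 0.9], population_id="b")
        assert pairwise_fst(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_fixed_difference_is_one(self):
        a = make_table([0.0], population_id="a")
        b = make_table([1.0], population_id="b")
        assert pairwise_fst(a, b) == pytest.approx(1.0)

    def test_five_site_hand_oracle(self):
        pa = [0.2, 0.8, 0.5, 0.0, 1.0]
        pb = [0.4, 0.6, 0.5, 0.0, 0.0]
        n = 100
        num = den = 0.0
        for x, y in zip(pa, pb):
            pw = 0.5 * (2 * x * (1 - x) * n / (n - 1)
                        + 2 * y * (1 - y) * n / (n - 1))
            pbar = 0.5 * (x + y)
            pt = 2 * pbar * (1 - pbar) * n / (n - 1)
            num += pt - pw
            den += pt
        expected = num / den
        got = pairwise_fst(make_table(pa, population_id="a"),
                           make_table(pb, population_id="b"))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_no_shared_sites_errors(self):
        a = make_table([0.5], start_pos=1000, population_id="a")
        b = make_table([0.5], start_pos=9000, population_id="b")
        with pytest.raises(ValueError, match="no shared sites"):
            pairwise_fst(a, b)

    def test_all_monomorphic_returns_nan(self):
        a = make_table([0.0, 0.0], population_id="a")
        b = make_table([0.0, 0.0], population_id="b")
        assert math.isnan(pairwise_fst(a, b))


class TestSpectra:
    def test_folded_sfs_tally(self):
        table = make_table([0.1, 0.9, 0.2], n=10)  # minor counts 1, 1, 2
        sfs = folded_sfs(table)
        assert sfs.counts[1] == 2 and sfs.counts[2] == 1
        assert sfs.n_sites == 3

    def test_folded_sfs_singleton_exclusion(self):
        table = make_table([0.1, 0.9, 0.2], n=10)
        sfs = folded_sfs(table, exclude_singletons=True)
        assert np.isnan(sfs.counts[1])
        assert sfs.counts[2] == 1
        assert sfs.n_masked_singletons == 2
        assert sfs.n_sites == 3  # masked singletons still counted

    def test_folded_sfs_monomorphic_mass_in_bin_zero(self):
        sfs = folded_sfs(make_table([0.0, 0.0], n=10))
        assert sfs.counts[0] == 2

    def test_joint_sfs_hand_enumeration(self):
        # n=10 each; (0.2,0.3)->(2,3); (0.9,0.8)->(9,8) folds to (1,2);
        # (0,0)->(0,0); (0.5,0.6)->(5,6) folds to (5,4)
        a = make_table([0.2, 0.9, 0.0, 0.5], n=10, population_id="a")
        b = make_table([0.3, 0.8, 0.0, 0.6], n=10, population_id="b")
        sfs = joint_2dsfs(a, b, fold=True)
        assert sfs.counts[2, 3] == 1
        assert sfs.counts[1, 2] == 1
        assert sfs.counts[0, 0] == 1
        assert sfs.counts[5, 4] == 1
        assert sfs.n_sites == 4  # conservation

    def test_joint_sfs_half_count_rounds_toward_minor(self):
        # raw count 2.5 in both pools; pooled freq 5/20 <= 1/2 so ALT is
        # minor and the count rounds down
        a = make_table([0.25], n=10, population_id="a")
        b = make_table([0.25], n=10, population_id="b")
        sfs = joint_2dsfs(a, b, fold=True)
        assert sfs.counts[2, 2] == 1

    def test_joint_sfs_site_count_conserved(self):
        rng = np.random.default_rng(3)
        a = make_table(rng.uniform(0, 1, 50), n=20, population_id="a")
        b = make_table(rng.uniform(0, 1, 50), n=20, population_id="b")
        for fold in (False, True):
            assert joint_2dsfs(a, b, fold=fold).n_sites == 50


class TestIBD:
    def test_equator_degree_distance(self):
        assert haversine_km(0, 0, 0, 1) == pytest.approx(111.195, abs=1e-3)

    def test_exact_linear_relation_recovered(self):
        coords = pd.DataFrame({"id": list("abcd"),
                               "lat": [55.0, 55.5, 56.0, 56.5],
                               "lon": [9.0, 9.8, 10.1, 8.9]})
        ids = list(coords["id"])
        lat = dict(zip(ids, coords["lat"]))
        lon = dict(zip(ids, coords["lon"]))
        slope, intercept = 2e-4, 0.01
        k = len(ids)
        mat = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                d = haversine_km(lat[ids[i]], lon[ids[i]],
                                 lat[ids[j]], lon[ids[j]])
                mat[i, j] = mat[j, i] = intercept + slope * d
        res = ibd_regression(FstMatrix(ids, mat), coords)
        assert res.slope == pytest.approx(slope, rel=1e-9)
        assert res.intercept == pytest.approx(intercept, rel=1e-9)
        assert res.r2_adj == pytest.approx(1.0, abs=1e-9)
        assert (res.df_num, res.df_den) == (1, k * (k - 1) // 2 - 2)

    def test_constant_fst_flat_regression(self):
        coords = pd.DataFrame({"id": list("abc"),
                               "lat": [55.0, 56.0, 57.0],
                               "lon": [9.0, 10.0, 9.5]})
        mat = np.full((3, 3), 0.05)
        np.fill_diagonal(mat, 0.0)
        res = ibd_regression(FstMatrix(list("abc"), mat), coords)
        assert res.slope == pytest.approx(0.0, abs=1e-6)
        assert res.r2_adj <= 0

    def test_degenerate_design_errors(self):
        coords = pd.DataFrame({"id": list("abc"),
                               "lat": [55.0, 55.0, 55.0],
                               "lon": [9.0, 9.0, 9.0]})
        mat = np.zeros((3, 3))
        with pytest.raises(ValueError, match="degenerate"):
            ibd_regression(FstMatrix(list("abc"), mat), coords)


class TestUPGMA:
    def test_two_taxa_halved_distance(self):
        mat = np.array([[0.0, 0.3], [0.3, 0.0]])
        nwk = upgma_tree(FstMatrix(["a", "b"], mat))
        assert nwk == "(a:0.15,b:0.15);"

    def test_three_taxon_hand_tree(self):
        mat = np.array([[0.0, 2.0, 8.0],
                        [2.0, 0.0, 8.0],
                        [8.0, 8.0, 0.0]])
        nwk = upgma_tree(FstMatrix(["A", "B", "C"], mat))
        assert nwk == "((A:1,B:1):3,C:4);"

    def test_output_is_ultrametric(self):
        rng = np.random.default_rng(7)
        k = 6
        pts = rng.normal(size=(k, 2))
        mat = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        nwk = upgma_tree(FstMatrix([f"t{i}" for i in range(k)], mat))
        import dendropy
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
        assert max(depths) - min(depths) < 1e-9
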