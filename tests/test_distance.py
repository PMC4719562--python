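"""Genotypic distances, AMOVA (against the coordinate-route oracle),
pairwise FST, Nei's D, haversine, Mantel and regressions."""

import itertools

import numpy as np
import pandas as pd
import pytest

import accdiv as ad
from accdiv.distance import DistanceMatrix

from conftest import amova_components_oracle, amova_ss_oracle, gm, random_matrix


class TestGenotypicDistance:
    def test_identical_individuals_distance_zero(self):
        g = gm({"i1": ("a", "AA AB BB"), "i2": ("a", "AA AB BB")})
        d = ad.genotypic_distance_matrix(g)
        assert d.values[0, 1] == 0

    def test_opposite_homozygotes(self):
        g = gm({"i1": ("a", "AA AA AA"), "i2": ("a", "BB BB BB")})
        assert ad.genotypic_distance_matrix(g).values[0, 1] == 12

    def test_per_locus_table(self):
        g = gm({"i1": ("a", "AA AB BB"), "i2": ("a", "AB AB BB")})
        assert ad.genotypic_distance_matrix(g).values[0, 1] == 1

    def test_missing_pairs_sum_over_shared_loci(self):
        g = gm({"i1": ("a", "AA .. BB"), "i2": ("a", "BB AB ..")})
        assert ad.genotypic_distance_matrix(g).values[0, 1] == 4

    def test_no_shared_loci_rejected(self):
        g = gm({"i1": ("a", "AA .."), "i2": ("a", ".. AA")})
        with pytest.raises(ValueError, match="share no called loci"):
            ad.genotypic_distance_matrix(g)


class TestAMOVA:
    def _grouping(self, g, n_groups=2):
        accs = g.accession_ids
        return {a: f"G{k % n_groups}" for k, a in enumerate(accs)}

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_components_match_coordinate_oracle(self, seed):
        """Distance-route AMOVA equals the definitional coordinate-route SS
        and method-of-moments components on complete-data toy panels."""
        rng = np.random.default_rng(seed)
        g = random_matrix(rng, n_acc=5, n_per_acc=rng.integers(3, 6), n_markers=15)
        grouping = self._grouping(g)
        res = ad.amova(g, grouping, n_perm=0)
        x = g.calls.astype(float)
        acc = np.array([g.accession_of[i] for i in g.individual_ids])
        grp = np.array([grouping[a] for a in acc])
        ss = amova_ss_oracle(x, acc, grp)
        comp = amova_components_oracle(x, acc, grp)
        for level in res.levels:
            assert level.ss == pytest.approx(ss[level.name], abs=1e-8)
            assert level.sigma2 == pytest.approx(comp[level.name], abs=1e-8)

    def test_identical_individuals_zero_everything(self):
        g = gm({f"i{k}": (f"a{k % 2}", "AA AB") for k in range(6)})
        res = ad.amova(g, {"a0": "X", "a1": "Y"}, n_perm=0)
        for level in res.levels:
            assert level.ss == pytest.approx(0) and level.sigma2 == pytest.approx(0)

    def test_single_group_collapses_to_two_levels(self, rng):
        g = random_matrix(rng, n_acc=4, n_per_acc=4, n_markers=12)
        res = ad.amova(g, None, n_perm=0)
        assert [l.name for l in res.levels] == ["among_accessions", "within_accessions"]
        assert sum(l.df for l in res.levels) == g.n_individuals - 1

    def test_df_sum_and_percent_sum(self, rng):
        g = random_matrix(rng, n_acc=6, n_per_acc=4, n_markers=25)
        res = ad.amova(g, self._grouping(g, 3), n_perm=0)
        assert sum(l.df for l in res.levels) == g.n_individuals - 1
        assert sum(l.percent for l in res.levels) == pytest.approx(100, abs=0.1)

    def test_structured_panel_significant_permutation_p(self):
        cfg = ad.SimConfig(n_clusters=2, accessions_per_cluster=4,
                           individuals_per_accession=6, n_markers=150,
                           f_ct=0.2, f_sc=0.05, seed=9)
        ds = ad.simulate_panel(cfg)
        grouping = {a: ds.truth["cluster_of"][a] for a in ds.genotypes.accession_ids}
        res = ad.amova(ds.genotypes, grouping, n_perm=99, seed=5)
        by = {l.name: l for l in res.levels}
        # permuting whole accessions (8 in 2 groups) can reproduce the
        # observed split ~2/70 of the time, so the attainable floor is ~0.03
        assert by["among_groups"].p <= 0.05
        assert by["within_accessions"].p == pytest.approx(0.01)  # floor of 99 perms
        assert by["among_groups"].percent > 10


class TestPairwiseFST:
    def test_complete_differentiation(self):
        rows = {f"i{k}": ("a", "AA AA") for k in range(3)}
        rows |= {f"j{k}": ("b", "BB BB") for k in range(3)}
        g = gm(rows)
        fst, _ = ad.pairwise_fst(g, {"a": "A", "b": "B"}, n_perm=0)
        assert fst.values[0, 1] == pytest.approx(1.0)

    def test_null_split_of_panmictic_population(self):
        cfg = ad.SimConfig(n_clusters=1, accessions_per_cluster=2,
                           individuals_per_accession=30, n_markers=300,
                           f_ct=0.0, f_sc=0.0, seed=77)
        ds = ad.simulate_panel(cfg)
        accs = ds.genotypes.accession_ids
        fst, p = ad.pairwise_fst(ds.genotypes, {accs[0]: "X", accs[1]: "Y"},
                                 n_perm=99, seed=4)
        assert abs(fst.values[0, 1]) < 0.02
        assert p.iloc[0, 1] > 0.05

    def test_matches_two_level_amova_on_toy(self, rng):
        g = random_matrix(rng, n_acc=2, n_per_acc=3, n_markers=10)
        accs = g.accession_ids
        grouping = {accs[0]: "A", accs[1]: "B"}
        fst, _ = ad.pairwise_fst(g, grouping, n_perm=0)
        res = ad.amova(g, None, n_perm=0)  # accessions as the only grouping
        phi = res.phi["phi_st"]
        assert fst.values[0, 1] == pytest.approx(phi, abs=1e-10)

    def test_weir_cockerham_cross_check_same_order(self):
        cfg = ad.SimConfig(n_clusters=2, accessions_per_cluster=3,
                           individuals_per_accession=10, n_markers=300,
                           f_ct=0.15, f_sc=0.0, seed=13)
        ds = ad.simulate_panel(cfg)
        grouping = {a: ds.truth["cluster_of"][a] for a in ds.genotypes.accession_ids}
        theta = ad.weir_cockerham_fst(ds.genotypes, grouping)
        fst_allele, _ = ad.pairwise_fst(ds.genotypes, grouping, n_perm=0, unit="allele")
        assert theta == pytest.approx(fst_allele.values[0, 1], abs=0.05)
        assert 0.05 < theta < 0.3


class TestNeiDistance:
    def test_identity(self):
        f = pd.Series([0.2, 0.8], index=["m1", "m2"])
        assert ad.nei_standard_distance(f, f.copy()) == pytest.approx(0.0)

    def test_hand_computed_single_locus(self):
        fx = pd.Series([0.5], index=["m1"])
        fy = pd.Series([1.0], index=["m1"])
        d = ad.nei_standard_distance(fx, fy)
        assert d == pytest.approx(-np.log(0.5 / np.sqrt(0.5)), abs=1e-6)
        assert d == pytest.approx(0.3466, abs=1e-4)

    def test_disjoint_alleles_give_infinity(self):
        fx = pd.Series([1.0, 1.0])
        fy = pd.Series([0.0, 0.0])
        assert ad.nei_standard_distance(fx, fy) == np.inf

    def test_no_shared_loci_rejected(self):
        fx = pd.Series([0.5], index=["m1"])
        fy = pd.Series([0.5], index=["m2"])
        with pytest.raises(ValueError):
            ad.nei_standard_distance(fx, fy)


class TestHaversine:
    def test_one_degree_latitude(self):
        assert ad.haversine_km(0, 0, 1, 0) == pytest.approx(111.19, abs=0.01)

    def test_symmetry_random_points(self, rng):
        for _ in range(10):
            a = rng.uniform([-80, -170], [80, 170])
            b = rng.uniform([-80, -170], [80, 170])
            assert ad.haversine_km(*a, *b) == pytest.approx(ad.haversine_km(*b, *a))

    def test_matrix_diagonal_zero(self):
        m = ad.haversine_matrix({"x": (10, 10), "y": (20, 20)})
        assert m.values[0, 0] == 0 and m.values[0, 1] > 0


class TestMantel:
    def _dm(self, vals, labels, kind="geographic_km"):
        return DistanceMatrix(tuple(labels), np.asarray(vals, float), kind)

    def test_self_correlation(self):
        rng = np.random.default_rng(3)
        pts = rng.random((5, 5))
        d = pts @ pts.T
        d = d.max() - d
        np.fill_diagonal(d, 0)
        d = (d + d.T) / 2
        a = self._dm(d, list("abcde"))
        r = ad.mantel_test(a, a, n_perm=99, seed=0)
        assert r.r == pytest.approx(1.0)
        assert r.p == pytest.approx(1 / 100)

    def test_exhaustive_enumeration_n4(self):
        """With 4 labels the permutation p matches exact enumeration over 4!."""
        rng = np.random.default_rng(8)
        a_v = np.zeros((4, 4))
        b_v = np.zeros((4, 4))
        iu = np.triu_indices(4, 1)
        a_v[iu] = rng.random(6); a_v += a_v.T
        b_v[iu] = rng.random(6); b_v += b_v.T
        a = self._dm(a_v, list("wxyz"))
        b = self._dm(b_v, list("wxyz"))
        x = a_v[iu]
        obs = np.corrcoef(x, b_v[iu])[0, 1]
        ge = sum(
            np.corrcoef(x, b_v[np.ix_(perm, perm)][iu])[0, 1] >= obs - 1e-12
            for perm in itertools.permutations(range(4))
        )
        exact = ge / 24
        res = ad.mantel_test(a, b, n_perm=4999, seed=1)
        assert res.p == pytest.approx(exact, abs=0.03)

    def test_agrees_with_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import mantel as sk_mantel

        rng = np.random.default_rng(5)
        pts = {f"p{i}": (float(rng.uniform(0, 50)), float(rng.uniform(0, 50)))
               for i in range(7)}
        geo = ad.haversine_matrix(pts)
        noise = geo.values + rng.normal(0, 200, geo.values.shape)
        noise = np.abs((noise + noise.T) / 2)
        np.fill_diagonal(noise, 0)
        b = self._dm(noise, geo.labels)
        ours = ad.mantel_test(geo, b, n_perm=999, seed=2)
        r_sk, p_sk, _ = sk_mantel(
            skbio.DistanceMatrix(geo.values, geo.labels),
            skbio.DistanceMatrix(b.values, b.labels),
            permutations=999, alternative="greater",
        )
        assert ours.r == pytest.approx(float(r_sk), abs=1e-9)
        assert ours.p == pytest.approx(float(p_sk), abs=0.05)

    def test_constant_matrix_rejected(self):
        a = self._dm(1 - np.eye(3), list("abc"))
        ones = 1 - np.eye(3)
        b = self._dm(ones * 2, list("abc"))
        with pytest.raises(ValueError):
            ad.mantel_test(a, b)


class TestDiversityGeography:
    def test_linear_in_latitude(self):
        he = {f"a{i}": 0.1 + 0.02 * i for i in range(5)}
        coords = {f"a{i}": (40.0 + i, 10.0 + 0.3 * i) for i in range(5)}
        res = ad.diversity_geography(he, coords, n_perm=99, seed=0)
        assert res["latitude"].r == pytest.approx(1.0)

    def test_pearson_matches_closed_form(self):
        he = {"a": 0.1, "b": 0.3, "c": 0.2, "d": 0.5, "e": 0.4}
        coords = {"a": (40, 1), "b": (42, 5), "c": (44, 2), "d": (46, 8), "e": (48, 3)}
        res = ad.diversity_geography(he, coords, n_perm=99, seed=0)
        x = np.array([40, 42, 44, 46, 48], float)
        y = np.array([0.1, 0.3, 0.2, 0.5, 0.4])
        r_hand = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert res["latitude"].r == pytest.approx(r_hand)

    def test_zero_variance_he_rejected(self):
        he = {f"a{i}": 0.2 for i in range(4)}
        coords = {f"a{i}": (40.0 + i, 10.0) for i in range(4)}
        with pytest.raises(ValueError):
            ad.diversity_geography(he, coords, n_perm=9, seed=0)


class TestGroupComparisons:
    def test_identical_groups_t_zero(self):
        vals = {"a1": 0.2, "a2": 0.3, "a3": 0.2, "a4": 0.3}
        factors = pd.DataFrame(
            {"type": ["w", "w", "c", "c"]}, index=["a1", "a2", "a3", "a4"]
        )
        tab = ad.group_mean_comparisons(vals, factors, pairs=[("type", "w", "c")])
        t_row = tab[tab["test"].str.startswith("ttest")].iloc[0]
        assert t_row["statistic"] == pytest.approx(0.0)
        assert t_row["p"] == pytest.approx(1.0)

    def test_t_statistic_closed_form(self):
        va, vb = [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]
        vals = dict(zip("abcdef", va + vb))
        factors = pd.DataFrame({"grp": ["x"] * 3 + ["y"] * 3}, index=list("abcdef"))
        tab = ad.group_mean_comparisons(vals, factors, pairs=[("grp", "x", "y")])
        t_row = tab[tab["test"].str.startswith("ttest")].iloc[0]
        ma, mb = np.mean(va), np.mean(vb)
        sp = np.sqrt((np.var(va, ddof=1) * 2 + np.var(vb, ddof=1) * 2) / 4)
        t_hand = (ma - mb) / (sp * np.sqrt(2 / 3))
        assert t_row["statistic"] == pytest.approx(t_hand)

    def test_oneway_anova_brute_force(self):
        groups = {"g1": [1.0, 2.0], "g2": [2.0, 4.0], "g3": [5.0, 7.0]}
        vals, fac = {}, {}
        for gname, xs in groups.items():
            for k, v in enumerate(xs):
                vals[f"{gname}_{k}"] = v
                fac[f"{gname}_{k}"] = gname
        factors = pd.DataFrame({"grp": pd.Series(fac)})
        tab = ad.group_mean_comparisons(vals, factors)
        f_row = tab[tab["test"] == "oneway_anova[grp]"].iloc[0]
        all_vals = np.array(sum(groups.values(), []))
        grand = all_vals.mean()
        ss_between = sum(len(xs) * (np.mean(xs) - grand) ** 2 for xs in groups.values())
        ss_within = sum(((np.array(xs) - np.mean(xs)) ** 2).sum() for xs in groups.values())
        f_hand = (ss_between / 2) / (ss_within / 3)
        assert f_row["statistic"] == pytest.approx(f_hand)

    def test_tiny_t_group_rejected(self):
        vals = {"a": 1.0, "b": 2.0, "c": 3.0}
        factors = pd.DataFrame({"grp": ["x", "y", "y"]}, index=["a", "b", "c"])
        with pytest.raises(ValueError):
            ad.group_mean_comparisons(vals, factors, pairs=[("grp", "x", "y")])
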