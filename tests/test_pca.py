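"""PCA, PC dispersion (isometry with the input space) and near-identical
individual detection."""

import numpy as np
import pandas as pd
import pytest

import accdiv as ad
from accdiv.pca import centered_imputed_dosages

from conftest import gm, random_matrix


class TestAccessionPCA:
    def test_identical_accessions_collapse_to_origin(self):
        freqs = pd.DataFrame([[0.5, 0.2], [0.5, 0.2], [0.5, 0.2]],
                             index=["a", "b", "c"], columns=["m1", "m2"])
        res = ad.accession_frequency_pca(freqs)
        np.testing.assert_allclose(res.coordinates, 0, atol=1e-12)

    def test_toy_matches_hand_eigendecomposition(self):
        freqs = pd.DataFrame([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]],
                             index=["a", "b", "c"], columns=["m1", "m2"])
        res = ad.accession_frequency_pca(freqs)
        x = freqs.to_numpy() - freqs.to_numpy().mean(axis=0)
        cov = x.T @ x / 2
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(res.explained_variance, evals, atol=1e-12)
        # pairwise distances preserved by the rotation
        for i in range(3):
            for j in range(3):
                assert np.linalg.norm(res.coordinates[i] - res.coordinates[j]) == \
                    pytest.approx(np.linalg.norm(x[i] - x[j]), abs=1e-10)

    def test_explained_variance_conserves_total(self, rng):
        freqs = pd.DataFrame(rng.random((6, 10)))
        res = ad.accession_frequency_pca(freqs)
        total = freqs.to_numpy().var(axis=0, ddof=1).sum()
        assert res.explained_variance.sum() == pytest.approx(total)

    def test_allele_flip_leaves_coordinates_unchanged_up_to_sign(self, rng):
        freqs = pd.DataFrame(rng.random((5, 8)))
        flipped = freqs.copy()
        flipped.iloc[:, [1, 4]] = 1 - flipped.iloc[:, [1, 4]]
        a = ad.accession_frequency_pca(freqs)
        b = ad.accession_frequency_pca(flipped)
        np.testing.assert_allclose(np.abs(a.coordinates), np.abs(b.coordinates), atol=1e-9)

    def test_fewer_than_two_accessions_rejected(self):
        with pytest.raises(ValueError):
            ad.accession_frequency_pca(pd.DataFrame([[0.5]], index=["a"]))


class TestIndividualPCA:
    def test_duplicate_individuals_identical_coordinates(self):
        g = gm({"i1": ("a", "AA AB BB"), "i2": ("a", "AA AB BB"), "i3": ("a", "BB AA AB")})
        res = ad.individual_pca(g)
        np.testing.assert_allclose(res.coordinates[0], res.coordinates[1], atol=1e-12)

    def test_isometry_with_centered_imputed_space(self, rng):
        """Full PC space is a rotation: pairwise distances equal those in the
        centered, mean-imputed genotype space."""
        g = random_matrix(rng, n_acc=3, n_per_acc=4, n_markers=25, missing_rate=0.15)
        res = ad.individual_pca(g)
        x = centered_imputed_dosages(g, list(g.individual_ids))
        n = g.n_individuals
        for i in range(n):
            for j in range(i + 1, n):
                d_pc = np.linalg.norm(res.coordinates[i] - res.coordinates[j])
                d_x = np.linalg.norm(x[i] - x[j])
                assert d_pc == pytest.approx(d_x, abs=1e-8)

    def test_all_missing_locus_rejected(self):
        g = gm({"i1": ("a", ".. AA"), "i2": ("a", ".. AB")})
        with pytest.raises(ValueError):
            ad.individual_pca(g)


class TestPCDispersion:
    def test_identical_members_zero_dispersion(self):
        g = gm({"i1": ("a", "AA AB"), "i2": ("a", "AA AB"), "i3": ("b", "BB AA"),
                "i4": ("b", "AB AB")})
        res = ad.individual_pca(g)
        disp, _ = ad.pc_dispersion(res, dict(g.accession_of))
        by = {d.accession_id: d for d in disp}
        assert by["a"].mean_distance == pytest.approx(0.0, abs=1e-10)
        assert by["a"].var_distance == pytest.approx(0.0, abs=1e-10)

    def test_two_members_variance_zero(self):
        g = gm({"i1": ("a", "AA AA"), "i2": ("a", "BB BB"), "i3": ("b", "AB AB"),
                "i4": ("b", "AB AA")})
        res = ad.individual_pca(g)
        disp, _ = ad.pc_dispersion(res, dict(g.accession_of))
        by = {d.accession_id: d for d in disp}
        assert by["a"].var_distance == pytest.approx(0.0, abs=1e-12)
        assert by["a"].mean_distance > 0

    def test_matches_brute_force_on_raw_centered_data(self, rng):
        g = random_matrix(rng, n_acc=2, n_per_acc=5, n_markers=30, missing_rate=0.1)
        res = ad.individual_pca(g)
        disp, _ = ad.pc_dispersion(res, dict(g.accession_of))
        x = centered_imputed_dosages(g, list(g.individual_ids))
        idx = {ind: k for k, ind in enumerate(g.individual_ids)}
        for d in disp:
            members = g.members_of(d.accession_id)
            dists = [
                np.linalg.norm(x[idx[a]] - x[idx[b]])
                for i, a in enumerate(members)
                for b in members[i + 1:]
            ]
            assert d.mean_distance == pytest.approx(np.mean(dists), abs=1e-8)
            assert d.var_distance == pytest.approx(np.var(dists), abs=1e-8)

    def test_singleton_accessions_skipped_with_notice(self):
        g = gm({"i1": ("a", "AA AB"), "i2": ("b", "AB AA"), "i3": ("b", "BB AB")})
        res = ad.individual_pca(g)
        disp, skipped = ad.pc_dispersion(res, dict(g.accession_of))
        assert skipped == ["a"]
        assert [d.accession_id for d in disp] == ["b"]


class TestNearIdentical:
    def test_exact_duplicates_flagged_at_ibs_one(self, rng):
        g = random_matrix(rng, n_acc=1, n_per_acc=2, n_markers=120)
        dup = ad.GenotypeMatrix(
            g.individual_ids, g.marker_ids,
            np.vstack([g.calls[0], g.calls[0]]), dict(g.accession_of),
        )
        flags = ad.flag_near_identical(dup)
        assert len(flags) == 1
        assert flags.iloc[0]["ibs"] == 1.0

    def test_one_mismatch_in_100_loci_sits_on_threshold(self):
        calls = np.zeros((2, 100), dtype=np.int8)
        calls[1, 0] = 1
        g = ad.GenotypeMatrix(("i1", "i2"), tuple(f"m{j}" for j in range(100)),
                              calls, {"i1": "a", "i2": "a"})
        flags = ad.flag_near_identical(g, ibs_threshold=0.99)
        assert len(flags) == 1 and flags.iloc[0]["ibs"] == pytest.approx(0.99)

    def test_distinct_panel_not_flagged(self):
        cfg = ad.SimConfig(n_clusters=1, accessions_per_cluster=3,
                           individuals_per_accession=5, n_markers=200,
                           f_ct=0.0, f_sc=0.05, seed=55)
        ds = ad.simulate_panel(cfg)
        assert ad.flag_near_identical(ds.genotypes).empty

    def test_clones_detected_and_dropped_deterministically(self):
        cfg = ad.SimConfig(n_clusters=1, accessions_per_cluster=3,
                           individuals_per_accession=5, n_markers=200,
                           f_ct=0.0, f_sc=0.05, seed=56,
                           clone_spec=(ad.CloneSpec("C1A01", 1, 0.002),))
        ds = ad.simulate_panel(cfg)
        flags = ad.flag_near_identical(ds.genotypes)
        truth_clones = {c["clone"] for c in ds.truth["clones"]}
        flagged = set(flags["individual_a"]) | set(flags["individual_b"])
        assert truth_clones & flagged
        reduced = ad.drop_flagged_duplicates(ds.genotypes, flags)
        assert reduced.n_individuals == ds.genotypes.n_individuals - len(flags)
        # kept member is the lexicographically first of each pair
        for _, row in flags.iterrows():
            keep = min(row["individual_a"], row["individual_b"])
            assert keep in reduced.individual_ids

    def test_duplicate_removal_bounds_diversity_shift(self, rng):
        """Dropping a duplicate changes within-accession Ho/He by no more than
        the leave-one-out bound computed directly."""
        g = random_matrix(rng, n_acc=1, n_per_acc=4, n_markers=150)
        dup_calls = np.vstack([g.calls, g.calls[0]])
        ids = g.individual_ids + ("a0dup",)
        acc = dict(g.accession_of) | {"a0dup": "acc0"}
        gd = ad.GenotypeMatrix(ids, g.marker_ids, dup_calls, acc)
        flags = ad.flag_near_identical(gd)
        reduced = ad.drop_flagged_duplicates(gd, flags)
        he_before = ad.locus_stats(gd, gd.individual_ids)["he"].mean()
        he_after = ad.locus_stats(reduced, reduced.individual_ids)["he"].mean()
        # direct leave-one-out bound: max shift over single removals
        bound = max(
            abs(
                ad.locus_stats(
                    gd, [i for i in gd.individual_ids if i != drop]
                )["he"].mean() - he_before
            )
            for drop in gd.individual_ids
        )
        assert abs(he_after - he_before) <= bound + 1e-12

    def test_invalid_threshold_rejected(self):
        g = gm({"i1": ("a", "AA"), "i2": ("a", "AA")})
        with pytest.raises(ValueError):
            ad.flag_near_identical(g, ibs_threshold=1.5)
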