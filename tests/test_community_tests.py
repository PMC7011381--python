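"""Permutation tests vs enumeration/closed-form oracles; rank-test wrappers."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from skbio.stats.distance import DistanceMatrix

from recoverymics.core_io import CountTable
from recoverymics.community_tests import (
    bh_adjust,
    betadisper,
    differential_abundance,
    fisher_exact_2x2,
    kruskal_wallis,
    mrpp,
    pairwise_permutation_tests,
    pcoa,
    permanova,
    wilcoxon_rank_sum,
)


def euclidean_dm(x, ids=None):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1:
        x = x.T
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    ids = ids or [f"s{i}" for i in range(len(x))]
    return DistanceMatrix(d, ids=ids)


def enumerate_splits_p(dm, labels, stat_fn, tail):
    """Oracle: exact p over all distinct label assignments."""
    labels = np.asarray(labels)
    obs = stat_fn(labels)
    seen, vals = set(), []
    for perm in itertools.permutations(labels):
        if perm in seen:
            continue
        seen.add(perm)
        vals.append(stat_fn(np.asarray(perm)))
    vals = np.asarray(vals)
    if tail == "upper":
        return float(np.mean(vals >= obs - 1e-12))
    return float(np.mean(vals <= obs + 1e-12))


class TestPermanova:
    def test_pseudo_f_equals_anova_f_euclidean_1d(self, rng):
        x = rng.normal(size=9)
        labels = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        dm = euclidean_dm(x)
        res = permanova(dm, labels, n_perm=9, seed=0)
        f_ref = stats.f_oneway(x[:3], x[3:6], x[6:]).statistic
        assert res.statistic == pytest.approx(f_ref, abs=1e-10)

    def test_exact_matches_enumeration_n6(self, rng):
        x = rng.normal(size=(6, 2))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        dm = euclidean_dm(x)
        res = permanova(dm, labels, method="exact")
        from recoverymics.community_tests import _pseudo_f

        d2 = dm.data**2
        p_oracle = enumerate_splits_p(dm, labels, lambda lab: _pseudo_f(d2, lab), "upper")
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)
        assert res.n_permutations == 20

    def test_seeded_permutations_reproducible(self, rng):
        dm = euclidean_dm(rng.normal(size=(12, 3)))
        labels = np.array(["a", "b"] * 6)
        p1 = permanova(dm, labels, n_perm=199, seed=42).p_value
        p2 = permanova(dm, labels, n_perm=199, seed=42).p_value
        assert p1 == p2

    def test_p_never_zero(self, rng):
        x = np.concatenate([rng.normal(0, 1, 6), rng.normal(40, 1, 6)])
        dm = euclidean_dm(x)
        labels = np.array(["a"] * 6 + ["b"] * 6)
        res = permanova(dm, labels, n_perm=99, seed=0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_singleton_group_rejected(self, rng):
        dm = euclidean_dm(rng.normal(size=5))
        with pytest.raises(ValueError, match="singleton"):
            permanova(dm, ["a", "a", "a", "a", "b"], n_perm=9)

    def test_matches_skbio_permanova(self, rng):
        """Cross-check statistic against the independent scikit-bio code."""
        from skbio.stats.distance import permanova as sk_permanova

        x = rng.normal(size=(10, 3))
        x[5:] += 1.5
        dm = euclidean_dm(x)
        labels = ["a"] * 5 + ["b"] * 5
        ours = permanova(dm, labels, n_perm=99, seed=1)
        theirs = sk_permanova(dm, grouping=list(labels), permutations=99)
        assert ours.statistic == pytest.approx(theirs["test statistic"], abs=1e-10)

    def test_strata_restrict_permutations(self, rng):
        x = rng.normal(size=8)
        dm = euclidean_dm(x)
        labels = np.array(["a", "b"] * 4)
        strata = np.repeat([1, 2, 3, 4], 2)
        res = permanova(dm, labels, n_perm=99, seed=0, strata=strata)
        assert 0 < res.p_value <= 1


class TestMRPP:
    def test_no_structure_gives_A_near_zero(self, rng):
        # exchangeable points, arbitrary labels: delta ~ its permutation mean
        pts = rng.normal(size=8)
        labels = np.array(["a", "b"] * 4)
        res = mrpp(euclidean_dm(pts), labels, method="exact")
        assert abs(res.effect_size) < 0.2
        assert res.p_value > 0.1

    def test_separated_clusters_significant(self):
        pts = np.array([0.0, 0.1, 0.2, 10.0, 10.1, 10.2])
        labels = np.array(["a"] * 3 + ["b"] * 3)
        res = mrpp(euclidean_dm(pts), labels, method="exact")
        assert res.effect_size > 0
        # the true partition and its label swap are the only minimal-delta
        # assignments among the 20
        assert res.p_value == pytest.approx(2 / 20)

    def test_exact_matches_enumeration_n6(self, rng):
        x = rng.normal(size=(6, 2))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        dm = euclidean_dm(x)
        from recoverymics.community_tests import _mrpp_delta

        res = mrpp(dm, labels, method="exact")
        p_oracle = enumerate_splits_p(dm, labels, lambda lab: _mrpp_delta(dm.data, lab), "lower")
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)


class TestPCoA:
    def test_three_equidistant_points(self):
        dm = DistanceMatrix(np.ones((3, 3)) - np.eye(3), ids=list("abc"))
        res = pcoa(dm)
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1], abs=1e-10)
        assert not res.has_negative

    def test_recovers_euclidean_configuration(self, rng):
        x = rng.normal(size=(8, 2))
        res = pcoa(euclidean_dm(x))
        y = res.coords_real[:, :2]
        # Procrustes: optimal rotation of centered configs
        xc = x - x.mean(0)
        yc = y - y.mean(0)
        u, _, vt = np.linalg.svd(yc.T @ xc)
        rot = u @ vt
        rms = np.sqrt(((yc @ rot - xc) ** 2).mean())
        assert rms < 1e-8

    def test_reconstruction_identity_non_euclidean(self, rng):
        # random symmetric dissimilarity: negative eigenvalues expected
        a = rng.random((7, 7))
        d = (a + a.T) / 2
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(7)])
        res = pcoa(dm)
        assert res.has_negative
        for i in range(7):
            for j in range(7):
                dr = ((res.coords_real[i] - res.coords_real[j]) ** 2).sum()
                di = ((res.coords_imag[i] - res.coords_imag[j]) ** 2).sum()
                assert dr - di == pytest.approx(d[i, j] ** 2, abs=1e-8)


class TestBetadisper:
    def test_mirror_groups_f_zero(self):
        pts = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        labels = np.array(["a"] * 3 + ["b"] * 3)
        res = betadisper(euclidean_dm(pts), labels, method="exact")
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value > 0.9

    def test_levene_type_oracle_euclidean_1d(self, rng):
        x = np.concatenate([rng.normal(0, 1, 6), rng.normal(0, 4, 6)])
        labels = np.array(["a"] * 6 + ["b"] * 6)
        res = betadisper(euclidean_dm(x), labels, n_perm=9, seed=0)
        z = np.abs(
            np.concatenate([x[:6] - x[:6].mean(), x[6:] - x[6:].mean()])
        )
        f_ref = stats.f_oneway(z[:6], z[6:]).statistic
        assert res.statistic == pytest.approx(f_ref, abs=1e-10)

    def test_dispersion_difference_detected(self, rng):
        hits = 0
        for seed in range(20):
            g = np.random.default_rng(seed)
            x = np.concatenate([g.normal(0, 0.2, 8), g.normal(0, 4, 8)])
            labels = np.array(["a"] * 8 + ["b"] * 8)
            res = betadisper(euclidean_dm(x), labels, n_perm=199, seed=seed)
            hits += res.p_value <= 0.05
        assert hits >= 18

    def test_exact_matches_enumeration_n6(self, rng):
        x = rng.normal(size=(6, 2))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        dm = euclidean_dm(x)
        from recoverymics.community_tests import _anova_f, _centroid_distances

        res_obj = pcoa(dm)
        res = betadisper(dm, labels, method="exact")
        p_oracle = enumerate_splits_p(
            dm, labels, lambda lab: _anova_f(_centroid_distances(res_obj, lab), lab), "upper"
        )
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)


class TestRankTests:
    def test_kruskal_hand_formula_disjoint_groups(self):
        values = np.array([1.0, 2, 3, 4, 5, 6])
        groups = np.array(["a", "a", "b", "b", "c", "c"])
        h, p = kruskal_wallis(values, groups)
        n = 6
        rsum = {"a": 1 + 2, "b": 3 + 4, "c": 5 + 6}
        h_ref = 12 / (n * (n + 1)) * sum(v**2 / 2 for v in rsum.values()) - 3 * (n + 1)
        assert h == pytest.approx(h_ref, abs=1e-10)

    def test_all_tied_returns_null(self):
        h, p = kruskal_wallis([1.0, 1, 1, 1], ["a", "a", "b", "b"])
        assert h == 0.0 and p == 1.0

    def test_wilcoxon_enumeration_oracle(self):
        w, p = wilcoxon_rank_sum([1.0, 2.0], [3.0, 4.0])
        assert p == pytest.approx(1 / 3, abs=1e-12)  # 2 extreme of 6 splits
        assert w == 3.0  # ranks 1+2

    def test_wilcoxon_identical_samples(self):
        _, p = wilcoxon_rank_sum([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert p > 0.97

    def test_wilcoxon_approx_close_to_exact(self, rng):
        x, y = rng.normal(size=8), rng.normal(0.5, 1, size=8)
        _, p_exact = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        _, p_norm = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert abs(p_exact - p_norm) < 0.02

    def test_fisher_extreme_table(self):
        orat, p = fisher_exact_2x2([[0, 5], [5, 0]])
        assert p == pytest.approx(2 / 252, abs=1e-12)

    def test_fisher_independence(self):
        orat, p = fisher_exact_2x2([[3, 7], [3, 7]])
        assert orat == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_fisher_enumeration_oracle(self):
        # sum of hypergeometric probabilities <= observed table's
        table = [[3, 1], [1, 3]]
        obs_p = stats.hypergeom.pmf(3, 8, 4, 4)
        total = sum(
            stats.hypergeom.pmf(k, 8, 4, 4)
            for k in range(5)
            if stats.hypergeom.pmf(k, 8, 4, 4) <= obs_p + 1e-12
        )
        _, p = fisher_exact_2x2(table)
        assert p == pytest.approx(total, abs=1e-10)


class TestBHAdjust:
    def test_equal_inputs_unchanged(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_step_up_formula(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_never_decreases(self, rng):
        p = rng.random(50)
        assert (bh_adjust(p) >= p - 1e-12).all()

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestDifferentialAbundance:
    def _table(self, rng, shift_otu=None, factor=10.0, n_per=24, S=40):
        base = rng.integers(5, 50, size=S)
        counts = rng.poisson(base, size=(2 * n_per, S))
        if shift_otu is not None:
            counts[n_per:, shift_otu] = rng.poisson(base[shift_otu] * factor, size=n_per)
        meta = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(2 * n_per)],
                "treatment": ["Ctrl"] * n_per + ["CC"] * n_per,
                "habitat": "gut", "timepoint": "T3", "tank": 1, "replicate": 1,
            }
        )
        tab = CountTable(meta["sample_id"].tolist(), [f"o{j}" for j in range(S)], counts)
        return tab, meta

    def test_null_rarely_significant(self):
        quiet = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            tab, meta = self._table(rng)
            out = differential_abundance(tab, meta, contrast=("Ctrl", "CC"))
            quiet += out["p_adj"].min() >= 0.05
        assert quiet >= 19

    def test_shifted_taxon_detected(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            tab, meta = self._table(rng, shift_otu=3)
            out = differential_abundance(tab, meta, contrast=("Ctrl", "CC"))
            hits += out.loc[out["otu_id"] == "o3", "p_adj"].iloc[0] <= 0.05
        assert hits >= 9

    def test_row_per_taxon_no_drops(self, rng):
        tab, meta = self._table(rng)
        for test in ("wilcoxon", "fisher_presence"):
            out = differential_abundance(tab, meta, contrast=("Ctrl", "CC"), test=test)
            assert len(out) == tab.n_otus

    def test_absent_contrast_level_rejected(self, rng):
        tab, meta = self._table(rng)
        with pytest.raises(ValueError, match="CV"):
            differential_abundance(tab, meta, contrast=("Ctrl", "CV"))


def test_pairwise_tests_shape_and_bh_family(rng):
    x = np.concatenate([rng.normal(0, 1, 5), rng.normal(3, 1, 5), rng.normal(6, 1, 5)])
    labels = pd.Series(
        ["a"] * 5 + ["b"] * 5 + ["c"] * 5, index=[f"s{i}" for i in range(15)]
    )
    dm = euclidean_dm(x, ids=list(labels.index))
    out = pairwise_permutation_tests(dm, labels, n_perm=99, seed=0)
    assert len(out) == 3 * 3  # 3 tests x 3 pairs
    for test in out["test"].unique():
        sub = out[out["test"] == test]
        assert np.allclose(
            sub["p_adj"].to_numpy(), bh_adjust(sub["p"].to_numpy()), atol=1e-12
        )
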