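import numpy as np
import pandas as pd
import pytest
import scipy.stats as ss
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from pgpbcomp.phylo import parse_newick
from pgpbcomp.stats import (
    bm_covariance,
    enrichment_scan,
    one_way_anova,
    pca,
    permanova,
    phylo_pca,
    significance_tier,
    student_t,
)
from tests.conftest import euclidean_dm


class TestSignificanceTier:
    @pytest.mark.parametrize(
        "p,tier",
        [
            (1e-4, "****"),
            (1.0001e-4, "***"),
            (1e-3, "***"),
            (0.0011, "**"),
            (0.01, "**"),
            (0.011, "*"),
            (0.05, "*"),
            (0.0501, "ns"),
            (1.0, "ns"),
            (0.0, "****"),
        ],
    )
    def test_boundaries(self, p, tier):
        assert significance_tier(p) == tier

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            significance_tier(1.5)
        with pytest.raises(ValueError):
            significance_tier(-0.1)


class TestStudentT:
    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 20)
        y = rng.normal(0.5, 1, 25)
        res = student_t(x, y)
        ref = ss.ttest_ind(x, y, equal_var=True)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)
        assert res.df == (43.0,)

    def test_identical_constant_samples(self):
        res = student_t([3.0, 3.0, 3.0], [3.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == 1.0 and res.tier == "ns"

    def test_constant_unequal_samples(self):
        res = student_t([3.0, 3.0], [5.0, 5.0])
        assert np.isinf(res.statistic) and res.statistic < 0
        assert res.p_value > 0 and res.tier == "****"

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            student_t([1.0], [2.0, 3.0])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            student_t([1.0, np.nan], [2.0, 3.0])


class TestAnova:
    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = rng.normal(0, 1, 12)
            y = rng.normal(0.8, 1, 15)
            t = student_t(x, y)
            f = one_way_anova([x, y])
            assert f.statistic == pytest.approx(t.statistic**2, abs=1e-9)
            assert f.p_value == pytest.approx(t.p_value, abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1, 10) for m in (0, 0.5, 1.5)]
        res = one_way_anova(groups)
        ref = ss.f_oneway(*groups)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.df == (2.0, 27.0)

    def test_all_identical(self):
        res = one_way_anova([[2.0, 2.0], [2.0, 2.0, 2.0]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_constant_groups_unequal_means(self):
        res = one_way_anova([[1.0, 1.0], [2.0, 2.0]])
        assert np.isinf(res.statistic) and res.tier == "****"

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 2.0]])


def random_frame(n, p, seed):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(n, p)),
        index=[f"s{i}" for i in range(n)],
        columns=[f"f{j}" for j in range(p)],
    )


class TestPCA:
    def test_perfectly_correlated_single_component(self):
        x = np.arange(10.0)
        df = pd.DataFrame(
            {"a": x, "b": 2 * x}, index=[f"s{i}" for i in range(10)]
        )
        res = pca(df)
        assert res.explained[0] == pytest.approx(1.0, abs=1e-12)

    def test_reconstruction_identity(self):
        df = random_frame(15, 4, seed=4)
        res = pca(df)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T + res.mean
        np.testing.assert_allclose(recon, df.to_numpy(), atol=1e-8)

    def test_explained_sums_to_one(self):
        res = pca(random_frame(12, 5, seed=5))
        assert res.explained.sum() == pytest.approx(1.0, abs=1e-12)

    def test_loadings_orthonormal(self):
        res = pca(random_frame(20, 4, seed=6))
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-9)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            pca(random_frame(1, 3, seed=0))


def star_tree(n, length=1.0):
    leaves = ",".join(f"s{i}:{length}" for i in range(n))
    return parse_newick(f"({leaves});")


class TestPhyloPCA:
    def test_star_tree_reduces_to_pca(self):
        df = random_frame(10, 4, seed=7)
        tree = star_tree(10)
        plain = pca(df)
        phylo = phylo_pca(df, tree)
        np.testing.assert_allclose(
            phylo.scores.to_numpy(), plain.scores.to_numpy(), atol=1e-8
        )
        np.testing.assert_allclose(
            phylo.loadings.to_numpy(), plain.loadings.to_numpy(), atol=1e-8
        )
        np.testing.assert_allclose(phylo.explained, plain.explained, atol=1e-10)

    def test_bm_covariance_structure(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        C = bm_covariance(tree, ["A", "B", "C"])
        expect = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
        np.testing.assert_allclose(C, expect, atol=1e-12)

    def test_row_permutation_equivariance(self):
        df = random_frame(8, 3, seed=8)
        tree = star_tree(8, length=2.0)
        res1 = phylo_pca(df, tree)
        perm = list(df.index)[::-1]
        res2 = phylo_pca(df.loc[perm], tree)
        np.testing.assert_allclose(
            res1.scores.loc[perm].to_numpy(), res2.scores.to_numpy(), atol=1e-8
        )

    def test_singular_covariance_rejected(self):
        # two tips at zero distance make C singular
        tree = parse_newick("((A:0,B:0):1,(C:1,D:1):1);")
        df = random_frame(4, 3, seed=9)
        df.index = ["A", "B", "C", "D"]
        with pytest.raises(ValueError, match="jitter"):
            phylo_pca(df, tree)


def labelled_blobs(n_per, shift, seed, groups=("LA", "SA")):
    rng = np.random.default_rng(seed)
    pts = []
    labels = {}
    ids = []
    for g_i, g in enumerate(groups):
        block = rng.normal(size=(n_per, 3))
        block[:, 0] += g_i * shift
        pts.append(block)
        for j in range(n_per):
            sid = f"{g}{j}"
            ids.append(sid)
            labels[sid] = g
    dm = euclidean_dm(np.vstack(pts), ids=ids)
    return dm, labels


class TestPermanova:
    def test_f_matches_skbio(self):
        for seed in range(5):
            dm, labels = labelled_blobs(8, shift=1.0, seed=seed)
            mine = permanova(dm, labels, n_perm=99, seed=0)
            ref = skbio_permanova(
                dm, [labels[s] for s in dm.ids], permutations=0
            )
            assert mine.statistic == pytest.approx(
                float(ref["test statistic"]), abs=1e-10
            )

    def test_direct_sum_of_squares_oracle(self):
        dm, labels = labelled_blobs(6, shift=2.0, seed=11)
        ids = list(dm.ids)
        D2 = dm.data**2
        n = len(ids)
        ss_total = D2.sum() / (2 * n)
        ssw = 0.0
        for g in ("LA", "SA"):
            idx = [i for i, s in enumerate(ids) if labels[s] == g]
            ssw += D2[np.ix_(idx, idx)].sum() / (2 * len(idx))
        f_expect = ((ss_total - ssw) / 1.0) / (ssw / (n - 2))
        res = permanova(dm, labels, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(f_expect, abs=1e-9)

    def test_p_floor_with_strong_separation(self):
        # groups of 15: the chance a random permutation reproduces the exact
        # planted partition (the only way to tie F) is ~1e-8 per draw
        dm, labels = labelled_blobs(15, shift=60.0, seed=12)
        res = permanova(dm, labels, n_perm=999, seed=5)
        assert res.p_value == pytest.approx(0.001)
        assert res.tier == "***"

    def test_deterministic_given_seed(self):
        dm, labels = labelled_blobs(7, shift=0.5, seed=13)
        a = permanova(dm, labels, n_perm=199, seed=9)
        b = permanova(dm, labels, n_perm=199, seed=9)
        assert (a.statistic, a.p_value) == (b.statistic, b.p_value)

    def test_singleton_group_rejected(self):
        dm = euclidean_dm(np.arange(6.0)[:, None])
        labels = {s: ("A" if i else "B") for i, s in enumerate(dm.ids)}
        with pytest.raises(ValueError):
            permanova(dm, labels, n_perm=99, seed=0)

    def test_low_n_perm_rejected(self):
        dm, labels = labelled_blobs(5, shift=1.0, seed=14)
        with pytest.raises(ValueError):
            permanova(dm, labels, n_perm=10, seed=0)

    def test_label_permutation_invariance_of_f(self):
        # F depends on the partition, not which group is called what
        dm, labels = labelled_blobs(6, shift=1.5, seed=15)
        swapped = {s: ("SA" if g == "LA" else "LA") for s, g in labels.items()}
        a = permanova(dm, labels, n_perm=99, seed=1)
        b = permanova(dm, swapped, n_perm=99, seed=1)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)


def feature_frame_with_groups(seed, n_per=12, boost=1.0):
    rng = np.random.default_rng(seed)
    rows, habs, taxa = [], {}, {}
    idx = []
    for c in ("1", "2"):
        for h in ("LA", "SA"):
            for j in range(n_per):
                sid = f"c{c}{h}{j}"
                idx.append(sid)
                habs[sid] = h
                taxa[sid] = c
                gh = rng.normal(10, 1)
                if c == "1" and h == "LA":
                    gh *= boost
                rows.append({"GH": gh, "GT": rng.normal(5, 1)})
    return pd.DataFrame(rows, index=idx), habs, taxa


class TestEnrichmentScan:
    def test_planted_enrichment_flagged(self):
        df, habs, taxa = feature_frame_with_groups(seed=21, boost=2.0)
        out = enrichment_scan(df, habs, taxa)
        hit = out[
            (out["test"] == "t_LA_vs_SA")
            & (out["scope"] == "1")
            & (out["feature"] == "GH")
        ].iloc[0]
        assert hit["testable"] and hit["p"] < 1e-4

    def test_unboosted_cell_usually_ns(self):
        df, habs, taxa = feature_frame_with_groups(seed=22, boost=1.0)
        out = enrichment_scan(df, habs, taxa)
        sub = out[(out["test"] == "t_LA_vs_SA") & (out["feature"] == "GT")]
        assert (sub["p"] > 0.001).all()

    def test_all_zero_feature_untestable_not_dropped(self):
        df, habs, taxa = feature_frame_with_groups(seed=23)
        df["PL"] = 0.0
        out = enrichment_scan(df, habs, taxa)
        pl = out[out["feature"] == "PL"]
        assert len(pl) > 0 and not pl["testable"].any()
        assert pl["p"].isna().all()

    def test_bh_column_bounds(self):
        df, habs, taxa = feature_frame_with_groups(seed=24, boost=1.5)
        out = enrichment_scan(df, habs, taxa)
        ok = out["testable"].astype(bool)
        assert (out.loc[ok, "p_bh"] >= out.loc[ok, "p"] - 1e-12).all()
        assert (out.loc[ok, "p_bh"] <= 1.0 + 1e-12).all()

    def test_missing_grouping_rejected(self):
        df, habs, taxa = feature_frame_with_groups(seed=25)
        habs.pop(df.index[0])
        with pytest.raises(ValueError):
            enrichment_scan(df, habs, taxa)
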