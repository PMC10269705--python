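import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from pgpbcomp.clustering import (
    cluster_composition,
    habitat_concordance,
    hclust_complete,
    mean_silhouette,
    pam,
    select_k,
)
from tests.conftest import (
    PUBLISHED_CLUSTER_COUNTS,
    assignment_from_counts,
    euclidean_dm,
)


def brute_force_pam_objective(D, k):
    n = len(D)
    best = np.inf
    for medoids in itertools.combinations(range(n), k):
        obj = D[list(medoids)].min(axis=0).sum()
        best = min(best, obj)
    return best


def line_dm(points):
    return euclidean_dm(np.asarray(points, dtype=float)[:, None])


class TestPam:
    def test_two_separated_pairs(self):
        dm = line_dm([0, 1, 10, 11])
        a = pam(dm, 2, seed=0)
        assert a.objective == pytest.approx(2.0)
        groups = {frozenset(m) for m in a.cluster_members().values()}
        assert groups == {frozenset({"s000", "s001"}), frozenset({"s002", "s003"})}

    def test_k_equals_n(self):
        dm = line_dm([0, 3, 7, 20])
        a = pam(dm, 4, seed=0)
        assert a.objective == 0.0
        assert len(set(a.medoids.values())) == 4

    def test_k_one_is_distance_sum_minimizer(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(15, 2))
        dm = euclidean_dm(pts)
        a = pam(dm, 1, seed=0)
        D = dm.data
        expected = list(dm.ids)[int(D.sum(axis=0).argmin())]
        assert a.medoids[1] == expected

    def test_invalid_k(self):
        dm = line_dm([0, 1, 2])
        with pytest.raises(ValueError):
            pam(dm, 0, seed=0)
        with pytest.raises(ValueError):
            pam(dm, 4, seed=0)

    def test_matches_exhaustive_optimum(self):
        rng = np.random.default_rng(77)
        for trial in range(10):
            n = int(rng.integers(5, 13))
            k = int(rng.integers(2, 4))
            pts = rng.normal(size=(n, 2))
            dm = euclidean_dm(pts)
            a = pam(dm, k, seed=trial)
            assert a.objective == pytest.approx(
                brute_force_pam_objective(dm.data, k), abs=1e-9
            )

    def test_medoids_belong_to_their_cluster(self):
        dm = line_dm([0, 0, 5, 5, 9])
        a = pam(dm, 2, seed=0)
        for c, m in a.medoids.items():
            assert a.cluster_of[m] == c


class TestSilhouette:
    def test_worked_example(self):
        dm = line_dm([0, 1, 10, 11])
        a = pam(dm, 2, seed=0)
        # direct per-point evaluation: s = (b - a) / max(a, b)
        s0 = (10.5 - 1) / 10.5
        s1 = (9.5 - 1) / 9.5
        expected = (2 * s0 + 2 * s1) / 4
        assert mean_silhouette(dm, a) == pytest.approx(expected, abs=1e-9)
        assert mean_silhouette(dm, a) == pytest.approx(0.8997, abs=2e-4)

    def test_all_equal_distances_give_zero(self):
        D = np.ones((6, 6)) - np.eye(6)
        dm = DistanceMatrix(D, [f"s{i}" for i in range(6)])
        a = pam(dm, 2, seed=0)
        assert mean_silhouette(dm, a) == pytest.approx(0.0, abs=1e-12)

    def test_separation_limit(self):
        vals = []
        for sep in (10.0, 100.0, 1000.0):
            dm = line_dm([0, 0.001, sep, sep + 0.001])
            a = pam(dm, 2, seed=0)
            vals.append(mean_silhouette(dm, a))
        assert vals == sorted(vals) and vals[-1] > 0.999

    def test_undefined_for_k1(self):
        dm = line_dm([0, 1, 2])
        a = pam(dm, 1, seed=0)
        with pytest.raises(ValueError):
            mean_silhouette(dm, a)

    def test_bounded(self):
        rng = np.random.default_rng(8)
        dm = euclidean_dm(rng.normal(size=(20, 3)))
        for k in (2, 3, 5):
            s = mean_silhouette(dm, pam(dm, k, seed=0))
            assert -1.0 <= s <= 1.0


def planted_blobs(k, n_per, sep, seed, dim=2):
    rng = np.random.default_rng(seed)
    pts = []
    truth = []
    for c in range(k):
        center = np.zeros(dim)
        center[0] = c * sep
        pts.append(rng.normal(scale=1.0, size=(n_per, dim)) + center)
        truth += [c] * n_per
    return euclidean_dm(np.vstack(pts)), np.array(truth)


class TestSelectK:
    @pytest.mark.parametrize("k_true", [2, 4])
    def test_recovers_planted_k(self, k_true):
        hits = 0
        for seed in range(10):
            dm, _ = planted_blobs(k_true, 12, sep=12.0, seed=seed)
            sel = select_k(dm, 2, 8, seed=seed)
            hits += sel.k_best == k_true
        assert hits >= 9

    def test_k_max_clipped_with_warning(self):
        dm, _ = planted_blobs(2, 3, sep=10.0, seed=0)  # n = 6
        with pytest.warns(UserWarning, match="clipped"):
            sel = select_k(dm, 2, 20, seed=0)
        assert max(k for k, _ in sel.curve) == 5

    def test_curve_is_complete(self):
        dm, _ = planted_blobs(3, 5, sep=8.0, seed=1)
        sel = select_k(dm, 2, 6, seed=1)
        assert [k for k, _ in sel.curve] == [2, 3, 4, 5, 6]


class TestHclustComplete:
    def test_two_blobs_perfect_split(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.uniform(0, 1, size=(10, 3)),
                       rng.uniform(10, 11, size=(10, 3))])
        df = pd.DataFrame(X, index=[f"s{i}" for i in range(20)],
                          columns=["a", "b", "c"])
        a = hclust_complete(df, 2)
        groups = {frozenset(m) for m in a.cluster_members().values()}
        assert groups == {
            frozenset(f"s{i}" for i in range(10)),
            frozenset(f"s{i}" for i in range(10, 20)),
        }

    def test_single_cluster(self):
        df = pd.DataFrame(np.arange(12.0).reshape(6, 2),
                          index=[f"s{i}" for i in range(6)], columns=["x", "y"])
        a = hclust_complete(df, 1)
        assert a.k == 1 and set(a.cluster_of.values()) == {1}

    def test_merge_heights_monotone(self):
        from scipy.cluster.hierarchy import linkage

        rng = np.random.default_rng(5)
        X = rng.normal(size=(15, 4))
        Z = linkage(X, method="complete", metric="euclidean")
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_nonfinite_rejected(self):
        df = pd.DataFrame([[1.0, np.nan]], index=["s0"], columns=["x", "y"])
        with pytest.raises(ValueError):
            hclust_complete(df, 1)


class TestComposition:
    def test_published_cluster_shares(self):
        assignment, habitats = assignment_from_counts(PUBLISHED_CLUSTER_COUNTS)
        comp = cluster_composition(assignment, habitats)
        assert comp.loc[1, "LA_pct"] == 61.05
        assert comp.loc[2, "OA_pct"] == 51.28
        assert comp.loc[3, "SA_pct"] == 61.11
        assert comp.loc[4, "SA_pct"] == 86.27
        assert int(comp["total"].sum()) == 573

    def test_single_habitat_cluster(self):
        assignment, habitats = assignment_from_counts({1: {"LA": 7}})
        comp = cluster_composition(assignment, habitats)
        assert comp.loc[1, "LA_pct"] == 100.00

    def test_rows_sum_to_hundred(self):
        assignment, habitats = assignment_from_counts(PUBLISHED_CLUSTER_COUNTS)
        comp = cluster_composition(assignment, habitats)
        pct_cols = [c for c in comp.columns if c.endswith("_pct")]
        for _, row in comp[pct_cols].iterrows():
            assert row.sum() == pytest.approx(100.0, abs=0.02)


class TestConcordance:
    def test_published_counts_give_published_percentages(self):
        counts = {
            1: {"LA": 168, "SA": 10, "OA": 10},
            2: {"LA": 20, "SA": 251, "OA": 4},
            3: {"LA": 7, "SA": 22, "OA": 81},
        }
        assignment, habitats = assignment_from_counts(counts)
        conc = habitat_concordance(assignment, habitats)
        assert conc.total == 573
        assert conc.concordant_n == {"LA": 168, "SA": 251, "OA": 81}
        assert conc.concordant_pct_of_all == {"LA": 29.32, "SA": 43.80, "OA": 14.14}

    def test_single_habitat_single_cluster(self):
        assignment, habitats = assignment_from_counts({1: {"SA": 9}})
        conc = habitat_concordance(assignment, habitats)
        assert conc.concordant_pct_of_all == {"SA": 100.00}

    def test_random_labels_near_majority_baseline(self):
        # two balanced habitats, clusters independent of habitat: the
        # majority habitat captures about half the strains in each cluster,
        # so total concordance hovers a little above 50%
        rng = np.random.default_rng(42)
        rates = []
        for _ in range(30):
            counts = {}
            for c in (1, 2):
                a = int(rng.binomial(50, 0.5))
                counts[c] = {"LA": a, "SA": 50 - a}
            assignment, habitats = assignment_from_counts(counts)
            conc = habitat_concordance(assignment, habitats)
            rates.append(sum(conc.concordant_n.values()) / conc.total)
        assert 0.5 <= np.mean(rates) <= 0.62
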