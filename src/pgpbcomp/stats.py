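"""Statistical layer: Student's t tests, one-way ANOVA with significance
tiers, PCA, phylogenetic PCA and PERMANOVA (Adonis) with seeded permutation
p-values.

Significance tiers follow the star convention
* 0.01 < p <= 0.05, ** 0.001 < p <= 0.01, *** 0.0001 < p <= 0.001,
**** p <= 0.0001.

Phylogenetic PCA is the Brownian-motion generalized-least-squares variant:
the trait matrix is centered with the GLS mean under the phylogenetic
covariance C (C_ij = shared root-to-MRCA branch length of strains i and j)
and the eigen-decomposition is taken of the phylogenetically corrected
covariance. On a star tree C is proportional to the identity and the result
reduces exactly to ordinary PCA.

PERMANOVA p-values use the add-one convention
p = (1 + #{F_perm >= F_obs}) / (1 + n_perm), so the smallest attainable
p at 999 permutations is 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as ss
from skbio import DistanceMatrix, TreeNode

_TINY = np.finfo(float).tiny


def significance_tier(p: float) -> str:
    """Star tier for a p-value; 'ns' above 0.05."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value out of [0, 1]: {p}")
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass
class StatResult:
    method: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    tier: str
    n_perm: int | None = None


def student_t(
    x: Sequence[float], y: Sequence[float], pooled: bool = True
) -> StatResult:
    """Two-sided two-sample t test (pooled-variance Student's by default).

    With zero variance in both samples: equal means give t=0, p=1; unequal
    means are reported as an infinite statistic with the smallest positive p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in samples")
    method = "student_t" if pooled else "welch_t"
    df = (len(x) + len(y) - 2.0,) if pooled else ()
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            return StatResult(method, 0.0, df or (np.nan,), 1.0, "ns")
        stat = np.inf if x.mean() > y.mean() else -np.inf
        return StatResult(method, float(stat), df or (np.nan,), _TINY, "****")
    res = ss.ttest_ind(x, y, equal_var=pooled)
    dof = float(res.df) if hasattr(res, "df") else df[0]
    p = float(res.pvalue)
    return StatResult(method, float(res.statistic), (dof,), p, significance_tier(p))


def one_way_anova(groups: Sequence[Sequence[float]]) -> StatResult:
    """Classic one-way ANOVA F test across >= 2 groups.

    Zero within-group variance with unequal means yields an infinite F and
    the smallest positive p; all-identical data give F=0, p=1.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(len(a) < 2 for a in arrs):
        raise ValueError("need >= 2 groups with n >= 2 each")
    if any(not np.isfinite(a).all() for a in arrs):
        raise ValueError("non-finite values in groups")
    k = len(arrs)
    n = sum(len(a) for a in arrs)
    dfb, dfw = float(k - 1), float(n - k)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    if ss_within == 0.0:
        means = [a.mean() for a in arrs]
        if len(set(means)) == 1:
            return StatResult("anova", 0.0, (dfb, dfw), 1.0, "ns")
        return StatResult("anova", np.inf, (dfb, dfw), _TINY, "****")
    res = ss.f_oneway(*arrs)
    p = float(res.pvalue)
    return StatResult("anova", float(res.statistic), (dfb, dfw), p, significance_tier(p))


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained: np.ndarray  # variance fractions, sum to 1
    mean: np.ndarray


def _fix_signs(scores: np.ndarray, loadings: np.ndarray) -> None:
    """Make the largest-magnitude loading of each component positive."""
    for c in range(loadings.shape[1]):
        col = loadings[:, c]
        i = int(np.abs(col).argmax())
        if col[i] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1


def _as_frame(features) -> pd.DataFrame:
    return getattr(features, "df", features)


def pca(features) -> PCAResult:
    """Ordinary PCA via SVD of the column-centered data matrix."""
    df = _as_frame(features)
    X = df.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("PCA needs >= 2 strains and >= 2 features")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U * s
    loadings = Vt.T
    _fix_signs(scores, loadings)
    var = s**2
    explained = var / var.sum() if var.sum() > 0 else np.full(len(s), 1 / len(s))
    comp = [f"PC{i+1}" for i in range(loadings.shape[1])]
    return PCAResult(
        pd.DataFrame(scores, index=df.index, columns=comp),
        pd.DataFrame(loadings, index=df.columns, columns=comp),
        explained,
        mean,
    )


def bm_covariance(tree: TreeNode, order: Sequence[str]) -> np.ndarray:
    """Brownian-motion covariance: C_ij = root-to-MRCA(i,j) branch length."""
    tips = {t.name: t for t in tree.tips()}
    missing = [s for s in order if s not in tips]
    if missing:
        raise ValueError(f"strains absent from tree: {missing[:5]}")
    root = tree.root()
    depth = {s: tips[s].distance(root) for s in order}
    dm = tree.tip_tip_distances().filter(list(order))
    d = dm.data
    n = len(order)
    dep = np.array([depth[s] for s in order])
    C = (dep[:, None] + dep[None, :] - d) / 2.0
    np.fill_diagonal(C, dep)
    return C


def phylo_pca(features, tree: TreeNode) -> PCAResult:
    """Phylogenetic PCA under a Brownian-motion covariance (GLS centering).

    Reduces exactly to :func:`pca` when the tree is a star with equal tip
    lengths. A singular phylogenetic covariance (e.g. duplicated zero-length
    tips) raises with advice to jitter branch lengths.
    """
    df = _as_frame(features)
    X = df.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("phylo-PCA needs >= 2 strains and >= 2 features")
    C = bm_covariance(tree, list(df.index))
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular phylogenetic covariance; jitter zero branch lengths"
        ) from exc
    cond = np.linalg.cond(C)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            "singular phylogenetic covariance; jitter zero branch lengths"
        )
    ones = np.ones((n, 1))
    a = (ones.T @ Cinv @ X) / (ones.T @ Cinv @ ones)
    Xc = X - a
    P = Xc.T @ Cinv @ Xc / (n - 1)
    evals, evecs = np.linalg.eigh(P)
    idx = np.argsort(evals)[::-1]
    evals, evecs = evals[idx], evecs[:, idx]
    scores = Xc @ evecs
    loadings = evecs.copy()
    _fix_signs(scores, loadings)
    evals = np.clip(evals, 0, None)
    explained = evals / evals.sum() if evals.sum() > 0 else np.full(p, 1 / p)
    comp = [f"PC{i+1}" for i in range(loadings.shape[1])]
    return PCAResult(
        pd.DataFrame(scores, index=df.index, columns=comp),
        pd.DataFrame(loadings, index=df.columns, columns=comp),
        explained,
        a.ravel(),
    )


def _permanova_ss(d2: np.ndarray, codes: np.ndarray, k: int) -> float:
    """Within-group sum of squared distances / group size, summed."""
    ssw = 0.0
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            ssw += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ssw


def permanova(
    dist: DistanceMatrix,
    labels: Mapping[str, str] | Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> StatResult:
    """PERMANOVA (Adonis): pseudo-F on a distance matrix with permutation p.

    Requires >= 2 groups with >= 2 members each and n_perm >= 99; the
    permutation p-value is (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    ids = list(dist.ids)
    if isinstance(labels, Mapping):
        grouping = [labels[s] for s in ids]
    else:
        grouping = list(labels)
        if len(grouping) != len(ids):
            raise ValueError("labels length does not match distance matrix")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    names = sorted(set(grouping))
    code_of = {g: i for i, g in enumerate(names)}
    codes = np.array([code_of[g] for g in grouping])
    k = len(names)
    sizes = np.bincount(codes, minlength=k)
    if k < 2 or (sizes < 2).any():
        raise ValueError("need >= 2 groups with >= 2 members each")
    n = len(ids)
    d2 = np.asarray(dist.data, dtype=float) ** 2
    ss_total = d2.sum() / (2.0 * n)
    dfb, dfw = float(k - 1), float(n - k)

    def pseudo_f(c: np.ndarray) -> float:
        ssw = _permanova_ss(d2, c, k)
        return ((ss_total - ssw) / dfb) / (ssw / dfw)

    f_obs = pseudo_f(codes)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if pseudo_f(rng.permutation(codes)) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return StatResult(
        "permanova", float(f_obs), (dfb, dfw), p, significance_tier(p), n_perm
    )


def enrichment_scan(
    features,
    habitats: Mapping[str, str],
    taxa: Mapping[str, str | int],
    alpha_habitats: tuple[str, str] = ("LA", "SA"),
) -> pd.DataFrame:
    """Habitat-enrichment tests over a feature table.

    For every (taxon cluster, feature class): a two-sided Student's t test
    between the two focal habitats (default LA vs SA). For every (habitat,
    feature class): a one-way ANOVA across taxon clusters. Cells with a
    group below n=2 or with no variation are marked untestable instead of
    being dropped. Raw p-values are primary; a Benjamini-Hochberg adjusted
    column is appended for reuse.
    """
    df = _as_frame(features)
    missing = [s for s in df.index if s not in habitats or s not in taxa]
    if missing:
        raise ValueError(f"grouping missing for strains: {missing[:5]}")
    hab = pd.Series({s: habitats[s] for s in df.index})
    tax = pd.Series({s: str(taxa[s]) for s in df.index})
    h1, h2 = alpha_habitats
    rows: list[dict] = []
    for cluster in sorted(tax.unique()):
        in_c = tax == cluster
        for feat in df.columns:
            x = df.loc[in_c & (hab == h1), feat].to_numpy(dtype=float)
            y = df.loc[in_c & (hab == h2), feat].to_numpy(dtype=float)
            row = {
                "test": f"t_{h1}_vs_{h2}",
                "scope": cluster,
                "feature": feat,
            }
            if len(x) < 2 or len(y) < 2 or (x.var() == 0 and y.var() == 0 and
                                            np.all(x == 0) and np.all(y == 0)):
                row.update(statistic=np.nan, p=np.nan, tier="", testable=False)
            else:
                r = student_t(x, y)
                row.update(statistic=r.statistic, p=r.p_value, tier=r.tier,
                           testable=True)
            rows.append(row)
    for habitat in sorted(hab.unique()):
        in_h = hab == habitat
        for feat in df.columns:
            groups = [
                df.loc[in_h & (tax == c), feat].to_numpy(dtype=float)
                for c in sorted(tax.unique())
            ]
            groups = [g for g in groups if len(g) > 0]
            row = {"test": "anova_across_clusters", "scope": habitat,
                   "feature": feat}
            vals = np.concatenate(groups) if groups else np.array([])
            if (
                len(groups) < 2
                or any(len(g) < 2 for g in groups)
                or np.all(vals == 0)
            ):
                row.update(statistic=np.nan, p=np.nan, tier="", testable=False)
            else:
                r = one_way_anova(groups)
                row.update(statistic=r.statistic, p=r.p_value, tier=r.tier,
                           testable=True)
            rows.append(row)
    out = pd.DataFrame(rows)
    out["p_bh"] = np.nan
    testable = out["testable"].fillna(False).to_numpy(dtype=bool)
    if testable.any():
        from statsmodels.stats.multitest import multipletests

        _, p_adj, _, _ = multipletests(out.loc[testable, "p"], method="fdr_bh")
        out.loc[testable, "p_bh"] = p_adj
    return out
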