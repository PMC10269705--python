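"""Synthetic PGPB cohorts with planted habitat structure.

The generator emulates the statistical features the comparative analysis
relies on: habitat-dependent genome size and GC distributions (leaf
strains smaller and GC-richer than soil strains), a clocklike strain
phylogeny with habitat-correlated clades, core / accessory / unit-specific
orthogroup structure, near-duplicate genome pairs (ANI >= 99.9%) and
habitat-dependent per-Mb feature-class rates for CAZyme and biosynthetic
gene cluster (BGC) classes. Every draw is seeded, and the planted truth is
recorded so downstream recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm
from skbio import TreeNode

from pgpbcomp._util import HABITATS, derive_seed
from pgpbcomp.profiles import AMINO_ACIDS, FeatureTable, parse_ref_header
from pgpbcomp.qc import ANIPair, GenomeRecord

#: per-Mb feature-class rates per habitat. CAZyme classes dominate; BGC
#: classes are rarer. Soil strains are the most feature-rich, matching the
#: habitat contrast the analysis is designed to detect.
DEFAULT_FEATURE_RATES: dict[str, dict[str, float]] = {
    "LA": {"AA": 1.0, "CBM": 1.0, "CE": 2.0, "GH": 12.0, "GT": 10.0, "PL": 0.5,
           "NRPS": 0.8, "bacteriocin": 0.4, "terpene": 0.5, "siderophore": 0.2,
           "T3PKS": 0.2},
    "SA": {"AA": 1.5, "CBM": 1.5, "CE": 3.0, "GH": 18.0, "GT": 14.0, "PL": 1.0,
           "NRPS": 1.6, "bacteriocin": 0.8, "terpene": 0.8, "siderophore": 0.4,
           "T3PKS": 0.4},
    "OA": {"AA": 1.2, "CBM": 1.2, "CE": 2.4, "GH": 14.0, "GT": 11.0, "PL": 0.7,
           "NRPS": 1.0, "bacteriocin": 0.5, "terpene": 0.6, "siderophore": 0.3,
           "T3PKS": 0.3},
}


def _default_n() -> dict[str, int]:
    return {"LA": 195, "SA": 283, "OA": 95}


def _default_size_mean() -> dict[str, float]:
    return {"LA": 4.67, "SA": 6.08, "OA": 5.97}


def _default_size_sd() -> dict[str, float]:
    return {"LA": 0.8, "SA": 1.2, "OA": 1.5}


def _default_gc_mean() -> dict[str, float]:
    return {"LA": 63.27, "SA": 57.12, "OA": 56.95}


def _default_rates() -> dict[str, dict[str, float]]:
    return {h: dict(v) for h, v in DEFAULT_FEATURE_RATES.items()}


@dataclass
class SimConfig:
    """Parameters of a synthetic cohort.

    Defaults are the study conditions: habitat sample sizes 195/283/95
    (LA/SA/OA), habitat mean genome sizes 4.67/6.08/5.97 Mb and mean GC
    63.27/57.12/56.95%; orthogroup class counts are the observed pan-genome
    partition scaled by 1/100 (163 core kept unscaled, 378 accessory,
    212 unit-specific).
    """

    n_strains_per_habitat: dict[str, int] = field(default_factory=_default_n)
    genome_size_mean_mb: dict[str, float] = field(default_factory=_default_size_mean)
    genome_size_sd_mb: dict[str, float] = field(default_factory=_default_size_sd)
    gc_mean_pct: dict[str, float] = field(default_factory=_default_gc_mean)
    gc_sd_pct: float = 4.0
    feature_rate_per_mb: dict[str, dict[str, float]] = field(
        default_factory=_default_rates
    )
    n_core: int = 163
    n_accessory: int = 378
    n_specific: int = 212
    n_redundant_pairs: int = 5
    n_taxa: int = 4
    habitat_assortativity: float = 1.0
    clade_separation: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.n_strains_per_habitat) != set(HABITATS):
            raise ValueError(f"habitats must be exactly {set(HABITATS)}")
        for h in HABITATS:
            if self.genome_size_mean_mb[h] <= 0 or self.gc_mean_pct[h] <= 0:
                raise ValueError("means must be positive")
            if self.genome_size_sd_mb[h] < 0:
                raise ValueError("sds must be >= 0")
            if self.n_strains_per_habitat[h] < 0:
                raise ValueError("strain counts must be >= 0")
            for cls, rate in self.feature_rate_per_mb[h].items():
                if rate < 0:
                    raise ValueError(f"rate for {h}/{cls} must be >= 0")
        if self.gc_sd_pct < 0:
            raise ValueError("gc_sd_pct must be >= 0")
        for name in ("n_core", "n_accessory", "n_specific",
                     "n_redundant_pairs", "n_taxa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.habitat_assortativity <= 1.0:
            raise ValueError("habitat_assortativity must be in [0, 1]")

    @property
    def n_total(self) -> int:
        return sum(self.n_strains_per_habitat.values())


@dataclass
class Cohort:
    """A simulated strain cohort plus its planted truth."""

    records: list[GenomeRecord]
    tree: TreeNode
    ortho: pd.DataFrame
    ani_pairs: list[ANIPair]
    features: FeatureTable
    truth: dict
    seed: int

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        tips = sorted(t.name for t in self.tree.tips())
        if sorted(ids) != tips:
            raise ValueError("tree leaves do not match genome records")
        if sorted(ids) != sorted(self.ortho.index):
            raise ValueError("orthogroup rows do not match genome records")
        if sorted(ids) != sorted(self.features.df.index):
            raise ValueError("feature rows do not match genome records")

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def habitat_of(self) -> dict[str, str]:
        return {r.id: r.habitat for r in self.records}

    def taxon_of(self) -> dict[str, str]:
        return {r.id: r.taxon for r in self.records}

    def unit_of(self) -> dict[str, str]:
        return {r.id: f"{r.taxon}|{r.habitat}" for r in self.records}

    def sizes_bp(self) -> dict[str, int]:
        return {r.id: r.size_bp for r in self.records}


def _yule(labels: Sequence[str], rng: np.random.Generator) -> TreeNode:
    """Ultrametric pure-birth tree over the given leaves (unit birth rate)."""
    if len(labels) == 1:
        return TreeNode(name=labels[0])
    root = TreeNode()
    start: dict[int, float] = {id(root): 0.0}
    active: list[TreeNode] = [root]
    t = 0.0
    while len(active) < len(labels):
        t += rng.exponential(1.0 / len(active))
        node = active.pop(int(rng.integers(len(active))))
        if node is not root:
            node.length = t - start[id(node)]
        kids = [TreeNode(), TreeNode()]
        node.extend(kids)
        for c in kids:
            start[id(c)] = t
        active.extend(kids)
    t_end = t + rng.exponential(1.0 / len(active))
    order = list(labels)
    rng.shuffle(order)
    for leaf, name in zip(active, order):
        leaf.name = name
        leaf.length = t_end - start[id(leaf)]
    return root


def simulate_tree(
    n_taxa: int,
    seed: int,
    habitat_assortativity: float = 1.0,
    groups: Sequence[str] = HABITATS,
    group_counts: Mapping[str, int] | None = None,
    labels: Sequence[str] | None = None,
    clade_separation: float = 10.0,
) -> tuple[TreeNode, dict[str, str]]:
    """Clocklike binary tree with habitat-correlated clades.

    Each group gets its own pure-birth subtree; subtrees are joined by
    branches of length ``clade_separation``, so at assortativity 1 every
    group is monophyletic and well separated. With assortativity ``a``, each
    leaf keeps its clade's group with probability ``a``; the remaining
    leaves have their group labels shuffled uniformly among themselves, so
    at 0 the assignment is a uniform random permutation over leaves (group
    sizes are preserved in all cases).
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    if not 0.0 <= habitat_assortativity <= 1.0:
        raise ValueError("habitat_assortativity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"S{i+1:04d}" for i in range(n_taxa)]
    if len(labels) != n_taxa:
        raise ValueError("labels length must equal n_taxa")
    if group_counts is None:
        base = n_taxa // len(groups)
        group_counts = {g: base for g in groups}
        for g in list(groups)[: n_taxa - base * len(groups)]:
            group_counts[g] += 1
    if sum(group_counts.values()) != n_taxa:
        raise ValueError("group_counts must sum to n_taxa")

    # block assignment of labels to groups, then per-group subtrees
    label_iter = iter(labels)
    block_of: dict[str, str] = {}
    subtrees: list[TreeNode] = []
    for g in groups:
        g_labels = [next(label_iter) for _ in range(group_counts[g])]
        for lab in g_labels:
            block_of[lab] = g
        if g_labels:
            subtrees.append(_yule(g_labels, rng))
    subtrees = [s for s in subtrees if s is not None]
    if len(subtrees) == 1:
        tree = subtrees[0]
    else:
        tree = subtrees[0]
        for nxt in subtrees[1:]:
            parent = TreeNode()
            tree.length = clade_separation
            nxt.length = clade_separation
            parent.extend([tree, nxt])
            tree = parent

    group_of = dict(block_of)
    reshuffle = [
        lab for lab in labels if rng.random() > habitat_assortativity
    ]
    pool = [group_of[lab] for lab in reshuffle]
    rng.shuffle(pool)
    for lab, g in zip(reshuffle, pool):
        group_of[lab] = g
    return tree, group_of


def _trunc_normal(
    mean: float, sd: float, lower: float, upper: float, size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    if sd == 0.0:
        return np.full(size, mean)
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_orthogroups(
    strains: Sequence[str],
    n_core: int,
    n_accessory: int,
    n_specific: int,
    unit_labels: Mapping[str, str],
    seed: int,
    n_single_copy: int = 14,
) -> pd.DataFrame:
    """Strains x families count matrix with planted class structure.

    Core families have count >= 1 in every strain (the first
    ``min(n_single_copy, n_core)`` are exactly single-copy everywhere, the
    rest are forced multi-copy somewhere); unit-specific families are
    confined to exactly one taxon x habitat unit; accessory families are
    present in >= 2 strains spanning >= 2 units but absent from at least
    one strain. Column order is shuffled.
    """
    if n_core + n_accessory + n_specific == 0:
        raise ValueError("at least one family class must be non-empty")
    missing = [s for s in strains if s not in unit_labels]
    if missing:
        raise ValueError(f"unit label missing for strains: {missing[:5]}")
    n = len(strains)
    units = sorted({unit_labels[s] for s in strains})
    if n_accessory > 0 and (n < 3 or len(units) < 2):
        raise ValueError("accessory families need >= 3 strains in >= 2 units")
    if n_specific > 0 and n < 2:
        raise ValueError("unit-specific families need >= 2 strains")
    rng = np.random.default_rng(seed)
    members = {u: [s for s in strains if unit_labels[s] == u] for u in units}
    cols: dict[str, np.ndarray] = {}
    classes: dict[str, str] = {}
    fam_i = 0

    def new_fam(cls: str) -> str:
        nonlocal fam_i
        fam_i += 1
        fid = f"OG{fam_i:06d}"
        classes[fid] = cls
        return fid

    single = []
    for i in range(n_core):
        fid = new_fam("core")
        if i < min(n_single_copy, n_core):
            counts = np.ones(n, dtype=int)
            single.append(fid)
        else:
            counts = 1 + rng.poisson(0.3, size=n)
            if (counts == 1).all():
                counts[rng.integers(n)] = 2
        cols[fid] = counts
    for _ in range(n_accessory):
        fid = new_fam("accessory")
        u1, u2 = rng.choice(len(units), size=2, replace=False)
        chosen = {
            members[units[u1]][rng.integers(len(members[units[u1]]))],
            members[units[u2]][rng.integers(len(members[units[u2]]))],
        }
        extra = rng.integers(0, max(1, n - 2))
        others = [s for s in strains if s not in chosen]
        if extra > 0 and others:
            take = min(int(extra), len(others) - 1)  # keep >= 1 strain absent
            if take > 0:
                chosen.update(rng.choice(others, size=take, replace=False))
        counts = np.zeros(n, dtype=int)
        idx = [i for i, s in enumerate(strains) if s in chosen]
        counts[idx] = 1 + rng.poisson(0.3, size=len(idx))
        cols[fid] = counts
    for _ in range(n_specific):
        fid = new_fam("specific")
        u = units[rng.integers(len(units))]
        pool = members[u]
        cap = len(pool) if len(pool) < n else n - 1
        size = int(rng.integers(1, cap + 1))
        chosen = set(rng.choice(pool, size=size, replace=False))
        counts = np.zeros(n, dtype=int)
        idx = [i for i, s in enumerate(strains) if s in chosen]
        counts[idx] = 1 + rng.poisson(0.3, size=len(idx))
        cols[fid] = counts

    order = list(cols)
    rng.shuffle(order)
    df = pd.DataFrame({f: cols[f] for f in order}, index=list(strains))
    df.attrs["family_class"] = classes
    df.attrs["single_copy"] = single
    return df


def simulate_ani_pairs(
    strains: Sequence[str],
    n_redundant: int,
    seed: int,
    n_decoys: int | None = None,
) -> tuple[list[ANIPair], list[tuple[str, str]]]:
    """ANI/coverage pairs with exactly ``n_redundant`` planted redundancies.

    Redundant pairs are disjoint, with ANI >= 99.9 and both coverages > 95;
    decoy pairs fail at least one rule (low ANI or low coverage). Returns
    the pair table and the planted redundant id pairs.
    """
    n = len(strains)
    if n_redundant > n // 2:
        raise ValueError("n_redundant exceeds n_strains / 2")
    rng = np.random.default_rng(seed)
    chosen = list(rng.choice(strains, size=2 * n_redundant, replace=False))
    pairs: list[ANIPair] = []
    truth: list[tuple[str, str]] = []
    for i in range(n_redundant):
        a, b = chosen[2 * i], chosen[2 * i + 1]
        pairs.append(
            ANIPair(a, b, float(rng.uniform(99.9, 100.0)),
                    float(rng.uniform(95.5, 99.5)), float(rng.uniform(95.5, 99.5)))
        )
        truth.append((a, b))
    rest = [s for s in strains if s not in set(chosen)]
    if n_decoys is None:
        n_decoys = min(len(rest) // 2, n_redundant + 3)
    dec = list(rng.choice(rest, size=2 * n_decoys, replace=False)) if n_decoys else []
    for i in range(n_decoys):
        a, b = dec[2 * i], dec[2 * i + 1]
        if rng.random() < 0.5:  # fails the ANI rule
            pairs.append(
                ANIPair(a, b, float(rng.uniform(85.0, 99.5)),
                        float(rng.uniform(95.5, 99.5)),
                        float(rng.uniform(95.5, 99.5)))
            )
        else:  # fails the coverage rule
            pairs.append(
                ANIPair(a, b, float(rng.uniform(99.9, 100.0)),
                        float(rng.uniform(95.5, 99.5)),
                        float(rng.uniform(80.0, 94.9)))
            )
    return pairs, truth


def simulate_cohort(config: SimConfig) -> Cohort:
    """Draw a full cohort under the configured habitat conditions.

    Genome sizes are habitat-specific normals truncated at 0.5 Mb; GC is
    truncated to (20, 80); feature counts are Poisson with mean
    rate_per_Mb x size_Mb. The same config and seed reproduce the cohort
    byte-for-byte.
    """
    n_total = config.n_total
    tree_seed = derive_seed(config.seed, "tree")
    tree, habitat_of = simulate_tree(
        n_total,
        tree_seed,
        habitat_assortativity=config.habitat_assortativity,
        groups=HABITATS,
        group_counts=config.n_strains_per_habitat,
        clade_separation=config.clade_separation,
    )
    ids = sorted(habitat_of)
    rng = np.random.default_rng(derive_seed(config.seed, "genomes"))
    taxa = [f"T{rng.integers(1, config.n_taxa + 1)}" for _ in ids]
    records: list[GenomeRecord] = []
    class_names = sorted(
        {c for rates in config.feature_rate_per_mb.values() for c in rates}
    )
    feat_rows = []
    for sid, taxon in zip(ids, taxa):
        h = habitat_of[sid]
        size_mb = float(
            _trunc_normal(config.genome_size_mean_mb[h],
                          config.genome_size_sd_mb[h], 0.5, np.inf, 1, rng)[0]
        )
        gc = float(
            _trunc_normal(config.gc_mean_pct[h], config.gc_sd_pct, 20.0, 80.0,
                          1, rng)[0]
        )
        completeness = float(rng.uniform(96.0, 100.0))
        contamination = float(rng.uniform(0.0, 3.0))
        records.append(
            GenomeRecord(sid, h, taxon, int(round(size_mb * 1e6)), gc,
                         completeness, contamination)
        )
        rates = config.feature_rate_per_mb[h]
        feat_rows.append(
            {c: int(rng.poisson(rates.get(c, 0.0) * size_mb)) for c in class_names}
        )
    features = FeatureTable(pd.DataFrame(feat_rows, index=ids), normalized=False)
    unit_of = {r.id: f"{r.taxon}|{r.habitat}" for r in records}
    ortho = simulate_orthogroups(
        ids, config.n_core, config.n_accessory, config.n_specific, unit_of,
        derive_seed(config.seed, "ortho"),
    )
    ani_pairs, redundant = simulate_ani_pairs(
        ids, config.n_redundant_pairs, derive_seed(config.seed, "ani")
    )
    truth = {
        "habitat_of": {r.id: r.habitat for r in records},
        "taxon_of": {r.id: r.taxon for r in records},
        "unit_of": unit_of,
        "redundant_pairs": redundant,
        "family_class": ortho.attrs["family_class"],
        "single_copy_families": ortho.attrs["single_copy"],
        "habitat_assortativity": config.habitat_assortativity,
    }
    return Cohort(records, tree, ortho, ani_pairs, features, truth, config.seed)


def make_reference_families(
    families: Sequence[str] = ("GH13", "GT2", "CE1", "AA3", "PL1", "CBM50"),
    length: int = 80,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Random reference proteins, one per family, headers ``id|FAMILY``."""
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(AMINO_ACIDS))
    refs = []
    for i, fam in enumerate(families):
        seq = "".join(rng.choice(alphabet, size=length))
        refs.append((f"R{i+1:03d}|{fam}", seq))
    return refs


def simulate_proteins(
    family_refs: Sequence[tuple[str, str]],
    n_queries: int,
    identity_targets: Sequence[float],
    seed: int,
) -> tuple[list[tuple[str, str]], dict[str, dict]]:
    """Queries mutated from references to hit target global identities.

    Each query is a reference sequence with point substitutions only (no
    indels), so its global identity to the source is controllable to within
    about two percentage points. The truth mapping records the source
    reference, family and target per query.
    """
    refs = list(family_refs)
    if not refs:
        raise ValueError("reference set is empty")
    for t in identity_targets:
        if not 0.0 <= t <= 100.0:
            raise ValueError(f"identity target out of [0, 100]: {t}")
    rng = np.random.default_rng(seed)
    queries: list[tuple[str, str]] = []
    truth: dict[str, dict] = {}
    aas = list(AMINO_ACIDS)
    for q in range(n_queries):
        target = float(identity_targets[q % len(identity_targets)])
        header, seq = refs[rng.integers(len(refs))]
        ref_id, family = parse_ref_header(header)
        L = len(seq)
        k = int(round(L * (1.0 - target / 100.0)))
        pos = rng.choice(L, size=k, replace=False)
        chars = list(seq)
        for p in pos:
            choices = [a for a in aas if a != chars[p]]
            chars[p] = choices[rng.integers(len(choices))]
        qid = f"q{q+1:04d}"
        queries.append((qid, "".join(chars)))
        truth[qid] = {"ref_id": ref_id, "family": family, "target": target}
    return queries, truth
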