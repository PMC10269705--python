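"""Pan-genome partitioning and phylogenetically matched subsampling.

Gene families (orthogroups) are partitioned over analysis "units" — the
taxon x habitat combinations — into three exclusive classes:

* core: present (count >= 1) in every strain;
* unit-specific: non-core families whose presence is confined to exactly
  one unit;
* accessory: everything else (shared by some strains spanning >= 2 units
  but absent from at least one strain).

For balanced core-genome comparisons across habitats, strains are selected
so that each habitat panel is phylogenetically matched to a reference
habitat: candidates are ranked by how far their mean cophenetic distance to
the reference set deviates from the candidate pool's grand mean, and the
least deviant n are taken.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from pgpbcomp._util import pct


@dataclass
class PartitionSummary:
    n_total: int
    n_core: int
    n_accessory: int
    n_specific: int

    def __post_init__(self) -> None:
        if self.n_core + self.n_accessory + self.n_specific != self.n_total:
            raise ValueError("class counts must sum to the total")

    def shares(self) -> dict[str, float]:
        return partition_shares(self)


def partition_pangenome(
    ortho: pd.DataFrame, unit_of: Mapping[str, str]
) -> tuple[PartitionSummary, dict[str, str]]:
    """Classify every family as core / accessory / specific.

    ``ortho`` is a strains x families count matrix; ``unit_of`` maps every
    strain to its taxon x habitat unit. Returns the summary and a
    family -> class map. Classes are exclusive and exhaustive; families
    absent from every strain are rejected as data errors.
    """
    if ortho.size == 0:
        raise ValueError("orthogroup matrix is empty")
    missing = [s for s in ortho.index if s not in unit_of]
    if missing:
        raise ValueError(f"unit missing for strains: {missing[:5]}")
    presence = ortho.to_numpy() >= 1
    if (~presence.any(axis=0)).any():
        bad = [f for f, m in zip(ortho.columns, ~presence.any(axis=0)) if m]
        raise ValueError(f"families absent from every strain: {bad[:5]}")
    units = np.array([unit_of[s] for s in ortho.index])
    classes: dict[str, str] = {}
    for j, fam in enumerate(ortho.columns):
        col = presence[:, j]
        if col.all():
            classes[fam] = "core"
        elif len(set(units[col])) == 1:
            classes[fam] = "specific"
        else:
            classes[fam] = "accessory"
    n_core = sum(1 for c in classes.values() if c == "core")
    n_spec = sum(1 for c in classes.values() if c == "specific")
    n_acc = len(classes) - n_core - n_spec
    return PartitionSummary(len(classes), n_core, n_acc, n_spec), classes


def partition_shares(summary: PartitionSummary) -> dict[str, float]:
    """Percentage share of each class, rounded half-up to two decimals."""
    if summary.n_total <= 0:
        raise ValueError("n_total must be positive")
    return {
        "core": pct(summary.n_core, summary.n_total),
        "accessory": pct(summary.n_accessory, summary.n_total),
        "specific": pct(summary.n_specific, summary.n_total),
    }


def matched_subsample(
    dist: DistanceMatrix,
    habitats: Mapping[str, str],
    reference_habitat: str,
    n_per_group: int,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Phylogenetically matched panels of ``n_per_group`` strains per habitat.

    The reference habitat contributes all of its strains (or a seeded random
    subset of ``n_per_group`` if it has more). For every other habitat, each
    candidate's mean cophenetic distance to the reference panel is computed;
    candidates are then ranked by the absolute deviation of that mean from
    the pool's grand mean and the ``n_per_group`` least deviant are selected
    (ties broken lexicographically by strain id). Deterministic for a fixed
    seed.
    """
    ids = list(dist.ids)
    missing = [s for s in ids if s not in habitats]
    if missing:
        raise ValueError(f"habitat missing for strains: {missing[:5]}")
    pools: dict[str, list[str]] = {}
    for s in ids:
        pools.setdefault(habitats[s], []).append(s)
    if reference_habitat not in pools:
        raise ValueError(f"no strains in reference habitat {reference_habitat!r}")
    for h, pool in pools.items():
        if len(pool) < n_per_group:
            raise ValueError(
                f"habitat {h!r} has {len(pool)} strains < n_per_group={n_per_group}"
            )
    rng = np.random.default_rng(seed)
    D = np.asarray(dist.data)
    pos = {s: i for i, s in enumerate(ids)}

    ref_pool = sorted(pools[reference_habitat])
    if len(ref_pool) > n_per_group:
        ref_sel = sorted(rng.choice(ref_pool, size=n_per_group, replace=False))
    else:
        ref_sel = ref_pool
    ref_idx = [pos[s] for s in ref_sel]

    selected = {reference_habitat: list(ref_sel)}
    for h in sorted(pools):
        if h == reference_habitat:
            continue
        cand = sorted(pools[h])
        means = np.array([D[pos[s], ref_idx].mean() for s in cand])
        grand = means.mean()
        dev = np.abs(means - grand)
        order = sorted(range(len(cand)), key=lambda i: (dev[i], cand[i]))
        selected[h] = sorted(cand[i] for i in order[:n_per_group])
    return selected


def family_abundance_by_group(
    ortho: pd.DataFrame,
    families: Sequence[str],
    group_of: Mapping[str, str],
) -> pd.DataFrame:
    """Per (group, family) mean gene count, SD and n — ANOVA-ready.

    SD is the sample standard deviation (ddof=1), reported as missing for
    single-strain groups.
    """
    unknown = [f for f in families if f not in ortho.columns]
    if unknown:
        raise ValueError(f"unknown families: {unknown[:5]}")
    missing = [s for s in ortho.index if s not in group_of]
    if missing:
        raise ValueError(f"group missing for strains: {missing[:5]}")
    sub = ortho[list(families)].copy()
    sub["__group"] = [group_of[s] for s in sub.index]
    rows = []
    for grp, block in sub.groupby("__group", sort=True):
        vals = block[list(families)]
        for fam in families:
            v = vals[fam].to_numpy(dtype=float)
            rows.append(
                {
                    "group": grp,
                    "family": fam,
                    "mean": float(v.mean()),
                    "sd": float(v.std(ddof=1)) if len(v) > 1 else np.nan,
                    "n": len(v),
                }
            )
    return pd.DataFrame(rows)
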