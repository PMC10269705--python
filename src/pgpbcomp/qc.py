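"""Genome-set construction: completeness/contamination filtering and
ANI/coverage dereplication.

A genome enters the analysis set only if it is at least 95% complete with no
more than 5% contamination (CheckM-style estimates consumed as metadata).
Two genomes are treated as functionally redundant when their average
nucleotide identity (ANI) is at least 99.9% and both directional alignment
coverages exceed 95%; redundancy is closed over connected components and a
single representative per component is retained, chosen uniformly with a
seeded RNG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from pgpbcomp._util import HABITATS


@dataclass(frozen=True)
class GenomeRecord:
    """One strain's metadata row."""

    id: str
    habitat: str
    taxon: str
    size_bp: int
    gc_pct: float
    completeness_pct: float
    contamination_pct: float

    def __post_init__(self) -> None:
        if self.habitat not in HABITATS:
            raise ValueError(f"habitat must be one of {HABITATS}, got {self.habitat!r}")
        if self.size_bp <= 0:
            raise ValueError(f"size_bp must be positive, got {self.size_bp}")
        if not 0.0 < self.gc_pct < 100.0:
            raise ValueError(f"gc_pct must be in (0, 100), got {self.gc_pct}")
        if not 0.0 <= self.completeness_pct <= 100.0:
            raise ValueError("completeness_pct must be in [0, 100]")
        if self.contamination_pct < 0.0:
            raise ValueError("contamination_pct must be >= 0")

    @property
    def size_mb(self) -> float:
        return self.size_bp / 1e6


@dataclass(frozen=True)
class ANIPair:
    """Pairwise ANI and directional coverages between two genomes."""

    id_a: str
    id_b: str
    ani_pct: float
    coverage_ab_pct: float
    coverage_ba_pct: float

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise ValueError("ANI pair must reference two distinct genomes")
        for name in ("ani_pct", "coverage_ab_pct", "coverage_ba_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be in [0, 100], got {v}")

    def key(self) -> frozenset[str]:
        return frozenset((self.id_a, self.id_b))


@dataclass
class Removal:
    record: GenomeRecord
    reasons: list[str] = field(default_factory=list)


def quality_filter(
    records: Sequence[GenomeRecord],
    min_completeness: float = 95.0,
    max_contamination: float = 5.0,
) -> tuple[list[GenomeRecord], list[Removal]]:
    """Keep genomes that are complete enough and clean enough.

    Both bounds are inclusive: completeness >= ``min_completeness`` and
    contamination <= ``max_contamination`` pass. Input order is preserved;
    removed genomes carry the list of thresholds they failed.
    """
    for name, thr in (("min_completeness", min_completeness),
                      ("max_contamination", max_contamination)):
        if not 0.0 <= thr <= 100.0:
            raise ValueError(f"{name} must be in [0, 100], got {thr}")
    kept: list[GenomeRecord] = []
    removed: list[Removal] = []
    for rec in records:
        reasons = []
        if rec.completeness_pct < min_completeness:
            reasons.append("completeness")
        if rec.contamination_pct > max_contamination:
            reasons.append("contamination")
        if reasons:
            removed.append(Removal(rec, reasons))
        else:
            kept.append(rec)
    return kept, removed


@dataclass
class DereplicationResult:
    kept_ids: list[str]
    removed_ids: list[str]
    components: list[list[str]]  # redundant components with >= 2 members


def dereplicate(
    records: Sequence[GenomeRecord],
    pairs: Iterable[ANIPair],
    ani_min: float = 99.9,
    cov_min: float = 95.0,
    seed: int = 0,
) -> DereplicationResult:
    """Collapse functionally redundant genomes to one representative each.

    An edge joins two genomes when ani >= ``ani_min`` (inclusive) and the
    minimum of the two directional coverages is strictly greater than
    ``cov_min``. Within each connected component of the resulting redundancy
    graph exactly one genome is kept, drawn uniformly with the seeded RNG, so
    chains and triangles collapse to a single representative.
    """
    ids = [r.id for r in records]
    id_set = set(ids)
    if len(id_set) != len(ids):
        raise ValueError("duplicate genome ids in records")
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    for p in pairs:
        if p.id_a not in id_set or p.id_b not in id_set:
            raise ValueError(
                f"ANI pair ({p.id_a}, {p.id_b}) references a genome id "
                "absent from records"
            )
        if p.ani_pct >= ani_min and min(p.coverage_ab_pct, p.coverage_ba_pct) > cov_min:
            graph.add_edge(p.id_a, p.id_b)

    rng = np.random.default_rng(seed)
    removed: set[str] = set()
    components: list[list[str]] = []
    # sort for a stable iteration order so the seeded draw is reproducible
    comps = sorted((sorted(c) for c in nx.connected_components(graph)),
                   key=lambda c: c[0])
    for comp in comps:
        if len(comp) < 2:
            continue
        components.append(comp)
        keep = comp[rng.integers(len(comp))]
        removed.update(m for m in comp if m != keep)
    kept_ids = [i for i in ids if i not in removed]
    removed_ids = [i for i in ids if i in removed]
    return DereplicationResult(kept_ids, removed_ids, components)
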