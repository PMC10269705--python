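"""CAZyme-style family profiling: best-hit assignment by global alignment
identity with a strict 40% cutoff, feature-class count tables and per-Mb
normalization.

Family assignment scores each query protein against every reference with a
Needleman-Wunsch global alignment (match +1, mismatch 0, linear gap -1) and
keeps the query only if the best hit's identity is strictly greater than the
cutoff. Identity is computed over all alignment columns, gaps included; the
unknown residue X never counts as a match. The simple transparent scoring
scheme is the default on purpose — substitution-matrix scoring is a
configuration extension, not the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET = set(AMINO_ACIDS + "X")


@dataclass
class AlignmentResult:
    score: int
    identity_pct: float
    length: int
    aligned_a: str
    aligned_b: str


def _check_protein(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    seq = seq.upper()
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"{name}: invalid residues {sorted(bad)}")
    return seq


def align_global(seq_a: str, seq_b: str) -> AlignmentResult:
    """Needleman-Wunsch global alignment (match +1, mismatch 0, gap -1).

    Traceback ties are resolved diagonal > up > left, making the reported
    alignment (and hence its identity) deterministic. X aligns like any
    residue but never scores or counts as a match.
    """
    a = _check_protein(seq_a, "seq_a")
    b = _check_protein(seq_b, "seq_b")
    la, lb = len(a), len(b)
    H = np.zeros((la + 1, lb + 1), dtype=np.int64)
    H[:, 0] = -np.arange(la + 1)
    H[0, :] = -np.arange(lb + 1)
    match = np.zeros((la, lb), dtype=np.int64)
    for i, ca in enumerate(a):
        if ca == "X":
            continue
        for j, cb in enumerate(b):
            if ca == cb:
                match[i, j] = 1
    for i in range(1, la + 1):
        Hi, Hp = H[i], H[i - 1]
        mi = match[i - 1]
        for j in range(1, lb + 1):
            Hi[j] = max(Hp[j - 1] + mi[j - 1], Hp[j] - 1, Hi[j - 1] - 1)
    # traceback, tie order: diagonal > up (consume a) > left (consume b)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = la, lb
    while i > 0 or j > 0:
        if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + match[i - 1, j - 1]:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and H[i, j] == H[i - 1, j] - 1:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    matches = sum(
        1
        for x, y in zip(aligned_a, aligned_b)
        if x == y and x not in ("-", "X")
    )
    length = len(aligned_a)
    identity = 100.0 * matches / length
    return AlignmentResult(int(H[la, lb]), identity, length, aligned_a, aligned_b)


def global_identity(seq_a: str, seq_b: str) -> tuple[float, int]:
    """Percent identity (gap-inclusive denominator) and alignment length."""
    res = align_global(seq_a, seq_b)
    return res.identity_pct, res.length


@dataclass
class FamilyAssignment:
    """Best reference hit for one query protein."""

    query: str
    family: str
    ref_id: str
    identity_pct: float
    aln_length: int
    kept: bool


def parse_ref_header(header: str) -> tuple[str, str]:
    """Split a ``id|FAMILY`` reference header into id and family label."""
    if "|" not in header:
        raise ValueError(f"reference header {header!r} lacks an 'id|FAMILY' label")
    ref_id, family = header.rsplit("|", 1)
    if not ref_id or not family:
        raise ValueError(f"reference header {header!r} lacks an 'id|FAMILY' label")
    return ref_id, family


def assign_families(
    queries: Mapping[str, str] | Iterable[tuple[str, str]],
    refdb: Mapping[str, str] | Iterable[tuple[str, str]],
    min_identity: float = 40.0,
) -> list[FamilyAssignment]:
    """Best-hit family assignment with a strict identity cutoff.

    Every query is aligned to every reference; the best hit is the highest
    identity, ties resolved by longer alignment then lexicographically
    smaller reference id. A query is kept iff its best identity is strictly
    greater than ``min_identity`` (the "more than 40%" rule); filtered
    queries are still reported with ``kept=False``.
    """
    q_items = list(queries.items() if isinstance(queries, Mapping) else queries)
    r_items = list(refdb.items() if isinstance(refdb, Mapping) else refdb)
    if not r_items:
        raise ValueError("reference database is empty")
    refs = []
    for header, seq in r_items:
        ref_id, family = parse_ref_header(header)
        refs.append((ref_id, family, seq))
    out: list[FamilyAssignment] = []
    for qid, qseq in q_items:
        best: tuple[float, int, str, str] | None = None
        for ref_id, family, rseq in refs:
            ident, alen = global_identity(qseq, rseq)
            cand = (-ident, -alen, ref_id, family)
            if best is None or cand < best:
                best = cand
        assert best is not None
        ident, alen, ref_id, family = -best[0], -best[1], best[2], best[3]
        out.append(
            FamilyAssignment(qid, family, ref_id, ident, alen, ident > min_identity)
        )
    return out


@dataclass
class FeatureTable:
    """Strains x feature-classes table of counts or per-Mb rates."""

    df: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        vals = self.df.to_numpy(dtype=float)
        if (vals < 0).any():
            raise ValueError("feature values must be non-negative")
        if not self.normalized and not np.allclose(vals, np.round(vals)):
            raise ValueError("raw feature counts must be integers")

    @property
    def strains(self) -> list[str]:
        return list(self.df.index)

    @property
    def classes(self) -> list[str]:
        return list(self.df.columns)


def class_counts(
    assignments: Sequence[FamilyAssignment],
    class_of: Mapping[str, str],
    strain_of: Mapping[str, str] | Callable[[str], str] | None = None,
    strains: Sequence[str] | None = None,
    classes: Sequence[str] | None = None,
) -> FeatureTable:
    """Per-strain counts of kept assignments by feature class.

    ``strain_of`` maps a query id to its strain; by default queries are
    named ``strain|gene`` and the prefix is used. Classes never observed get
    zero counts when an explicit ``classes`` axis is supplied.
    """
    if strain_of is None:
        strain_fn = lambda q: q.split("|", 1)[0]  # noqa: E731
    elif callable(strain_of):
        strain_fn = strain_of
    else:
        strain_fn = strain_of.__getitem__
    kept = [a for a in assignments if a.kept]
    unmapped = sorted({a.family for a in kept if a.family not in class_of})
    if unmapped:
        raise ValueError(f"families with no class mapping: {unmapped[:5]}")
    strain_axis = list(strains) if strains is not None else sorted(
        {strain_fn(a.query) for a in assignments}
    )
    class_axis = list(classes) if classes is not None else sorted(
        set(class_of.values())
    )
    df = pd.DataFrame(0, index=strain_axis, columns=class_axis, dtype=int)
    for a in kept:
        s = strain_fn(a.query)
        c = class_of[a.family]
        if s not in df.index:
            raise ValueError(f"query {a.query!r} maps to unknown strain {s!r}")
        df.loc[s, c] += 1
    return FeatureTable(df, normalized=False)


def per_mb(features: FeatureTable, sizes: Mapping[str, int]) -> FeatureTable:
    """Normalize raw counts to rates per megabase of genome."""
    if features.normalized:
        raise ValueError("feature table is already per-Mb normalized")
    missing = [s for s in features.strains if s not in sizes]
    if missing:
        raise ValueError(f"genome size missing for strains: {missing[:5]}")
    mb = pd.Series({s: sizes[s] / 1e6 for s in features.strains})
    if (mb <= 0).any():
        raise ValueError("genome sizes must be positive")
    df = features.df.div(mb, axis=0)
    return FeatureTable(df, normalized=True)
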