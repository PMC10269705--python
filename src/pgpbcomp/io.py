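"""Plain-text I/O: TSV tables, Newick trees, FASTA and cohort directories.

All artifacts are deterministic text so that pipeline runs are diffable:
genomes.tsv, ani_pairs.tsv, orthogroups.tsv (strains x families counts),
features.tsv, labeled square distance-matrix TSVs, Newick 1.0 trees and
FASTA protein files (reference headers ``id|FAMILY``).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import DistanceMatrix, TreeNode

from pgpbcomp.phylo import (
    distance_matrix_from_frame,
    distance_matrix_to_frame,
    parse_newick,
    write_newick,
)
from pgpbcomp.profiles import FeatureTable
from pgpbcomp.qc import ANIPair, GenomeRecord

GENOME_COLUMNS = [
    "id", "habitat", "taxon", "size_bp", "gc_pct",
    "completeness_pct", "contamination_pct",
]


def write_genomes_tsv(records: Sequence[GenomeRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "id": r.id, "habitat": r.habitat, "taxon": r.taxon,
                "size_bp": r.size_bp, "gc_pct": r.gc_pct,
                "completeness_pct": r.completeness_pct,
                "contamination_pct": r.contamination_pct,
            }
            for r in records
        ],
        columns=GENOME_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_genomes_tsv(path: str | Path) -> list[GenomeRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(GENOME_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"genomes table missing columns: {sorted(missing)}")
    return [
        GenomeRecord(
            str(row.id), str(row.habitat), str(row.taxon), int(row.size_bp),
            float(row.gc_pct), float(row.completeness_pct),
            float(row.contamination_pct),
        )
        for row in df.itertuples(index=False)
    ]


def write_ani_pairs_tsv(pairs: Iterable[ANIPair], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "id_a": p.id_a, "id_b": p.id_b, "ani_pct": p.ani_pct,
                "coverage_ab_pct": p.coverage_ab_pct,
                "coverage_ba_pct": p.coverage_ba_pct,
            }
            for p in pairs
        ],
        columns=["id_a", "id_b", "ani_pct", "coverage_ab_pct", "coverage_ba_pct"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_ani_pairs_tsv(path: str | Path) -> list[ANIPair]:
    df = pd.read_csv(path, sep="\t")
    return [
        ANIPair(str(r.id_a), str(r.id_b), float(r.ani_pct),
                float(r.coverage_ab_pct), float(r.coverage_ba_pct))
        for r in df.itertuples(index=False)
    ]


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="id")


def read_ortho_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="id")
    return df.astype(int)


def write_distance_tsv(dm: DistanceMatrix, path: str | Path) -> None:
    write_matrix_tsv(distance_matrix_to_frame(dm), path)


def read_distance_tsv(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col="id")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return distance_matrix_from_frame(df)


def write_features_tsv(features: FeatureTable, path: str | Path) -> None:
    write_matrix_tsv(features.df, path)


def read_features_tsv(path: str | Path, normalized: bool = False) -> FeatureTable:
    df = pd.read_csv(path, sep="\t", index_col="id")
    df.index = df.index.astype(str)
    return FeatureTable(df, normalized=normalized)


def write_tree(tree: TreeNode, path: str | Path) -> None:
    Path(path).write_text(write_newick(tree) + "\n")


def read_tree(path: str | Path) -> TreeNode:
    return parse_newick(Path(path).read_text())


def write_fasta(entries: Sequence[tuple[str, str]], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=header, description="") for header, seq in entries
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_cohort(cohort, outdir: str | Path) -> dict[str, str]:
    """Write a simulated cohort as a directory of plain-text artifacts."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genomes": out / "genomes.tsv",
        "tree": out / "tree.nwk",
        "orthogroups": out / "orthogroups.tsv",
        "ani_pairs": out / "ani_pairs.tsv",
        "features": out / "features.tsv",
        "truth": out / "truth.json",
    }
    write_genomes_tsv(cohort.records, paths["genomes"])
    write_tree(cohort.tree, paths["tree"])
    write_matrix_tsv(cohort.ortho, paths["orthogroups"])
    write_ani_pairs_tsv(cohort.ani_pairs, paths["ani_pairs"])
    write_features_tsv(cohort.features, paths["features"])
    truth = dict(cohort.truth)
    truth["seed"] = cohort.seed
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}
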