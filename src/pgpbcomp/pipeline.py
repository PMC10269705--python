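"""End-to-end orchestration: simulate/load -> QC -> distances -> clustering
-> pan-genome -> profiles -> statistics, with per-stage seeds and a
machine-readable run report.

A single root seed deterministically derives one seed per stage (stage-name
hashing), so any stage can be rerun alone and see the same random stream it
saw inside the full run. Re-running the pipeline with the same config and
seed reproduces the report byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from pgpbcomp import __version__
from pgpbcomp import io as pio
from pgpbcomp._util import derive_seed
from pgpbcomp.clustering import (
    cluster_composition,
    habitat_concordance,
    hclust_complete,
    pam,
    select_k,
)
from pgpbcomp.pangenome import (
    family_abundance_by_group,
    matched_subsample,
    partition_pangenome,
)
from pgpbcomp.phylo import cophenetic_matrix, subset_distance_matrix
from pgpbcomp.profiles import per_mb
from pgpbcomp.qc import dereplicate, quality_filter
from pgpbcomp.stats import enrichment_scan, permanova
from pgpbcomp.synthetic import SimConfig, simulate_cohort


class InputPaths(BaseModel):
    genomes: str
    tree: str
    orthogroups: str
    ani_pairs: str
    features: str


class PipelineConfig(BaseModel):
    """Declarative pipeline configuration; every threshold is overridable."""

    sim: Optional[dict[str, Any]] = None
    inputs: Optional[InputPaths] = None
    ani_min: float = 99.9
    cov_min: float = 95.0
    min_completeness: float = 95.0
    max_contamination: float = 5.0
    min_identity: float = 40.0
    k_min: int = Field(2, ge=2)
    k_max: int = Field(20, ge=2)
    hclust_clusters: int = 3
    n_per_group: int = 95
    reference_habitat: str = "OA"
    n_perm: int = 999
    seed: int = 0
    out: str = "pipeline_out"

    @model_validator(mode="after")
    def _check_source(self) -> "PipelineConfig":
        if self.sim is None and self.inputs is None:
            raise ValueError("config needs either a sim block or input paths")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})


class RunReport(BaseModel):
    """Machine-readable summary of one pipeline run."""

    version: str
    seed: int
    stage_seeds: dict[str, int]
    n_input: int
    n_after_quality: int
    n_after_dereplication: int
    k_best: int
    silhouette_best: float
    silhouette_curve: list[tuple[int, float]]
    composition: dict[str, dict[str, float]]
    hclust_clusters: int
    concordance_counts: dict[str, int]
    concordance_pct_of_all: dict[str, float]
    partition: dict[str, float]
    matched_panel_sizes: dict[str, int]
    adonis_f: float
    adonis_p: float
    n_perm: int
    n_enrichment_tests: int
    n_enrichment_significant: int
    artifacts: dict[str, str]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> RunReport:
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    stages = ["simulate", "qc", "cluster", "pangenome", "stats"]
    stage_seeds = {s: derive_seed(config.seed, s) for s in stages}
    artifacts: dict[str, str] = {}

    # --- inputs -----------------------------------------------------------
    stage = "simulate"
    try:
        if config.sim is not None:
            sim_cfg = SimConfig(**{**config.sim, "seed": stage_seeds["simulate"]})
            cohort = simulate_cohort(sim_cfg)
            paths = pio.write_cohort(cohort, out / "cohort")
            artifacts.update({f"cohort_{k}": v for k, v in paths.items()})
            records, tree = cohort.records, cohort.tree
            ortho, ani_pairs = cohort.ortho, cohort.ani_pairs
            features = cohort.features
        else:
            assert config.inputs is not None
            records = pio.read_genomes_tsv(config.inputs.genomes)
            tree = pio.read_tree(config.inputs.tree)
            ortho = pio.read_ortho_tsv(config.inputs.orthogroups)
            ani_pairs = pio.read_ani_pairs_tsv(config.inputs.ani_pairs)
            features = pio.read_features_tsv(config.inputs.features)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- QC ---------------------------------------------------------------
    stage = "qc"
    try:
        kept_q, removed_q = quality_filter(
            records, config.min_completeness, config.max_contamination
        )
        derep = dereplicate(
            kept_q, ani_pairs, config.ani_min, config.cov_min,
            seed=stage_seeds["qc"],
        )
        kept_ids = derep.kept_ids
        kept_records = [r for r in kept_q if r.id in set(kept_ids)]
        pio.write_genomes_tsv(kept_records, out / "kept.tsv")
        removed_rows = [
            {"id": rm.record.id, "reason": ",".join(rm.reasons)}
            for rm in removed_q
        ] + [{"id": i, "reason": "redundant"} for i in derep.removed_ids]
        pd.DataFrame(removed_rows, columns=["id", "reason"]).to_csv(
            out / "removed.tsv", sep="\t", index=False
        )
        artifacts["kept"] = str(out / "kept.tsv")
        artifacts["removed"] = str(out / "removed.tsv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    habitats = {r.id: r.habitat for r in kept_records}
    units = {r.id: f"{r.taxon}|{r.habitat}" for r in kept_records}
    sizes = {r.id: r.size_bp for r in kept_records}

    # --- distances + clustering --------------------------------------------
    stage = "cluster"
    try:
        dm = subset_distance_matrix(cophenetic_matrix(tree), sorted(kept_ids))
        pio.write_distance_tsv(dm, out / "dist.tsv")
        artifacts["distances"] = str(out / "dist.tsv")
        k_max = min(config.k_max, len(kept_ids) - 1)
        sel = select_k(dm, config.k_min, k_max, seed=stage_seeds["cluster"])
        assignment = sel.best_assignment
        pd.DataFrame(
            {"id": assignment.labels,
             "cluster": [assignment.cluster_of[s] for s in assignment.labels]}
        ).to_csv(out / "assignment.tsv", sep="\t", index=False)
        pd.DataFrame(sel.curve, columns=["k", "silhouette"]).to_csv(
            out / "silhouette_curve.tsv", sep="\t", index=False
        )
        comp = cluster_composition(assignment, habitats)
        comp.to_csv(out / "composition.tsv", sep="\t")
        features_kept = type(features)(
            features.df.loc[sorted(kept_ids)], normalized=features.normalized
        )
        feats_mb = (
            features_kept if features_kept.normalized
            else per_mb(features_kept, sizes)
        )
        pio.write_features_tsv(feats_mb, out / "features_per_mb.tsv")
        artifacts["features_per_mb"] = str(out / "features_per_mb.tsv")
        hc = hclust_complete(feats_mb, config.hclust_clusters)
        conc = habitat_concordance(hc, habitats)
        artifacts["assignment"] = str(out / "assignment.tsv")
        artifacts["silhouette_curve"] = str(out / "silhouette_curve.tsv")
        artifacts["composition"] = str(out / "composition.tsv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- pan-genome ---------------------------------------------------------
    stage = "pangenome"
    try:
        ortho_kept = ortho.loc[sorted(kept_ids)]
        ortho_kept = ortho_kept.loc[:, (ortho_kept >= 1).any(axis=0)]
        summary, classes = partition_pangenome(ortho_kept, units)
        pd.DataFrame(
            {"family": list(classes), "class": list(classes.values())}
        ).to_csv(out / "partition.tsv", sep="\t", index=False)
        shares = summary.shares()
        (out / "summary.json").write_text(
            json.dumps(
                {
                    "n_total": summary.n_total, "n_core": summary.n_core,
                    "n_accessory": summary.n_accessory,
                    "n_specific": summary.n_specific, "shares": shares,
                },
                indent=2, sort_keys=True,
            )
        )
        n_per_group = min(
            config.n_per_group,
            min(sum(1 for h in habitats.values() if h == hh)
                for hh in set(habitats.values())),
        )
        panels = matched_subsample(
            dm, habitats, config.reference_habitat, n_per_group,
            seed=stage_seeds["pangenome"],
        )
        core_fams = [f for f, c in classes.items() if c == "core"]
        panel_ids = sorted(i for ids in panels.values() for i in ids)
        abundance = family_abundance_by_group(
            ortho_kept.loc[panel_ids], core_fams,
            {i: habitats[i] for i in panel_ids},
        )
        abundance.to_csv(out / "core_abundance.tsv", sep="\t", index=False)
        artifacts["partition"] = str(out / "partition.tsv")
        artifacts["pangenome_summary"] = str(out / "summary.json")
        artifacts["core_abundance"] = str(out / "core_abundance.tsv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- statistics ---------------------------------------------------------
    stage = "stats"
    try:
        ids = feats_mb.strains
        X = feats_mb.df.to_numpy(dtype=float)
        eu = DistanceMatrix(squareform(pdist(X)), ids)
        adonis = permanova(eu, habitats, n_perm=config.n_perm,
                           seed=stage_seeds["stats"])
        taxa = {r.id: r.taxon for r in kept_records}
        enrich = enrichment_scan(feats_mb, habitats, taxa)
        enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        artifacts["enrichment"] = str(out / "enrichment.tsv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    report = RunReport(
        version=__version__,
        seed=config.seed,
        stage_seeds=stage_seeds,
        n_input=len(records),
        n_after_quality=len(kept_q),
        n_after_dereplication=len(kept_ids),
        k_best=sel.k_best,
        silhouette_best=max(s for _, s in sel.curve),
        silhouette_curve=[(k, float(s)) for k, s in sel.curve],
        composition={
            str(c): {col: float(comp.loc[c, col]) for col in comp.columns}
            for c in comp.index
        },
        hclust_clusters=hc.k,
        concordance_counts=conc.concordant_n,
        concordance_pct_of_all=conc.concordant_pct_of_all,
        partition={
            "n_total": summary.n_total, "n_core": summary.n_core,
            "n_accessory": summary.n_accessory,
            "n_specific": summary.n_specific, **{
                f"{k}_pct": v for k, v in shares.items()
            },
        },
        matched_panel_sizes={h: len(v) for h, v in panels.items()},
        adonis_f=adonis.statistic,
        adonis_p=adonis.p_value,
        n_perm=config.n_perm,
        n_enrichment_tests=int(enrich["testable"].sum()),
        n_enrichment_significant=int(
            ((enrich["p"] <= 0.05) & enrich["testable"]).sum()
        ),
        artifacts=artifacts,
    )
    (out / "report.json").write_text(
        json.dumps(report.model_dump(), indent=2, sort_keys=True)
    )
    (out / "report.schema.json").write_text(
        json.dumps(RunReport.model_json_schema(), indent=2, sort_keys=True)
    )
    return report
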