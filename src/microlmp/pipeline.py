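"""End-to-end orchestration: simulate -> phenotype -> associate -> enterotype
-> CAGs -> network, driven by one config with a reproducibility manifest.

Every stochastic stage receives its own substream derived from the single
top-level seed (keyed by stage name), so enabling or disabling one stage
never perturbs another's randomness. A manifest (JSON) records the config
hash, the seed, per-stage row counts, and package versions; rerunning with
the same config and seed reproduces byte-identical TSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enterotype import enterotype_profile, jsd_matrix, select_k
from .network import build_network, network_stats
from .phenotype import adjust_phenotype
from .sparcc import (
    cag_abundance,
    cag_phenotype_correlation,
    cluster_cags,
    scan_cags,
    sparcc,
)
from .synthetic import SimulationConfig, simulate_dataset
from .tables import (
    OtuTable,
    aggregate_by_rank,
    filter_otus,
    read_otu_table,
    read_taxonomy,
    to_relative,
    write_otu_table,
)
from .twopart import permutation_fdr, two_part_scan

__all__ = ["PipelineConfig", "run_pipeline", "ValidationError", "StageError"]


class ValidationError(ValueError):
    """Config problems detected before any stage executes."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Inputs + per-stage parameters. Defaults follow the production
    settings: abundance filter 0.05% / prevalence 1% for the association
    scan, 0.1% for CAG construction, 1000 permutations for the FDR and for
    PERMANOVA, FDR threshold 0.01, edge rule |rho| > 0.5."""

    outdir: str = "pipeline_out"
    seed: int = 0
    # either simulate, or read the three input TSVs
    simulate: dict[str, Any] | None = None
    otu_table: str | None = None
    taxonomy: str | None = None
    metadata: str | None = None
    # association stage
    assoc_min_abundance: float = 0.0005
    assoc_min_prevalence: float = 0.01
    permutations: int = 1000
    fdr_threshold: float = 0.01
    # enterotype stage
    enterotype_rank: str = "genus"
    k_min: int = 2
    k_max: int = 10
    # CAG stage
    cag_min_abundance: float = 0.001
    n_cags: int | None = None
    cag_scan_max: int = 20
    permanova_permutations: int = 1000
    permanova_alpha: float = 0.01
    sparcc_resamples: int = 20
    # network stage
    edge_rule: str = "threshold"
    edge_tau: float = 0.5
    stages: tuple[str, ...] = ("associate", "enterotype", "cag", "network")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValidationError(f"unknown config keys: {sorted(bad)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def validate(self) -> None:
        if self.simulate is None:
            for name in ("otu_table", "taxonomy", "metadata"):
                path = getattr(self, name)
                if path is None:
                    raise ValidationError(f"no simulation block and no {name} path")
                if not Path(path).exists():
                    raise ValidationError(f"{name} path does not exist: {path}")
        unknown = set(self.stages) - {"associate", "enterotype", "cag", "network"}
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")
        if "network" in self.stages and "cag" not in self.stages:
            raise ValidationError("the network stage requires the cag stage")


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def _config_hash(config: PipelineConfig) -> str:
    canon = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the configured stages in order; returns the results bundle.

    Writes each stage's TSV outputs under ``config.outdir`` plus
    ``manifest.json``. Raises ValidationError before touching the
    filesystem if the config is inconsistent, StageError (with the stage
    name) if a stage fails.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": {"microlmp": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "counts": {},
    }
    results: dict[str, Any] = {}

    # ---- inputs -----------------------------------------------------------
    stage = "inputs"
    try:
        if config.simulate is not None:
            sim = SimulationConfig(
                **{**config.simulate, "seed": _stage_seed(config.seed, "simulate")}
            )
            counts, taxonomy, metadata, truth = simulate_dataset(sim)
            results["truth"] = truth
            write_otu_table(counts, outdir / "otu_table.tsv")
            metadata.to_csv(outdir / "metadata.tsv", sep="\t")
        else:
            counts = read_otu_table(config.otu_table, kind="counts")
            taxonomy = read_taxonomy(config.taxonomy)
            metadata = pd.read_csv(config.metadata, sep="\t", index_col=0)
        metadata = adjust_phenotype(metadata)
        metadata.to_csv(outdir / "metadata_adjusted.tsv", sep="\t")
        rel = to_relative(counts)
        results.update(counts=counts, taxonomy=taxonomy, metadata=metadata, rel=rel)
        manifest["counts"]["samples"] = counts.n_samples
        manifest["counts"]["taxa"] = counts.n_taxa
    except Exception as exc:  # noqa: BLE001 — rewrap with stage context
        raise StageError(stage, exc) from exc

    # ---- association ------------------------------------------------------
    if "associate" in config.stages:
        stage = "associate"
        try:
            filtered = filter_otus(
                rel, config.assoc_min_abundance, config.assoc_min_prevalence
            )
            assoc = two_part_scan(filtered, metadata)
            assoc = permutation_fdr(
                assoc, filtered, metadata, B=config.permutations,
                seed=_stage_seed(config.seed, "permutation_fdr"),
            )
            assoc.to_csv(outdir / "association.tsv", sep="\t")
            results["association"] = assoc
            manifest["counts"]["assoc_taxa_tested"] = len(assoc)
            manifest["counts"]["assoc_taxa_significant"] = int(
                (assoc["q_perm"] < config.fdr_threshold).sum()
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    # ---- enterotype -------------------------------------------------------
    if "enterotype" in config.stages:
        stage = "enterotype"
        try:
            genus = aggregate_by_rank(rel, taxonomy, config.enterotype_rank)
            dist = jsd_matrix(genus)
            ent = select_k(dist, range(config.k_min, config.k_max + 1))
            ent.dominant_taxon = enterotype_profile(genus, ent.assignments)
            ent.assignments.to_frame().to_csv(outdir / "enterotypes.tsv", sep="\t")
            pd.DataFrame(
                {"k": list(ent.ch_by_k), "ch": list(ent.ch_by_k.values()),
                 "silhouette": [ent.silhouette_by_k[k] for k in ent.ch_by_k]}
            ).to_csv(outdir / "enterotype_model_selection.tsv", sep="\t", index=False)
            results["enterotype"] = ent
            manifest["counts"]["enterotype_k"] = ent.k_selected
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    # ---- CAGs -------------------------------------------------------------
    if "cag" in config.stages:
        stage = "cag"
        try:
            cag_table_rel = filter_otus(rel, config.cag_min_abundance, 0.0)
            cag_counts = OtuTable(
                counts.data.loc[:, cag_table_rel.taxon_ids], kind="counts"
            )
            sp = sparcc(
                cag_counts, n_resamples=config.sparcc_resamples,
                seed=_stage_seed(config.seed, "sparcc"),
            )
            sp.rho.to_csv(outdir / "sparcc_rho.tsv", sep="\t")
            if config.n_cags is not None:
                assign = cluster_cags(sp.rho, config.n_cags)
                report = None
            else:
                assign, report = scan_cags(
                    sp.rho, range(2, config.cag_scan_max + 1),
                    alpha=config.permanova_alpha,
                    n_perm=config.permanova_permutations,
                    seed=_stage_seed(config.seed, "permanova"),
                )
                report.to_csv(outdir / "cag_scan.tsv", sep="\t", index=False)
                if assign is None:
                    raise RuntimeError("CAG scan found no PERMANOVA-valid cut")
            assign.labels.to_frame().to_csv(outdir / "cag_assignments.tsv", sep="\t")
            cags = cag_abundance(cag_table_rel, assign)
            cags.to_csv(outdir / "cag_abundance.tsv", sep="\t")
            corr = cag_phenotype_correlation(cags, metadata["adj_p"])
            corr.to_csv(outdir / "cag_phenotype.tsv", sep="\t")
            results.update(sparcc=sp, cag_assignment=assign, cag_table=cags,
                           cag_phenotype=corr, cag_scan=report)
            manifest["counts"]["cag_taxa"] = len(assign.labels)
            manifest["counts"]["n_cags"] = assign.n_cags
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    # ---- network ----------------------------------------------------------
    if "network" in config.stages:
        stage = "network"
        try:
            sp = results["sparcc"]
            mean_ab = results["rel"].data[sp.rho.index].mean(axis=0)
            graph = build_network(
                sp.rho, rule=config.edge_rule, tau=config.edge_tau,
                node_abundance=mean_ab,
            )
            stats = network_stats(graph)
            stats.nodes.to_csv(outdir / "network_nodes.tsv", sep="\t")
            edges = pd.DataFrame(
                [(u, v, d["rho"], d["sign"]) for u, v, d in graph.edges(data=True)],
                columns=["source", "target", "rho", "sign"],
            )
            edges.to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
            results.update(graph=graph, network=stats)
            manifest["counts"]["network_nodes"] = graph.number_of_nodes()
            manifest["counts"]["network_edges"] = graph.number_of_edges()
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
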