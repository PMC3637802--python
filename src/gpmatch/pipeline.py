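"""End-to-end orchestration: prepare -> match -> relate -> cluster -> report.

All stage parameters live in one :class:`RunConfig`; shipped defaults are the
standard analysis settings (3 bins, 100 bags, 3 replicates, support 3, stop
at <=5 removals, 60% accuracy gate, top 50 genes, variance threshold 0.05,
2500 nt proximity).  One master seed fans out deterministically to per-stage
and per-phenotype streams so any phenotype can be recomputed in isolation.
Outputs are written with a write-then-rename discipline so an aborted run
leaves no truncated tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass

import numpy as np
import pandas as pd

from gpmatch._random import derive_seed
from gpmatch import geno_prep, pheno_prep, phenoclust, relate
from gpmatch.rf_core import ForestConfig
from gpmatch.selector import (PhenotypeResult, accuracy_gate,
                              iterate_selection, rank_and_augment)
from gpmatch.synth import SimulatedDataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters of one analysis run."""

    # input paths (unused when a dataset object is passed directly)
    genotype_path: str | None = None
    gene_table_paths: tuple[str, ...] = ()
    phenotype_path: str | None = None
    experiment_meta_path: str | None = None

    bins: int = 3                    # terciles for continuous readouts
    bags: int = 100
    replicates: int = 3
    min_support: int = 3
    stop_removals: int = 5
    gate: float = 0.60
    topk: int = 50
    var_min: float = 0.05
    corr_threshold: float = 0.95
    proximity_bp: int = 2500
    keywords: tuple[str, ...] = relate.MOBILE_KEYWORDS
    min_complete: int = 6
    min_class_size: int = 3
    trees: int = 500                 # trees per bag forest
    seed: int = 0
    outdir: str = "gpmatch_run"
    make_figures: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gene_table_paths"] = list(self.gene_table_paths)
        d["keywords"] = list(self.keywords)
        return d


@dataclass
class RunResult:
    config: RunConfig
    summary: dict
    phenotype_results: list[PhenotypeResult]
    relations: pd.DataFrame
    clusters: dict[str, list[relate.GeneCluster]]
    clusterings: dict[str, "phenoclust.StrainClustering"]
    outdir: str


def _atomic_write_text(text: str, path: str) -> None:
    d = os.path.dirname(path) or "."
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    with os.fdopen(fd, "w") as fh:
        fh.write(text)
    os.replace(tmp, path)


def _atomic_write_tsv(df: pd.DataFrame, path: str, index: bool = False) -> None:
    _atomic_write_text(df.to_csv(sep="\t", index=index), path)


def _load_inputs(config: RunConfig):
    if config.genotype_path is None or config.phenotype_path is None:
        raise ValueError("genotype_path and phenotype_path are required "
                         "when no dataset object is given")
    matrix, plasmid = geno_prep.read_genotype_matrix(config.genotype_path)
    gene_tables = {}
    for p in config.gene_table_paths:
        table = geno_prep.read_gene_table(p)
        name = os.path.basename(p)
        ref = name[len("genes_"):-len(".tsv")] if \
            name.startswith("genes_") and name.endswith(".tsv") else name
        gene_tables[ref] = table
    pheno = pheno_prep.read_phenotype_table(config.phenotype_path)
    if config.experiment_meta_path:
        meta = pheno_prep.read_experiment_meta(config.experiment_meta_path)
    else:
        meta = pd.DataFrame({"experiment_id": pheno.columns,
                             "category": None, "readout": "continuous",
                             "description": ""})
    return matrix, plasmid, gene_tables, pheno, meta


def run_all(config: RunConfig,
            dataset: SimulatedDataset | None = None) -> RunResult:
    """Execute every stage and write the run directory.

    ``dataset`` may be an in-memory simulated panel; otherwise inputs are
    read from the paths in ``config``.
    """
    stage = "load"
    try:
        if dataset is not None:
            matrix, plasmid = dataset.genotype, dataset.plasmid_flags
            gene_tables = dataset.gene_tables
            pheno, meta = dataset.phenotypes, dataset.experiment_meta
        else:
            matrix, plasmid, gene_tables, pheno, meta = _load_inputs(config)
        os.makedirs(config.outdir, exist_ok=True)

        stage = "prep-pheno"
        prepared = pheno_prep.prepare_phenotypes(
            pheno, meta, min_class_size=config.min_class_size)
        logger.info("%d usable phenotype units from %d experiments "
                    "(%d experiments unusable)", len(prepared.units),
                    pheno.shape[1], len(prepared.unusable))

        stage = "prep-geno"
        filtered, removed = geno_prep.variance_filter(matrix, config.var_min)
        reduced, groups = geno_prep.collapse_correlated(
            filtered, config.corr_threshold)
        group_map = geno_prep.expansion_map(groups)

        stage = "match"
        results: list[PhenotypeResult] = []
        per_unit_rows = []
        for unit in prepared.units:
            fc = ForestConfig(n_trees=config.trees,
                              n_replicates=config.replicates,
                              seed=derive_seed(config.seed, "match", unit.id))
            bags = pheno_prep.make_bags(
                unit, n_bags=config.bags,
                seed=derive_seed(config.seed, "bags", unit.id))
            sel = iterate_selection(reduced, unit, bags, fc,
                                    min_support=config.min_support,
                                    stop_removals=config.stop_removals)
            gated = sel.usable and accuracy_gate(sel.accuracy, config.gate)
            row = {"phenotype": unit.id,
                   "experiment": unit.experiment_id,
                   "n_positive": len(unit.positive_strains),
                   "accuracy": sel.accuracy,
                   "final_accuracy": sel.final_accuracy, "gated": gated,
                   "iterations": len(sel.history), "n_selected": 0}
            if gated:
                pr = rank_and_augment(sel, group_map, k=config.topk)
                results.append(pr)
                row["n_selected"] = len(pr.genes)
            per_unit_rows.append(row)
        per_unit = pd.DataFrame(per_unit_rows)

        stage = "relate"
        all_records = []
        for pr in results:
            all_records.extend(relate.build_relations(pr, matrix))
        relations = relate.relations_frame(all_records)
        categories = prepared.categories

        clusters: dict[str, list[relate.GeneCluster]] = {}
        related_ogs = (set(relations["og_id"]) if not relations.empty
                       else set())
        phenotypes_of: dict[str, tuple[str, ...]] = {}
        if not relations.empty:
            phenotypes_of = {
                og: tuple(sorted(sub["phenotype"]))
                for og, sub in relations.groupby("og_id")}
        for ref, table in gene_tables.items():
            related = table.loc[table["og_id"].isin(related_ogs)]
            kept, _removed = relate.filter_mobile_elements(
                related, config.keywords)
            cl, singles = relate.extract_clusters(
                kept, ref, config.proximity_bp, phenotypes_of)
            clusters[ref] = cl
            _atomic_write_tsv(relate.clusters_frame(cl),
                              os.path.join(config.outdir,
                                           f"clusters_{ref}.tsv"))
            _atomic_write_tsv(singles, os.path.join(
                config.outdir, f"singletons_{ref}.tsv"))
            if config.make_figures:
                relate.export_relation_figures(
                    relations, table, categories, ref, config.outdir)

        stage = "cluster"
        clusterings: dict[str, phenoclust.StrainClustering] = {}
        clustering_summary = {}
        for category in sorted(categories.unique()):
            ci = phenoclust.build_cluster_input(
                pheno, categories, category, config.min_complete)
            if ci.skipped:
                clustering_summary[category] = {"skipped": True,
                                                "reason": ci.skip_reason}
                continue
            sc = phenoclust.cluster_strains(ci)
            clusterings[category] = sc
            clustering_summary[category] = {
                "skipped": False, "n_experiments": len(ci.experiments)}
            _atomic_write_text(sc.newick, os.path.join(
                config.outdir, f"strain_dendrogram_{category}.nwk"))
            _atomic_write_tsv(phenoclust.linkage_frame(sc), os.path.join(
                config.outdir, f"strain_linkage_{category}.tsv"))

        stage = "report"
        summary = {
            "n_strains": int(matrix.shape[1]),
            "n_ogs": int(matrix.shape[0]),
            "n_ogs_after_variance_filter": int(len(filtered)),
            "n_ogs_after_collapse": int(len(reduced)),
            "n_experiments": int(pheno.shape[1]),
            "n_usable_experiments": int(pheno.shape[1]
                                        - len(prepared.unusable)),
            "n_phenotype_units": len(prepared.units),
            "n_gated_phenotypes": len(results),
            "n_related_ogs": len(related_ogs),
            "n_relations": int(len(relations)),
            "n_clusters": {ref: len(cl) for ref, cl in clusters.items()},
            "clustering": clustering_summary,
        }
        _atomic_write_tsv(per_unit, os.path.join(config.outdir,
                                                 "phenotypes.tsv"))
        for pr in results:
            safe = pr.unit.id.replace(":", "_")
            _atomic_write_tsv(pr.genes.reset_index(), os.path.join(
                config.outdir, f"genes_{safe}.tsv"))
        if not relations.empty:
            _atomic_write_tsv(relations, os.path.join(config.outdir,
                                                      "relations.tsv"))
        _atomic_write_text(json.dumps(summary, indent=2, sort_keys=True),
                           os.path.join(config.outdir, "summary.json"))
        manifest = {
            "config": config.to_dict(),
            "config_sha256": hashlib.sha256(
                json.dumps(config.to_dict(), sort_keys=True).encode()
            ).hexdigest(),
            "seed": config.seed,
            "versions": _versions(),
        }
        _atomic_write_text(json.dumps(manifest, indent=2, sort_keys=True),
                           os.path.join(config.outdir, "manifest.json"))
        return RunResult(config, summary, results, relations, clusters,
                         clusterings, config.outdir)
    except Exception:
        logger.exception("run aborted in stage %r", stage)
        raise


def _versions() -> dict:
    import sklearn
    import scipy

    from gpmatch import __version__
    return {"gpmatch": __version__, "numpy": np.__version__,
            "pandas": pd.__version__, "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__}
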