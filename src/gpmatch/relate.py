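"""Relation classification, gene-strain views, proximity clusters, figures.

Each selected gene-phenotype pair is classified by the predominance of the
gene among the phenotype's positive strains: present in >= 75% of them ->
predominantly present; absent in >= 75% -> predominantly absent; otherwise
present in a subset (a *partial* relation, drawn black).  Crossing the three
presence states with a two-level importance factor (high/low around the
per-phenotype split) gives the 6-colour scheme; black is the 7th for
subset/partial.

Phenotype-related genes of one reference strain are chained into clusters
when consecutive genomic start positions are at most ``proximity_bp`` apart
(operon-scale proximity); mobile-element annotations (transposase,
integrase, phage) are filtered out first because such relations are likely
spurious.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from gpmatch.selector import PhenotypeResult

logger = logging.getLogger(__name__)

MOBILE_KEYWORDS = ("transposase", "integrase", "phage")

PRESENCE_STATES = ("predominantly_present", "predominantly_absent", "subset")

#: colour per (presence state, importance level); black for subset/partial
CATEGORY_COLORS = {
    ("predominantly_present", "high"): "#b2182b",
    ("predominantly_present", "low"): "#ef8a62",
    ("predominantly_absent", "high"): "#2166ac",
    ("predominantly_absent", "low"): "#67a9cf",
    ("subset", "high"): "#000000",
    ("subset", "low"): "#404040",
}


@dataclass(frozen=True)
class RelationRecord:
    og_id: str
    phenotype_id: str
    importance: float
    presence_state: str       # predominantly_present | predominantly_absent | subset
    importance_level: str     # high | low
    partial: bool
    presence_fraction: float

    @property
    def category(self) -> str:
        return f"{self.presence_state}_{self.importance_level}"


@dataclass
class GeneCluster:
    reference_strain: str
    replicon: str
    gene_ids: tuple[str, ...]       # ordered by start position
    og_ids: tuple[str, ...]
    starts: tuple[int, ...]
    phenotype_ids: tuple[str, ...]  # all phenotypes linked to member genes

    @property
    def size(self) -> int:
        return len(self.gene_ids)


def classify_predominance(occurrence, importance: float,
                          importance_split: float,
                          phenotype_id: str = "", og_id: str = "") -> RelationRecord:
    """Apply the >=75% predominance rule to one gene-phenotype pair.

    ``occurrence`` is the gene's 0/1 occurrence over the phenotype's
    positive-class strains.  Both boundaries are inclusive ("at least 75%"
    present, and symmetrically at least 75% absent).
    """
    occ = np.asarray(occurrence, dtype=float)
    if occ.size == 0:
        raise ValueError("empty positive-class strain set")
    f = float(occ.mean())
    if f >= 0.75:
        state = "predominantly_present"
    elif f <= 0.25:
        state = "predominantly_absent"
    else:
        state = "subset"
    level = "high" if importance >= importance_split else "low"
    return RelationRecord(og_id=og_id, phenotype_id=phenotype_id,
                          importance=float(importance), presence_state=state,
                          importance_level=level, partial=(state == "subset"),
                          presence_fraction=f)


def build_relations(result: PhenotypeResult, matrix: pd.DataFrame,
                    importance_split: float | None = None) -> list[RelationRecord]:
    """Classify every selected gene of one gated phenotype.

    The high/low importance split defaults to the per-phenotype median of the
    selected genes' importances.
    """
    imps = result.genes["importance"]
    split = float(imps.median()) if importance_split is None else importance_split
    records = []
    pos = [s for s in result.unit.positive_strains if s in matrix.columns]
    for og, row in result.genes.iterrows():
        if og not in matrix.index:
            logger.warning("OG %s not in genotype matrix, skipped", og)
            continue
        occ = matrix.loc[og, pos]
        records.append(classify_predominance(
            occ, row["importance"], split,
            phenotype_id=result.unit.id, og_id=og))
    return records


def relations_frame(records: list[RelationRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "og_id": r.og_id, "phenotype": r.phenotype_id,
        "importance": r.importance, "presence_state": r.presence_state,
        "importance_level": r.importance_level, "category": r.category,
        "partial": r.partial, "presence_fraction": r.presence_fraction,
    } for r in records])


def gene_strain_view(result: PhenotypeResult, matrix: pd.DataFrame,
                     scores: pd.DataFrame) -> pd.DataFrame:
    """Per-(gene, strain) table merging occurrence with the contribution sign.

    Only the phenotype's retained strains appear.  Categories:
    present/absent x contributing (c > 0) / unrelated (c <= 0 or unscored).
    """
    strains = [s for s in result.unit.strains if s in matrix.columns]
    rows = []
    for og in result.genes.index:
        if og not in matrix.index:
            continue
        occ = matrix.loc[og, strains]
        for s in strains:
            c = float(scores.loc[og, s]) if (og in scores.index and
                                             s in scores.columns) else 0.0
            state = "present" if occ[s] else "absent"
            rel = "contributing" if c > 0 else "unrelated"
            rows.append({"og_id": og, "strain": s, "occurrence": int(occ[s]),
                         "contribution": c, "category": f"{state}_{rel}"})
    return pd.DataFrame(rows)


def filter_mobile_elements(genes: pd.DataFrame,
                           keywords: tuple[str, ...] = MOBILE_KEYWORDS,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop genes whose annotation matches any keyword (case-insensitive
    substring); returns (retained, removed)."""
    if not keywords:
        return genes, genes.iloc[0:0]
    ann = genes.get("annotation", pd.Series("", index=genes.index))
    ann = ann.fillna("").astype(str).str.lower()
    hit = ann.apply(lambda a: any(kw.lower() in a for kw in keywords))
    removed = genes.loc[hit]
    if len(removed):
        logger.info("mobile-element filter removed %d genes", len(removed))
    return genes.loc[~hit], removed


def extract_clusters(genes: pd.DataFrame, reference_strain: str,
                     proximity_bp: int = 2500,
                     phenotypes_of: dict[str, tuple[str, ...]] | None = None,
                     ) -> tuple[list[GeneCluster], pd.DataFrame]:
    """Chain phenotype-related genes into proximity clusters per replicon.

    Genes are sorted by start position; consecutive genes whose starts differ
    by at most ``proximity_bp`` (inclusive) are chained (transitive closure).
    Chains of >= 2 genes are clusters; the rest are returned as singletons.
    Genes lacking coordinates are skipped with a warning.
    """
    needed = {"gene_id", "og_id", "replicon", "start"}
    missing_cols = needed - set(genes.columns)
    if missing_cols:
        raise ValueError(f"gene table missing columns {sorted(missing_cols)}")
    ok = genes["start"].notna() & genes["replicon"].notna()
    if (~ok).any():
        logger.warning("%d genes without coordinates skipped", int((~ok).sum()))
    genes = genes.loc[ok]
    phenotypes_of = phenotypes_of or {}
    clusters: list[GeneCluster] = []
    singleton_rows = []
    for replicon, sub in genes.groupby("replicon", sort=True):
        sub = sub.sort_values(["start", "gene_id"], kind="stable")
        starts = sub["start"].to_numpy()
        breaks = np.flatnonzero(np.diff(starts) > proximity_bp)
        bounds = np.concatenate([[0], breaks + 1, [len(sub)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            chunk = sub.iloc[int(a):int(b)]
            if len(chunk) >= 2:
                phen = sorted(set().union(*(
                    phenotypes_of.get(og, ()) for og in chunk["og_id"])))
                clusters.append(GeneCluster(
                    reference_strain=reference_strain, replicon=str(replicon),
                    gene_ids=tuple(chunk["gene_id"]),
                    og_ids=tuple(chunk["og_id"]),
                    starts=tuple(int(s) for s in chunk["start"]),
                    phenotype_ids=tuple(phen)))
            else:
                singleton_rows.append(chunk.iloc[0])
    singletons = (pd.DataFrame(singleton_rows).reset_index(drop=True)
                  if singleton_rows else genes.iloc[0:0])
    return clusters, singletons


def clusters_frame(clusters: list[GeneCluster]) -> pd.DataFrame:
    return pd.DataFrame([{
        "reference_strain": c.reference_strain, "replicon": c.replicon,
        "size": c.size, "start": c.starts[0], "end": c.starts[-1],
        "gene_ids": ",".join(c.gene_ids), "og_ids": ",".join(c.og_ids),
        "phenotypes": ",".join(c.phenotype_ids),
    } for c in clusters])


def export_relation_figures(relations: pd.DataFrame, gene_table: pd.DataFrame,
                            categories: pd.Series, reference_strain: str,
                            outdir: str | os.PathLike) -> list[str]:
    """One gene x phenotype heat grid per experiment category, plus TSVs.

    Rows are the reference strain's related genes in genomic order
    (replicon, start); columns the category's gated phenotypes; cells the
    6-colour predominance/importance scheme with black for partial
    relations.  Empty categories yield a placeholder TSV and no figure.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    os.makedirs(outdir, exist_ok=True)
    written = []
    if relations.empty:
        exp_of = pd.Series(dtype=object)
    else:
        exp_of = relations["phenotype"].str.split(":").str[0]
    order = gene_table.sort_values(["replicon", "start"],
                                   kind="stable")
    pos_of = {og: i for i, og in enumerate(order["og_id"])}
    cat_keys = list(CATEGORY_COLORS)
    cat_index = {f"{s}_{l}": i for i, (s, l) in enumerate(cat_keys)}
    for category in sorted(categories.unique()):
        exps = set(categories.index[categories == category])
        sel = relations.loc[exp_of.isin(exps)] if not relations.empty \
            else relations
        path = os.path.join(
            outdir, f"relations_{category}_{reference_strain}.tsv")
        sel.to_csv(path, sep="\t", index=False)
        written.append(path)
        if sel.empty:
            continue
        sel = sel.loc[sel["og_id"].isin(pos_of)]
        if sel.empty:
            continue
        phenos = sorted(sel["phenotype"].unique())
        ogs = sorted(sel["og_id"].unique(), key=lambda o: pos_of[o])
        grid = np.full((len(ogs), len(phenos)), -1.0)
        for _, r in sel.iterrows():
            grid[ogs.index(r["og_id"]), phenos.index(r["phenotype"])] = \
                cat_index[r["category"]]
        fig, ax = plt.subplots(
            figsize=(max(3, 0.4 * len(phenos) + 2),
                     max(3, 0.15 * len(ogs) + 1)))
        cmap = ListedColormap(["#ffffff"] + [CATEGORY_COLORS[k]
                                             for k in cat_keys])
        ax.imshow(grid + 1, cmap=cmap, vmin=0, vmax=len(cat_keys),
                  aspect="auto", interpolation="nearest")
        ax.set_xticks(range(len(phenos)))
        ax.set_xticklabels(phenos, rotation=90, fontsize=6)
        ax.set_yticks(range(len(ogs)))
        ax.set_yticklabels(ogs, fontsize=5)
        ax.set_title(f"{reference_strain}: {category}")
        fig.tight_layout()
        figpath = os.path.join(
            outdir, f"relations_{category}_{reference_strain}.png")
        fig.savefig(figpath, dpi=120)
        plt.close(fig)
        written.append(figpath)
    return written
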