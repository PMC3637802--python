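"""Phenotype-based strain clustering, per experiment category.

Strains are clustered hierarchically (Euclidean distance, unweighted
average linkage / UPGMA) from the raw measurements of experiments with
complete data for every strain; clustering is done per experiment category
because readouts are not comparable across experiment types.  A category is
skipped when fewer than ``min_complete`` complete experiments remain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage, to_tree
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)


@dataclass
class ClusterInput:
    category: str
    strains: list[str]
    experiments: list[str]          # complete-data experiments only
    matrix: pd.DataFrame            # strain x experiment, no missing cells
    skipped: bool = False
    skip_reason: str | None = None


@dataclass
class StrainClustering:
    category: str
    strains: list[str]
    linkage_matrix: np.ndarray
    newick: str

    def cophenetic_matrix(self) -> pd.DataFrame:
        d = squareform(cophenet(self.linkage_matrix))
        return pd.DataFrame(d, index=self.strains, columns=self.strains)


def build_cluster_input(pheno: pd.DataFrame, categories: pd.Series,
                        category: str, min_complete: int = 6,
                        standardize: bool = False) -> ClusterInput:
    """Keep the category's experiments with data for every strain; decide skip.

    Default ``min_complete`` = 6: one more than the five complete experiments
    that justified skipping the smallest category in the motivating panel.
    """
    exps = [e for e in pheno.columns
            if categories.get(e) == category]
    complete = [e for e in exps if pheno[e].notna().all()]
    dropped = sorted(set(exps) - set(complete))
    if dropped:
        logger.info("category %s: %d experiments dropped for missing strains",
                    category, len(dropped))
    if len(complete) < min_complete:
        reason = (f"only {len(complete)} complete experiments "
                  f"(< {min_complete})")
        logger.info("category %s skipped: %s", category, reason)
        return ClusterInput(category, list(pheno.index), complete,
                            pheno[complete], skipped=True, skip_reason=reason)
    mat = pheno[complete].astype(float)
    if standardize:
        mat = (mat - mat.mean()) / mat.std(ddof=0).replace(0, 1)
    return ClusterInput(category, list(pheno.index), complete, mat)


def _to_newick(node, names) -> str:
    if node.is_leaf():
        return names[node.id]
    left = _to_newick(node.left, names)
    right = _to_newick(node.right, names)
    bl = node.dist / 2.0
    lb = bl - (node.left.dist / 2.0 if not node.left.is_leaf() else 0.0)
    rb = bl - (node.right.dist / 2.0 if not node.right.is_leaf() else 0.0)
    return f"({left}:{lb:.6g},{right}:{rb:.6g})"


def cluster_strains(ci: ClusterInput) -> StrainClustering:
    """UPGMA over pairwise Euclidean distances of the strain rows.

    Merge heights are non-decreasing (UPGMA on a metric).  The dendrogram is
    exported as a newick string with ultrametric branch lengths (leaf depth =
    half the root merge height).
    """
    if ci.skipped:
        raise ValueError(f"category {ci.category} was skipped: {ci.skip_reason}")
    if len(ci.strains) < 2:
        raise ValueError("need at least 2 strains to cluster")
    if not ci.experiments:
        raise ValueError("need at least 1 complete experiment")
    X = ci.matrix.to_numpy(dtype=float)
    Z = linkage(pdist(X, metric="euclidean"), method="average")
    tree = to_tree(Z)
    newick = _to_newick(tree, ci.strains) + ";"
    return StrainClustering(ci.category, ci.strains, Z, newick)


def linkage_frame(sc: StrainClustering) -> pd.DataFrame:
    Z = sc.linkage_matrix
    return pd.DataFrame(Z, columns=["node_a", "node_b", "height", "size"])
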