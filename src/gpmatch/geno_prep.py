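"""Genotype ingestion, homogeneity filtering, correlated-gene collapsing and
probe-level segment-presence calls.

The occurrence matrix is binary (OG x strain).  Genes present or absent in
nearly all strains cannot separate phenotype classes, so OGs whose
population variance p(1-p) falls below a threshold are removed; on a
38-strain panel the default threshold 0.05 removes exactly the OGs present
in <=2 or >=36 strains.  Perfectly or near-perfectly co-occurring OGs (e.g.
operon members) are collapsed to a single representative before
classification and re-expanded afterwards.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationGroup:
    representative: str
    members: tuple[str, ...]
    threshold: float


def read_genotype_matrix(path: str | os.PathLike) -> tuple[pd.DataFrame, pd.Series]:
    """Read an OG x strain 0/1 TSV; returns (matrix, per-OG plasmid flags).

    Missing calls are treated as absent (CGH calling emits binary calls, so
    missingness is an artifact); the count is logged.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if "plasmid" in df.columns:
        plasmid = df.pop("plasmid").astype(bool)
    else:
        plasmid = pd.Series(False, index=df.index, name="plasmid")
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        logger.warning("genotype matrix: %d missing calls treated as absent",
                       n_missing)
        df = df.fillna(0)
    matrix = df.astype(np.int8)
    bad = ~matrix.isin([0, 1]).all(axis=1)
    if bad.any():
        raise ValueError(f"non-binary genotype values for OGs "
                         f"{matrix.index[bad].tolist()[:5]}")
    if matrix.index.duplicated().any():
        raise ValueError("duplicate OG ids in genotype matrix")
    return matrix, plasmid


def read_gene_table(path: str | os.PathLike) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "og_id", "replicon", "start", "end"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"gene table missing columns {sorted(missing)}")
    if (table["start"] > table["end"]).any():
        raise ValueError("gene table has start > end")
    return table


def variance_filter(matrix: pd.DataFrame,
                    var_min: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop OGs with homogeneous occurrence (population variance < var_min).

    Variance is p(1-p) with p the presence fraction over strains with data.
    Returns (retained matrix, removal log with p and variance per removed OG).
    """
    if matrix.empty:
        raise ValueError("empty genotype matrix")
    if matrix.shape[1] < 2:
        raise ValueError("variance filter needs >= 2 strains")
    values = matrix.to_numpy(dtype=float)
    p = np.nanmean(values, axis=1)
    var = p * (1.0 - p)
    removed_mask = var < var_min
    removed = pd.DataFrame({
        "og_id": matrix.index[removed_mask],
        "presence_fraction": p[removed_mask],
        "variance": var[removed_mask],
    }).set_index("og_id")
    logger.info("variance filter: removed %d of %d OGs (variance < %g)",
                removed_mask.sum(), len(matrix), var_min)
    return matrix.loc[~removed_mask], removed


def collapse_correlated(matrix: pd.DataFrame, threshold: float = 0.95,
                        ) -> tuple[pd.DataFrame, list[CorrelationGroup]]:
    """Group OGs by single-linkage over pairwise Pearson correlation >=
    threshold of their occurrence vectors, keep one representative per group.

    Single linkage (connected components of the thresholded correlation
    graph) is used because downstream re-expansion must add any gene
    correlated to any selected gene.  The representative is the
    lexicographically smallest member id.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"correlation threshold must be in (0, 1], got {threshold}")
    if matrix.empty:
        raise ValueError("empty genotype matrix")
    X = matrix.to_numpy(dtype=np.float64)
    sd = X.std(axis=1)
    variable = sd > 0
    n = len(matrix)
    # constant rows (should not survive the variance filter) stay singletons
    var_idx = np.flatnonzero(variable)
    if len(var_idx) > 1:
        corr = np.corrcoef(X[variable])
        ii, jj = np.nonzero(corr >= threshold)
    else:
        ii = jj = np.array([], dtype=np.intp)
    edges_i = var_idx[ii]
    edges_j = var_idx[jj]
    graph = csr_matrix((np.ones(len(edges_i), dtype=np.int8),
                        (edges_i, edges_j)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    groups: list[CorrelationGroup] = []
    reps: list[str] = []
    ogs = matrix.index.to_numpy()
    for c in range(n_comp):
        members = tuple(sorted(ogs[labels == c]))
        rep = members[0]
        groups.append(CorrelationGroup(rep, members, threshold))
        reps.append(rep)
    groups.sort(key=lambda g: g.representative)
    keep = matrix.index.isin(set(reps))
    reduced = matrix.loc[keep]
    logger.info("correlation collapse: %d OGs -> %d representatives "
                "(r >= %g, single linkage)", n, len(reduced), threshold)
    return reduced, groups


def expansion_map(groups: list[CorrelationGroup]) -> dict[str, tuple[str, ...]]:
    """representative -> full member tuple (for top-list augmentation)."""
    return {g.representative: g.members for g in groups}


def segment_presence(probes: pd.DataFrame, query_strain: str, replicon: str,
                     start: int, end: int, reference_strain: str | None = None,
                     call_threshold: float = -1.0) -> tuple[pd.DataFrame, str]:
    """Per-probe log2(query/reference) over a region plus a segment call.

    The segment is called absent iff the median log ratio over the region's
    probes is <= ``call_threshold`` (default -1, i.e. less than half the
    reference signal).
    """
    if reference_strain is None:
        refs = probes["reference_strain"].unique()
        if len(refs) != 1:
            raise ValueError("ambiguous reference strain; pass it explicitly")
        reference_strain = refs[0]
    in_region = (probes["replicon"] == replicon) & \
        (probes["position"] >= start) & (probes["position"] <= end)
    sub = probes.loc[in_region]
    if sub.empty:
        raise ValueError(f"no probes in {replicon}:{start}-{end}")
    for col in (query_strain, reference_strain):
        if col not in probes.columns:
            raise KeyError(f"strain {col!r} not in probe table")
    ref = sub[reference_strain].to_numpy(dtype=float)
    if (ref <= 0).any():
        raise ValueError("non-positive reference intensities in region")
    qry = sub[query_strain].to_numpy(dtype=float)
    if (qry <= 0).any():
        raise ValueError("non-positive query intensities in region")
    log_ratio = np.log2(qry / ref)
    out = sub[["probe_id", "replicon", "position"]].copy()
    out["log2_ratio"] = log_ratio
    call = "absent" if float(np.median(log_ratio)) <= call_threshold else "present"
    return out.reset_index(drop=True), call
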