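"""Iterative gene selection, accuracy gating and top-gene list construction.

Per phenotype unit, replicate forests are trained on the active gene set and
genes that are not consistently supported (positive contribution for at
least ``min_support`` positive-class strains in every replicate) are removed.
The loop repeats until no more than ``stop_removals`` genes are removed in
an iteration.  Phenotypes whose final OOB accuracy falls below the gate are
dropped from all downstream outputs.  Genes are ranked by phenotype
importance (the sum of contribution scores over positive-class strains), the
top ``k`` are kept, and members of the correlation group of any selected
representative are appended with the representative's importance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from gpmatch.pheno_prep import Bag, PhenotypeUnit
from gpmatch.rf_core import (ForestConfig,
                             replicate_consistency, train_replicates)

logger = logging.getLogger(__name__)


@dataclass
class SelectionState:
    iteration: int
    active: tuple[str, ...]
    removed: tuple[str, ...]


@dataclass
class SelectionResult:
    unit: PhenotypeUnit
    history: list[SelectionState]
    final_scores: pd.DataFrame | None   # mean over replicates, active genes
    #: mean OOB accuracy of the first-iteration replicates, i.e. of forests
    #: trained on the full pre-selection gene set.  This is the phenotype's
    #: classification accuracy used for gating: accuracy measured after
    #: label-informed gene removal is inflated by selection bias and would
    #: pass even label-permuted data.
    accuracy: float
    #: mean OOB accuracy of the last iteration's forests (diagnostic only)
    final_accuracy: float
    usable: bool

    @property
    def active_genes(self) -> list[str]:
        return list(self.final_scores.index) if self.final_scores is not None else []


@dataclass
class PhenotypeResult:
    """Gated, ranked, augmented gene list for one phenotype unit."""

    unit: PhenotypeUnit
    accuracy: float
    genes: pd.DataFrame           # og_id index; importance, provenance, sponsor


def iterate_selection(matrix: pd.DataFrame, unit: PhenotypeUnit,
                      bags: list[Bag], config: ForestConfig,
                      min_support: int = 3,
                      stop_removals: int = 5) -> SelectionResult:
    """Iteratively remove inconsistent genes until removals <= stop_removals.

    The active set never grows, and every non-final iteration removes at
    least ``stop_removals + 1`` genes, so termination is guaranteed.
    """
    active = list(matrix.index)
    history: list[SelectionState] = []
    iteration = 0
    gate_accuracy = float("nan")
    while True:
        iteration += 1
        reps = train_replicates(matrix.loc[active], unit, bags, config,
                                base_key=("iter", iteration))
        if iteration == 1:
            # honest accuracy: estimated before any label-informed removal
            gate_accuracy = float(np.mean([cm.accuracy for cm in reps]))
        kept = replicate_consistency(reps, unit.positive_strains, min_support)
        removed = tuple(g for g in active if g not in set(kept))
        history.append(SelectionState(iteration, tuple(kept), removed))
        logger.debug("%s iteration %d: %d active, %d removed",
                     unit.id, iteration, len(active), len(removed))
        if not kept:
            return SelectionResult(unit, history, None, gate_accuracy,
                                   float("nan"), usable=False)
        active = kept
        if len(removed) <= stop_removals:
            mean_scores = sum(cm.scores for cm in reps) / len(reps)
            final_accuracy = float(np.mean([cm.accuracy for cm in reps]))
            return SelectionResult(unit, history, mean_scores.loc[active],
                                   gate_accuracy, final_accuracy, usable=True)


def accuracy_gate(accuracy: float, min_accuracy: float = 0.60) -> bool:
    """Keep a phenotype iff classified with at least ``min_accuracy``."""
    return bool(accuracy >= min_accuracy)


def phenotype_importance(scores: pd.DataFrame,
                         positive_strains: tuple[str, ...]) -> pd.Series:
    """I(g) = sum of contribution scores over the phenotype's positive strains."""
    pos = [s for s in positive_strains if s in scores.columns]
    return scores[pos].sum(axis=1)


def rank_and_augment(result: SelectionResult,
                     groups: dict[str, tuple[str, ...]] | None = None,
                     k: int = 50) -> PhenotypeResult:
    """Top-k genes by phenotype importance, plus correlated partners.

    Ties at the k-th importance value are all included (so membership does
    not depend on tie order); every member of a correlation group whose
    representative was selected is appended with the representative's
    importance and provenance "correlated".
    """
    if result.final_scores is None:
        raise ValueError(f"phenotype {result.unit.id} has no usable selection")
    imp = phenotype_importance(result.final_scores,
                               result.unit.positive_strains)
    order = imp.sort_values(ascending=False, kind="stable")
    # stable sort on descending importance; break remaining ties by OG id
    order = order.iloc[np.lexsort((order.index, -order.to_numpy()))]
    if len(order) > k:
        cutoff = order.iloc[k - 1]
        top = order[order >= cutoff]     # keep boundary ties
    else:
        top = order
    rows = [{"og_id": g, "importance": float(v),
             "provenance": "selected", "sponsor": g}
            for g, v in top.items()]
    selected = {r["og_id"] for r in rows}
    if groups:
        for g, v in top.items():
            for member in groups.get(g, ()):
                if member not in selected:
                    selected.add(member)
                    rows.append({"og_id": member, "importance": float(v),
                                 "provenance": "correlated", "sponsor": g})
    genes = pd.DataFrame(rows).set_index("og_id")
    return PhenotypeResult(result.unit, result.accuracy, genes)
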