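"""Random-Forest training over balanced bags with casewise contribution scores.

One forest is trained per bag; a strain's predicted class is the majority
vote over all trees (across bags) for which the strain was out-of-bag (OOB).
A strain is OOB for a tree if it was not drawn into the tree's bootstrap --
strains left out of a bag entirely count as OOB for all of that bag's trees.

The contribution score c(g, s) is a casewise permutation importance: for
every tree and every OOB occurrence of strain s, the margin of the true
class (p_true - p_other from the tree's leaf estimate) is compared before
and after permuting gene g's values among the tree's OOB strains; c(g, s)
is the mean decrease over all OOB occurrences of s.  A positive score means
the gene helps classify that strain correctly.  Trees that never split on g
contribute a decrease of exactly zero.

Bagging is implemented directly over scikit-learn decision trees so that
per-tree bootstrap membership, votes and leaf estimates are all accessible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from gpmatch._random import seed_sequence
from gpmatch.pheno_prep import Bag, PhenotypeUnit

logger = logging.getLogger(__name__)


@dataclass
class ForestConfig:
    """Forest hyper-parameters; one forest of ``n_trees`` is grown per bag."""

    n_trees: int = 500
    features_per_split: int | str = "sqrt"   # floor(sqrt(m)), the RF default
    n_replicates: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class ContributionMatrix:
    """Per-(OG, strain) contribution scores plus OOB classification accuracy."""

    scores: pd.DataFrame          # OG x strain
    oob_counts: pd.Series         # per strain, #trees for which it was OOB
    correct: pd.Series            # per strain with >=1 OOB evaluation
    accuracy: float


def _p_positive(tree: DecisionTreeClassifier, X32: np.ndarray) -> np.ndarray:
    """Tree-estimated P(class 1) per row, via the raw tree structure."""
    val = tree.tree_.predict(X32)
    if val.ndim == 3:            # (n, n_outputs, n_classes) in some versions
        val = val[:, 0, :]
    total = val.sum(axis=1)
    classes = tree.classes_
    if len(classes) == 1:
        return np.full(X32.shape[0], 1.0 if classes[0] == 1 else 0.0)
    pos = int(np.flatnonzero(classes == 1)[0])
    return val[:, pos] / total


def train_and_score(matrix: pd.DataFrame, unit: PhenotypeUnit,
                    bags: list[Bag], config: ForestConfig,
                    seed=None) -> ContributionMatrix:
    """Train one forest per bag and score every (gene, strain) pair.

    ``matrix`` is the reduced OG x strain occurrence matrix; only the unit's
    retained strains are used.  Deterministic for a fixed seed.
    """
    config.validate()
    if matrix.shape[0] < 1:
        raise ValueError("need at least one feature")
    for bag in bags:
        if not bag.positive or not bag.negative:
            raise ValueError("single-class bag")
    strains = list(unit.strains)
    if len(unit.positive_strains) < 2 or len(unit.negative_strains) < 2:
        raise ValueError("need >= 2 strains per class")
    rng = np.random.default_rng(
        seed_sequence(config.seed, "forest", unit.id) if seed is None else seed)

    n = len(strains)
    m = matrix.shape[0]
    strain_pos = {s: i for i, s in enumerate(strains)}
    X = np.ascontiguousarray(matrix[strains].to_numpy(dtype=np.float32).T)
    y = np.zeros(n, dtype=np.intp)
    for s in unit.positive_strains:
        y[strain_pos[s]] = 1
    sign = np.where(y == 1, 1.0, -1.0)

    sum_c = np.zeros((m, n))
    oob_count = np.zeros(n, dtype=np.int64)
    votes_pos = np.zeros(n, dtype=np.int64)
    votes_neg = np.zeros(n, dtype=np.int64)

    for bag in bags:
        bag_idx = np.array([strain_pos[s] for s in bag.strains], dtype=np.intp)
        nb = len(bag_idx)
        for _ in range(config.n_trees):
            boot = bag_idx[rng.integers(0, nb, nb)]
            tree = DecisionTreeClassifier(
                max_features=config.features_per_split,
                random_state=int(rng.integers(2**31 - 1)))
            # X is pre-validated float32; skipping re-validation per tree
            tree.fit(X[boot], y[boot], check_input=False)

            oob_mask = np.ones(n, dtype=bool)
            oob_mask[boot] = False
            oob = np.flatnonzero(oob_mask)
            if oob.size == 0:
                continue
            Xo = np.ascontiguousarray(X[oob])
            p_pos = _p_positive(tree, Xo)
            pred_pos = p_pos > 0.5                      # tie -> negative class
            votes_pos[oob[pred_pos]] += 1
            votes_neg[oob[~pred_pos]] += 1
            oob_count[oob] += 1

            margin0 = (2.0 * p_pos - 1.0) * sign[oob]
            used = np.unique(tree.tree_.feature)
            used = used[used >= 0]
            for f in used:
                col = Xo[:, f].copy()
                Xo[:, f] = col[rng.permutation(oob.size)]
                p_perm = _p_positive(tree, Xo)
                Xo[:, f] = col
                margin_perm = (2.0 * p_perm - 1.0) * sign[oob]
                sum_c[f, oob] += margin0 - margin_perm

    never_oob = oob_count == 0
    if never_oob.any():
        names = [strains[i] for i in np.flatnonzero(never_oob)]
        warnings.warn(f"strains never out-of-bag, excluded from accuracy: "
                      f"{names}", stacklevel=2)
    denom = np.maximum(oob_count, 1)
    scores = pd.DataFrame(sum_c / denom, index=matrix.index, columns=strains)

    pred = votes_pos > votes_neg                        # tie -> negative class
    evaluated = ~never_oob
    correct = pd.Series((pred == (y == 1))[evaluated],
                        index=[s for s, e in zip(strains, evaluated) if e])
    accuracy = float(correct.mean()) if len(correct) else float("nan")
    return ContributionMatrix(
        scores=scores,
        oob_counts=pd.Series(oob_count, index=strains),
        correct=correct, accuracy=accuracy)


def train_replicates(matrix: pd.DataFrame, unit: PhenotypeUnit,
                     bags: list[Bag], config: ForestConfig,
                     base_key: tuple = ()) -> list[ContributionMatrix]:
    """The same data classified ``n_replicates`` times with different seeds."""
    out = []
    for r in range(config.n_replicates):
        ss = seed_sequence(config.seed, "replicate", unit.id, *base_key, r)
        out.append(train_and_score(matrix, unit, bags, config, seed=ss))
    return out


def replicate_consistency(matrices: list[ContributionMatrix],
                          positive_strains: tuple[str, ...],
                          min_support: int = 3) -> list[str]:
    """Genes consistently related to the phenotype across replicates.

    A gene is kept iff in *every* replicate it has a strictly positive
    contribution score for at least ``min_support`` strains of the positive
    class (intersection across replicates, the strictest reading of
    consistency).
    """
    if not matrices:
        raise ValueError("no replicates given")
    index = matrices[0].scores.index
    for cm in matrices[1:]:
        if not cm.scores.index.equals(index):
            raise ValueError("replicates computed on different gene sets")
    pos = [s for s in positive_strains if s in matrices[0].scores.columns]
    keep = np.ones(len(index), dtype=bool)
    for cm in matrices:
        support = (cm.scores[pos].to_numpy() > 0).sum(axis=1)
        keep &= support >= min_support
    return index[keep].tolist()
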