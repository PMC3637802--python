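"""Forest training over bags: OOB accuracy, casewise contribution scores."""

import numpy as np
import pandas as pd
import pytest

from gpmatch.pheno_prep import Bag, PhenotypeUnit, make_bags
from gpmatch.rf_core import (ContributionMatrix, ForestConfig,
                             replicate_consistency, train_and_score,
                             train_replicates)


def _toy_problem(n_pos=8, n_neg=8, n_noise=8, seed=0, perfect=True):
    """A matrix with one perfectly separating feature plus noise features."""
    rng = np.random.default_rng(seed)
    strains = [f"p{i}" for i in range(n_pos)] + [f"n{i}" for i in range(n_neg)]
    unit = PhenotypeUnit("exp", "1", tuple(strains[:n_pos]),
                         tuple(strains[n_pos:]))
    rows = {}
    if perfect:
        rows["og_signal"] = [1] * n_pos + [0] * n_neg
    for i in range(n_noise):
        rows[f"og_noise{i:02d}"] = rng.integers(0, 2, n_pos + n_neg).tolist()
    m = pd.DataFrame(rows).T
    m.columns = strains
    m.index.name = "og_id"
    return m, unit


class TestTrainAndScore:
    def test_perfect_feature_gets_top_contribution_and_accuracy_one(self):
        m, unit = _toy_problem(seed=1)
        bags = make_bags(unit, n_bags=20, seed=1)
        cm = train_and_score(m, unit, bags, ForestConfig(n_trees=25, seed=1))
        assert cm.accuracy == 1.0
        totals = cm.scores.sum(axis=1)
        assert totals.idxmax() == "og_signal"
        assert totals["og_signal"] > totals.drop("og_signal").max()

    def test_permuted_labels_mean_contribution_near_zero(self):
        """Permutation null: every gene's mean score ~ 0, accuracy ~ 0.5."""
        rng = np.random.default_rng(3)
        means, accs = [], []
        for rep in range(10):
            m, unit = _toy_problem(n_noise=15, seed=100 + rep, perfect=False)
            bags = make_bags(unit, n_bags=20, seed=rep)
            cm = train_and_score(m, unit, bags,
                                 ForestConfig(n_trees=25, seed=rep))
            means.append(cm.scores.to_numpy().mean())
            accs.append(cm.accuracy)
        assert abs(np.mean(means)) < 0.02
        assert 0.25 < np.mean(accs) < 0.75

    def test_constant_feature_contributes_nothing(self):
        m, unit = _toy_problem(seed=5)
        m.loc["og_const"] = 0
        bags = make_bags(unit, n_bags=20, seed=5)
        cm = train_and_score(m, unit, bags, ForestConfig(n_trees=25, seed=5))
        # a constant column is never split on -> its score is exactly 0
        assert (cm.scores.loc["og_const"] == 0).all()

    def test_deterministic_given_seed(self):
        m, unit = _toy_problem(seed=2)
        bags = make_bags(unit, n_bags=10, seed=2)
        a = train_and_score(m, unit, bags, ForestConfig(n_trees=10, seed=9))
        b = train_and_score(m, unit, bags, ForestConfig(n_trees=10, seed=9))
        pd.testing.assert_frame_equal(a.scores, b.scores)
        assert a.accuracy == b.accuracy

    def test_separable_accuracy_with_larger_forest(self):
        m, unit = _toy_problem(n_noise=12, seed=5)
        bags = make_bags(unit, n_bags=10, seed=5)
        cm = train_and_score(m, unit, bags, ForestConfig(n_trees=10, seed=5))
        assert cm.accuracy >= 0.9    # >= 100 trees in total

    def test_zero_trees_errors(self):
        m, unit = _toy_problem()
        bags = make_bags(unit, n_bags=2, seed=0)
        with pytest.raises(ValueError):
            train_and_score(m, unit, bags, ForestConfig(n_trees=0))

    def test_single_class_bag_errors(self):
        m, unit = _toy_problem()
        bad = [Bag(strains=unit.positive_strains,
                   positive=unit.positive_strains, negative=())]
        with pytest.raises(ValueError, match="single-class"):
            train_and_score(m, unit, bad, ForestConfig(n_trees=5))


class TestReplicateConsistency:
    def _fake(self, scores: pd.DataFrame) -> ContributionMatrix:
        n = scores.shape[1]
        return ContributionMatrix(
            scores=scores,
            oob_counts=pd.Series(1, index=scores.columns),
            correct=pd.Series(True, index=scores.columns), accuracy=1.0)

    def test_two_strain_support_dropped_with_min_support_3(self):
        pos = ("a", "b", "c", "d")
        idx = ["g1", "g2"]
        base = pd.DataFrame(1.0, index=idx, columns=pos)
        weak = base.copy()
        weak.loc["g1", ["c", "d"]] = -1.0   # positive for only 2 strains
        kept = replicate_consistency([self._fake(base), self._fake(weak)],
                                     pos, min_support=3)
        assert kept == ["g2"]

    def test_all_positive_always_kept(self):
        pos = ("a", "b", "c")
        scores = pd.DataFrame(0.5, index=["g1"], columns=pos)
        reps = [self._fake(scores)] * 3
        assert replicate_consistency(reps, pos, min_support=3) == ["g1"]

    def test_matches_bruteforce_rule(self):
        rng = np.random.default_rng(11)
        pos = tuple(f"p{i}" for i in range(6))
        neg = tuple(f"n{i}" for i in range(4))
        idx = [f"g{i}" for i in range(30)]
        reps = [self._fake(pd.DataFrame(rng.normal(size=(30, 10)),
                                        index=idx, columns=pos + neg))
                for _ in range(3)]
        kept = replicate_consistency(reps, pos, min_support=3)
        expected = [g for g in idx
                    if all((r.scores.loc[g, list(pos)] > 0).sum() >= 3
                           for r in reps)]
        assert kept == expected

    def test_mismatched_gene_sets_error(self):
        a = self._fake(pd.DataFrame(1.0, index=["g1"], columns=["a", "b", "c"]))
        b = self._fake(pd.DataFrame(1.0, index=["g2"], columns=["a", "b", "c"]))
        with pytest.raises(ValueError):
            replicate_consistency([a, b], ("a", "b", "c"))


def test_replicates_differ_but_are_reproducible():
    m, unit = _toy_problem(seed=4)
    bags = make_bags(unit, n_bags=5, seed=4)
    fc = ForestConfig(n_trees=5, n_replicates=3, seed=4)
    reps1 = train_replicates(m, unit, bags, fc)
    reps2 = train_replicates(m, unit, bags, fc)
    for a, b in zip(reps1, reps2):
        pd.testing.assert_frame_equal(a.scores, b.scores)
    assert not reps1[0].scores.equals(reps1[1].scores)
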