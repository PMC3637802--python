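"""Discretization, phenotype-unit enumeration, balanced bags, categories."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gpmatch.pheno_prep import (PhenotypeUnit, categorize_experiments,
                                discretize_experiment, enumerate_phenotypes,
                                make_bags, prepare_phenotypes)


def _series(values, prefix="s"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))],
                     name="exp")


class TestDiscretize:
    def test_terciles_of_1_to_9(self):
        """Sort-and-split oracle: 1..9 -> low {1,2,3}, high {7,8,9}."""
        pc = discretize_experiment(_series([1, 2, 3, 4, 5, 6, 7, 8, 9.0]),
                                   "continuous")
        assert pc.usable
        low = set(pc.labels.index[pc.labels == "low"])
        high = set(pc.labels.index[pc.labels == "high"])
        assert low == {"s0", "s1", "s2"}
        assert high == {"s6", "s7", "s8"}
        assert {s for s, r in pc.excluded.items() if r == "middle bin"} == \
            {"s3", "s4", "s5"}

    def test_ordinal_passthrough_levels_become_digit_classes(self):
        pc = discretize_experiment(
            _series([0, 0, 0, 1, 1, 1, 2, 2, 2.0]), "ordinal")
        assert pc.usable
        assert pc.classes == ["0", "1", "2"]

    def test_constant_column_unusable(self):
        pc = discretize_experiment(_series([1.0] * 8), "binary")
        assert not pc.usable and "fewer than 2" in pc.reason

    def test_all_missing_unusable(self):
        pc = discretize_experiment(_series([np.nan] * 5), "continuous")
        assert not pc.usable
        assert all(r == "missing" for r in pc.excluded.values())

    def test_small_class_flags_experiment_unusable(self):
        pc = discretize_experiment(_series([0, 0, 0, 0, 0, 0, 1, 1.0]),
                                   "binary", min_class_size=3)
        assert not pc.usable and "below min size" in pc.reason

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        values = _series(rng.normal(size=12))
        pc = discretize_experiment(values, "continuous")
        perm = values.sample(frac=1, random_state=1)
        pc2 = discretize_experiment(perm, "continuous")
        pd.testing.assert_series_equal(
            pc.labels.sort_index(), pc2.labels.sort_index())


class TestEnumerate:
    @pytest.mark.parametrize("values,readout,n_units", [
        ([1, 1, 1, 2, 2, 2, 3, 3, 3.0], "continuous", 2),   # low/high
        ([0, 0, 0, 1, 1, 1, 2, 2, 2.0], "ordinal", 3),
    ])
    def test_unit_count(self, values, readout, n_units):
        pc = discretize_experiment(_series(values), readout)
        units = enumerate_phenotypes(pc)
        assert len(units) == n_units
        for u in units:
            assert set(u.positive_strains).isdisjoint(u.negative_strains)
            assert set(u.strains) == set(pc.labels.index)

    def test_middle_bin_strains_in_no_unit(self):
        pc = discretize_experiment(_series(list(range(9))), "continuous")
        units = enumerate_phenotypes(pc)
        mid = {s for s, r in pc.excluded.items() if r == "middle bin"}
        for u in units:
            assert not mid & set(u.strains)


class TestBags:
    def _unit(self, n_pos, n_neg):
        return PhenotypeUnit("e", "1",
                             tuple(f"p{i}" for i in range(n_pos)),
                             tuple(f"n{i}" for i in range(n_neg)))

    def test_equal_classes_bag_is_everyone(self):
        bags = make_bags(self._unit(10, 10), n_bags=5, seed=0)
        for b in bags:
            assert len(b.strains) == 20
            assert len(b.positive) == len(b.negative) == 10

    def test_imbalanced_30_8(self):
        """Balancing rule: 8 minority + 8 sampled majority = 16 per bag."""
        bags = make_bags(self._unit(30, 8), n_bags=100, seed=1)
        assert len(bags) == 100
        for b in bags:
            assert len(b.strains) == 16
            assert len(b.positive) == len(b.negative) == 8
            assert set(b.negative) == {f"n{i}" for i in range(8)}  # minority
            assert len(set(b.positive)) == 8   # sampled without replacement

    def test_default_bag_count_is_100(self):
        assert len(make_bags(self._unit(6, 4), seed=0)) == 100

    def test_empty_class_errors(self):
        with pytest.raises(ValueError):
            make_bags(PhenotypeUnit("e", "1", (), ("a", "b")), seed=0)

    def test_deterministic(self):
        u = self._unit(20, 5)
        assert make_bags(u, 10, seed=3) == make_bags(u, 10, seed=3)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(n_pos=st.integers(3, 25), n_neg=st.integers(3, 25),
           seed=st.integers(0, 1000))
    def test_every_bag_balanced_minority_complete(self, n_pos, n_neg, seed):
        u = self._unit(n_pos, n_neg)
        minority = set(u.positive_strains if n_pos <= n_neg
                       else u.negative_strains)
        for b in make_bags(u, n_bags=10, seed=seed):
            assert len(b.positive) == len(b.negative)
            assert minority <= set(b.strains)


class TestCategories:
    def test_keyword_and_fallback_rules(self):
        meta = pd.DataFrame({
            "experiment_id": ["a", "b", "c", "d"],
            "category": [None, None, None, "metal"],
            "description": ["50CH API growth on arabinose",
                            "growth test on medium with nisin",
                            "", "whatever"],
        })
        cats = categorize_experiments(meta)
        assert cats["a"] == "sugar"
        assert cats["b"] == "other"     # nisin tests fall into "other"
        assert cats["c"] == "other"     # empty description -> fallback
        assert cats["d"] == "metal"     # explicit category wins


def test_prepare_phenotypes_logs_unusable(small_dataset):
    prepared = prepare_phenotypes(small_dataset.phenotypes,
                                  small_dataset.experiment_meta)
    n_exp = small_dataset.phenotypes.shape[1]
    assert len(prepared.units) > 0
    usable = n_exp - len(prepared.unusable)
    per_exp = {}
    for u in prepared.units:
        per_exp.setdefault(u.experiment_id, 0)
        per_exp[u.experiment_id] += 1
    assert len(per_exp) == usable
    assert all(v >= 2 for v in per_exp.values())
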