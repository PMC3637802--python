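"""Phenotype ingestion, discretization into classes, and balanced bagging.

A "phenotype" downstream is one class of one experiment (e.g. "no growth on
melibiose"): each retained class of each usable experiment becomes one binary
one-vs-rest classification task against the experiment's other retained
strains.  Continuous readouts are discretized into equal-frequency terciles
and the middle tercile is excluded; binary and ordinal readouts pass through
with every observed level as a class.  Class imbalance is countered by
drawing class-balanced bags of strains.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gpmatch._random import spawn_rng
from gpmatch.synth import CATEGORIES

logger = logging.getLogger(__name__)

#: case-insensitive description keywords -> experiment category ("other" is
#: the fallback, so e.g. a nisin growth test lands there)
CATEGORY_KEYWORDS: dict[str, tuple[str, ...]] = {
    "sugar": ("api", "50ch", "sugar", "carbohydrate"),
    "antibiotic": ("antibiotic",),
    "metal": ("metal",),
    "milk_polysaccharide": ("milk", "polysaccharide"),
}


@dataclass(frozen=True)
class Experiment:
    id: str
    category: str
    readout: str
    description: str = ""


@dataclass
class PhenotypeClass:
    """Discretized class labels of one experiment."""

    experiment_id: str
    labels: pd.Series                 # strain -> class label (retained only)
    excluded: dict[str, str]          # strain -> reason (missing | middle bin)
    usable: bool
    reason: str | None = None         # why unusable

    @property
    def classes(self) -> list[str]:
        return sorted(self.labels.unique()) if len(self.labels) else []


@dataclass(frozen=True)
class PhenotypeUnit:
    """One binary one-vs-rest task: one class of one experiment."""

    experiment_id: str
    class_label: str
    positive_strains: tuple[str, ...]
    negative_strains: tuple[str, ...]

    @property
    def id(self) -> str:
        return f"{self.experiment_id}:{self.class_label}"

    @property
    def strains(self) -> tuple[str, ...]:
        return self.positive_strains + self.negative_strains


@dataclass(frozen=True)
class Bag:
    """A class-balanced strain subsample."""

    strains: tuple[str, ...]
    positive: tuple[str, ...]
    negative: tuple[str, ...]


def _format_level(v) -> str:
    """Ordinal/binary levels label classes by their digit, as in the views."""
    f = float(v)
    return str(int(f)) if f == int(f) else str(f)


def discretize_experiment(values: pd.Series, readout: str,
                          min_class_size: int = 3) -> PhenotypeClass:
    """Turn one experiment's measurements into class labels.

    Continuous readouts are split into equal-frequency terciles (stable
    rank-based, scale-free across heterogeneous assays); the middle tercile
    is excluded and the outer two become classes "low" and "high".  Binary
    and ordinal readouts pass through, one class per observed level.  An
    experiment is unusable if fewer than two classes remain or any retained
    class has fewer than ``min_class_size`` strains.
    """
    eid = values.name if values.name is not None else "experiment"
    excluded = {s: "missing" for s in values.index[values.isna()]}
    obs = values.dropna()
    if obs.empty:
        return PhenotypeClass(eid, pd.Series(dtype=object), excluded,
                              usable=False, reason="all values missing")
    if readout == "continuous":
        order = obs.sort_values(kind="stable")
        parts = np.array_split(np.arange(len(order)), 3)
        low = order.index[parts[0]]
        mid = order.index[parts[1]]
        high = order.index[parts[2]]
        labels = pd.Series(index=obs.index, dtype=object)
        labels.loc[low] = "low"
        labels.loc[high] = "high"
        for s in mid:
            excluded[s] = "middle bin"
        labels = labels.dropna()
    elif readout in ("binary", "ordinal"):
        labels = obs.map(_format_level)
    else:
        raise ValueError(f"unknown readout {readout!r}")

    counts = labels.value_counts()
    if len(counts) < 2:
        return PhenotypeClass(eid, labels, excluded, usable=False,
                              reason="fewer than 2 classes")
    if (counts < min_class_size).any():
        small = counts[counts < min_class_size].index.tolist()
        return PhenotypeClass(
            eid, labels, excluded, usable=False,
            reason=f"class(es) {small} below min size {min_class_size}")
    return PhenotypeClass(eid, labels, excluded, usable=True)


def enumerate_phenotypes(pc: PhenotypeClass) -> list[PhenotypeUnit]:
    """One binary one-vs-rest unit per retained class of a usable experiment."""
    if not pc.usable:
        raise ValueError(f"experiment {pc.experiment_id} is not usable: "
                         f"{pc.reason}")
    units = []
    for label in pc.classes:
        pos = tuple(pc.labels.index[pc.labels == label])
        neg = tuple(pc.labels.index[pc.labels != label])
        units.append(PhenotypeUnit(pc.experiment_id, label, pos, neg))
    return units


def make_bags(unit: PhenotypeUnit, n_bags: int = 100,
              seed: int = 0, rng: np.random.Generator | None = None) -> list[Bag]:
    """Class-balanced bags: every minority strain plus an equal-size sample
    of the majority class, drawn without replacement within a bag."""
    if not unit.positive_strains or not unit.negative_strains:
        raise ValueError("both classes must be non-empty to build bags")
    if n_bags < 1:
        raise ValueError("n_bags must be >= 1")
    if rng is None:
        rng = spawn_rng(seed, "bags", unit.id)
    pos, neg = list(unit.positive_strains), list(unit.negative_strains)
    if len(pos) <= len(neg):
        minority, majority, min_is_pos = pos, neg, True
    else:
        minority, majority, min_is_pos = neg, pos, False
    k = len(minority)
    bags = []
    for _ in range(n_bags):
        pick = rng.choice(len(majority), size=k, replace=False)
        sampled = [majority[i] for i in sorted(pick)]
        if min_is_pos:
            b_pos, b_neg = tuple(minority), tuple(sampled)
        else:
            b_pos, b_neg = tuple(sampled), tuple(minority)
        bags.append(Bag(strains=b_pos + b_neg, positive=b_pos, negative=b_neg))
    return bags


def categorize_experiments(meta: pd.DataFrame) -> pd.Series:
    """Assign each experiment exactly one of the 5 categories.

    An explicit valid ``category`` column wins; otherwise the description is
    matched against keywords; anything unmatched falls into "other".
    """
    out = {}
    for _, row in meta.iterrows():
        eid = row["experiment_id"]
        cat = row.get("category")
        if isinstance(cat, str) and cat in CATEGORIES:
            out[eid] = cat
            continue
        desc = str(row.get("description") or "").lower()
        assigned = "other"
        for category, keywords in CATEGORY_KEYWORDS.items():
            if any(kw in desc for kw in keywords):
                assigned = category
                break
        out[eid] = assigned
    return pd.Series(out, name="category")


@dataclass
class PreparedPhenotypes:
    """All usable phenotype units of a table, plus the exclusion log."""

    classes: dict[str, PhenotypeClass]
    units: list[PhenotypeUnit]
    categories: pd.Series
    unusable: dict[str, str] = field(default_factory=dict)


def prepare_phenotypes(pheno: pd.DataFrame, meta: pd.DataFrame,
                       min_class_size: int = 3) -> PreparedPhenotypes:
    """Discretize every experiment and enumerate all usable phenotype units."""
    readouts = meta.set_index("experiment_id")["readout"]
    categories = categorize_experiments(meta)
    classes, units, unusable = {}, [], {}
    for eid in pheno.columns:
        readout = readouts.get(eid, "continuous")
        pc = discretize_experiment(pheno[eid], readout, min_class_size)
        classes[eid] = pc
        if pc.usable:
            units.extend(enumerate_phenotypes(pc))
        else:
            unusable[eid] = pc.reason or "unusable"
            logger.info("experiment %s unusable: %s", eid, pc.reason)
    return PreparedPhenotypes(classes, units, categories, unusable)


def read_phenotype_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def read_experiment_meta(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
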