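import numpy as np
import pytest

from gpmatch import geno_prep, pheno_prep
from gpmatch.rf_core import ForestConfig
from gpmatch.selector import iterate_selection, rank_and_augment
from gpmatch.synth import SimConfig, simulate_dataset

SMALL_PLAN = (
    ("sugar", "ordinal", 3),
    ("antibiotic", "continuous", 4),
    ("metal", "ordinal", 3),
    ("milk_polysaccharide", "continuous", 3),
    ("other", "binary", 3),
)


@pytest.fixture(scope="session")
def small_dataset():
    """A small panel with one planted relation of each kind."""
    cfg = SimConfig(
        n_strains=24, n_ogs=150, n_plasmid_ogs=10, n_reference_strains=2,
        n_causal_clusters=1, n_inverse_clusters=1, n_partial_pairs=1,
        cluster_size_range=(3, 5), penetrance=1.0, label_noise=0.0,
        missing_rate=0.05, experiment_plan=SMALL_PLAN, seed=42)
    return simulate_dataset(cfg)


def recovery_sim_config(seed: int, direction: str = "direct",
                        cluster_size: int = 5, n_ogs: int = 500) -> SimConfig:
    """One planted cluster among noise OGs; noise-free labels."""
    return SimConfig(
        n_strains=38, n_ogs=n_ogs, n_plasmid_ogs=0, n_reference_strains=2,
        n_causal_clusters=1 if direction == "direct" else 0,
        n_inverse_clusters=1 if direction == "inverse" else 0,
        n_partial_pairs=0, cluster_size_range=(cluster_size, cluster_size),
        penetrance=1.0, label_noise=0.0, missing_rate=0.0,
        experiment_plan=(("other", "binary", 1),), seed=seed)


def run_planted_recovery(seed: int, direction: str = "direct",
                         n_trees: int = 8, n_bags: int = 100):
    """Simulate one planted-cluster panel and run the selection pipeline.

    Returns (planted relation, selection result, ranked PhenotypeResult or
    None if the selection emptied, reduced matrix, full matrix).
    """
    ds = simulate_dataset(recovery_sim_config(seed, direction))
    rel = ds.truth.relations[0]
    prepared = pheno_prep.prepare_phenotypes(ds.phenotypes, ds.experiment_meta)
    filtered, _ = geno_prep.variance_filter(ds.genotype)
    reduced, groups = geno_prep.collapse_correlated(filtered)
    gmap = geno_prep.expansion_map(groups)
    unit = next(u for u in prepared.units
                if u.experiment_id == rel.experiment_id
                and u.class_label == "1")
    bags = pheno_prep.make_bags(unit, n_bags=n_bags, seed=seed)
    fc = ForestConfig(n_trees=n_trees, seed=seed)
    sel = iterate_selection(reduced, unit, bags, fc)
    result = rank_and_augment(sel, gmap, k=50) if sel.usable else None
    return rel, sel, result, reduced, ds.genotype


def brute_force_upgma(dist: np.ndarray) -> np.ndarray:
    """Independent UPGMA: pairwise average of original distances, O(n^3).

    Returns the cophenetic distance matrix.
    """
    n = dist.shape[0]
    clusters = [[i] for i in range(n)]
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        best = (None, None, np.inf)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([dist[i, j] for i in clusters[a]
                             for j in clusters[b]])
                if d < best[2] - 1e-12:
                    best = (a, b, d)
        a, b, d = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return coph
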