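"""Synthetic strain panels with planted gene-cluster -> phenotype relations.

The generator emulates the data a pan-genome CGH study produces for a panel
of bacterial strains: a binary ortholog-group (OG) x strain occurrence
matrix, per-reference-strain gene tables with genomic coordinates, a mixed
binary/ordinal/continuous phenotype table with missing values, and a
probe-level signal table for segment-presence views.  Known gene-cluster ->
phenotype relations are planted so that the downstream matching analysis can
be validated against ground truth:

* a *direct* relation plants a cluster of co-occurring genes whose presence
  in a strain causes the positive phenotype class;
* an *inverse* relation plants a cluster whose absence causes the positive
  class (e.g. loss of a repressor);
* a *partial* relation plants two disjoint analogous clusters, either of
  which confers the trait, so each cluster is present in only a subset of
  the positive strains.

Genes of one planted cluster share a single occurrence pattern (operon-like
correlation) and are laid out contiguously on the genome of one reference
strain.  Everything is driven by a single integer seed: identical
configurations and seeds give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from gpmatch._random import spawn_rng

CATEGORIES = ("sugar", "antibiotic", "metal", "milk_polysaccharide", "other")
READOUTS = ("binary", "ordinal", "continuous")

#: Default experiment plan: 5 categories, 130 experiments in total, with the
#: readout type a panel of that category typically produces (API-style sugar
#: scores are ordinal, resistance titrations ordinal or continuous, growth
#: readouts continuous, presence/absence tests binary).
DEFAULT_EXPERIMENT_PLAN = (
    ("sugar", "ordinal", 29),
    ("antibiotic", "continuous", 32),
    ("metal", "ordinal", 30),
    ("milk_polysaccharide", "continuous", 20),
    ("other", "binary", 19),
)

_DECOY_ANNOTATIONS = (
    "IS element transposase",
    "transposase, IS30 family",
    "integrase",
    "phage integrase",
    "prophage protein",
    "phage tail protein",
)

_GENERIC_ANNOTATIONS = (
    "hypothetical protein",
    "hypothetical protein",
    "hypothetical protein",
    "ABC transporter permease",
    "PTS system transporter subunit",
    "LacI family transcriptional regulator",
    "glycosyl hydrolase",
    "membrane protein",
    "oxidoreductase",
    "aminotransferase",
    "two-component system histidine kinase",
    "cation efflux protein",
)

_PLANTED_ANNOTATIONS = (
    "sugar ABC transporter substrate-binding protein",
    "alpha-galactosidase",
    "metal resistance efflux pump",
    "arsenical resistance operon protein",
    "polysaccharide biosynthesis protein",
    "amino acid permease",
)


@dataclass
class SimConfig:
    """Parameters of one synthetic panel.

    Defaults mirror the scale of a 38-strain CGH panel: 4026 OGs of which
    149 are single plasmid genes, 4 sequenced reference strains, and a
    130-experiment phenotype plan over 5 experiment categories.
    """

    n_strains: int = 38
    n_ogs: int = 4026
    n_reference_strains: int = 4
    n_plasmid_ogs: int = 149
    cluster_size_range: tuple[int, int] = (2, 11)
    gene_length_range: tuple[int, int] = (300, 1500)
    intergenic_gap_range: tuple[int, int] = (50, 400)
    n_causal_clusters: int = 3
    n_inverse_clusters: int = 1
    n_partial_pairs: int = 1
    #: probability a causal strain expresses the positive class
    penetrance: float = 0.95
    #: per-cell flip rate of planted-cluster occurrence bits (CGH call errors)
    label_noise: float = 0.02
    #: per-cell missing rate within experiments subject to missingness
    missing_rate: float = 0.10
    #: fraction of experiments that carry missing cells at all
    frac_incomplete_experiments: float = 0.4
    #: background per-OG presence frequency is drawn uniformly in this range
    presence_freq_range: tuple[float, float] = (0.25, 0.85)
    plasmid_freq_range: tuple[float, float] = (0.10, 0.50)
    #: fraction of background genes annotated as mobile elements (decoys)
    decoy_fraction: float = 0.05
    #: separation (in sd units) of class-conditional continuous readouts
    class_separation_sd: float = 3.0
    experiment_plan: tuple[tuple[str, str, int], ...] = DEFAULT_EXPERIMENT_PLAN
    seed: int = 0

    def validate(self) -> None:
        for name in ("penetrance", "label_noise", "missing_rate",
                     "frac_incomplete_experiments", "decoy_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_strains", "n_ogs", "n_reference_strains"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_plasmid_ogs < 0 or self.n_plasmid_ogs > self.n_ogs:
            raise ValueError("n_plasmid_ogs must be in [0, n_ogs]")
        if self.cluster_size_range[0] < 2:
            raise ValueError("planted clusters need at least 2 genes")
        if self.cluster_size_range[0] > self.cluster_size_range[1]:
            raise ValueError("cluster_size_range must be (lo, hi) with lo <= hi")
        if self.n_reference_strains > self.n_strains:
            raise ValueError("n_reference_strains cannot exceed n_strains")
        for cat, readout, count in self.experiment_plan:
            if cat not in CATEGORIES:
                raise ValueError(f"unknown experiment category {cat!r}")
            if readout not in READOUTS:
                raise ValueError(f"unknown readout {readout!r}")
            if count < 0:
                raise ValueError("experiment counts must be >= 0")
        if self.n_partial_pairs > 0 and self.n_reference_strains < 2:
            raise ValueError(
                "partial pairs need >= 2 reference strains to host the two "
                "analogous clusters")
        n_clusters = (self.n_causal_clusters + self.n_inverse_clusters
                      + 2 * self.n_partial_pairs)
        max_planted = n_clusters * self.cluster_size_range[1]
        if max_planted > self.n_ogs - self.n_plasmid_ogs:
            raise ValueError(
                f"infeasible plan: {n_clusters} planted clusters of up to "
                f"{self.cluster_size_range[1]} genes do not fit among "
                f"{self.n_ogs - self.n_plasmid_ogs} chromosomal OGs")
        n_targetable = sum(c for _, r, c in self.experiment_plan
                           if r in ("binary", "continuous"))
        n_targets = (self.n_causal_clusters + self.n_inverse_clusters
                     + self.n_partial_pairs)
        if n_targets > n_targetable:
            raise ValueError(
                f"infeasible plan: {n_targets} planted relations but only "
                f"{n_targetable} binary/continuous experiments to attach them to")

    def to_yaml(self, path: str | os.PathLike) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("cluster_size_range", "gene_length_range",
                    "intergenic_gap_range", "presence_freq_range",
                    "plasmid_freq_range"):
            if key in d:
                d[key] = tuple(d[key])
        if "experiment_plan" in d:
            d["experiment_plan"] = tuple(tuple(e) for e in d["experiment_plan"])
        return cls(**d)


@dataclass(frozen=True)
class PlantedRelation:
    """Ground truth for one planted gene-cluster -> phenotype relation."""

    relation_id: str
    direction: str                      # direct | inverse | partial
    og_ids: tuple[str, ...]
    reference_strain: str
    replicon: str
    start: int                          # 1-based, start of first cluster gene
    end: int                            # end of last cluster gene
    experiment_id: str
    carrier_strains: tuple[str, ...]    # strains carrying the cluster
    partner_id: str | None = None       # the analogous cluster of a partial pair


@dataclass
class PlantedTruth:
    relations: list[PlantedRelation]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.relations:
            rows.append({
                "relation_id": r.relation_id,
                "direction": r.direction,
                "reference_strain": r.reference_strain,
                "replicon": r.replicon,
                "start": r.start,
                "end": r.end,
                "experiment_id": r.experiment_id,
                "og_ids": ",".join(r.og_ids),
                "carrier_strains": ",".join(r.carrier_strains),
                "partner_id": r.partner_id or "",
            })
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PlantedTruth":
        rels = []
        for _, row in df.iterrows():
            rels.append(PlantedRelation(
                relation_id=row["relation_id"],
                direction=row["direction"],
                og_ids=tuple(str(row["og_ids"]).split(",")),
                reference_strain=row["reference_strain"],
                replicon=row["replicon"],
                start=int(row["start"]),
                end=int(row["end"]),
                experiment_id=row["experiment_id"],
                carrier_strains=tuple(str(row["carrier_strains"]).split(",")),
                partner_id=(row["partner_id"] or None)
                if isinstance(row["partner_id"], str) and row["partner_id"]
                else None,
            ))
        return cls(rels)


@dataclass
class SimulatedDataset:
    """In-memory form of one synthetic panel."""

    config: SimConfig
    genotype: pd.DataFrame              # OG x strain, values in {0, 1}
    plasmid_flags: pd.Series            # per-OG bool
    gene_tables: dict[str, pd.DataFrame]
    phenotypes: pd.DataFrame            # strain x experiment, NaN = missing
    experiment_meta: pd.DataFrame
    probes: pd.DataFrame                # probe signal table for one reference
    truth: PlantedTruth


def _strain_names(n: int) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(n)]


def _og_names(n: int) -> list[str]:
    return [f"OG{i + 1:04d}" for i in range(n)]


def _build_experiments(plan) -> pd.DataFrame:
    desc = {
        "sugar": "API 50CH growth on sugar panel well",
        "antibiotic": "growth in medium with antibiotic, dilution series",
        "metal": "growth in medium with metal salt, dilution series",
        "milk_polysaccharide": "growth on milk or polysaccharide medium",
        "other": "growth test on medium with nisin, salt or enzyme assay",
    }
    rows = []
    for cat, readout, count in plan:
        for i in range(count):
            rows.append({
                "experiment_id": f"{cat}_{i + 1:02d}",
                "category": cat,
                "readout": readout,
                "description": f"{desc[cat]} {i + 1}",
            })
    return pd.DataFrame(rows)


def _pick_carriers(rng, strains, host, lo_frac=0.3, hi_frac=0.7):
    n = len(strains)
    lo = max(4, int(np.ceil(lo_frac * n)))
    hi = max(lo, min(n - 4, int(np.floor(hi_frac * n))))
    size = int(rng.integers(lo, hi + 1))
    carriers = set(rng.choice(n, size=size, replace=False).tolist())
    host_i = strains.index(host)
    carriers.add(host_i)
    return tuple(strains[i] for i in sorted(carriers))


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate one panel with planted relations; fully seed-deterministic."""
    config.validate()
    rng = spawn_rng(config.seed, "synth")

    strains = _strain_names(config.n_strains)
    refs = strains[: config.n_reference_strains]
    ogs = _og_names(config.n_ogs)
    n_chrom = config.n_ogs - config.n_plasmid_ogs
    chrom_ogs = ogs[:n_chrom]
    plasmid_ogs = ogs[n_chrom:]
    plasmid_flags = pd.Series(
        [og in set(plasmid_ogs) for og in ogs], index=ogs, name="plasmid")

    experiments = _build_experiments(config.experiment_plan)

    # --- background occurrence matrix -------------------------------------
    lo, hi = config.presence_freq_range
    p_og = rng.uniform(lo, hi, size=n_chrom)
    plo, phi = config.plasmid_freq_range
    p_plasmid = rng.uniform(plo, phi, size=config.n_plasmid_ogs)
    freqs = np.concatenate([p_og, p_plasmid])
    M = (rng.random((config.n_ogs, config.n_strains)) < freqs[:, None]).astype(np.int8)

    # --- plant clusters ----------------------------------------------------
    n_clusters = (config.n_causal_clusters + config.n_inverse_clusters
                  + 2 * config.n_partial_pairs)
    sizes = rng.integers(config.cluster_size_range[0],
                         config.cluster_size_range[1] + 1, size=n_clusters)
    pool = rng.permutation(n_chrom)
    taken = 0
    cluster_ogs: list[tuple[str, ...]] = []
    for s in sizes:
        idx = pool[taken:taken + int(s)]
        cluster_ogs.append(tuple(sorted(chrom_ogs[i] for i in idx)))
        taken += int(s)

    targetable = experiments.loc[
        experiments["readout"].isin(["binary", "continuous"]), "experiment_id"
    ].tolist()
    n_targets = (config.n_causal_clusters + config.n_inverse_clusters
                 + config.n_partial_pairs)
    target_exps = [targetable[i] for i in
                   rng.choice(len(targetable), size=n_targets, replace=False)]

    og_index = {og: i for i, og in enumerate(ogs)}
    strain_index = {s: i for i, s in enumerate(strains)}
    relations: list[PlantedRelation] = []
    ci = 0   # cluster cursor
    ti = 0   # target-experiment cursor

    def plant(direction: str, og_set, host, exp_id, partner=None, carriers=None):
        if carriers is None:
            carriers = _pick_carriers(rng, strains, host)
        rows = [og_index[o] for o in og_set]
        cols = [strain_index[s] for s in carriers]
        M[np.ix_(rows, range(config.n_strains))] = 0
        M[np.ix_(rows, cols)] = 1
        return PlantedRelation(
            relation_id=f"rel{len(relations) + 1:02d}",
            direction=direction, og_ids=og_set, reference_strain=host,
            replicon="chr", start=0, end=0, experiment_id=exp_id,
            carrier_strains=tuple(carriers), partner_id=partner)

    for _ in range(config.n_causal_clusters):
        host = refs[ci % len(refs)]
        relations.append(plant("direct", cluster_ogs[ci], host, target_exps[ti]))
        ci += 1
        ti += 1
    for _ in range(config.n_inverse_clusters):
        host = refs[ci % len(refs)]
        relations.append(plant("inverse", cluster_ogs[ci], host, target_exps[ti]))
        ci += 1
        ti += 1
    for p in range(config.n_partial_pairs):
        host_a = refs[ci % len(refs)]
        host_b = refs[(ci + 1) % len(refs)]
        exp_id = target_exps[ti]
        ti += 1
        # two disjoint carrier sets; either cluster confers the trait
        n = config.n_strains
        size_a = int(rng.integers(max(3, n // 6), max(4, n // 4) + 1))
        size_b = int(rng.integers(max(3, n // 6), max(4, n // 4) + 1))
        order = rng.permutation(n)
        set_a = {int(i) for i in order[:size_a]}
        set_b = {int(i) for i in order[size_a:size_a + size_b]}
        set_a.add(strain_index[host_a])
        set_b.discard(strain_index[host_a])
        set_b.add(strain_index[host_b])
        set_a.discard(strain_index[host_b])
        carriers_a = tuple(strains[i] for i in sorted(set_a))
        carriers_b = tuple(strains[i] for i in sorted(set_b))
        id_a = f"rel{len(relations) + 1:02d}"
        id_b = f"rel{len(relations) + 2:02d}"
        relations.append(plant("partial", cluster_ogs[ci], host_a, exp_id,
                               partner=id_b, carriers=carriers_a))
        relations.append(plant("partial", cluster_ogs[ci + 1], host_b, exp_id,
                               partner=id_a, carriers=carriers_b))
        ci += 2

    # occurrence-call noise on planted bits; the home reference strain keeps
    # its cluster intact so that gene-table coordinates stay meaningful
    if config.label_noise > 0:
        for rel in relations:
            rows = [og_index[o] for o in rel.og_ids]
            keep = strain_index[rel.reference_strain]
            flip = rng.random((len(rows), config.n_strains)) < config.label_noise
            flip[:, keep] = False
            sub = M[rows, :]
            sub[flip] = 1 - sub[flip]
            M[rows, :] = sub

    genotype = pd.DataFrame(M, index=pd.Index(ogs, name="og_id"), columns=strains)

    # --- phenotype table ----------------------------------------------------
    pheno = pd.DataFrame(
        np.nan, index=pd.Index(strains, name="strain"),
        columns=experiments["experiment_id"])
    target_of = {}
    for rel in relations:
        target_of.setdefault(rel.experiment_id, []).append(rel)

    for _, exp in experiments.iterrows():
        eid, readout = exp["experiment_id"], exp["readout"]
        if eid in target_of:
            rels = target_of[eid]
            carrier_union = set().union(*(r.carrier_strains for r in rels))
            present = np.array([s in carrier_union for s in strains])
            direction = rels[0].direction
            z = (~present if direction == "inverse" else present).astype(int)
            flip = rng.random(config.n_strains) > config.penetrance
            z = np.where(flip, 1 - z, z)
            if readout == "binary":
                pheno[eid] = z.astype(float)
            else:  # continuous, class-conditional Gaussians
                mu = z * config.class_separation_sd
                pheno[eid] = rng.normal(mu, 1.0)
        else:
            if readout == "binary":
                p = rng.uniform(0.2, 0.8)
                pheno[eid] = (rng.random(config.n_strains) < p).astype(float)
            elif readout == "ordinal":
                probs = rng.dirichlet(np.full(3, 2.0))
                pheno[eid] = rng.choice(3, size=config.n_strains,
                                        p=probs).astype(float)
            else:
                pheno[eid] = rng.normal(0.0, 1.0, size=config.n_strains)

    # two-level missingness: a fraction of experiments carries missing cells
    n_exp = len(experiments)
    n_incomplete = int(round(config.frac_incomplete_experiments * n_exp))
    if n_incomplete > 0 and config.missing_rate > 0:
        incomplete = rng.choice(n_exp, size=n_incomplete, replace=False)
        for j in incomplete:
            eid = experiments["experiment_id"].iloc[int(j)]
            mask = rng.random(config.n_strains) < config.missing_rate
            # keep at least one observed value per experiment
            if mask.all():
                mask[int(rng.integers(config.n_strains))] = False
            col = pheno[eid].to_numpy(copy=True)
            col[mask] = np.nan
            pheno[eid] = col

    # --- reference-strain gene tables --------------------------------------
    annotations = {}
    for og in ogs:
        if rng.random() < config.decoy_fraction:
            annotations[og] = _DECOY_ANNOTATIONS[
                int(rng.integers(len(_DECOY_ANNOTATIONS)))]
        else:
            annotations[og] = _GENERIC_ANNOTATIONS[
                int(rng.integers(len(_GENERIC_ANNOTATIONS)))]
    for rel in relations:
        for og in rel.og_ids:
            annotations[og] = _PLANTED_ANNOTATIONS[
                int(rng.integers(len(_PLANTED_ANNOTATIONS)))]

    coords: dict[tuple[str, str], tuple[int, int]] = {}
    gene_tables: dict[str, pd.DataFrame] = {}
    plasmid_bearing = set(refs[: min(2, len(refs))])
    for ref in refs:
        present = genotype[ref].to_numpy().astype(bool)
        chrom_present = [og for og in chrom_ogs if present[og_index[og]]]
        # keep a planted cluster contiguous wherever the strain has it whole
        blocks: list[list[str]] = []
        blocked: set[str] = set()
        present_set = set(chrom_present)
        for rel in relations:
            if set(rel.og_ids) <= present_set and not (set(rel.og_ids) & blocked):
                blocks.append(list(rel.og_ids))
                blocked |= set(rel.og_ids)
        items: list[list[str]] = [[og] for og in chrom_present
                                  if og not in blocked] + blocks
        order = rng.permutation(len(items))
        ordered = [og for i in order for og in items[int(i)]]

        rows = []
        pos = 0
        for k, og in enumerate(ordered):
            gap = int(rng.integers(config.intergenic_gap_range[0],
                                   config.intergenic_gap_range[1] + 1))
            length = int(rng.integers(config.gene_length_range[0],
                                      config.gene_length_range[1] + 1))
            start = pos + gap + 1
            end = start + length - 1
            pos = end
            coords[(ref, og)] = (start, end)
            rows.append({
                "gene_id": f"{ref}_{k + 1:04d}", "og_id": og, "replicon": "chr",
                "start": start, "end": end,
                "strand": "+" if rng.random() < 0.5 else "-",
                "annotation": annotations[og]})
        if ref in plasmid_bearing:
            ppresent = [og for og in plasmid_ogs if present[og_index[og]]]
            pos = 0
            for k, og in enumerate(ppresent):
                gap = int(rng.integers(config.intergenic_gap_range[0],
                                       config.intergenic_gap_range[1] + 1))
                length = int(rng.integers(config.gene_length_range[0],
                                          config.gene_length_range[1] + 1))
                start = pos + gap + 1
                end = start + length - 1
                pos = end
                rows.append({
                    "gene_id": f"{ref}_p{k + 1:03d}", "og_id": og,
                    "replicon": "plasmid_1", "start": start, "end": end,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "annotation": annotations[og]})
        gene_tables[ref] = pd.DataFrame(rows)

    # patch planted-relation coordinates now that genomes are laid out
    fixed = []
    for rel in relations:
        spans = [coords[(rel.reference_strain, og)] for og in rel.og_ids
                 if (rel.reference_strain, og) in coords]
        if spans:
            start = min(s for s, _ in spans)
            end = max(e for _, e in spans)
        else:  # pragma: no cover - host always carries its cluster
            start, end = 0, 0
        fixed.append(dataclasses.replace(rel, start=start, end=end))
    truth = PlantedTruth(fixed)

    probes = emit_probe_signals(
        gene_tables[refs[0]], genotype, reference_strain=refs[0],
        probes_per_gene=3, noise_sd=0.15,
        rng=spawn_rng(config.seed, "synth", "probes"))

    return SimulatedDataset(
        config=config, genotype=genotype, plasmid_flags=plasmid_flags,
        gene_tables=gene_tables, phenotypes=pheno,
        experiment_meta=experiments, probes=probes, truth=truth)


def emit_probe_signals(gene_table: pd.DataFrame, genotype: pd.DataFrame,
                       reference_strain: str, probes_per_gene: int = 3,
                       noise_sd: float = 0.15,
                       rng: np.random.Generator | None = None,
                       base_intensity: float = 1000.0,
                       absent_log2_drop: float = 3.0) -> pd.DataFrame:
    """Tile each reference gene with probes and emit per-strain intensities.

    A probe over a gene present in a strain draws from a high-signal
    log-normal regime centred on ``base_intensity``; an absent gene draws
    from a regime ``absent_log2_drop`` doublings lower, so the log2 ratio to
    the reference centres on ``-absent_log2_drop``.
    """
    if probes_per_gene <= 0:
        raise ValueError("probes_per_gene must be >= 1")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if rng is None:
        rng = np.random.default_rng(0)
    strains = list(genotype.columns)
    rows = []
    for _, g in gene_table.iterrows():
        positions = np.linspace(g["start"], g["end"],
                                probes_per_gene).round().astype(int)
        present = genotype.loc[g["og_id"]].to_numpy().astype(bool)
        for k, pos in enumerate(positions):
            eps = rng.normal(0.0, noise_sd, size=len(strains))
            log2_int = np.log2(base_intensity) + eps
            log2_int = np.where(present, log2_int, log2_int - absent_log2_drop)
            row = {"probe_id": f"{g['gene_id']}_pr{k + 1}",
                   "replicon": g["replicon"], "position": int(pos),
                   "reference_strain": reference_strain}
            row.update({s: float(v) for s, v in
                        zip(strains, np.exp2(log2_int))})
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TSV round-trip

def _write_tsv(df: pd.DataFrame, path, seed: int, index: bool) -> None:
    with open(path, "w") as fh:
        fh.write(f"# gpmatch-sim seed={seed}\n")
        df.to_csv(fh, sep="\t", index=index)


def write_dataset(ds: SimulatedDataset, outdir: str | os.PathLike) -> None:
    """Write a panel as the TSV files the ingestion steps read back."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    seed = ds.config.seed
    geno = ds.genotype.copy()
    geno.insert(0, "plasmid", ds.plasmid_flags.astype(int).to_numpy())
    _write_tsv(geno, os.path.join(outdir, "genotype.tsv"), seed, index=True)
    for ref, table in ds.gene_tables.items():
        _write_tsv(table, os.path.join(outdir, f"genes_{ref}.tsv"), seed,
                   index=False)
    _write_tsv(ds.phenotypes, os.path.join(outdir, "phenotypes.tsv"), seed,
               index=True)
    _write_tsv(ds.experiment_meta, os.path.join(outdir, "experiments.tsv"),
               seed, index=False)
    _write_tsv(ds.probes, os.path.join(outdir, "probes.tsv"), seed, index=False)
    _write_tsv(ds.truth.to_frame(), os.path.join(outdir, "truth.tsv"), seed,
               index=False)
    ds.config.to_yaml(os.path.join(outdir, "config.yaml"))
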