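"""Seeded synthetic fixtures with known ground truth for every pipeline input.

The generator emulates a reference genome collection (taxonomy, functional
roles constructed from the pathway rules themselves, surrogate 16S
sequences, a consistent phylogeny), 16S ASV datasets (Dirichlet community
compositions, copy-number bias applied in reverse so the pipeline has to
undo it), and WGS datasets (taxon abundance profiles and multinomial
per-role read counts over a universal single-copy core gene set).

16S surrogates use disjoint per-family mutated position blocks plus
lineage-specific tail substitutions, which makes identity arithmetic exact:
cross-family identity is guaranteed below the 90% mapping threshold,
within-family identity above it, and within-species identity above 97%.
All randomness flows from a single integer seed; global random state is
never touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from skbio import TreeNode

from .bpm import RANKS, GenomeRecord, BinaryPhenotypeMatrix, build_bpm
from .rules import PRODUCTS, RuleSet, base_label, default_ruleset

#: producer-clade prevalence per product, following the genome-level
#: producer fractions of the reference collection the rules describe
DEFAULT_PREVALENCE = {
    "butyrate": 0.126,
    "propionate": 0.289,
    "acetate": 0.868,
    "formate": 0.714,
    "L-lactate": 0.633,
    "D-lactate": 0.45,
}

_BASES = np.array(list("ACGT"))


@dataclass
class FixtureSpec:
    """Knobs of the synthetic study; the defaults are the study conditions."""

    seed: int
    n_families: int = 6
    genera_per_family: int = 2
    species_per_genus: int = 2
    strains_per_species: int = 2
    prevalence: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    #: probability that a genome inside a producer family is NOT a producer
    within_family_heterogeneity: float = 0.0
    #: probability a non-producer carries an incomplete pathway fragment
    partial_pathway_rate: float = 0.1
    seq_length: int = 250
    family_block: int = 15
    species_mutations: int = 4
    strain_mutations: int = 2
    n_samples: int = 20
    dirichlet_alpha: float = 1.0
    copy_number_range: tuple[int, int] = (1, 7)
    #: relative abundance of an injected unmappable ASV (0 disables)
    alien_abundance: float = 0.0
    wgs_depth: int = 200_000
    n_core_genes: int = 20

    @property
    def n_genomes(self) -> int:
        return (
            self.n_families
            * self.genera_per_family
            * self.species_per_genus
            * self.strains_per_species
        )

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for k, v in self.prevalence.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"prevalence for {k} must be in [0, 1]")
        for name in ("n_families", "genera_per_family", "species_per_genus",
                     "strains_per_species", "n_samples", "n_core_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.copy_number_range
        if lo < 1 or hi < lo:
            raise ValueError("copy_number_range must satisfy 1 <= lo <= hi")
        L, B = self.seq_length, self.family_block
        if self.n_families * B > L:
            raise ValueError("infeasible divergence targets: family blocks exceed sequence length")
        if 2 * B <= 0.10 * L:
            raise ValueError(
                "infeasible divergence targets: family blocks too small to keep "
                "cross-family identity below 90%"
            )
        if 2 * (self.species_mutations + self.strain_mutations) >= 0.10 * L:
            raise ValueError(
                "infeasible divergence targets: within-family divergence would "
                "cross the 90% mapping threshold"
            )
        if 2 * self.strain_mutations >= 0.03 * L:
            raise ValueError(
                "infeasible divergence targets: within-species identity would "
                "fall below 97%"
            )


@dataclass
class ReferenceCollection:
    """Generated genomes with role sets, ground-truth phenotypes, 16S
    surrogates and a consistent phylogeny."""

    genomes: list[GenomeRecord]
    bpm_truth: pd.DataFrame  # genomes x products, int
    variant_truth: dict[str, dict[str, frozenset[str]]]
    sequences: dict[str, str]  # genome_id -> 16S surrogate
    tree_newick: str
    family_of: dict[str, str]

    @property
    def tree(self) -> TreeNode:
        return TreeNode.read([self.tree_newick])

    def bpm(self, definitions: RuleSet | None = None) -> BinaryPhenotypeMatrix:
        return build_bpm(self.genomes, definitions or default_ruleset())


def _mutate(rng: np.random.Generator, seq: np.ndarray, positions: np.ndarray) -> np.ndarray:
    out = seq.copy()
    for pos in positions:
        choices = _BASES[_BASES != out[pos]]
        out[pos] = rng.choice(choices)
    return out


def generate_reference_collection(spec: FixtureSpec) -> ReferenceCollection:
    spec.validate()
    rng = np.random.default_rng([int(spec.seed), 0])
    definitions = default_ruleset()

    # --- taxonomy scaffold -------------------------------------------------
    records: list[tuple[str, tuple[str, ...]]] = []  # (genome_id, taxonomy)
    gid = 0
    for f in range(spec.n_families):
        phylum = f"Phylum{(f % 2) + 1}"
        klass = f"Class{(f % 2) + 1}"
        order = f"Order{f + 1:02d}"
        family = f"Family{f + 1:02d}"
        for g in range(spec.genera_per_family):
            genus = f"Genus_f{f + 1:02d}g{g + 1}"
            for s in range(spec.species_per_genus):
                species = f"{genus}_sp{s + 1}"
                for t in range(spec.strains_per_species):
                    gid += 1
                    genome_id = f"G{gid:04d}"
                    strain = f"{species}_st{t + 1}"
                    records.append(
                        (genome_id, (phylum, klass, order, family, genus, species, strain))
                    )

    # --- phenotype ground truth and role sets ------------------------------
    fam_idx = {rec[0]: rec[1][3] for rec in records}
    families = sorted({fam for fam in fam_idx.values()})
    producer_family = {
        product: {fam: bool(rng.random() < spec.prevalence.get(product, 0.0)) for fam in families}
        for product in PRODUCTS
    }

    genomes: list[GenomeRecord] = []
    truth_rows = []
    variant_truth: dict[str, dict[str, frozenset[str]]] = {}
    for genome_id, taxonomy in records:
        roles: set[str] = set()
        truth = {}
        vtruth: dict[str, frozenset[str]] = {}
        for product in PRODUCTS:
            variants = definitions.for_product(product)
            is_producer = producer_family[product][fam_idx[genome_id]]
            if is_producer and spec.within_family_heterogeneity > 0:
                is_producer = rng.random() >= spec.within_family_heterogeneity
            truth[product] = int(is_producer)
            if is_producer:
                n_pick = 1 if (len(variants) == 1 or rng.random() < 0.8) else 2
                picked = rng.choice(len(variants), size=n_pick, replace=False)
                labels = set()
                for vi in picked:
                    d = variants[vi]
                    for group in d.requirements:
                        if not group.required:
                            continue
                        alternative = group.alternatives[rng.integers(len(group.alternatives))]
                        roles |= set(alternative)
                    labels.add(d.variant_label)
                vtruth[product] = frozenset(labels)
            else:
                vtruth[product] = frozenset()
                if variants and rng.random() < spec.partial_pathway_rate:
                    d = variants[rng.integers(len(variants))]
                    groups = [g for g in d.requirements if g.required]
                    if len(groups) >= 2:
                        drop = rng.integers(len(groups))
                        partial: set[str] = set()
                        for gi, group in enumerate(groups):
                            if gi == drop:
                                continue
                            alternative = group.alternatives[rng.integers(len(group.alternatives))]
                            partial |= set(alternative)
                        # never re-complete the dropped group through shared roles
                        partial -= groups[drop].all_roles()
                        roles |= partial
        genomes.append(GenomeRecord(genome_id, taxonomy, frozenset(roles)))
        truth_rows.append(truth)
        variant_truth[genome_id] = vtruth

    index = pd.Index([g.genome_id for g in genomes], name="genome_id")
    bpm_truth = pd.DataFrame(truth_rows, index=index, columns=list(PRODUCTS), dtype=int)

    # --- 16S surrogates and phylogeny --------------------------------------
    # Family-diagnostic positions are dispersed across the sequence and
    # interleaved between families, so alignment gap tricks cannot inflate
    # cross-family identity above the Hamming bound (< 90%), while species
    # and strain substitutions live on the complementary positions.
    L, B = spec.seq_length, spec.family_block
    root = rng.choice(_BASES, size=L)
    marker = np.round(np.linspace(0, L - 1, spec.n_families * B)).astype(int)
    if len(np.unique(marker)) != len(marker):
        marker = np.arange(spec.n_families * B)
    family_positions = {f: marker[f :: spec.n_families] for f in range(spec.n_families)}
    tail = np.setdiff1d(np.arange(L), marker)
    sequences: dict[str, str] = {}
    family_clades = []
    by_family: dict[str, list[GenomeRecord]] = {}
    for genome in genomes:
        by_family.setdefault(genome.rank("family"), []).append(genome)
    for f, family in enumerate(families):
        fam_seq = _mutate(rng, root, family_positions[f])
        genus_clades = []
        members = by_family[family]
        by_genus: dict[str, list[GenomeRecord]] = {}
        for genome in members:
            by_genus.setdefault(genome.rank("genus"), []).append(genome)
        for genus, g_members in sorted(by_genus.items()):
            species_clades = []
            by_species: dict[str, list[GenomeRecord]] = {}
            for genome in g_members:
                by_species.setdefault(genome.rank("species"), []).append(genome)
            for species, s_members in sorted(by_species.items()):
                pos = rng.choice(tail, size=spec.species_mutations, replace=False)
                sp_seq = _mutate(rng, fam_seq, pos)
                leaves = []
                for genome in s_members:
                    pos = rng.choice(tail, size=spec.strain_mutations, replace=False)
                    st_seq = _mutate(rng, sp_seq, pos)
                    sequences[genome.genome_id] = "".join(st_seq)
                    leaves.append(f"{genome.genome_id}:{spec.strain_mutations / L:.6f}")
                species_clades.append(f"({','.join(leaves)}):{spec.species_mutations / L:.6f}")
            genus_clades.append(f"({','.join(species_clades)}):0.001")
        family_clades.append(f"({','.join(genus_clades)}):{B / L:.6f}")
    newick = f"({','.join(family_clades)})root;"

    return ReferenceCollection(
        genomes=genomes,
        bpm_truth=bpm_truth,
        variant_truth=variant_truth,
        sequences=sequences,
        tree_newick=newick,
        family_of=fam_idx,
    )


ALIEN_ASV_ID = "asv_alien"


@dataclass
class AsvDataset:
    """Observed ASV table (copy-number biased) with the generating truth."""

    table: pd.DataFrame  # samples x ASVs, observed relative abundances
    sequences: dict[str, str]
    copy_numbers: pd.Series
    truth_abundance: pd.DataFrame  # samples x genomes (cell fractions)
    truth_cpi: pd.DataFrame  # samples x products
    asv_to_genome: dict[str, str]


def generate_asv_dataset(reference: ReferenceCollection, spec: FixtureSpec) -> AsvDataset:
    spec.validate()
    rng = np.random.default_rng([int(spec.seed), 1])
    genome_ids = [g.genome_id for g in reference.genomes]
    n = len(genome_ids)

    truth = rng.dirichlet(np.full(n, spec.dirichlet_alpha), size=spec.n_samples)
    samples = pd.Index([f"S{i + 1:03d}" for i in range(spec.n_samples)], name="sample")
    truth_abundance = pd.DataFrame(truth, index=samples, columns=genome_ids)
    truth_cpi = pd.DataFrame(
        truth @ reference.bpm_truth.loc[genome_ids].to_numpy(),
        index=samples,
        columns=list(PRODUCTS),
    )

    asv_ids = [f"asv{i + 1:04d}" for i in range(n)]
    asv_to_genome = dict(zip(asv_ids, genome_ids))
    sequences = {a: reference.sequences[g] for a, g in asv_to_genome.items()}
    lo, hi = spec.copy_number_range
    copy_numbers = pd.Series(
        rng.integers(lo, hi + 1, size=n).astype(float), index=asv_ids, name="copy_number"
    )

    # forward model: observed read fractions are cell fractions times copy
    # number, renormalized -- the pipeline's copy-number correction inverts it
    biased = truth * copy_numbers.to_numpy()[None, :]
    biased /= biased.sum(axis=1, keepdims=True)
    table = pd.DataFrame(biased, index=samples, columns=asv_ids)

    if spec.alien_abundance > 0:
        a = float(spec.alien_abundance)
        if not a < 1:
            raise ValueError("alien_abundance must be < 1")
        root_len = spec.seq_length
        alien_positions = rng.choice(root_len, size=int(0.4 * root_len), replace=False)
        template = np.array(list(next(iter(reference.sequences.values()))))
        sequences[ALIEN_ASV_ID] = "".join(_mutate(rng, template, alien_positions))
        table = table * (1.0 - a)
        table[ALIEN_ASV_ID] = a
        copy_numbers.loc[ALIEN_ASV_ID] = 1.0

    return AsvDataset(
        table=table,
        sequences=sequences,
        copy_numbers=copy_numbers,
        truth_abundance=truth_abundance,
        truth_cpi=truth_cpi,
        asv_to_genome=asv_to_genome,
    )


@dataclass
class WgsDataset:
    """Taxon abundance profiles and per-role read counts with ground truth."""

    taxon_table: pd.DataFrame  # samples x species-level taxa
    taxon_paths: dict[str, tuple[str, ...]]
    gene_counts: pd.DataFrame  # roles x samples, ints
    core_genes: list[str]
    truth_abundance: pd.DataFrame  # samples x genomes
    truth_carriage: pd.DataFrame  # samples x (product, variant base label)


def generate_wgs_dataset(reference: ReferenceCollection, spec: FixtureSpec) -> WgsDataset:
    spec.validate()
    rng = np.random.default_rng([int(spec.seed), 2])
    definitions = default_ruleset()
    genomes = reference.genomes
    genome_ids = [g.genome_id for g in genomes]
    n = len(genome_ids)

    truth = rng.dirichlet(np.full(n, spec.dirichlet_alpha), size=spec.n_samples)
    samples = pd.Index([f"S{i + 1:03d}" for i in range(spec.n_samples)], name="sample")
    truth_abundance = pd.DataFrame(truth, index=samples, columns=genome_ids)

    # species-level taxon table with 7-rank paths (strain undefined)
    species_of = {g.genome_id: g.rank("species") for g in genomes}
    taxon_paths = {
        g.rank("species"): g.taxonomy[:6] + ("undefined",) for g in genomes
    }
    taxon_table = truth_abundance.T.groupby(
        pd.Series(species_of)
    ).sum().T
    taxon_table = taxon_table[sorted(taxon_table.columns)]

    # per-role counts: multinomial over abundance-weighted role presence;
    # core genes are universal and single-copy, so their weight is 1 each
    pathway_roles = sorted(
        {r for g in genomes for r in g.roles_present}
    )
    core_genes = [f"core{i + 1:03d}" for i in range(spec.n_core_genes)]
    presence = np.zeros((len(pathway_roles), n))
    for j, g in enumerate(genomes):
        for r in g.roles_present:
            presence[pathway_roles.index(r), j] = 1.0
    all_roles = pathway_roles + core_genes
    counts = np.zeros((len(all_roles), spec.n_samples), dtype=int)
    for si in range(spec.n_samples):
        w = np.concatenate([presence @ truth[si], np.ones(len(core_genes))])
        counts[:, si] = rng.multinomial(spec.wgs_depth, w / w.sum())
    gene_counts = pd.DataFrame(counts, index=all_roles, columns=samples)

    # ground-truth variant carriage (base labels; P3* folds into P3)
    carriage_cols = []
    carriage = []
    for product in definitions.products:
        for d in definitions.for_product(product):
            label = base_label(d.variant_label)
            carrier = np.array(
                [
                    1.0 if any(base_label(l) == label
                               for l in reference.variant_truth[g][product])
                    else 0.0
                    for g in genome_ids
                ]
            )
            carriage_cols.append((product, label))
            carriage.append(truth @ carrier)
    truth_carriage = pd.DataFrame(
        np.array(carriage).T,
        index=samples,
        columns=pd.MultiIndex.from_tuples(carriage_cols, names=["product", "variant"]),
    )

    return WgsDataset(
        taxon_table=taxon_table,
        taxon_paths=taxon_paths,
        gene_counts=gene_counts,
        core_genes=core_genes,
        truth_abundance=truth_abundance,
        truth_carriage=truth_carriage,
    )
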