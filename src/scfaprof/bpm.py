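"""Pathway-variant calling and the Binary Phenotype Matrix (BPM).

A genome's functional-role presence set is evaluated against the pathway
rule grammar to yield, per fermentation product, the set of complete
pathway variants; a binary phenotype of 1 means at least one complete
variant.  Rows over a genome collection form the BPM used downstream for
community phenotype profiling.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .rules import PRODUCTS, RuleSet, base_label

RANKS = ("phylum", "class", "order", "family", "genus", "species", "strain")
UNDEFINED = "undefined"


@dataclass(frozen=True)
class GenomeRecord:
    """A reference genome: identifier, 7-rank taxonomy, role presence set."""

    genome_id: str
    taxonomy: tuple[str, ...]
    roles_present: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise ValueError("genome_id must be non-empty")
        if len(self.taxonomy) != len(RANKS):
            raise ValueError(
                f"taxonomy must have {len(RANKS)} ranks ({', '.join(RANKS)}); "
                f"got {len(self.taxonomy)} for {self.genome_id}"
            )
        object.__setattr__(self, "roles_present", frozenset(self.roles_present))

    def rank(self, name: str) -> str:
        return self.taxonomy[RANKS.index(name)]


def call_pathway_variants(
    genome: GenomeRecord | Iterable[str], definitions: RuleSet
) -> dict[str, set[str]]:
    """Per product, the set of complete variant labels in the genome.

    Missing roles yield absent calls, never errors; the result is monotone
    in the role set (adding roles can only add calls).
    """
    roles = (
        genome.roles_present
        if isinstance(genome, GenomeRecord)
        else frozenset(genome)
    )
    calls: dict[str, set[str]] = {p: set() for p in definitions.products}
    for definition in definitions:
        label = definition.call_label(roles)
        if label is not None:
            calls[definition.product].add(label)
    return calls


def assign_binary_phenotypes(variant_calls: Mapping[str, set[str]]) -> dict[str, int]:
    """1 iff the product has at least one complete variant."""
    return {p: int(bool(variant_calls.get(p))) for p in PRODUCTS}


_LABEL_SPLIT = re.compile(r"(\d+)")


def _label_key(label: str):
    # natural sort so P2 < P10; the starred form sorts right after its base
    return [int(t) if t.isdigit() else t for t in _LABEL_SPLIT.split(label)]


def combination_label(labels: Iterable[str], collapse_star: bool = False) -> str:
    """Canonical "P1+P2+P4"-style rendering of a variant set."""
    labels = set(labels)
    if collapse_star:
        labels = {base_label(l) for l in labels}
    return "+".join(sorted(labels, key=_label_key))


@dataclass
class BinaryPhenotypeMatrix:
    """Genomes x six phenotypes in {0,1}, with per-product variant labels."""

    phenotypes: pd.DataFrame  # genomes x PRODUCTS, int 0/1
    variant_labels: pd.DataFrame  # genomes x PRODUCTS, "P1+P3" style ("" if none)
    taxonomy: pd.DataFrame  # genomes x RANKS

    def __post_init__(self) -> None:
        values = self.phenotypes.to_numpy()
        if not ((values == 0) | (values == 1)).all():
            raise ValueError("BPM entries must be strictly binary")
        has_variant = (self.variant_labels != "").to_numpy()
        if not (has_variant == (values == 1)).all():
            raise ValueError("phenotype must be 1 iff the variant set is non-empty")

    @property
    def genome_ids(self) -> list[str]:
        return list(self.phenotypes.index)

    def __len__(self) -> int:
        return len(self.phenotypes)

    def to_frame(self) -> pd.DataFrame:
        """taxonomy columns, six 0/1 phenotype columns, six variant columns."""
        variants = self.variant_labels.rename(columns=lambda c: f"{c}_variants")
        out = pd.concat([self.taxonomy, self.phenotypes, variants], axis=1)
        out.index.name = "genome_id"
        return out


def build_bpm(genomes: Sequence[GenomeRecord], definitions: RuleSet) -> BinaryPhenotypeMatrix:
    """Evaluate every genome against the rule set; deterministic row order."""
    if not genomes:
        raise ValueError("genome list must be non-empty")
    ids = [g.genome_id for g in genomes]
    dupes = {i for i in ids if ids.count(i) > 1} if len(set(ids)) != len(ids) else set()
    if dupes:
        raise ValueError(f"duplicate genome_id(s): {sorted(dupes)}")

    pheno_rows, label_rows, tax_rows = [], [], []
    for genome in genomes:
        calls = call_pathway_variants(genome, definitions)
        pheno_rows.append(assign_binary_phenotypes(calls))
        label_rows.append(
            {p: combination_label(calls.get(p, set())) for p in PRODUCTS}
        )
        tax_rows.append(dict(zip(RANKS, genome.taxonomy)))
    index = pd.Index(ids, name="genome_id")
    return BinaryPhenotypeMatrix(
        phenotypes=pd.DataFrame(pheno_rows, index=index, columns=list(PRODUCTS), dtype=int),
        variant_labels=pd.DataFrame(label_rows, index=index, columns=list(PRODUCTS)),
        taxonomy=pd.DataFrame(tax_rows, index=index, columns=list(RANKS)),
    )


def summarize_variant_distribution(bpm: BinaryPhenotypeMatrix) -> pd.DataFrame:
    """Distribution of producer genomes over exact variant combinations.

    One row per (product, combination) with genome and species counts, plus
    a "Total" row per product counting genomes with at least one variant.
    Sub-labels collapse to their base variant (P3* counts as P3).  Genomes
    without a taxonomically defined species name are included in genome
    counts but excluded from species counts.
    """
    rows = []
    species = bpm.taxonomy["species"]
    for product in PRODUCTS:
        labels = bpm.variant_labels[product]
        producers = labels != ""
        if not producers.any():
            rows.append({"product": product, "variants": "Total", "n_genomes": 0, "n_species": 0})
            continue
        collapsed = labels[producers].map(
            lambda s: combination_label(s.split("+"), collapse_star=True)
        )
        sp = species[producers]
        for combo, idx in collapsed.groupby(collapsed).groups.items():
            named = sp.loc[idx]
            rows.append(
                {
                    "product": product,
                    "variants": combo,
                    "n_genomes": len(idx),
                    "n_species": named[named != UNDEFINED].nunique(),
                }
            )
        named = sp[sp != UNDEFINED]
        rows.append(
            {
                "product": product,
                "variants": "Total",
                "n_genomes": int(producers.sum()),
                "n_species": named.nunique(),
            }
        )
    out = pd.DataFrame(rows, columns=["product", "variants", "n_genomes", "n_species"])
    return out
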