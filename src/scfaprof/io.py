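"""Readers and writers for the interchange formats.

TSV dialect: tab-separated, UTF-8, mandatory header row, "." for missing
values.  Taxonomy is a 7-rank path (phylum..strain) with the sentinel
"undefined" for unnamed ranks.  FASTA via Biopython, Newick via scikit-bio.
Every writer/reader pair round-trips losslessly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

from .bpm import RANKS, BinaryPhenotypeMatrix, GenomeRecord
from .rules import PRODUCTS

MISSING = "."


class FormatError(ValueError):
    """Raised on malformed input files."""


# --- FASTA -----------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise FormatError(f"{path}: duplicate FASTA id {record.id!r}")
        seqs[record.id] = str(record.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# --- Newick ----------------------------------------------------------------

def read_newick(path) -> TreeNode:
    tree = TreeNode.read(str(path))
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise FormatError(f"{path}: negative branch length on {node.name!r}")
    names = [tip.name for tip in tree.tips()]
    if len(names) != len(set(names)):
        raise FormatError(f"{path}: duplicate leaf names")
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path))


# --- generic TSV helpers ----------------------------------------------------

def _read_tsv(path, index_col: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", na_values=[MISSING], keep_default_na=False)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message has line no
        raise FormatError(f"{path}: {exc}") from exc
    if index_col not in df.columns:
        raise FormatError(f"{path}: missing required column {index_col!r}")
    if df[index_col].duplicated().any():
        dupes = list(df.loc[df[index_col].duplicated(), index_col][:5])
        raise FormatError(f"{path}: duplicate {index_col} value(s): {dupes}")
    return df.set_index(index_col)


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", na_rep=MISSING)


# --- genome annotations -----------------------------------------------------

def read_annotations(path) -> list[GenomeRecord]:
    """Wide TSV: genome_id, seven taxonomy columns, one 0/1 column per role."""
    df = _read_tsv(path, "genome_id")
    missing = [r for r in RANKS if r not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing taxonomy column(s) {missing}")
    role_cols = [c for c in df.columns if c not in RANKS]
    genomes = []
    for genome_id, row in df.iterrows():
        present = frozenset(r for r in role_cols if int(row[r]) == 1)
        taxonomy = tuple(str(row[r]) for r in RANKS)
        genomes.append(GenomeRecord(str(genome_id), taxonomy, present))
    return genomes


def write_annotations(genomes: Sequence[GenomeRecord], path, roles: Iterable[str] | None = None) -> None:
    if roles is None:
        roles = sorted({r for g in genomes for r in g.roles_present})
    roles = list(roles)
    rows = []
    for g in genomes:
        row = {"genome_id": g.genome_id}
        row.update(dict(zip(RANKS, g.taxonomy)))
        row.update({r: int(r in g.roles_present) for r in roles})
        rows.append(row)
    _write_tsv(pd.DataFrame(rows).set_index("genome_id"), path)


# --- BPM --------------------------------------------------------------------

def write_bpm(bpm: BinaryPhenotypeMatrix, path) -> None:
    _write_tsv(bpm.to_frame(), path)


def read_bpm(path) -> BinaryPhenotypeMatrix:
    df = _read_tsv(path, "genome_id")
    needed = list(RANKS) + list(PRODUCTS) + [f"{p}_variants" for p in PRODUCTS]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing BPM column(s) {missing}")
    variants = df[[f"{p}_variants" for p in PRODUCTS]].fillna("")
    variants.columns = list(PRODUCTS)
    return BinaryPhenotypeMatrix(
        phenotypes=df[list(PRODUCTS)].astype(int),
        variant_labels=variants.astype(str),
        taxonomy=df[list(RANKS)].astype(str),
    )


# --- abundance / count tables ----------------------------------------------

def read_abundance_table(path) -> pd.DataFrame:
    """Samples as rows (column ``sample``), ASV/taxon ids as columns."""
    return _read_tsv(path, "sample").astype(float)


def write_abundance_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index.name = "sample"
    _write_tsv(out, path)


def read_gene_counts(path) -> pd.DataFrame:
    """Roles as rows (column ``role_id``), samples as columns."""
    return _read_tsv(path, "role_id").astype(int)


def write_gene_counts(counts: pd.DataFrame, path) -> None:
    out = counts.copy()
    out.index.name = "role_id"
    _write_tsv(out, path)


def read_copy_numbers(path) -> pd.Series:
    df = _read_tsv(path, "asv_id")
    if "copy_number" not in df.columns:
        raise FormatError(f"{path}: missing column 'copy_number'")
    return df["copy_number"].astype(float)


def write_copy_numbers(copies: pd.Series, path) -> None:
    df = copies.rename("copy_number").to_frame()
    df.index.name = "asv_id"
    _write_tsv(df, path)


def read_core_genes(path) -> list[str]:
    lines = [l.strip() for l in Path(path).read_text().splitlines()]
    genes = [l for l in lines if l and not l.startswith("#")]
    if len(genes) != len(set(genes)):
        raise FormatError(f"{path}: duplicate core gene ids")
    return genes


def write_core_genes(genes: Iterable[str], path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def read_taxon_paths(path) -> dict[str, tuple[str, ...]]:
    """TSV: taxon plus the seven rank columns."""
    df = _read_tsv(path, "taxon")
    missing = [r for r in RANKS if r not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing taxonomy column(s) {missing}")
    return {
        str(taxon): tuple(str(row[r]) for r in RANKS) for taxon, row in df.iterrows()
    }


def write_taxon_paths(paths: Mapping[str, Sequence[str]], path) -> None:
    rows = [{"taxon": t, **dict(zip(RANKS, p))} for t, p in paths.items()]
    _write_tsv(pd.DataFrame(rows).set_index("taxon"), path)


def read_mapping(path) -> pd.DataFrame:
    """Precomputed ASV->genome mapping TSV: asv, genome, identity."""
    df = pd.read_csv(path, sep="\t")
    needed = {"asv_id", "genome_id", "identity"}
    if not needed <= set(df.columns):
        raise FormatError(f"{path}: mapping TSV needs columns {sorted(needed)}")
    return df


def write_mapping(hits: pd.DataFrame, path) -> None:
    hits.to_csv(path, sep="\t", index=False)


def write_cpi_profile(profile, path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False, na_rep=MISSING)
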