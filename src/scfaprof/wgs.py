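"""WGS-side profiling: taxonomy-mapped CPI and pathway gene abundances.

Two complementary views of a shotgun sample:

* taxonomy route — relative taxon abundances are mapped onto BPM genomes by
  shared taxonomy (family level or better); entries without a family-level
  match are discarded and the rest renormalized, after which CPI and its
  error follow the same formulas as the 16S pipeline;

* gene route — per-role read counts are TMM-normalized against a designated
  set of universal single-copy core genes, and pathway abundances are sums
  of normalized abundances of the roles *specific to* each pathway variant
  (roles shared between variants of one product are reported only under the
  product's named shared segments, preventing double counting).

Count tables are DataFrames with roles as rows and samples as columns.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .amplicon import (
    CpiProfile,
    compute_cpi,
    compute_cpi_error,
    compute_cpi_variance,
)
from .bpm import RANKS, BinaryPhenotypeMatrix, UNDEFINED
from .rules import PRODUCTS, RuleSet

TRIM_M = 0.30
TRIM_A = 0.05

# ranks at which a taxonomic match is considered good enough for mapping
_MAPPABLE_RANKS = ("strain", "species", "genus", "family")


def _map_taxon(path: Sequence[str], bpm: BinaryPhenotypeMatrix) -> list[str]:
    """BPM genomes sharing the taxon's lowest defined rank at family level
    or better; empty when no family-level-or-better match exists."""
    if len(path) != len(RANKS):
        raise ValueError(f"rank path must have {len(RANKS)} ranks, got {len(path)}")
    tax = bpm.taxonomy
    for rank in _MAPPABLE_RANKS:
        i = RANKS.index(rank)
        if path[i] == UNDEFINED:
            continue
        mask = np.ones(len(tax), dtype=bool)
        for j in range(i + 1):
            if path[j] != UNDEFINED:
                mask &= (tax[RANKS[j]] == path[j]).to_numpy()
        if mask.any():
            return list(tax.index[mask])
    return []


def taxonomy_map_cpi(
    table: pd.DataFrame,
    taxon_paths: Mapping[str, Sequence[str]],
    bpm: BinaryPhenotypeMatrix,
    sigma_mode: str = "sqrt",
) -> tuple[CpiProfile, pd.DataFrame]:
    """CPI from taxon relative abundances mapped to BPM genomes by taxonomy.

    ``table`` is samples x taxa; ``taxon_paths`` gives each taxon's 7-rank
    path ("undefined" below the assigned rank).  PI per taxon is the mean
    phenotype of its mapped genomes.  Returns the profile plus the PI
    table.  Samples whose taxa are all unmapped are flagged not retained.
    """
    pi_rows = {}
    for taxon in table.columns:
        if taxon not in taxon_paths:
            raise ValueError(f"no rank path for taxon {taxon!r}")
        genomes = _map_taxon(tuple(taxon_paths[taxon]), bpm)
        if genomes:
            pi_rows[taxon] = bpm.phenotypes.loc[genomes, list(PRODUCTS)].mean(axis=0)
    pis = pd.DataFrame(pi_rows).T if pi_rows else pd.DataFrame(columns=list(PRODUCTS))
    pis = pis.reindex(columns=list(PRODUCTS))

    mapped = [t for t in table.columns if t in pis.index]
    coverage = table[mapped].sum(axis=1) if mapped else pd.Series(0.0, index=table.index)
    retained = coverage > 0
    kept = table.loc[retained, mapped]
    kept = kept.div(kept.sum(axis=1), axis=0)
    profile = CpiProfile(
        cpi=compute_cpi(kept, pis),
        sigma=compute_cpi_error(kept, pis, sigma_mode=sigma_mode),
        variance=compute_cpi_variance(kept, pis),
        coverage=coverage,
        retained=retained,
    )
    return profile, pis


def tmm_factors(
    counts: pd.DataFrame,
    core_genes: Sequence[str],
    trim_m: float = TRIM_M,
    trim_a: float = TRIM_A,
    lib_sizes: pd.Series | None = None,
    ref_sample: str | None = None,
    weighted: bool = False,
) -> pd.Series:
    """Per-sample TMM scaling factors computed on the core-gene rows.

    Follows the standard trimmed-mean-of-M-values recipe: per gene, the
    log2 ratio M of library-size-normalized counts against a reference
    sample and the mean log2 abundance A; the most extreme ``trim_m``
    fraction by M and ``trim_a`` fraction by A are trimmed (two-sided) and
    the factor is 2 to the trimmed mean of the remaining M values.  Genes
    with a zero count in either sample are excluded (the log ratio is
    undefined).  The reference sample is the one whose core-gene
    count-per-million upper quartile is closest to the mean (override with
    ``ref_sample``); factors are rescaled so their log-mean is zero.

    ``weighted=True`` switches to the inverse approximate-variance
    (delta-method) weighting of the M values.  The default is the plain
    trimmed mean: precision weights depend on absolute counts, so they
    break exact invariance under per-sample count scaling, which this
    module guarantees.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    missing = [g for g in core_genes if g not in counts.index]
    if missing:
        raise ValueError(f"core gene(s) absent from the count table: {missing[:5]}")
    core = counts.loc[list(core_genes)].astype(float)
    if (core.sum(axis=0) == 0).any():
        bad = list(core.columns[core.sum(axis=0) == 0])
        raise ValueError(f"sample(s) with zero total core counts: {bad}")
    lib = (
        counts.sum(axis=0).astype(float)
        if lib_sizes is None
        else pd.Series(lib_sizes, dtype=float).reindex(counts.columns)
    )
    if lib.isna().any() or (lib <= 0).any():
        raise ValueError("library sizes must be positive for every sample")

    if ref_sample is None:
        q75 = (core.div(lib, axis=1)).quantile(0.75, axis=0)
        ref_sample = (q75 - q75.mean()).abs().idxmin()
    elif ref_sample not in counts.columns:
        raise ValueError(f"unknown reference sample {ref_sample!r}")

    r = core[ref_sample].to_numpy()
    n_r = lib[ref_sample]
    log_factors = {}
    for sample in counts.columns:
        o = core[sample].to_numpy()
        n_o = lib[sample]
        finite = (o > 0) & (r > 0)
        if not finite.any():
            log_factors[sample] = 0.0
            continue
        fo, fr = o[finite] / n_o, r[finite] / n_r
        m = np.log2(fo / fr)
        a = 0.5 * np.log2(fo * fr)
        # approximate (delta-method) variance of M
        v = (n_o - o[finite]) / (n_o * o[finite]) + (n_r - r[finite]) / (n_r * r[finite])
        if np.max(np.abs(m)) < 1e-6:
            log_factors[sample] = 0.0
            continue
        n = m.size
        lo_m = np.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep.any():
            log_factors[sample] = 0.0
            continue
        if weighted:
            f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
        else:
            f = np.mean(m[keep])
        log_factors[sample] = 0.0 if not np.isfinite(f) else f
    factors = pd.Series(log_factors).reindex(counts.columns)
    factors -= factors.mean()  # log2-mean zero, as in the reference recipe
    return 2.0**factors


def normalize_counts(
    counts: pd.DataFrame,
    factors: pd.Series,
    lib_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Counts per million on TMM-adjusted library sizes:
    CPM = count / (library size x factor) x 1e6."""
    missing = [s for s in counts.columns if s not in factors.index]
    if missing:
        raise ValueError(f"no TMM factor for sample(s): {missing[:5]}")
    lib = (
        counts.sum(axis=0).astype(float)
        if lib_sizes is None
        else pd.Series(lib_sizes, dtype=float).reindex(counts.columns)
    )
    if (lib <= 0).any() or lib.isna().any():
        raise ValueError("library sizes must be positive for every sample")
    eff = lib * factors.reindex(counts.columns)
    return counts.div(eff, axis=1) * 1e6


def pathway_signatures(definitions: RuleSet) -> dict[tuple[str, str], frozenset[str]]:
    """Signature roles per (product, variant) plus named shared segments.

    A role is *specific to* a variant when it appears in that variant's own
    groups and in no other variant of the same product.  Shared segments
    (e.g. the universal butyrate crotonyl-CoA -> butyrate steps) are
    reported under (product, segment name).  Signature sets of different
    variants of one product are disjoint by construction.
    """
    signatures: dict[tuple[str, str], frozenset[str]] = {}
    for product in definitions.products:
        variants = definitions.for_product(product)
        role_use: dict[str, int] = {}
        per_variant: dict[str, set[str]] = {}
        for d in variants:
            roles: set[str] = set()
            for g in d.own_groups:
                roles |= g.all_roles()
            per_variant[d.variant_label] = roles
            for role in roles:
                role_use[role] = role_use.get(role, 0) + 1
        for label, roles in per_variant.items():
            signatures[(product, label)] = frozenset(
                r for r in roles if role_use[r] == 1
            )
        for seg_name, groups in definitions.shared_segments.get(product, {}).items():
            seg_roles: set[str] = set()
            for g in groups:
                seg_roles |= g.all_roles()
            signatures[(product, seg_name)] = frozenset(seg_roles)
    return signatures


def pathway_abundance(
    normalized: pd.DataFrame,
    signatures: Mapping[tuple[str, str], frozenset[str]],
) -> pd.DataFrame:
    """Sum of normalized gene abundances over each signature's roles.

    Output is samples x (product, variant) with a MultiIndex column per
    signature entry.  Signature roles absent from the table count as zero
    (with a warning); an empty signature set is an error.
    """
    cols = {}
    for key, roles in signatures.items():
        if not roles:
            raise ValueError(f"empty signature for {key}")
        present = [r for r in roles if r in normalized.index]
        absent = sorted(set(roles) - set(present))
        if absent:
            warnings.warn(
                f"signature roles missing from count table for {key}: {absent}",
                stacklevel=2,
            )
        cols[key] = (
            normalized.loc[present].sum(axis=0)
            if present
            else pd.Series(0.0, index=normalized.columns)
        )
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["product", "variant"])
    return out


def cpi_pathway_correlation(
    cpi: pd.DataFrame, abundances: pd.DataFrame
) -> pd.DataFrame:
    """Spearman rank correlation between CPI and pathway abundance across
    shared samples, per (phenotype, variant); ties mid-ranked."""
    shared = cpi.index.intersection(abundances.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples for rank correlation")
    rows = []
    for product, variant in abundances.columns:
        if product not in cpi.columns:
            continue
        rho, p = stats.spearmanr(
            cpi.loc[shared, product], abundances.loc[shared, (product, variant)]
        )
        rows.append(
            {"phenotype": product, "variant": variant, "spearman_rho": rho, "p_value": p}
        )
    return pd.DataFrame(rows, columns=["phenotype", "variant", "spearman_rho", "p_value"])
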