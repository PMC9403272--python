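"""16S amplicon community phenotype profiling.

Pipeline: renormalize ASV relative abundances by 16S rRNA gene copy number,
map ASV sequences to reference 16S sequences by percent identity (default
threshold 90%, roughly family-level resolution), average reference binary
phenotypes into per-ASV Phenotype Indices (PI in [0, 1]), discard samples
whose mapped-abundance coverage is below 75%, and compute per-sample
Community Phenotype Indices

    CPI = sum_i A_i * PI_i

with prediction variance v = sum_i A_i^2 * PI_i * (1 - PI_i) and reported
error sigma = sqrt(v).

Abundance tables are pandas DataFrames with samples as rows and ASVs (or
taxa) as columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import edlib
import numpy as np
import pandas as pd

from .bpm import BinaryPhenotypeMatrix
from .rules import PRODUCTS

IDENTITY_THRESHOLD = 90.0
COVERAGE_THRESHOLD = 0.75


def _check_sums(table: pd.DataFrame, tol: float = 1e-6) -> None:
    sums = table.sum(axis=1)
    bad = sums[(sums - 1.0).abs() > tol]
    if len(bad):
        raise ValueError(
            f"per-sample abundances must sum to 1 (+/- {tol}); offending samples: "
            f"{list(bad.index[:5])}"
        )


def renormalize_by_copy_number(
    table: pd.DataFrame, copies: pd.Series | Mapping[str, float], default: float = 1.0
) -> pd.DataFrame:
    """Divide each ASV's abundance by its 16S copy number and renormalize.

    ASVs missing from ``copies`` get the default copy number 1 (logged as a
    warning).  Copy numbers must be positive.
    """
    _check_sums(table)
    copies = pd.Series(copies, dtype=float)
    missing = [a for a in table.columns if a not in copies.index]
    if missing:
        warnings.warn(
            f"no copy number for {len(missing)} ASV(s); using default {default}",
            stacklevel=2,
        )
    c = copies.reindex(table.columns).fillna(default)
    if (c <= 0).any():
        raise ValueError(
            f"copy numbers must be positive; offending: {list(c[c <= 0].index[:5])}"
        )
    corrected = table.div(c, axis=1)
    return corrected.div(corrected.sum(axis=1), axis=0)


def pairwise_identity(query: str, target: str) -> float:
    """Percent identity of a semi-global (end-gap-free on the reference)
    alignment: matches / alignment length * 100.  ``N`` never matches."""
    query, target = query.upper(), target.upper()
    if not query or not target:
        return 0.0
    res = edlib.align(query, target, mode="HW", task="path")
    nice = edlib.getNiceAlignment(res, query, target)
    qa, ta = nice["query_aligned"], nice["target_aligned"]
    matches = sum(1 for qc, tc in zip(qa, ta) if qc == tc and qc not in "N-")
    return 100.0 * matches / len(qa)


@dataclass
class AsvMapping:
    """All reference hits at/above the identity threshold, per ASV."""

    hits: pd.DataFrame  # columns asv_id, genome_id, identity (only >= threshold)
    asv_ids: tuple[str, ...]
    identity_threshold: float

    @property
    def mapped_asvs(self) -> set[str]:
        return set(self.hits["asv_id"])

    def is_mapped(self, asv_id: str) -> bool:
        return asv_id in self.mapped_asvs

    def genomes_for(self, asv_id: str) -> list[str]:
        return list(self.hits.loc[self.hits["asv_id"] == asv_id, "genome_id"])


def map_asvs(
    asv_seqs: Mapping[str, str],
    reference_16s: Mapping[str, str],
    identity_threshold: float = IDENTITY_THRESHOLD,
) -> AsvMapping:
    """Map each ASV to every reference sequence at >= threshold identity.

    ASVs whose best identity falls below the threshold are left unmapped
    (they are discarded downstream); empty ASV sequences are unmapped with
    a warning.
    """
    if not reference_16s:
        raise ValueError("reference 16S collection must be non-empty")
    rows = []
    for asv_id, seq in asv_seqs.items():
        if not seq:
            warnings.warn(f"ASV {asv_id!r} has an empty sequence; unmapped", stacklevel=2)
            continue
        for genome_id, ref in reference_16s.items():
            identity = pairwise_identity(seq, ref)
            if identity >= identity_threshold:
                rows.append({"asv_id": asv_id, "genome_id": genome_id, "identity": identity})
    hits = pd.DataFrame(rows, columns=["asv_id", "genome_id", "identity"])
    return AsvMapping(
        hits=hits, asv_ids=tuple(asv_seqs), identity_threshold=identity_threshold
    )


def compute_phenotype_indices(
    mapping: AsvMapping, bpm: BinaryPhenotypeMatrix
) -> pd.DataFrame:
    """PI per mapped ASV and phenotype: unweighted mean of the binary
    phenotype over all mapped genomes."""
    known = set(bpm.genome_ids)
    absent = sorted(set(mapping.hits["genome_id"]) - known)
    if absent:
        raise ValueError(f"mapped genome(s) absent from the BPM: {absent[:5]}")
    if mapping.hits.empty:
        return pd.DataFrame(columns=list(PRODUCTS), dtype=float)
    joined = mapping.hits.join(bpm.phenotypes, on="genome_id")
    return joined.groupby("asv_id")[list(PRODUCTS)].mean()


def filter_and_renormalize(
    table: pd.DataFrame,
    mapping: AsvMapping,
    coverage_threshold: float = COVERAGE_THRESHOLD,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Restrict to mapped ASVs, flag low-coverage samples, renormalize.

    Coverage is the total abundance of mapped ASVs before renormalization.
    Samples with coverage >= threshold (inclusive) are retained; the
    returned table contains only retained samples with mapped abundances
    renormalized to sum 1.
    """
    mapped = [a for a in table.columns if mapping.is_mapped(a)]
    coverage = table[mapped].sum(axis=1)
    retained = coverage >= coverage_threshold
    kept = table.loc[retained, mapped]
    kept = kept.div(kept.sum(axis=1), axis=0)
    return kept, coverage, retained


def _align_pis(table: pd.DataFrame, pis: pd.DataFrame) -> pd.DataFrame:
    missing = [a for a in table.columns if a not in pis.index]
    if missing:
        raise ValueError(f"no phenotype index for ASV(s): {missing[:5]}")
    return pis.loc[list(table.columns), list(PRODUCTS)]


def compute_cpi(table: pd.DataFrame, pis: pd.DataFrame) -> pd.DataFrame:
    """CPI = sum_i A_i PI_i per sample and phenotype (samples x phenotypes)."""
    _check_sums(table)
    p = _align_pis(table, pis)
    return pd.DataFrame(
        table.to_numpy() @ p.to_numpy(), index=table.index, columns=p.columns
    )


def compute_cpi_variance(table: pd.DataFrame, pis: pd.DataFrame) -> pd.DataFrame:
    """Prediction variance v = sum_i A_i^2 PI_i (1 - PI_i); zero iff every
    PI is binary."""
    p = _align_pis(table, pis).to_numpy()
    return pd.DataFrame(
        (table.to_numpy() ** 2) @ (p * (1.0 - p)),
        index=table.index,
        columns=list(PRODUCTS),
    )


def compute_cpi_error(
    table: pd.DataFrame, pis: pd.DataFrame, sigma_mode: str = "sqrt"
) -> pd.DataFrame:
    """Reported CPI error: sqrt of the variance by default, or the raw
    variance sum with ``sigma_mode='raw'``."""
    v = compute_cpi_variance(table, pis)
    if sigma_mode == "sqrt":
        return np.sqrt(v)
    if sigma_mode == "raw":
        return v
    raise ValueError(f"sigma_mode must be 'sqrt' or 'raw', got {sigma_mode!r}")


@dataclass
class CpiProfile:
    """Per-sample, per-phenotype CPI with error, coverage and retained flag."""

    cpi: pd.DataFrame  # retained samples x phenotypes
    sigma: pd.DataFrame
    variance: pd.DataFrame
    coverage: pd.Series  # all input samples
    retained: pd.Series  # all input samples, bool

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: sample, phenotype, cpi, sigma, coverage, retained."""
        rows = []
        for sample in self.coverage.index:
            for phenotype in PRODUCTS:
                kept = bool(self.retained.loc[sample])
                rows.append(
                    {
                        "sample": sample,
                        "phenotype": phenotype,
                        "cpi": self.cpi.loc[sample, phenotype] if kept else np.nan,
                        "sigma": self.sigma.loc[sample, phenotype] if kept else np.nan,
                        "coverage": self.coverage.loc[sample],
                        "retained": kept,
                    }
                )
        return pd.DataFrame(rows)


def profile_16s(
    table: pd.DataFrame,
    asv_seqs: Mapping[str, str],
    reference_16s: Mapping[str, str],
    bpm: BinaryPhenotypeMatrix,
    copy_numbers: pd.Series | Mapping[str, float] | None = None,
    identity_threshold: float = IDENTITY_THRESHOLD,
    coverage_threshold: float = COVERAGE_THRESHOLD,
    sigma_mode: str = "sqrt",
    mapping: AsvMapping | None = None,
) -> tuple[CpiProfile, AsvMapping, pd.DataFrame]:
    """Full 16S profiling pipeline; returns (profile, mapping, PI table).

    A precomputed ``mapping`` (e.g. from an external search tool) bypasses
    the alignment step.
    """
    if copy_numbers is not None:
        table = renormalize_by_copy_number(table, copy_numbers)
    if mapping is None:
        mapping = map_asvs(asv_seqs, reference_16s, identity_threshold)
    pis = compute_phenotype_indices(mapping, bpm)
    kept, coverage, retained = filter_and_renormalize(table, mapping, coverage_threshold)
    cpi = compute_cpi(kept, pis)
    variance = compute_cpi_variance(kept, pis)
    sigma = compute_cpi_error(kept, pis, sigma_mode=sigma_mode)
    profile = CpiProfile(
        cpi=cpi, sigma=sigma, variance=variance, coverage=coverage, retained=retained
    )
    return profile, mapping, pis
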