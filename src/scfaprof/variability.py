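"""Phenotype variability within taxonomic groups (NVP and OPVS).

For a group of genomes sharing a species or genus label, each of the six
binary phenotypes has a producer fraction p.  The per-phenotype variability
score is the Gini impurity 2p(1-p), which attains its stated maximum 0.5 at
an equal producer/non-producer split for groups of any size.  NVP counts
phenotypes with 0 < p < 1; OPVS sums the six scores, so 0 <= OPVS <= 3.

Population variance p(1-p) and unbiased sample variance are available as
alternative score modes for sensitivity checks; they do not reach 0.5 at an
equal split for every group size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bpm import RANKS, BinaryPhenotypeMatrix
from .rules import PRODUCTS

SCORE_MODES = ("gini", "population", "sample")


def variability_score(p: float, mode: str = "gini", n: int | None = None) -> float:
    """Per-phenotype variability score for producer fraction ``p``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"producer fraction must lie in [0, 1], got {p}")
    if mode == "gini":
        return 2.0 * p * (1.0 - p)
    if mode == "population":
        return p * (1.0 - p)
    if mode == "sample":
        if n is None or n < 2:
            return 0.0
        return n / (n - 1.0) * p * (1.0 - p)
    raise ValueError(f"unknown score mode {mode!r}; expected one of {SCORE_MODES}")


@dataclass
class VariabilityReport:
    """Per-phenotype producer fractions and scores, NVP and OPVS."""

    producer_fraction: pd.Series  # indexed by phenotype
    scores: pd.Series
    nvp: int
    opvs: float
    n_members: int


def group_variability(members: pd.DataFrame, mode: str = "gini") -> VariabilityReport:
    """Variability report for one taxonomic group of BPM rows.

    ``members`` is a genomes x phenotypes 0/1 frame (one row per member).
    Singleton groups have all scores 0 and NVP 0.
    """
    if len(members) == 0:
        raise ValueError("group must have at least one member")
    p = members[list(PRODUCTS)].mean(axis=0)
    scores = pd.Series(
        [variability_score(v, mode=mode, n=len(members)) for v in p], index=p.index
    )
    nvp = int(((p > 0) & (p < 1)).sum())
    return VariabilityReport(
        producer_fraction=p,
        scores=scores,
        nvp=nvp,
        opvs=float(scores.sum()),
        n_members=len(members),
    )


def rank_variable_groups(
    bpm: BinaryPhenotypeMatrix,
    rank: str,
    nvp_min: int = 0,
    opvs_min: float = 0.0,
    mode: str = "gini",
) -> pd.DataFrame:
    """Multi-member groups at ``rank`` passing both thresholds (>=),
    sorted by OPVS descending with alphabetical tie-break.

    Output mirrors the per-genus summary table: group, n_members, NVP,
    OPVS, family, phylum.  Groups labelled "undefined" at the rank are
    skipped (they are not a real taxon).
    """
    if rank not in ("species", "genus"):
        raise ValueError(f"rank must be 'species' or 'genus', got {rank!r}")
    labels = bpm.taxonomy[rank]
    rows = []
    for name, idx in labels.groupby(labels).groups.items():
        if name == "undefined" or len(idx) < 2:
            continue
        report = group_variability(bpm.phenotypes.loc[idx], mode=mode)
        if report.nvp >= nvp_min and report.opvs >= opvs_min:
            tax = bpm.taxonomy.loc[idx[0]]
            rows.append(
                {
                    "group": name,
                    "n_members": report.n_members,
                    "nvp": report.nvp,
                    "opvs": report.opvs,
                    "family": tax["family"],
                    "phylum": tax["phylum"],
                }
            )
    out = pd.DataFrame(rows, columns=["group", "n_members", "nvp", "opvs", "family", "phylum"])
    if len(out):
        out = out.sort_values(
            ["opvs", "group"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
    return out
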