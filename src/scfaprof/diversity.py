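"""Community diversity: Faith PD, weighted UniFrac, and phenotype beta
diversity (PBD / rPBD) on carrier sub-communities.

Phenotype Beta Diversity restricts a sample to the ASVs that carry a
phenotype (PI >= carrier threshold, default 0.5 inclusive), renormalizes,
and measures beta diversity between the restricted profiles.  Relative PBD
divides by the whole-community beta diversity pair by pair, to account for
diversity scale inheritance.

Trees are scikit-bio ``TreeNode`` objects (rooted, named leaves, branch
lengths >= 0).  Both metrics are computed by direct per-branch summation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from skbio import TreeNode

CARRIER_THRESHOLD = 0.5


def _leaf_names(tree: TreeNode) -> set[str]:
    return {tip.name for tip in tree.tips()}


def faith_pd(observed: Iterable[str], tree: TreeNode) -> float:
    """Sum of branch lengths on the minimal rooted subtree spanning the
    observed leaves (branches up to the root included)."""
    observed = set(observed)
    leaves = _leaf_names(tree)
    missing = observed - leaves
    if missing:
        raise ValueError(f"observed leaf/leaves absent from tree: {sorted(missing)[:5]}")
    total = 0.0
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            node._observed = node.name in observed
        else:
            node._observed = any(c._observed for c in node.children)
        if node._observed and node.length:
            total += node.length
    return total


def _branch_proportions(tree: TreeNode, abundance: Mapping[str, float]) -> None:
    """Attach to every node the abundance fraction descending through it."""
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            node._prop = abundance.get(node.name, 0.0)
        else:
            node._prop = sum(c._prop for c in node.children)


def weighted_unifrac(
    sample_a: Mapping[str, float],
    sample_b: Mapping[str, float],
    tree: TreeNode,
    normalized: bool = True,
) -> float:
    """Weighted UniFrac distance between two abundance profiles.

    Normalized form: sum_l b_l |pA(l) - pB(l)| / sum_l b_l (pA(l) + pB(l)),
    where p_X(l) is the abundance fraction descending through branch l;
    symmetric, zero for identical profiles, bounded by [0, 1].  Profiles
    are renormalized to sum 1; an empty profile is an error.
    """
    leaves = _leaf_names(tree)
    profiles = []
    for sample in (sample_a, sample_b):
        sample = {k: v for k, v in dict(sample).items() if v > 0}
        extra = set(sample) - leaves
        if extra:
            raise ValueError(f"sample taxa absent from tree: {sorted(extra)[:5]}")
        total = sum(sample.values())
        if total <= 0:
            raise ValueError("cannot compute weighted UniFrac for an empty sample")
        profiles.append({k: v / total for k, v in sample.items()})
    pa, pb = profiles
    num = den = 0.0
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            node._pa = pa.get(node.name, 0.0)
            node._pb = pb.get(node.name, 0.0)
        else:
            node._pa = sum(c._pa for c in node.children)
            node._pb = sum(c._pb for c in node.children)
        b = node.length or 0.0
        num += b * abs(node._pa - node._pb)
        den += b * (node._pa + node._pb)
    if not normalized:
        return num
    return num / den if den > 0 else 0.0


@dataclass
class CarrierSubcommunity:
    """Phenotype-carrier slice of one sample, abundances renormalized."""

    sample: str
    phenotype: str
    carriers: tuple[str, ...]
    abundances: pd.Series  # renormalized over carriers; empty if none

    @property
    def empty(self) -> bool:
        return len(self.carriers) == 0


def carrier_subcommunities(
    table: pd.DataFrame,
    pis: pd.DataFrame,
    phenotype: str,
    carrier_threshold: float = CARRIER_THRESHOLD,
) -> dict[str, CarrierSubcommunity]:
    """Binary carrier call per ASV (PI >= threshold, inclusive) and the
    renormalized carrier abundances per sample."""
    missing = [a for a in table.columns if a not in pis.index]
    if missing:
        raise ValueError(f"no phenotype index for ASV(s): {missing[:5]}")
    carrier_asvs = [a for a in table.columns if pis.loc[a, phenotype] >= carrier_threshold]
    out = {}
    for sample in table.index:
        sub = table.loc[sample, carrier_asvs]
        sub = sub[sub > 0]
        total = float(sub.sum())
        out[sample] = CarrierSubcommunity(
            sample=sample,
            phenotype=phenotype,
            carriers=tuple(sub.index),
            abundances=(sub / total) if total > 0 else sub,
        )
    return out


def pbd_rpbd(
    table: pd.DataFrame,
    pis: pd.DataFrame,
    phenotype: str,
    tree: TreeNode,
    carrier_threshold: float = CARRIER_THRESHOLD,
    metric=weighted_unifrac,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise (PBD, rPBD, BD) matrices for a phenotype.

    PBD is the metric on carrier sub-communities, BD on full communities,
    rPBD the per-pair ratio PBD/BD.  Samples with empty carrier sets are
    excluded from PBD/rPBD pairs (NaN); pairs with BD = 0 have undefined
    rPBD (NaN).
    """
    subs = carrier_subcommunities(table, pis, phenotype, carrier_threshold)
    samples = list(table.index)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    n = len(samples)
    pbd = np.full((n, n), np.nan)
    bd = np.full((n, n), np.nan)
    np.fill_diagonal(bd, 0.0)
    for i in range(n):
        if not subs[samples[i]].empty:
            pbd[i, i] = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            d = metric(table.loc[samples[i]], table.loc[samples[j]], tree)
            bd[i, j] = bd[j, i] = d
            si, sj = subs[samples[i]], subs[samples[j]]
            if not si.empty and not sj.empty:
                pbd[i, j] = pbd[j, i] = metric(si.abundances, sj.abundances, tree)
    with np.errstate(divide="ignore", invalid="ignore"):
        rpbd = np.where(bd > 0, pbd / bd, np.nan)
    idx = pd.Index(samples, name="sample")
    return (
        pd.DataFrame(pbd, index=idx, columns=idx),
        pd.DataFrame(rpbd, index=idx, columns=idx),
        pd.DataFrame(bd, index=idx, columns=idx),
    )


def group_distance_summary(
    distances: pd.DataFrame, groups: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Mean pairwise distance within and between groups (diagonal excluded,
    unordered pairs).  Intragroup means are NaN for groups of one."""
    groups = pd.Series(groups).reindex(distances.index)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    labels = sorted(groups.unique())
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = list(distances.index)
    rows = []
    for gi_idx, gi in enumerate(labels):
        for gj in labels[gi_idx:]:
            vals = []
            members_i = [s for s in samples if groups[s] == gi]
            members_j = [s for s in samples if groups[s] == gj]
            if gi == gj:
                for a_idx, a in enumerate(members_i):
                    for b in members_i[a_idx + 1 :]:
                        vals.append(distances.loc[a, b])
            else:
                for a in members_i:
                    for b in members_j:
                        vals.append(distances.loc[a, b])
            rows.append(
                {
                    "group_a": gi,
                    "group_b": gj,
                    "kind": "intra" if gi == gj else "inter",
                    "mean_distance": float(np.nanmean(vals)) if vals else np.nan,
                    "n_pairs": len(vals),
                }
            )
    return pd.DataFrame(rows)


def cpi_vs_ad_bins(
    cpi: pd.Series, ad: pd.Series, n_bins: int
) -> pd.DataFrame:
    """Equal-width alpha-diversity bins with per-bin CPI quartile summaries."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    shared = cpi.index.intersection(ad.index)
    if len(shared) == 0:
        raise ValueError("no shared samples between CPI and AD")
    cpi, ad = cpi.loc[shared], ad.loc[shared]
    lo, hi = float(ad.min()), float(ad.max())
    if hi == lo:
        edges = np.array([lo, lo + 1e-12])
        n_bins = 1
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.digitize(ad, edges[1:-1], right=False), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        vals = cpi[which == b]
        rows.append(
            {
                "bin": b,
                "ad_low": edges[b],
                "ad_high": edges[b + 1],
                "count": len(vals),
                "cpi_median": float(vals.median()) if len(vals) else np.nan,
                "cpi_q1": float(vals.quantile(0.25)) if len(vals) else np.nan,
                "cpi_q3": float(vals.quantile(0.75)) if len(vals) else np.nan,
            }
        )
    return pd.DataFrame(rows)
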