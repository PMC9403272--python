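"""WGS profiling: taxonomy mapping, TMM normalization, pathway abundances."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scfaprof import (
    GenomeRecord,
    build_bpm,
    cpi_pathway_correlation,
    normalize_counts,
    pathway_abundance,
    pathway_signatures,
    taxonomy_map_cpi,
    tmm_factors,
)
from scfaprof.rules import PRODUCTS
from conftest import roles_for_combination


# --- taxonomy-based CPI -------------------------------------------------------

def _bpm_species(ruleset):
    ace = roles_for_combination(ruleset, "acetate", {"A"})
    base = ("P1", "C1", "O1", "Fam1", "Gen1", "Sp1")
    genomes = [
        GenomeRecord("g1", base + ("s1",), frozenset(ace)),
        GenomeRecord("g2", base + ("s2",), frozenset(ace)),
        GenomeRecord("g3", base + ("s3",), frozenset()),
    ]
    return build_bpm(genomes, ruleset)


def test_species_match_pi_is_strain_mean(ruleset):
    bpm = _bpm_species(ruleset)
    table = pd.DataFrame({"Sp1": [1.0]}, index=pd.Index(["s"], name="sample"))
    paths = {"Sp1": ("P1", "C1", "O1", "Fam1", "Gen1", "Sp1", "undefined")}
    profile, pis = taxonomy_map_cpi(table, paths, bpm)
    assert pis.loc["Sp1", "acetate"] == pytest.approx(2 / 3)
    assert profile.cpi.loc["s", "acetate"] == pytest.approx(2 / 3)


def test_order_level_match_is_discarded(ruleset):
    bpm = _bpm_species(ruleset)
    table = pd.DataFrame(
        {"Sp1": [0.6], "other": [0.4]}, index=pd.Index(["s"], name="sample")
    )
    paths = {
        "Sp1": ("P1", "C1", "O1", "Fam1", "Gen1", "Sp1", "undefined"),
        # same order as the BPM but a family absent from it
        "other": ("P1", "C1", "O1", "FamX", "GenX", "SpX", "undefined"),
    }
    profile, pis = taxonomy_map_cpi(table, paths, bpm)
    assert "other" not in pis.index
    assert profile.coverage.loc["s"] == pytest.approx(0.6)
    assert profile.cpi.loc["s", "acetate"] == pytest.approx(2 / 3)  # renormalized


def test_all_taxa_unmapped_flags_sample(ruleset):
    bpm = _bpm_species(ruleset)
    table = pd.DataFrame({"x": [1.0]}, index=pd.Index(["s"], name="sample"))
    paths = {"x": ("PX", "CX", "OX", "FX", "GX", "SX", "undefined")}
    profile, _ = taxonomy_map_cpi(table, paths, bpm)
    assert not bool(profile.retained.loc["s"])


def test_family_level_match_maps_all_family_genomes(ruleset):
    bpm = _bpm_species(ruleset)
    table = pd.DataFrame({"t": [1.0]}, index=pd.Index(["s"], name="sample"))
    paths = {"t": ("P1", "C1", "O1", "Fam1", "GenNew", "SpNew", "undefined")}
    _, pis = taxonomy_map_cpi(table, paths, bpm)
    assert pis.loc["t", "acetate"] == pytest.approx(2 / 3)


# --- TMM ----------------------------------------------------------------------

def _core_counts(seed=0, n_core=20, n_samples=3, n_extra=10):
    rng = np.random.default_rng(seed)
    core = [f"core{i}" for i in range(n_core)]
    extra = [f"role{i}" for i in range(n_extra)]
    counts = pd.DataFrame(
        rng.integers(100, 3000, size=(n_core + n_extra, n_samples)),
        index=core + extra,
        columns=[f"S{i}" for i in range(n_samples)],
    )
    return counts, core


def test_identical_samples_give_unit_factors():
    counts, core = _core_counts()
    counts["S1"] = counts["S0"]
    counts["S2"] = counts["S0"]
    f = tmm_factors(counts, core)
    assert np.allclose(f, 1.0)


def test_library_scaling_leaves_normalized_abundance_unchanged():
    counts, core = _core_counts(seed=1)
    scaled = counts.copy()
    scaled["S1"] = counts["S1"] * 4
    f0 = tmm_factors(counts, core)
    f1 = tmm_factors(scaled, core)
    n0 = normalize_counts(counts, f0)
    n1 = normalize_counts(scaled, f1)
    assert np.allclose(n0, n1, rtol=0, atol=1e-9 * n0.to_numpy().max())


def test_inflated_core_gene_is_trimmed():
    # a large background library keeps the inflated gene's contribution to
    # the library size small, so the trimmed factor must stay near 1
    counts, core = _core_counts(seed=2, n_samples=3, n_extra=150)
    # low-count core genes against a large background library, so the
    # inflated gene barely moves the library size itself
    rng = np.random.default_rng(12)
    counts.loc[core, "S0"] = rng.integers(100, 500, size=len(core))
    counts["S1"] = counts["S0"]
    counts["S2"] = counts["S0"]
    counts.loc["core0", "S1"] *= 10
    f = tmm_factors(counts, core)
    assert np.all(np.abs(f.to_numpy() - 1.0) < 0.05)
    # without any trimming the inflated gene shifts S1's mean M by
    # log2(10)/20 ~ 0.17; verify the trim actually removed it
    f_wide = tmm_factors(counts, core, trim_m=0.0, trim_a=0.0)
    assert np.abs(f_wide.to_numpy() - 1.0).max() > 0.05


def test_naive_trim_and_weight_oracle():
    """Weighted factors match an independent, literal re-computation of the
    trim-and-weight recipe with a fixed reference sample."""
    counts, core = _core_counts(seed=3, n_samples=4)
    lib = counts.sum(axis=0).astype(float)
    ref = "S0"
    logf = {}
    for s in counts.columns:
        o = counts.loc[core, s].to_numpy(float)
        r = counts.loc[core, ref].to_numpy(float)
        keep = (o > 0) & (r > 0)
        o, r = o[keep], r[keep]
        m = np.log2((o / lib[s]) / (r / lib[ref]))
        a = 0.5 * np.log2((o / lib[s]) * (r / lib[ref]))
        v = (lib[s] - o) / (lib[s] * o) + (lib[ref] - r) / (lib[ref] * r)
        n = len(m)
        ranks_m = stats.rankdata(m)
        ranks_a = stats.rankdata(a)
        lo_m, hi_m = np.floor(n * 0.3) + 1, n - np.floor(n * 0.3)
        lo_a, hi_a = np.floor(n * 0.05) + 1, n - np.floor(n * 0.05)
        sel = (ranks_m >= lo_m) & (ranks_m <= hi_m) & (ranks_a >= lo_a) & (ranks_a <= hi_a)
        logf[s] = 0.0 if np.max(np.abs(m)) < 1e-6 else np.sum(m[sel] / v[sel]) / np.sum(1 / v[sel])
    expected = pd.Series(logf)
    expected -= expected.mean()
    expected = 2.0 ** expected
    mine = tmm_factors(counts, core, ref_sample="S0", weighted=True)
    assert np.allclose(mine, expected.reindex(mine.index), atol=1e-12)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_tmm_matches_edger_on_core_matrix(tmp_path):
    """Independent oracle: edgeR's TMM on a core-only matrix."""
    counts, core = _core_counts(seed=4, n_samples=4, n_core=30, n_extra=0)
    path = tmp_path / "counts.tsv"
    counts.to_csv(path, sep="\t")
    script = (
        'suppressMessages(library(edgeR)); '
        f'x <- as.matrix(read.delim("{path}", row.names=1)); '
        'cat(paste(c(calcNormFactors(x, method="TMM"), '
        'calcNormFactors(x, method="TMM", doWeighting=FALSE)), collapse=","))'
    )
    proc = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
    )
    if proc.returncode != 0:
        pytest.skip(f"edgeR not usable: {proc.stderr[-200:]}")
    vals = np.array([float(v) for v in proc.stdout.strip().split(",")])
    theirs_weighted, theirs_plain = vals[:4], vals[4:]
    mine_weighted = tmm_factors(counts, core, weighted=True).to_numpy()
    mine_plain = tmm_factors(counts, core).to_numpy()
    assert np.allclose(mine_weighted, theirs_weighted, atol=1e-8)
    assert np.allclose(mine_plain, theirs_plain, atol=1e-8)


def test_tmm_errors():
    counts, core = _core_counts()
    with pytest.raises(ValueError, match="2 samples"):
        tmm_factors(counts[["S0"]], core)
    zeroed = counts.copy()
    zeroed.loc[core, "S1"] = 0
    with pytest.raises(ValueError, match="zero total core"):
        tmm_factors(zeroed, core)


def test_normalize_counts_formula():
    counts = pd.DataFrame({"S0": [10, 999990], "S1": [10, 999990]}, index=["g", "h"])
    f = pd.Series({"S0": 1.0, "S1": 2.0})
    cpm = normalize_counts(counts, f)
    assert cpm.loc["g", "S0"] == pytest.approx(10.0)
    assert cpm.loc["g", "S1"] == pytest.approx(5.0)  # factor 2 halves CPM
    doubled = normalize_counts(counts * 2, f)
    assert np.allclose(doubled, cpm)


# --- pathway abundances -------------------------------------------------------

def test_signatures_are_variant_specific_and_disjoint(ruleset):
    sigs = pathway_signatures(ruleset)
    assert sigs[("butyrate", "P1")] == {"Thl", "Hbd", "Crt"}
    assert sigs[("butyrate", "universal")] == {"Bcd-EtfAB"}
    assert sigs[("butyrate", "terminal")] == {"But", "CtfAB", "Ptb", "Buk"}
    for product in ("butyrate", "propionate"):
        variant_keys = [k for k in sigs if k[0] == product and k[1].startswith("P")]
        for i, ki in enumerate(variant_keys):
            for kj in variant_keys[i + 1:]:
                assert not (sigs[ki] & sigs[kj])
        # shared roles never appear in variant signatures
        assert "Bcd-EtfAB" not in set().union(*(sigs[k] for k in variant_keys))


def test_pathway_abundance_sums_signature_roles(ruleset):
    sigs = {("butyrate", "P1"): frozenset({"Thl", "Hbd", "Crt"})}
    normalized = pd.DataFrame(
        {"S0": [5.0, 3.0, 2.0, 100.0]}, index=["Thl", "Hbd", "Crt", "core0"]
    )
    out = pathway_abundance(normalized, sigs)
    assert out.loc["S0", ("butyrate", "P1")] == pytest.approx(10.0)
    zero = pathway_abundance(normalized * 0, sigs)
    assert zero.loc["S0", ("butyrate", "P1")] == 0.0
    with pytest.warns(UserWarning, match="missing"):
        out2 = pathway_abundance(
            normalized.drop(index="Thl"), sigs
        )
    assert out2.loc["S0", ("butyrate", "P1")] == pytest.approx(5.0)
    with pytest.raises(ValueError, match="empty"):
        pathway_abundance(normalized, {("butyrate", "P9"): frozenset()})


def test_correlation_monotone_and_reversed():
    idx = pd.Index([f"S{i}" for i in range(6)], name="sample")
    cpi = pd.DataFrame({"butyrate": np.linspace(0.1, 0.6, 6)}, index=idx)
    ab = pd.DataFrame(
        {("butyrate", "P1"): np.exp(np.linspace(0.1, 0.6, 6)),
         ("butyrate", "P2"): -np.linspace(0.1, 0.6, 6)},
        index=idx,
    )
    ab.columns = pd.MultiIndex.from_tuples(ab.columns)
    out = cpi_pathway_correlation(cpi, ab).set_index("variant")
    assert out.loc["P1", "spearman_rho"] == pytest.approx(1.0)
    assert out.loc["P2", "spearman_rho"] == pytest.approx(-1.0)
    with pytest.raises(ValueError, match="3 shared"):
        cpi_pathway_correlation(cpi.iloc[:2], ab.iloc[:2])
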