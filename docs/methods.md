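# Methods

## Pathway rules and binary phenotypes

The rule engine treats SCFA production as a deterministic function of a
genome's functional-role repertoire. A *pathway variant* for a product is a
conjunction of role groups; a group is satisfied when any one of its
alternatives is fully present, where an alternative is a single role or a
conjunction of roles (multi-subunit non-orthologous displacements, written
`PduC2+PduD2` in the config). Variants of one product may reference named
shared segments defined once per product — for butyrate, the universal
crotonyl-CoA → butyryl-CoA step (`Bcd-EtfAB`) and the terminal release
group (`But | CtfAB | Ptb+Buk`) are shared by all four variants. The
default rule content (four butyrate variants starting from acetyl-CoA,
succinate, glutamate and lysine; three propionate variants from succinate,
lactate and propanediol; single variants for acetate, formate and the two
lactate enantiomers; ~46 catalogued enzymes) ships as
`scfaprof/data/pathways.yaml` and is fully user-replaceable.

Consequences of the semantics that the tests rely on:

* **Monotonicity** — adding a role can only add variant calls, never remove
  them; phenotypes can only flip 0 → 1.
* **OR-equivalence** — swapping one present alternative for another member
  of the same group changes nothing downstream.
* **Sub-labels** — propionate P3 is reported as `P3*` when the dehydratase
  group is satisfied *only* by the B12-independent `PduC2+PduD2` form; the
  star is informative and collapses to P3 for phenotypes and distribution
  summaries.

Two deliberate knobs: the propionate P1 CoA-transferase group can be
relaxed (`default_ruleset(relaxed_propionate=True)`) because genomes of
known propionate producers exist that lack both known transferases,
suggesting an unidentified one; and the accessory mutase GTPase `MutB2` is
catalogued for annotation but never required.

## Variability metrics

For a taxonomic group, the per-phenotype score is the Gini impurity
s(p) = 2p(1−p) of the producer fraction p. This is the only simple
"variance-like" choice whose maximum is exactly 0.5 at an even split for
groups of *any* size, which keeps the six-phenotype sum (OPVS) in [0, 3];
population variance p(1−p) caps at 0.25 and the unbiased sample variance
exceeds 0.5 for small groups. Both alternatives remain available
(`mode="population" | "sample"`) for sensitivity analyses. NVP counts
phenotypes with 0 < p < 1. Group ranking uses inclusive thresholds on both
metrics, sorts by OPVS descending, and breaks ties alphabetically for
reproducibility; groups labelled `undefined` at the grouping rank are
skipped.

## 16S profiling

* **Copy-number correction.** Observed read fractions over-represent taxa
  with many 16S operons; corrected abundances are A′ᵢ ∝ Aᵢ/cᵢ. Unknown copy
  numbers default to 1 with a warning.
* **Mapping.** Percent identity is matches / alignment-length of a
  semi-global alignment (edlib `HW` mode: reference end-gaps free, unit
  costs), with `N` never counting as a match. All reference hits at or
  above the threshold (default 90%, ≈ family-level resolution) are kept —
  deliberately not best-hit-only, since the Phenotype Index is defined as
  the mean phenotype over *all* genomes within the mapping radius. A
  caveat of semi-global identity: contiguous mismatch runs at sequence ends
  can be partially absorbed by free end-gaps, so identity for such
  degenerate cases can exceed the Hamming value; dispersed substitutions
  (the realistic case, and what the synthetic generator produces) are
  unaffected.
* **Coverage filter.** Sample coverage is the total abundance of mapped
  ASVs before renormalization; samples below 0.75 are discarded. The
  boundary is inclusive (retain at exactly 0.75) — the stated rule only
  discards *less than* 75%. Retained samples' mapped abundances are
  renormalized to 1 before CPI, which is what makes CPI interpretable as a
  fraction in [0, 1]; this renormalization is an assumption documented
  here, not a printed rule.
* **Error model.** The prediction variance v = Σ Aᵢ²·PIᵢ(1−PIᵢ) treats each
  ASV's carrier status as an independent Bernoulli(PIᵢ); the reported error
  is σ = √v so it lives on the CPI scale (the raw sum is available with
  `sigma_mode="raw"`). σ = 0 exactly when every PI is binary.

## WGS profiling

Taxonomy-based mapping walks each taxon's rank path from strain up to
family and maps it to all BPM genomes matching the first defined rank with
any match; entries matching only above family are discarded and the rest
renormalized — after which CPI/σ use the identical formulas as the 16S
route (one code path).

Gene-level profiling TMM-normalizes per-role read counts using **only the
designated universal single-copy core genes** to estimate each sample's
scaling factor (reference sample = the one whose core-gene CPM upper
quartile is closest to the mean; configurable). The factor recipe follows
the standard trimmed mean of M-values: per-gene log2 abundance ratios M
against the reference, two-sided trims of 30% by M and 5% by A, factors
rescaled to log-mean zero, genes with a zero count in either sample
excluded. The default combines the kept M values with a **plain mean**
rather than inverse approximate-variance weights: precision weights depend
on absolute counts, so they break exact invariance of normalized
abundances under per-sample count scaling, a property this module
guarantees to 1e-9; `weighted=True` restores the precision-weighted
variant, which matches edgeR's `calcNormFactors(method="TMM")` to machine
precision on a core-only matrix (the unweighted default matches
`doWeighting=FALSE`). Normalized abundance is counts per million on the
TMM-adjusted library size.

Pathway abundance per variant sums the normalized abundances of the roles
*specific to* that variant (appearing in no other variant of the same
product); roles shared across variants are reported only under the
product's named shared segments (e.g. butyrate "universal"), preventing
double counting in P1–P4 comparisons. CPI-vs-abundance association uses
Spearman rank correlation with mid-ranked ties.

## Diversity

Faith PD sums branch lengths on the minimal rooted subtree spanning the
observed leaves, root connection included (the standard convention).
Weighted UniFrac is computed by direct per-branch summation,
Σ b·|p_A − p_B| normalized by Σ b·(p_A + p_B), giving values in [0, 1];
the raw (unnormalized) numerator is available. Carrier sub-communities use
an inclusive PI ≥ 0.5 cutoff by default (the cutoff is not a published
constant; it is configurable). PBD is the metric on renormalized carrier
profiles; rPBD is the per-pair ratio PBD/BD with pairs at BD = 0 left
undefined (an aggregate-ratio summary can be formed from the returned
matrices if preferred). CPI-vs-alpha-diversity summaries use equal-width
bins over the observed AD range with per-bin quartiles; the bin count is a
free parameter.

## Synthetic fixtures

The generator is the package's study design, not a test convenience dial.

* **Taxonomy and phenotypes.** Default shape: 6 families × 2 genera × 2
  species × 2 strains = 48 genomes. Producer status is assigned per family
  with per-product prevalences set to the genome-level producer fractions
  of the reference collection the rules describe (butyrate 0.126,
  propionate 0.289, acetate 0.868, formate 0.714, L-lactate 0.633,
  D-lactate 0.45). Producer genomes receive the complete role set of one
  (80%) or two randomly chosen variants with uniformly chosen alternatives;
  10% of non-producers carry an incomplete fragment (one required group
  deleted) so that near-miss genomes exist. Optional within-family
  heterogeneity flips producer-family members to non-producers with
  probability h, creating fractional PIs.
* **16S surrogates.** 250 nt sequences; family-diagnostic substitutions are
  placed on a dispersed position grid interleaved between families (15
  positions per family), and species/strain substitutions (4 and 2) on the
  complementary positions. Substitution-only mutations on dispersed
  positions make the optimal alignment the diagonal one, so identity
  arithmetic is exact: cross-family identity ≤ 88% (< the 90% threshold),
  within-family ≥ 95.2% (> 90%), within-species ≥ 98.4% (> 97%). The
  accompanying Newick tree uses the designed per-level mutation counts as
  branch lengths. Infeasible combinations (blocks exceeding the sequence,
  within-family divergence crossing the threshold) are rejected.
* **Communities.** Per-sample genome abundances are symmetric
  Dirichlet(α = 1); copy numbers are uniform integers in [1, 7] applied *in
  reverse* to produce the observed table, so the pipeline's correction must
  invert them; ground-truth CPI is the abundance-weighted genome phenotype.
  An optional "alien" ASV (40% of positions mutated, unmappable by
  construction) at fixed abundance exercises the coverage filter. WGS
  counts are multinomial draws (default depth 2×10⁵) over
  abundance-weighted role presence plus 20 universal single-copy core
  genes.

What the fixtures deliberately do **not** emulate: real taxon-abundance
distributions of any cohort, 16S indels and chimeras, multi-copy or
divergent intra-genomic 16S operons, annotation noise in roles_present, and
read-level processes (errors, mapping ambiguity). Passing tests therefore
demonstrate the correctness of the computations and thresholds, not field
accuracy on real cohorts.

## Numerical choices and degenerate inputs

Per-sample abundance sums are validated to 1 ± 1e-6 where the formulas
require it. Variant-combination labels sort naturally (P2 before P10).
Samples whose taxa are all unmapped are flagged rather than erroring.
Pairs with zero whole-community beta diversity yield undefined rPBD.
`tmm_factors` requires ≥ 2 samples and positive core totals; genes absent
from a signature sum as zero with a warning. All generator randomness
derives from `numpy.random.default_rng([seed, stream])`; nothing touches
global random state, and equal seeds give byte-identical outputs.

## Problem sizes

The test suite and the worked examples run on the default 48-genome
collection, 100-sample communities for parameter-recovery checks, and
trees of ≤ 5 leaves for exhaustive diversity oracles — sizes chosen so
every oracle can be brute-forced while still exercising all code paths;
the implementations themselves are vectorized and scale to
reference-collection sizes in the thousands of genomes.
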