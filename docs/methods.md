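# Methods

## The prioritization procedure

`expandeg` prioritizes candidate gene families for a tolerance trait by
intersecting two signals across a panel of related species that differ in
the trait:

1. **Trait-specific gene-family expansion.** Genes are grouped into
   hierarchical orthologous groups (families, "HOGs"). A family is called
   *expanded* in a focal species relative to a background set when the
   focal species' ploidy-corrected copy number is at least `factor`
   (default 2) times the ploidy-corrected copy number of **every**
   background species. Ploidy correction scales raw counts by `2/ploidy`,
   so a tetraploid's count is halved before comparison; the correction is
   applied symmetrically whether the polyploid is focal or background. A
   tie (exactly `factor` times) counts as expanded. A focal species must
   additionally carry at least `min_focal_copies` raw copies (default 2):
   "expansion" implies duplication, and without the guard a single-copy
   focal species would be called expanded against a tetraploid's halved
   single copy. Setting `min_focal_copies = 1` restores the literal ratio
   rule.
2. **Differential expression (DE) under the stress.** A gene is a DEG when
   its adjusted p-value from a count-based DE analysis is at most
   `alpha_de` (default 0.1, inclusive). Missing adjusted p-values (the
   independent-filtering convention) mean "not DE", never an error.

All statistics are computed over the **Conserved Set** — the families with
at least one gene from every study species. Families absent from any
species are excluded up front and tallied by absence pattern.

Candidate tiers are nested:

* `candidate`: expanded in both tolerant species (and in no sensitive
  species) AND DE in at least one tolerant species;
* `conserved_de`: additionally DE in both tolerant species;
* `unique_up`: additionally no DEG in any sensitive species and no
  down-regulated tolerant DEG.

The contrast tiers are the exact phenotype-swapped image of this
construction (verified by a swap-symmetry test).

## Statistics

**Enrichment engine.** Every over/under-representation claim is a
one-sided hypergeometric tail, computed by exact summation of log-space
PMF terms (log-gamma binomial coefficients combined with `logsumexp`); no
normal approximation. The tails match a rational-arithmetic enumeration
oracle to 1e-12 for every valid contingency with population size up to
25, and an independent library implementation at study scale. The
one-sided 2x2 Fisher test is exposed as the identical hypergeometric
tail. P-values are kept at full precision and displayed at two
significant figures; 0.05 is presentation metadata, never a hard filter
inside the engine. Raw p-values are reported across the enrichment
battery; a Benjamini–Hochberg column is available opt-in.

**DE conservation null.** For each species, `p_s` is the fraction of
conserved families containing at least one DEG of that species and
`p_f = 1 - p_s`. Under independence, the probability that one family is
DE in all species is the product of the `p_s` values (`p_s4`), and in no
species the product of the `p_f` values (`p_f4`). Observed counts of
all-species and no-species families are compared to `p_s4*N` and
`p_f4*N` with a two-cell chi-square goodness-of-fit (df = 1, no
continuity correction, mirroring R's `chisq.test(x, p)` so parity with an
R session is checkable).

**Regulation categories.** Families with at least two DEGs in the chosen
scope are classified `up` (all DEGs up-regulated), `down` (all down), or
`down_and_up` (both signs); fewer than two DEGs is `not_applicable`. The
scope may pool all species or restrict to one species or a phenotype
group; the classification scope is recorded per analysis because the
across-species and within-species readings answer different questions.

**Selection integration.** Diversifying-selection results arrive as a
per-gene corrected p-value plus a tested flag; a tested gene is
*selected* when p <= `alpha_sel` (default 0.05, inclusive). Denominators
use tested genes only — untested genes are outside both foreground and
background, which is the only convention under which per-species
percentages of the form "selected / tested" reconcile. Three gene-level
designs are provided: DEGs vs all genes (under-representation), genes in
species-specific expanded families vs all genes (over), and DEGs in
expanded families vs all DEGs (over). A family-level variant counts a
family as a success when at least one group DEG is selected and as
sampled when at least one group DEG was tested; its published form mixes
a family-count numerator with a gene-level background, so the output
carries both counting conventions side by side rather than resolving the
ambiguity.

**GO over-representation.** A family's annotation is the union of its
member genes' GO terms across all species. Terms are opaque ids; no DAG
propagation or decorrelation-style weighting is applied — a flat
term-by-term Fisher/hypergeometric test against the Conserved Set, with a
term `reported` when p < 0.05 (strict, unlike the inclusive DE/selection
thresholds) and it annotates at least two subset families.

## The synthetic-data generator

The generator produces complete inputs in the exact dialects the readers
consume, plus a truth ledger for recovery scoring. It emulates:

* **Family sizes**: per-species copy numbers are zero-truncated geometric
  with success probability `family_q = 0.85` (mean ~1.18 copies per
  diploid, matching the observed ratio of ~20k genes to ~17.5k conserved
  families per diploid genome); the tetraploid sums two subgenome draws
  (mean ~2.4). A per-species dropout (`missing_rate = 0.05`) creates
  non-conserved families.
* **Planted expansions** per hypothesis, with defaults near the observed
  study proportions (2–9% per species, well under 1% for group
  expansions). Families are assigned to at most one hypothesis
  (disjointly), and focal copy numbers are raised to the smallest value
  satisfying the expansion rule, so planted recall is 1 by construction;
  chance expansions in unplanted families are expected and measured as
  precision < 1.
* **DE with conservation structure.** `de_base_rate` (defaults 0.42,
  0.51, 0.16, 0.40, the observed family-with-DEG frequencies) is the
  per-family per-species probability of containing at least one DEG. Its
  odds are multiplied by `conservation_coupling` (default 2.5) once any
  previously generated species is DE in the family, and by
  `expansion_de_multiplier` (default 1.4, the observed odds ratio is
  ~1.35) in families planted-expanded for that species. The family-level
  rate is converted to a per-gene Bernoulli rate `1-(1-r)^(1/n)`; DE is
  then assigned per gene. This choice makes the family-level DE frequency
  independent of copy number — so null calibration of the expansion-DE
  tests is structurally attainable — while DEG counts still exceed
  family-with-DEG counts, as in real data. A constant per-gene rate
  would instead couple family DE probability to family size and make
  every "null" expansion-DE test anti-conservative by construction.
* **Signed regulation** (`up_fraction = 0.5`; 0.7 for DEGs of a planted
  focal species, emulating the up-bias in candidate families), adjusted
  p-values uniform below/above `alpha_de` with a 10% independent-filtering
  NA rate, and log-fold-change magnitudes from a lognormal — magnitudes
  carry no planted meaning beyond the sign.
* **Selection flags**: 72% of genes tested; base selected rate 9.5%
  (both observed), doubled on DEGs in tolerant-planted-expanded families.
* **GO terms**: Poisson(2) terms per gene from a 40-term vocabulary, with
  one designated term added with probability 0.4 to DEGs of
  candidate-tier families.

What the generator does **not** emulate: sequence evolution, the sampling
distribution of a real DE pipeline (dispersion, library-size effects),
phylogenetic correlation between the species' copy numbers, orthology
inference errors (e.g. polyploid family splitting), or GO-term
correlation along an ontology. Passing tests therefore demonstrate the
pipeline's correctness and calibration under the generative model, not
robustness to orthology or DE-estimation artifacts in real data.

Gene ids encode species and family of origin for debuggability; an id
scrambling test verifies the pipeline never exploits the encoding.
Identical config (seed included) yields byte-identical files.

## Numerical and design choices

* Inclusive thresholds (`<=`) for DE and selection calls; strict `<` for
  the GO reporting filter — each matching its source convention.
* Chi-square without continuity correction (R parity).
* A DEG with log-fold-change exactly 0 is rejected as degenerate rather
  than silently assigned a sign.
* The all-zero 2x2 table returns p = 1 by convention.
* Enrichment universes differ per test by design (whole Conserved Set;
  families DE in >= 1 tolerant species; families DE in both); every
  result row records its universe definition to prevent silent drift.
* `unique_up` is reported in both readings of the minimum-DEG rule
  (`unique_up`, permissive; `unique_up_min2`, requiring >= 2 tolerant
  DEGs) since either is defensible.
* Problem sizes in the shipped analyses and calibration studies: 2,000
  synthetic families for the end-to-end run and the 100-seed null
  calibration, 5,000 for the 100-seed power study of the expansion-DE
  association (multiplier 3). These sizes give stable rates while keeping
  a full calibration sweep inexpensive to re-run.

## Known limitations

* Expansion calls are ratio threshold rules, not birth–death model
  inference; no reconciliation-based duplication dating.
* The polyploid family-splitting artifact (a polyploid's copies landing
  in a separate family, masking shared expansions) is a documented caveat,
  not detected.
* GO enrichment on flat annotations overstates significance for
  correlated terms relative to decorrelating methods.
* The DE-conservation coupling in the generator is sequential in species
  order (each species' odds react to previously generated species); it
  reproduces pairwise conservation but is not an exchangeable joint model.
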