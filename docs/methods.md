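# Methods

## Scope and model

The package implements a connectivity-map style in-silico screen: given a
touchstone of perturbagen signatures (per-gene differential-expression
z-scores, one column per perturbagen per cell line), rank compounds by how
many genetic longevity interventions they transcriptionally mimic.  The
screening procedure itself — query construction, the >90 summary-score
cutoff, the drug-target concordance filter, and the tally-based dense
ranking — follows the published screen design.  The scoring chain beneath
it is not printed anywhere in that design (the original scores came from a
hosted platform), so this package fixes each step to the published
Connectivity Map convention and treats the chain as an exact, reproducible
contract:

* **Enrichment score.** A signed KS running-sum statistic on the z-ranked
  gene list.  Hit increments are proportional to |z| with weight exponent 1
  (an unweighted 1/|set| mode is kept for oracle testing); miss decrements
  are 1/(N − |set|); the score is the extremum of largest magnitude, sign
  preserved.  When the positive and negative extrema tie in magnitude
  (possible exactly in unweighted mode, where the walk is rational), the
  positive one is returned; the comparison carries a 1e-12 slack so that
  summation order cannot flip an exact tie.  A signature whose query hits
  carry zero total |z| has no directional evidence and scores 0 — this also
  makes an identically-zero signature score 0 through the whole chain.
* **WTCS.** (ES_up − ES_down)/2 when the two enrichment scores differ in
  sign (or one is zero); 0 when they agree — an up and down set enriched on
  the same side is an incoherent query.
* **NCS.** WTCS divided by the mean same-sign WTCS within one cell line and
  perturbagen type.  Sign stratification keeps extreme opposers from
  deflating mimics, and vice versa.
* **τ (signed percentile).** sign(NCS) · 100 · (fraction of same-sign
  touchstone |NCS| values ≤ |NCS|), stratified by cell line and perturbagen
  type.  The tie rule is inclusive (≤), so a compound queried with its own
  top/bottom genes — necessarily the strict maximum — reaches exactly 100,
  and the reversed query exactly −100.  An exclusive (<) rule is available
  in the configuration for sensitivity analysis, but then a self-query tops
  out just below 100.
* **Summary score.** Per (query, perturbagen), the 67th and 33rd linear
  percentiles of the per-cell-line τ values are computed and the one with
  the larger magnitude returned.  A singleton or constant collection
  returns itself.  The percentile pair is configurable.

Ranking ties anywhere in the chain are broken lexicographically by gene
id, making every output bit-reproducible across platforms.

## Screen semantics

* Queries are built from the intervention's own signature: top-k as the up
  set, bottom-k as the down set, per available cell line (default), or
  from the cross-cell-line mean signature applied uniformly ("consensus"
  mode).  Interventions profiled in no cell line are excluded and logged,
  mirroring the attrition between curated longevity interventions and
  those with usable signatures.
* Query size k defaults to 50 and is configuration-exposed; 25 is used in
  the synthetic benchmarks (with 500-gene universes, k must satisfy
  2k ≤ N).  Published platform practice uses larger sets against ~10k-gene
  spaces; at desk scale the ratio k/N is what matters for the statistic's
  granularity.
* The cutoff applies to the cell-line-consolidated summary score and is
  strict: exactly 90 is not a hit.
* Target concordance: a candidate survives if *any* of the compound's
  annotated target genes has a knockdown perturbagen scoring > cutoff
  against the same intervention; matched targets are recorded per hit.
  Unannotated compounds never survive — by design the screen cannot
  nominate a compound whose mechanism cannot be cross-checked.
* Tallies count interventions actually screened; dense ranking lets tied
  compounds share a rank.  Zero-tally compounds are omitted from the
  ranking unless requested.

## Differential expression and consensus

The quantification rules are implemented exactly as stated: genes are kept
when strictly more than `min_count` (default 2) reads appear in at least
`min_samples` (default 3) samples; logCPM uses a pseudo-count prior of 0.5
(configurable) on both numerator and library size; p-values are corrected
by the Benjamini–Hochberg step-up, implemented directly and verified
against an independent reference implementation.

The per-gene test is a Welch t on logCPM — deliberately simpler than the
TMM-normalized, precision-weighted moderated linear model used upstream of
the published consensus.  The package's contribution is the filtering and
consensus logic; externally produced DE tables (gene, logFC, pvalue,
adj_pvalue) drop into the consensus step unchanged.  Zero-variance genes
receive p = 1 (equal means) or p = 0 (exactly shifted) so set operations
stay total.

Consensus: per tissue, significant genes split by logFC sign under that
tissue's own threshold (strict <; raw p for kidney and brain, adjusted p
for heart by default — both presets are configurable since the upstream
analyses used p<0.01 for enrichment work).  Shared sets are the three-way
intersections per direction; upset counts use exact membership over the 7
non-empty tissue combinations, so a gene up in two tissues and down in the
third lands in the two-tissue "up" cell and in neither shared set.  The
heatmap matrix clamps logFC to ±2, a display contract tested exactly.
Tables need not share identical gene lists: per-tissue expression filtering
means a gene absent from one table was untestable there, and it simply
cannot be significant in that tissue.

## Synthetic data: what it emulates, what it does not

**Signature universes.** Mimicry is planted as correlation in z, not as
gene-set overlap: each planted compound has a latent core profile per cell
line; the compound's signature is the core, and each mimicked
intervention's signature (and, when concordance is planted, the annotated
target's knockdown) is α·core + √(1−α²)·σ·noise.  For a single mimicked
intervention this is distributionally identical to mixing the compound
from the intervention's signature at correlation α; with α = 1 compound,
interventions and target knockdown coincide exactly, which is what the
tally-ceiling benchmark requires.  Background compounds and unplanted
interventions are independent standard normal; half of background
compounds carry annotated targets with independent knockdown signatures so
the concordance filter sees realistic false-positive pressure.  Defaults:
500 genes, 200 background compounds, 25 interventions, the eight core cell
lines, α = 0.9.

Not emulated: landmark-gene inference structure, replicate collapsing,
compound chemistry, realistic gene–gene correlation.  Passing recovery
tests therefore demonstrates that the procedure's statistics behave as
designed under its own assumptions — not that the screen's real-data hit
list is reproduced (that would require the proprietary-scale touchstone
and its annotations).

**Counts.** Negative binomial with log-normal gene means (median 100,
log-sd 1) and gene-wise dispersion uniform on (0.01, 0.16) — biological
coefficients of variation of 0.1–0.4, the standard range for genetically
identical model organisms, which the emulated design (inbred mice,
n = 5–6/group) calls for; a cohort-like dispersion regime would make the
adjusted-p heart threshold unattainable at this n, contradicting the
design being emulated.  Planted effects multiply the treated group mean by
2^±logFC (default |logFC| = 2): 25 shared-up and 25 shared-down genes
across all three tissues plus 50 tissue-specific genes each.  Sample size
defaults to 6 per group.  Not emulated: library-size variation,
gene-length effects, count correlation between tissues from shared
animals.

All randomness derives from one user seed split by named keys (generator,
entity, cell line/tissue), so outputs are byte-stable under a fixed seed
and adding a new sub-generator never perturbs existing draws.

## Numerical and degenerate-input choices

* GCT 1.3 text I/O only; values serialized at full (`repr`) precision so
  write→read round trips are exact.  Missing metadata defaults: cell line
  "default", perturbagen type "compound"; the GCT null sentinels
  (na/NA/-666) are treated as absent.
* Gene identifiers are opaque strings; no symbol/Entrez mapping.
* Percentile interpolation is linear (numpy default); the consolidation
  percentiles (33, 67) are configurable.
* `ncs` with no same-sign reference returns 0 with a warning rather than
  failing a whole screen.
* Benchmarks are sized to run on a single CPU in seconds to a few minutes:
  500-gene, ~200-compound universes for screen recovery; 2000-gene,
  6-per-group counts for DE calibration; 50 small universes for the
  cutoff-monotonicity property.

## Known limitations

* The real screen's headline numbers (thousands of compounds, hundreds of
  hits, a specific top compound) are not reproducible here: they depend on
  a proprietary-scale signature service, its 2017 drug-target annotations,
  and server-side scoring whose exact consolidation is not public.  The
  package reproduces the *procedure* and validates it on planted truth.
* The Welch-t stand-in is less powerful than a moderated model at n = 5–6;
  with real data, users should import DE tables from a dedicated tool and
  use only the filter/consensus stages.
* The target-concordance filter needs a reasonably large knockdown
  reference per cell line; in very small universes τ becomes coarse
  (percentile steps of 1/n_knockdowns) and the filter is conservative.
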