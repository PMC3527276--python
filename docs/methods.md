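# Methods

## Screen model

The simulator represents a pooled dropout screen in an isogenic pair as a
branching process observed through multinomial sequencing.  Each shRNA *i*
carries a genotype-specific selection coefficient *s*<sub>*i*,*g*</sub> ∈ [0, 1]
(fractional reduction of the growth rate), and its expected cell count grows
as

  n<sub>i</sub>(t) = n<sub>i</sub>(0) · 2^(r (1 − s<sub>i,g</sub>) t),

with *r* the doubling rate (default 1 doubling/day) and *t* in days.  Gene
classes are drawn independently per gene — synthetic-lethal with the p53
deletion (s only in p53−), essential in both lines (same s in both), or
neutral — and all shRNAs of a gene share the class.  This gives the closed
form used throughout testing: between two sampling times Δt apart, an
affected shRNA's frequency falls 2^(r·s·Δt)-fold relative to neutral shRNAs.

Sampling layers, in order:

- **Initial representation.** Per-shRNA log-normal weights (σ = 0.5) model
  unequal library representation; the transduced population (10⁶ plated
  cells × 75% transduction at MOI 1) is a single multinomial over those
  weights.  Per-cell Poisson MOI bookkeeping is deliberately folded into
  this draw: only relative shRNA abundance reaches the sequencer.
- **Growth and passaging.** Growth is deterministic in expectation between
  events; 4-fold dilution passages are binomial thinning with keep
  probability 0.25 on days 3, 6 and 9.  The protocol fixes only "4-fold
  dilutions for 10 days", not the schedule; an every-third-day schedule is
  this package's declared choice.  In expectation mode the thinning is a
  scalar factor and cancels on normalization.
- **Sequencing.** Each sample (genotype × {T0 = 40 h, T10 = day 10}) is one
  multinomial draw of `depth_per_sample` reads over current abundances, so
  column sums are conserved exactly.  An optional Dirichlet-multinomial
  overdispersion knob (default off) stands in for PCR jackpotting.
- **Reads.** Fixed layout: positions 1–6 the 5′ vector flank, 7–27 the
  21-nt core, 28–33 the 3′ flank ("position 28" being the 1-based start of
  the 3′ flank forces 6 + 21).  Per-base substitution errors are i.i.d.
  uniform over the three other bases; quality lines are constant and never
  read.

What the simulator does **not** emulate: PCR chimeras, index hopping,
read-length variation, position-dependent error profiles, shRNA efficacy
variation within a gene, replicate structure (the screen design has none).
Passing tests therefore demonstrate correctness of the analysis under
multinomial-plus-bottleneck noise, not robustness to those artefacts.

## Library construction

Simulated cores are uniform random 21-mers accepted only at pairwise
Hamming distance ≥ 5, which makes ≤ 2-mismatch assignment provably
unambiguous (a read with ≤ 2 core errors is at distance ≥ 3 from every
other core).  Random 21-mers are essentially never that close, so rejection
sampling is cheap; a bounded attempt budget turns pathological requests
into an error.  Real libraries do not guarantee this separation — with real
data, ambiguous assignments are expected and are counted and excluded
rather than guessed.

## Read extraction

Flank anchors must match exactly by default; whether the original pipeline
tolerated flank mismatches is unknowable from its description, so the
strictest reading is the default and a `flank_max_mismatch` switch exposes
the alternative.  Core assignment computes the Hamming distance to every
library core and assigns on a unique minimum ≤ `max_mismatch` (default 2);
tied minima are "ambiguous" and discarded, mirroring standard multi-mapper
exclusion.  Genome alignment is replaced by direct library matching: the
informative sequence *is* a library core, and direct matching makes the
mismatch behaviour exactly specifiable.  Implementation detail: reads are
deduplicated by core before the distance scan, which also makes
order-invariance structural.

## Exact statistics

The 2×2 table for shRNA *i* in one genotype is (a, b; c, d) = (reads of *i*
at T0, all other assigned T0 reads; same at T10).  The "rest of library"
complement is the standard per-feature construction and the only one
available from the described data.

- **Fisher p.** Two-sided by the point-probability rule: sum of all
  hypergeometric outcomes with probability ≤ (1 + 10⁻⁷) × the observed
  probability.  The 10⁻⁷ relative slack matches R's `fisher.test`, which
  the original analysis used; probabilities are computed from `gammaln` in
  log space.
- **Conditional-MLE odds ratio.** Under the noncentral hypergeometric law
  the score equation is E<sub>ψ</sub>[A] = a.  E is strictly increasing in
  ψ, so the root is found by Brent's method on log ψ with geometric bracket
  expansion (|log ψ| ≤ 700, xtol 10⁻¹²; the expectation-equation residual
  on the acceptance grid is < 10⁻¹²).  Support-boundary observations give 0
  or +∞ by the likelihood limit; a single-point support (shRNA absent from
  both samples) leaves ψ unidentifiable and returns OR = 1 with CI (0, ∞).
- **Exact CI.** Tail inversion at level 1 − α: the upper endpoint solves
  P<sub>ψ</sub>(A ≤ a) = α/2, the lower P<sub>ψ</sub>(A ≥ a) = α/2, each by
  the same bracketed root-finding on log ψ with log-space tail sums.
  Endpoints always bracket the CMLE.
- **Fold depletion.** Computed on assigned-read *frequencies*,
  ((a + pc)/N_T0) / ((c + pc)/N_T10), with a Haldane-style pseudocount
  pc = 0.5 for display and thresholding only — exact tests always use raw
  counts.  Frequencies rather than raw counts are used because sample
  depths differ; true dropouts with c = 0 are expected and stay finite.
- **BH adjustment.** Step-up with running minimum, applied separately
  within each genotype (two families of m = library size), since the
  decision rule quotes adjusted p-values per cell line.

## Hit calling

is_hit ⇔ (p_adj⁻ < 0.01) ∧ (fold⁻ ≥ 4) ∧ ((fold⁺ ≤ 2) ∨ (p_adj⁺ ≥ 0.01)).

The escape clause is attached to the p53+ condition only: the p53− side
explicitly requires significance, so the only coherent reading lets a
non-significant p53+ change rescue an shRNA whose p53+ point estimate
exceeds 2-fold.  "Depleted" for category purposes means fold ≥ 4 with
adjusted p < α in that genotype; the three volcano categories plus OTHER
partition all shRNAs, and broadly essential shRNAs (depleted in both lines)
can never be hits — the p53+ guard excludes them by construction.  A gene
is a hit with ≥ 1 hit shRNA; requiring multi-shRNA concordance is stricter
than the reported gene mapping, so the ≥ 1 rule is the default and the
aggregation count is exposed for stricter post-filtering.

## Numerical and design choices

- Thresholds default to the published rule (4, 2, 0.01, 2 mismatches, 95%).
- All sequence positions are 1-based inclusive in documentation; Python
  slices internally.
- Library TSVs carry the flank anchors as `#flank5`/`#flank3` metadata
  lines so serialization round-trips the full library object; external
  tables without metadata require explicit flanks.
- Volcano encoding caps |log₂ fold| at 16 and −log₁₀ p_adj at 300 for
  plotting only; caps never feed back into calling.
- One master seed is split via `numpy` `SeedSequence.spawn` into per-stage
  generators, making every artifact byte-reproducible.
- Reference problem sizes (200 genes × 2 shRNAs, 200,000 reads/sample,
  ~5,000-table oracle grid at N ≤ 60) were chosen as the smallest screen
  that keeps per-shRNA T0 counts near the real screen's coverage regime
  (~500×) while remaining desk-scale.

## Known limitations

- Depletion-only framing: the two-sided test covers enrichment, but no
  enrichment-side hit rule is provided.
- No replicate-aware or dispersion-modelling inference (MAGeCK/edgeR
  style); with a single sample per condition the exact conditional test is
  the appropriate tool, but it treats sequencing as the only noise source —
  bottleneck-induced overdispersion slightly inflates significance at very
  high depth.
- Indels in the core or flanks are not modelled and not matched.
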