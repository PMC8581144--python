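# Methods

## Dose–survival: the single-hit multitarget model

Survival of seeds after acute irradiation is modelled as
`S(D) = 1 − (1 − e^(−D/D0))^m`, the classical multitarget form in which a
cell dies once all of `m` targets have been hit and `D0` is the dose
reducing survival to 1/e on the exponential limb. The model produces the
characteristic low-dose shoulder when `m > 1`; its two standard summaries
are the shoulder dose `Dq = D0·ln m` and `LD50 = −D0·ln(1 − 0.5^(1/m))`
(the closed-form root of `S(D) = 0.5`).

**Fitting.** Replicate counts are averaged to one survival fraction per
dose (an option weights by replicate size) and (D0, m) minimise the
residual sum of squares on the linear survival-fraction scale. The
optimiser is a coarse grid (D0 over [max dose/20, max dose] in 50 steps, m
log-spaced over [1, 1000] in 20 steps) followed by bounded
`scipy.optimize.least_squares` refinement at tight tolerances; on
noiseless model data the round trip is exact to a relative error below
1e-6. The classical semilog alternative — a straight-line fit of log
survival on the terminal limb whose slope gives D0 and back-extrapolated
intercept gives m — is available as `method="semilog"` but is not the
default because it depends on which doses happen to fall on the limb.
A fit refuses data without at least three distinct doses, one fraction
above 0.8 and one below 0.5: outside those conditions the shoulder and the
limb are not both sampled and (D0, m) are not identifiable.

**Identifiability under counting noise.** At the assay's own scale
(4 replicates × 50 seeds per dose) the binomial noise on each fraction is
about 0.035, which leaves `m` weakly identified: across seeds, truth
errors on `m` reach 10–15% on any realistic dose grid while the summary
doses Dq and LD50 stay within a few percent. The test suite therefore
checks the optimiser against an exhaustive grid-search oracle on the same
noisy data (agreement in RSS and argmin) and requires truth recovery only
for Dq and LD50, within 10%.

**Inversion of printed summaries.** `solve_from_dq_ld50` uses that
`LD50/Dq = −ln(1 − 0.5^(1/m))/ln m` depends on m alone and is strictly
decreasing from +∞ (m→1) toward 1, so a bracketed Brent search on
m ∈ [1.0001, 1000] is guaranteed to find the unique solution when the
ratio is attainable; `D0 = Dq/ln m` follows. Ratios at or below the
m = 1000 limit (≈1.053) are rejected as inconsistent.

## The threshold-burden model

The model formalises the observation that pushing dose above the shoulder
keeps killing plants without proportionally raising the mutation load of
the survivors. Assumptions:

* per-individual mutation burden at dose D is lognormal with linear-scale
  mean `κ·D` (no saturation term) and constant coefficient of variation
  `cv`; the lognormal parameters are `σ² = ln(1 + cv²)`,
  `μ(D) = ln(κD) − σ²/2`, so the mean is exactly `κ·D`;
* survival is a sharp threshold: an individual survives iff its burden is
  below `T` (mutations per genome). Survival probability is the CDF at `T`
  and the survivor mean burden is the left-truncated mean
  `E[X | X<T] = E[X]·Φ((ln T − μ − σ²)/σ)/Φ((ln T − μ)/σ)`, always below
  `T` and non-decreasing in dose.

A gamma family with the same (mean, cv) parameterisation is available
behind `family="gamma"` (truncated mean via regularised incomplete-gamma
ratios); the lognormal is the default because the right-skewed shape
matches the verbal model and the truncated mean is closed-form.

**Calibration.** Survival under this family depends only on σ and the
ratio `T/κ`, so matching survival at two anchor doses (the multitarget
survival at Dq, and 0.5 at LD50) determines σ — and hence cv — together
with `T/κ`, leaving the burden scale κ as the genuinely free parameter.
`calibrate` therefore takes κ from the user (default 0.08 mutations per
genome per Gy, which puts burdens in the tens of mutations at 500–1000 Gy,
the scale observed by whole-genome sequencing of survivors) and solves cv
and T. For the proton-calibrated curve this yields cv ≈ 0.72 and T ≈ 68
mutations/genome.

**Dose-efficiency curve.** For a dose ladder the toolkit tabulates
survival, survivor mean burden, and the incremental gain ratio
`Δburden/Δ(−survival)` between consecutive doses. A zero survival drop
leaves the ratio NaN rather than raising, so flat low-dose segments are
representable. The qualitative signature the model reproduces: the gain
ratio across the shoulder→LD50 step is smaller than across the
sub-shoulder→shoulder step.

## Mutation-spectrum classification

* **Zygosity**: mutant-read fraction ≥ 0.80 → homozygous; in [0.25, 0.80)
  → heterozygous; below 0.25 → not called. Boundaries are inclusive
  exactly as stated by the calling protocol.
* **InDel junction context**: homopolymer when the InDel allele plus
  adjacent flank bases form a single-base run ≥ 3 bp; else polynucleotide
  repeat when a tandem run (unit 2–6 bp, ≥ 2 full copies, i.e. any
  periodic window of length ≥ 2×unit) covers the allele with at least one
  full unit remaining in the flanks; homopolymer takes precedence. The
  run length, unit range and flank window (10 bp) are keyword knobs since
  no community-standard definition exists.
* **Consequences** assume single-transcript gene models with 1-based
  inclusive CDS intervals; SBSs are classified by translating the affected
  codon before and after (start loss for any change in codon 1), InDels
  by length mod 3, and InDels must lie wholly inside the CDS. Splice and
  UTR effects are out of scope. VCF-style anchored alleles are accepted
  and left-normalised on ingest when the genome is supplied.
* **Frequencies** are count/(genome length × individuals); the CDS-specific
  rate divides CDS-overlapping counts by total CDS length. No attempt is
  made to reproduce per-sample frequencies published on other
  normalisations.

## SV junction anatomy

The analyzer treats each junction as a pair (left source A, right source
B) of reference-derived sequences joined in the product: for an inversion,
junction 1 joins the prefix to the reverse-complemented segment and
junction 2 joins that segment to the suffix (located via a unique 20-mer
anchor inside the inverted segment); deletions, tandem duplications and
translocation-style joins contribute one junction. Steps:

1. maximal exact extension of A along the product from the left and of B
   from the right (each must cover ≥ 20 bp, else the product is declared
   inconsistent with the hypothesis; anchors aligning at several places
   raise an ambiguity error listing candidates);
2. reference-level microhomology `L` = longest suffix of A equal to a
   prefix of B (a 1 bp overlap is treated as none — uninformative);
3. missing-base attribution. With `missA`/`missB` the unmatched base
   counts at the junction-facing ends of A and B, the on-tract deletion is
   `min(missA, missB, L)`, the remaining microhomology is `L` minus that,
   and adjacent deletions are `max(0, miss − L)` per side. When both
   direct extensions lose contact with the tract but the product carries a
   junction island equal to part of the tract, the island is recognised as
   retained microhomology rather than an insertion. Unattributable product
   bases are reported as insertion.

These closed-form attributions are exact when the flanks are repeat-free,
which the synthetic generator guarantees by rejection sampling (the
screening uses only string primitives — common-prefix/suffix lengths and
the junction-overlap scan — not the analyzer's interpretive rules, so
round-trip tests remain meaningful). On real amplicons with repeated
flanks the analyzer errors rather than guessing, mirroring what manual
curation would flag. Nominal breakpoints are trusted as exact; deletions
are measured relative to them.

**Classes and mechanisms.** Classes: A (no microhomology), B
(microhomology, no deletion), C (microhomology with deletions, adjacent
ones ≤ 10 bp), D (microhomology with adjacent deletion > 10 bp).
Mechanism: microhomology with zero adjacent deletion → cNHEJ-MH (breaks on
or at the tract ends; deletions confined to the tract do not implicate
MMEJ, because MMEJ resects the region between break and tract); adjacent
deletion > 10 bp beside a tract → MMEJ candidate; everything else → cNHEJ.
The 10 bp cut-off follows the convention separating the small InDels of
classical end joining from resection-driven repair. In the group
tabulation, insertions at microhomology-bearing junctions count as "on
overlap", others as "adjacent"; percentages are integers of the group's
inversion total.

## Summary-table accounting

Phenotypic mutation rates are `100·mutants/lines` rounded half-up to two
decimals; fragment sizes are `|pos2 − pos1|` in kb to one decimal;
junction-table percentages round to integers (all inferred from the
printed tables' precision, implemented with decimal half-up rounding).
An event is one junction-forming rearrangement; a process groups events
arising in one break-repair episode (paired inversions share a process
id). A three-breakpoint interchromosomal duplication is stored as a single
event carrying its extra breakpoint, which is what makes the bundled table
reconcile: 41 events, 39 processes, 23 inversions, 10 homozygous events.
Fragment-size validation warns instead of failing, because three printed
rows of the bundled table disagree with their own breakpoints by more than
the 0.1 kb rounding tolerance; the validator surfaces exactly those rows.
Impact totals: moderate = missense + in-frame InDels; high = start loss +
premature stop + frameshift + truncation + complete deletion; the
SV-exclusive high total omits the last two (SV-driven) categories. Group
statistics are mean ± SE (ddof = 1, ≥ 2 samples required). No statistical
re-testing of group differences is attempted: per-individual data behind
the published ANOVA/t-tests are not available.

## Synthetic data: what it emulates and what it does not

Defaults mirror the reference assay: the proton dose grid (113.7–1188.4
Gy) with 4 × 50 seeds per dose and a survival curve near the
proton-consistent parameters (D0 = 631, m = 3.3); sequencing depth 40×
with binomial read-fraction noise and no overdispersion; an SBS share of
0.68, deletions outnumbering insertions 4:1, 65% homozygous sites;
junction classes mixed (A, B, C, D) = (3, 12, 6, 4) per 25 inversions with
microhomology 2–23 bp, small deletions on or next to the tract, and
adjacent deletions up to 61 bp. Genomes are i.i.d. base draws at a
configurable GC (default 0.36) carrying non-overlapping single-exon genes
(ATG, in-frame, stop). Test problem sizes (60–150 kb genomes, 150–1000
variants, up to 500 junction cases) keep the full suite in a few seconds.

Not emulated: real genome composition (repeats, gene structure,
methylation context), mapping and calling artefacts, overdispersed
coverage, multi-exon genes in the generator (the classifier supports
them), and complex multi-event rearrangements. Passing tests therefore
demonstrate correctness of the analysis logic under the stated generative
assumptions, not robustness to raw-data artefacts upstream of variant
calling.

## Numerical choices

Rounding of table-facing numbers uses decimal half-up (banker's rounding
would drop printed ties). Root finding uses Brent's method on provably
monotone functions with explicit brackets. The lognormal truncated mean is
evaluated via normal CDFs rather than sampling; survival probabilities of
exactly 0 raise a "no survivors" error instead of returning NaN. The fit
constrains m to [1, 1000]; survival fractions of exactly 0 or 1 are
retained (linear scale needs no transform). Seeds enter through
`numpy.random.default_rng` with per-stream derivation so each generator
output is independently reproducible.
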