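# Methods

## Classification rules

Each protein-level alteration is parsed from HGVS p. notation (one- or
three-letter codes; substitutions, in-frame del/ins/delins/dup,
nonsense, frameshift, synonymous) and classified by ordered rules:
hotspot first (missense at residue 219 with alternate C or S → class 2),
then missense/in-frame events by position relative to the forkhead
domain (168–269) and its Wing2 region (247–269): 1A inside FKH before
Wing2, 1B inside Wing2, 1C outside FKH; then truncating events split at
the FKH end (3A ≤ 269, 3B ≥ 270); amplification (≥ 6 copies) is class 4.
Synonymous changes are not alterations. The rule order matters only for
the hotspot: the remaining intervals partition the residue axis, which
the test suite verifies by exhaustive sweep against a flat truth table.

Deliberate choices where the schema leaves room:

- **Indels spanning a boundary** classify by their anchor (lowest
  affected) residue, matching lollipop-plot convention; an `overlap`
  policy instead pulls any indel touching Wing2 into 1B.
- **R219 events other than C/S substitutions** are *not* class 2:
  R219H is 1A, and in-frame indels touching 219 are 1A.
- **Splice variants** count as predicted truncating (class 3) anchored
  at the nearest affected codon; a policy flag excludes them.
- **A stop at residue 269 exactly** is 3A (the boundary is inclusive).
- **Wing2 start**: the domain literature sometimes places Wing2 at
  residue 248; this schema uses 247 for class 1B, and the boundary is a
  single configurable field (`DomainModel.wing2_start`).
- **Sample-level label** under multiple alterations: precedence
  2 > 1B > 1A > 3A > 3B > 1C > 4 > WT (rarest / most prognostically
  extreme first), configurable, since any single-label summary of a
  multi-altered sample is a convention.
- **Protein length** defaults to 472 (the canonical FOXA1 isoform) but
  follows a supplied reference sequence when one is given.

## Claims-based survival

Vital status is inferred, not observed: a patient whose last claim
precedes the data cutoff by strictly more than `gap_days` (default 100)
is presumed dead at the last-claim date; otherwise censored at last
contact. A gap of exactly 100 days censors. Overall survival runs from
the first start of the requested treatment category ("any" = earliest
treatment start) to the terminal date; non-positive follow-up drops the
record with a warning. Castration state: therapies starting ≤ 90 days
after the first first-line ADT are hormone-sensitive, strictly later
starts castration-resistant, and patients without an ADT reference are
`unknown`. Contrasts are two-arm Cox fits (single binary covariate,
Efron tie handling — lifelines' default) with 95% Wald CIs on the log-HR
and log-rank p values; an arm with zero events yields a flagged
non-convergent estimate. Subgroup analyses (site, castration state) are
row filters over the record table, not separate code paths.
Multivariable adjustment and competing risks are out of scope.

## Enrichment testing

Each binary feature forms a 2×2 table against the WT arm: Fisher's exact
test when any expected cell count is < 5, else χ² (continuity correction
on by default, configurable). Odds ratios use the raw counts with a
Haldane–Anscombe 0.5 correction only when a cell is zero. BH adjustment
runs across all features within one class comparison (one family per
class panel); cross-class pooling is deliberately avoided. Race analyses
exclude uncharacterised patients and test each class's prevalence in
each race against the European-American reference through the same 2×2
machinery. All tests are two-sided.

## Expression and signatures

Numeric-by-class comparisons are two-sided Mann–Whitney tests vs WT with
per-class median/IQR summaries and BH q across classes; arms under 3
samples are flagged untestable. The rank basis makes results invariant
under monotone transforms of the values. Signature scores are the mean
over the gene set of per-gene z-scores of log2(TPM+1), z computed across
samples; constant genes contribute 0, absent genes are dropped with a
warning. Gene lists ship as editable configuration (small placeholder
AR / NEPC / IFNγ / T-cell-inflammation sets) because published signature
memberships vary by source; scores are invariant to per-gene affine
rescaling of log-expression by construction.

## Missense tolerance ratio

Expected missense fractions come from exhaustively classifying the 9
single-nucleotide changes of every codon under the standard genetic code
(missense + synonymous + nonsense = 9 per coding codon; nonsense changes
are excluded from both numerator and denominator). The MTR at a residue
is the observed missense fraction over the expected fraction within a
centred window of 31 codons (configurable, truncated at the termini);
windows with no observed variants have undefined MTR. Per-residue
deviations use the two-sided exact binomial test (minimum-likelihood
method; a one-sided intolerance scan is available) with BH adjustment
across residues, and gene-specific 5th/25th/50th percentile lines are
computed over defined-MTR residues. Population-scale calibration with
trinucleotide mutation-rate weights is out of scope.

## Synthetic cohort generator

The generator emulates a large prostate-cancer registry cohort so the
pipeline's statistical behaviour can be measured against known truth.

- **Classes.** Race is drawn first (74.7% EA, 17.3% AF, 3.0% AP, 5%
  other), then class conditional on race. Baseline prevalences encode a
  ~16% overall alteration rate with 1B the most prevalent subclass and
  the hotspot class 2 the rarest (~0.5%): 1A 2.0%, 1B 7.0%, 1C 1.8%,
  2 0.5%, 3A 1.7%, 3B 1.1%, 4 1.8%. The within-class split is
  approximate configuration, not a fidelity claim. Race tilts raise 1B
  to 17.5% and 3A to 3.2% in AP patients and 1C to 3.2% in AF patients.
- **Variants.** Each altered sample receives an HGVS string drawn
  uniformly from its class's legal residue region and effect set, so
  re-classification recovers the generating class by construction
  (verified as a round-trip property at n = 5,000). VUS decoys are
  sprinkled over ~5% of patients to exercise the pathogenicity filter.
- **Survival.** Weibull baseline, shape 1.2, WT median 36 months
  (typical of advanced prostate-cancer cohorts), with proportional
  per-class hazards. Default hazard ratios encode the published
  all-tumors forest effects where stated — class 2 at 2.05, 3A at 0.70,
  3B at 1.50 — and modest placeholder values elsewhere (1A 0.85, 1B
  0.90, 1C 1.10, 4 1.15).
- **Claims.** Enrollment (first treatment) is uniform over 2 years;
  claims arrive at geometric gaps with mean 30 days, stop at death, and
  otherwise continue to the data cutoff at 12 years; ~2% of patients
  lose contact as an independent process. The long run-out keeps deaths
  inside the terminal 100-day blind window below ~1%, so the claim-gap
  rule recovers ≥ 99% of true vital statuses — a designed property,
  verified as a test. 85% of patients start first-line ADT at
  enrollment; ARSI (50%) and taxane (30%) starts follow at exponential
  delays, producing both hormone-sensitive and castration-resistant
  starts under the 90-day rule.
- **Features/expression.** Class-conditional probabilities follow the
  published contrasts: ERG fusion 34.5% in WT vs ~0 in 1B/2; TP53 35.8%
  WT vs 20.4% in 1B; MSI-high 3.3% WT vs 13.1% (1C) and 15.5% (3B);
  TMB-high 3.4% WT vs 12.1% (1C) and 19.0% (3B); one third of class 2
  samples are histologic NEPC. TMB values are drawn consistently with
  the ≥ 10 mut/Mb flag. The TPM matrix (log-normal, small gene panel)
  overexpresses FOXA1 in the activating classes and gives class 2 the
  neuroendocrine shift (NEPC genes up, AR programme down).
- **Null mode** zeroes every class effect (shared hazard, WT feature
  rates, no tilts, no expression shifts) for type-I-error calibration.

What the generator does **not** emulate: assay coverage and panel
composition, mutation signatures, multi-sample patients, correlated
comorbidity structure in claims, or calendar-time treatment-policy
drift. Passing tests therefore demonstrate that the statistical
machinery is correct and calibrated under the assumed data-generating
process, not that the published cohort estimates would be reproduced on
real registry data (which are not publicly available).

## Problem sizes and numerical choices

The test suite exercises the full pipeline at n = 5,000 (one seed) for
round-trip and hazard-ratio recovery (point estimates within 3 SE of the
generating values), 500 replicates at n = 200 for null log-rank
calibration (rejection rate in a 3σ binomial band around 5%), 25
replicates at n = 2,000 for race-enrichment power, and a ~470-codon
synthetic gene with 3,000 neutral variants for MTR calibration — sizes
chosen to make the checks statistically meaningful while keeping the
default run fast. Ties in the Cox model use Efron's method; CIs are
Wald on the log scale; the Fisher/χ² switch and BH families are as
above; dates are integer day offsets in the generator and ISO-8601 or
numeric in input files (both accepted). Known limitations: death dates
are imputed at the last-claim date (a backward-recurrence
underestimate of ~half a claim gap, common to both arms of any
contrast); patients dying almost immediately after treatment start drop
out of the record table (≈1% left truncation); and single-seed hazard
ratios for a 0.5%-prevalence class carry log-scale standard errors
around 0.2.
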