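# Methods

## Scope and model

`eggscreen` implements the validation scheme appropriate for qualitative /
semiquantitative screening methods: instead of trueness, precision and
linearity, it assesses — per analyte and per MRM transition — whether the
method detects the level of interest with a bounded false-negative rate,
using many blank and spiked samples.  The package also implements the
application of a validated method to study samples (identification,
positivity, compliance against a batch positive control), and generators
that emulate the instrument data and the animal-study data the pipeline
consumes.  Raw mass-spectral processing is out of scope: the pipeline
takes already-integrated responses and window noise as input, as opaque
area-unit values (whether a lab records noise as peak height or integrated
area does not matter to the calculus, which never mixes the two scales).

## Statistical core

All thresholds use the multiplier `k = 1.64` exactly (the one-sided normal
95% quantile to two decimals, as conventionally printed in this scheme,
not 1.645).  Standard deviations use the n−1 denominator: the 20 blanks
and 60 spiked replicates are treated as samples from the blank and spiked
populations.

- `T = B + k·SD_B` over the noise of the blank design (default n = 20).
- `Fc = M_an − k·SD_an` over spiked responses pooled across the three
  validation days (default n = 60) with no day-effect correction — the
  defining equation uses a single mean and SD over the pooled set.
  A negative `Fc` (possible at very low signal) is reported as-is with a
  `negative_fc` flag; clamping to zero would silently alter sensitivity.
- `LOD = 3·B·C/M_an`, with `C` the analyte's validation level (the only
  spike concentration in the design) and `M_an` the mean spiked response
  of the transition being reported, over the first day's 20 replicates —
  the 20-sample mean the LOD definition refers to.  Sensitivity uses the
  same first-day replicates against the pooled `Fc`.
- CCβ verdict: `below_level` iff `Fc > T`.  With normally distributed
  spiked responses the population cut-off `μ − 1.64σ` misses a fraction
  Φ(−1.64) ≈ 5.05% of truly contaminated samples; `Fc > T` therefore
  certifies a false-negative rate of *about* 5% (slightly above the nominal
  5% — the Monte-Carlo property test pins the exact tail), and `Fc ≤ T`
  means positivity against `T` would miss more than that.
- Ties are resolved in the consumer-protective direction: a response
  exactly at `Fc` counts as detected, and `Fc = T` yields `above_level`.
- Sensitivity is reported per transition against that transition's `Fc`.

## Identification and compliance

Identification requires S/N > 3 on both monitored transitions, the major
transition's retention time within ±2.5% (relative) of the expected RT,
and the minor/major response ratio within a tiered relative tolerance of
the reference relative intensity: ±20% when the reference exceeds 50% of
the major response, ±25% for 20–50%, ±30% for 10–20%, ±50% at or below
10%.  The tiers and the RT window follow the usual screening
identification-criteria convention and are configurable.  (The regulatory
decision that codifies these criteria is cited inconsistently in parts of
the surrounding literature — 2002/675/EC vs 2002/657/EC; the
implementation follows the criteria as described, not the citation.)

Positivity requires identification plus a major-transition response at or
above `Fc`.  Compliance is semiquantitative: a positive sample reading
*strictly above* the mean major-transition response of the batch positive
control (spiked at 0.75×`C_val`) is noncompliant; a sample exactly at the
control response is compliant, since the control itself sits below the
permitted level.  The number of control replicates per batch is a design
choice (default 2 in the study fixture); the mean is used rather than a
single replicate.  A concentration estimate
(`response × C_control / control response`) is exposed in the call details
but never drives the decision.  The per-sample gating chain — not
identified ⇒ not positive ⇒ not noncompliant — is enforced by the
`ScreeningCall` type itself.

When replicate calls exist for a group and day, the day-level call is the
worst replicate (noncompliant beats compliant beats not-detected) — the
conservative aggregation for a screening purpose.

## Panel

The packaged panel stores the 45 analytes with their MRM transitions,
declustering potentials, collision energies, retention times and reference
relative intensities, plus regulatory status and MRLs.  Level-of-interest
rules: MRL with a combined residue definition (parent + epimer) → 0.75×MRL;
plain MRL → MRL (tylosin is validated at its 200 µg/kg MRL without the
discount); otherwise the family's qualitative screening level
(quinolones/sulfonamides 10, β-lactams/lincosamides 50, macrolides 150,
tetracyclines 300, aminoglycosides 500 µg/kg).  Doxycycline, which has no
MRL of its own, carries an explicit 300 µg/kg override so it is screened
at the tetracycline level; overrides are a first-class panel field.
Where both Codex and EU statuses exist for a family the packaged levels
follow the validation concentrations as used; concentrations are µg/kg
throughout, with no unit-conversion layer.

## Validation simulator

Blanks draw a 0-truncated normal baseline recorded as both apparent
response and window noise (S/N ≈ 1).  Spiked samples draw the major
transition around `spike_mean` (default 40× the noise mean — a comfortably
detectable analyte at its level of interest) with a normal day offset
shared within each day; minor transitions scale by the panel's reference
relative intensity.  An optional interferent models a co-eluting matrix
compound: its peak response adds to the blank trace (in a blank it is the
only signal in the window) and a fraction (default 0.25) of it to the
recorded window noise of blanks and spiked samples.  Through the
blank-noise route it inflates `T` without touching `Fc`, reproducing the
single-transition validation failure caused by a co-eluting interferent,
while remaining visible to the selectivity check (S/N ≈ 4 in blanks).
All generators are deterministic under a fixed seed.

What the simulator does *not* emulate: matrix suppression/enhancement
varying between samples, heteroscedastic noise, retention-time drift, or
correlated transition responses.  Passing tests therefore demonstrate the
correctness of the calculus and classifier logic under the stated design,
not the performance of any real instrument method.

## Depletion model

The egg-residue generator is a deliberately minimal linear deposition
model — the physiology it reflects is qualitative (plasma kinetics,
albumen deposited over a few hours from freshly secreted protein, yolk
growing exponentially over a ~10-day window), and no published
concentration series exists to fit, so the model form and parameters are
artifact decisions:

- plasma: `p(t) = p(t−1)·e^(−k_el) + F·dose(t)` (first-order accumulation
  during the 5 dosing days, exponential washout after);
- albumen of the egg laid on day *t*: `∝ p(t−1)`;
- yolk: a weighted sum of plasma over the preceding 10 days with weights
  `w_j ∝ e^(g·j)` increasing toward lay — `g` is an *effective* deposition
  rate that absorbs both yolk growth and drug-specific deposition
  kinetics, which is why it varies per drug;
- whole egg: yolk fraction 0.36 (an average hen egg), the rest albumen;
  optional unit-mean lognormal noise.

The model is linear in dose and in the partition coefficients, plasma is
strictly decreasing after dosing stops, and the egg series decays to zero
— all property-tested.

The packaged per-drug defaults are **calibrated fixtures**: the feeding
study they emulate reports, per drug, only how many days after the end of
treatment residues stayed above the positive-control level (enrofloxacin
9, its metabolite ciprofloxacin 6, doxycycline 4, lincomycin 1,
oxytetracycline never above 225 µg/kg, neomycin — essentially not absorbed
from the gut — never detected).  Elimination rates, partitions and `g`
were chosen so the noise-free curves cross their thresholds on exactly
those days with ≥ ~4σ margin relative to the 5% replicate noise, and the
qualitative compartment assignment matches each drug's known disposition
(fluoroquinolones yolk-dominant, protein-bound lincomycin
albumen-dominant, lipophilic doxycycline high in both, oxytetracycline
poorly absorbed).  The timeline tests guard the simulator + classifier
contract; they are not an independent pharmacokinetic prediction, and the
per-day concentrations themselves validate against nothing.

The study fixture converts concentrations to responses with one linear
factor per drug (scaled so the positive control reads ~1000 area units
over a baseline of ~2), adds per-replicate lognormal concentration noise
(CV 5%) and baseline instrument noise, and emits day 0 as the
pre-treatment collection, 6 study replicates per group per day and 2
positive-control replicates per batch.

## Problem sizes and numerics

Default test and acceptance runs use the design sizes themselves (20
blanks, 60 spiked, 16-day studies with 6 replicates); Monte-Carlo
properties use 10⁵ draws, where the Φ(−1.64) tail is reproduced to ±0.005.
LODs below 1 µg/kg are rendered as `<1` in formatted reports (matching the
conventional reporting floor) but kept at full precision in the
machine-readable export; rendered and exported tables are tested to agree
under the documented rounding rules.  Degenerate inputs fail loudly:
fewer than 2 observations, non-positive mean spiked response (undefined
LOD), missing transitions, missing batch controls and coverage gaps each
raise a dedicated error type.

## Known limitations

- The calculus assumes approximately normal blank-noise and spiked-response
  distributions; heavy tails would erode the 5% guarantee.
- The depletion model has no follicle hierarchy, no egg-to-egg variation
  structure beyond lognormal noise, and no saturation in the response
  conversion; it supports ordering-based screening decisions only.
- The packaged MRL snapshot is fixed; there is no per-jurisdiction
  switching or registry lookup.
- CCα, quantitative confirmation and matrix-effect quantification beyond
  interference flagging are intentionally out of scope — suspect samples
  are routed to a separate confirmatory method.
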