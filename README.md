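# eggscreen

Validation calculus and compliance classification for qualitative /
semiquantitative multiresidue LC-MS/MS screening of antimicrobial residues
in eggs.

Regulatory residue surveillance needs screening methods that can say, with
a controlled false-negative rate, whether an egg sample contains an
antimicrobial at or above its permitted level — without running a full
quantitative calibration for each of dozens of analytes.  `eggscreen`
implements the screening-oriented validation scheme used for such methods
and the downstream sample-classification logic, for a 45-analyte panel
spanning tetracyclines, aminoglycosides, quinolones, lincosamides,
β-lactams, sulfonamides and macrolides.  It is a library for residue-lab
data analysts; a thin `eggscreen` command wraps it for pipeline use.

## The calculus

For each analyte and each of its two MRM transitions, at the level of
interest `C_val` (the MRL, 0.75×MRL for combined-residue definitions, or a
per-family screening level):

- **T-value** `T = B + 1.64·SD_B` — positivity threshold from the mean and
  standard deviation of the noise of 20 blank samples;
- **cut-off factor** `Fc = M_an − 1.64·SD_an` — operational detection
  cut-off from 60 spiked replicates (20/day × 3 days);
- **LOD** `= 3·B·C / M_an`;
- **detection capability CCβ**: `Fc > T` ⇒ CCβ is below `C_val`
  (false-negative rate < ~5%, since 1.64 is the one-sided normal 95%
  quantile); `Fc ≤ T` ⇒ CCβ is above `C_val` and the transition fails;
- **sensitivity**: percent of spiked samples whose response reaches `Fc`;
- **selectivity**: no blank-matrix signal with S/N > 3 inside any
  transition's retention window.

Study samples are identified by two transitions with S/N > 3, the expected
retention time, and a minor/major ion ratio within a tiered tolerance of
the reference relative intensity; identified samples are classified
compliant or noncompliant by comparing their response with the batch
positive control spiked at 0.75×`C_val`.

Because no instrument is needed to exercise any of this, the package ships
two generators: a validation-run simulator (blank noise, spiked responses,
day effects, optional co-eluting interferent) and a minimal linear
plasma→albumen/yolk deposition model that emulates residue depletion in
eggs of medicated hens (see `docs/methods.md`).

## Worked example

`examples/withdrawal_study.py` simulates a feeding study — hens on
enrofloxacin-medicated feed for 5 days, eggs collected for 15 days (6
pooled replicates/group/day) — and screens every sample against the 7.5
µg/kg positive control:

```
control  ciprofloxacin  noncompliant for 0 day(s) after treatment end
control  enrofloxacin   noncompliant for 0 day(s) after treatment end
treated  ciprofloxacin  noncompliant for 6 day(s) after treatment end
treated  enrofloxacin   noncompliant for 9 day(s) after treatment end
168/384 sample/analyte calls had identifiable residues
```

Enrofloxacin residues stay above the positive-control response for 9 days
after dosing stops (its metabolite ciprofloxacin for 6), while the
untreated control group never flags — the withdrawal behaviour the
depletion defaults are calibrated to.  `examples/validate_method.py` and
`examples/interference_failure.py` show a clean validation run and how a
co-eluting blank-matrix interferent drives `Fc < T` (verdict `>C_val`) on
exactly the affected transition.

The same things are available from the shell:

```sh
eggscreen simulate --kind study --drug enrofloxacin --seed 1 --out sim/
eggscreen screen --study sim/study_responses.csv --manifest sim/study_manifest.csv --out calls/
eggscreen validate --input responses.csv --out report/   # exit 1 if any transition fails
```

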