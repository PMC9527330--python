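# ergpheno

A full-field electroretinogram (ERG) analysis toolkit for inherited retinal
disease cohorts. It covers the complete chain from raw repeat traces to
genotype–phenotype statistics:

- **`ergpheno.synthcohort`** — synthetic cohort generator: two-lobe Gaussian
  flash waveforms (DA 10 / LA 3), 30 Hz flicker with a 60 Hz harmonic,
  repeat noise, drift and blink artifacts, tunable interocular correlation,
  and a biallelic variant model in which the milder allele limits disease
  severity.
- **`ergpheno.signal`** — preprocessing (baseline shift, resampling onto a
  0.5 ms grid over 0–80 ms), automated trace selection (minimum pairwise
  MSE triples for flash, maximum 30 Hz signal for flicker), and
  a-wave/b-wave/flicker-peak measurement via zero-phase Butterworth
  filtering and first-derivative zero crossings with minimum-time cutoffs.
- **`ergpheno.phenoclass`** — hierarchical soft-voting ensemble (RBF SVM,
  AdaBoost decision trees, logistic regression per stimulus; eye-averaged
  class probabilities feed a final SVM) evaluated with repeated nested
  five-fold cross-validation (64:16:20 train/validation/test at the patient
  level), in 3-class and binary (restricted vs generalized) modes.
- **`ergpheno.varseverity`** — elastic-net regression from per-variant
  allele counts (plus age, sex, pupil class) to z-scored ERG amplitudes;
  handles cis complex alleles, exclusion rules, LOOCV r², and
  cross-component coefficient concordance.
- **`ergpheno.metrics`** — prevalence, eye accounting, interocular symmetry
  (Pearson r and through-origin slope), age trends with an ND
  ("no decline detected") flag, Cohen's κ, one-vs-rest AUC, and per-variant
  phenotype-group profiles.
- **`ergpheno.io` / `ergpheno.cli`** — CSV schemas, run configuration
  (JSON/YAML), and the command-line interface.

## Command line

All subcommands accept `--config` (JSON/YAML `RunConfig`), `--seed`, and
`--verbose`.

```sh
# simulate a 400-patient cohort
ergpheno simulate --n 400 --mix 0.58,0.07,0.35 --seed 1 --out sim/

# measure ERG components (per-eye and per-patient tables)
ergpheno measure --traces sim/traces.csv --out meas/

# nested cross-validated phenotype classification
ergpheno classify --traces sim/traces.csv --cohort sim/cohort.csv \
    --mode binary --seed 0 --out cls/

# variant severity scores (simulate with --mode genotype first)
ergpheno severity --cohort sim/cohort.csv \
    --components meas/components_patient.csv --out sev/

# descriptive cohort report
ergpheno report --traces sim/traces.csv --cohort sim/cohort.csv --out rep/
```

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance suite (cohort accounting,
signal oracles, classifier behavior on separable/null/default synthetic
cohorts, severity parameter recovery, metric closed forms); the full run
takes roughly 10 minutes on one CPU.

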