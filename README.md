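# retscreen

Diabetic-retinopathy screening analytics: a deterministic fundus-image
analysis pipeline, a synthetic fundus/cohort generator with exact ground
truth, ICDR-based grading rules, and the complete diagnostic-validity
statistics battery used to benchmark a screening strategy against a
reference grader.

The package has five parts:

- **`retscreen.synth`** — synthetic 45°-field fundus captures (disc, vessel
  arcades, fovea, MA/HEM/EX/CWS lesions, controlled blur/vignette/exposure
  degradation) and whole screening cohorts (2 eyes × 3 captures per patient,
  configurable severity mix, ungradability rate, simulated graders). Every
  artifact is reproducible bit-for-bit from a seed, and every image carries
  its ground truth (landmarks, vessel mask, lesion placements, stage, DME).
- **`retscreen.pipeline`** — the image-analysis chain: quality/gradability
  gate, green-channel vessel segmentation (multi-orientation black top-hat),
  optic-disc and fovea localization, a fovea-centred polar coordinate frame
  in disc-diameter units, dark- and bright-lesion detection with structural
  typing, and annotated overlay rendering.
- **`retscreen.grading`** — diagnostic rules: per-image DR/NODR/UNG status,
  ICDR eye staging (NODR/MILD/MOD/SEV/PROL with the 4-2-1 rule), DME
  (bright lesion within 1 dd of the fovea), worst-eye patient aggregation,
  and sight-threatening DR (STDR).
- **`retscreen.diagstats`** — validation statistics: 3×3 rater cross-tabs,
  Se/Sp/PPV/NPV with continuity-corrected Wald CIs, likelihood ratios with
  log-method CIs, Cohen's kappa with the Fleiss–Cohen–Everitt variance, a
  kappa homogeneity chi-square test, single-operating-point ROC AUC with
  comparison z-test, Fagan post-test probabilities, and a pooled
  two-proportion z-test.
- **`retscreen.cli` / `retscreen.io`** — a `retscreen` command with
  `synth`, `analyze`, `validate` and `report` subcommands over documented
  CSV/JSON/PNG/TIFF formats.

`retscreen.datasets` bundles the patient-level cross-tabulations of a large
published teleophthalmology validation study (3520 diabetic patients; an
automated algorithm and primary-care physicians each compared against a
reference ophthalmologist panel). They serve as exact fixtures: every
headline statistic of that study is recomputed by this package to the
printed precision.

## Quick start (CLI)

```
# 1. generate a 20-patient synthetic screening cohort with images
retscreen synth --n 20 --seed 7 --out cohort/

# 2. run the imaging pipeline + grading over the cohort manifest
retscreen analyze --manifest cohort/manifest.csv --images cohort/images \
    --out results/ --overlays

# 3. validate the pipeline's calls against the simulated reference rater
retscreen validate results/diagnoses.csv cohort/rater_calls.csv --out report.json
```

`analyze` writes per-patient `diagnoses.csv` / `patients.csv` and one JSON
analysis per capture; `validate` prints the full battery, for example:

```
Validation: ALG vs OPH

3x3 cross-tabulation (rows = test, cols = reference; DR / NODR / UNG):
     DR     455    379     33
   NODR      80   1582     64
    UNG     118    499    310

GRAD/UNG collapse: GG=2496 GU=97 UG=617 UU=310  kappa=0.3623

2x2 after UNG exclusion (n=2496): TP=455 FP=379 FN=80 TN=1582
  Prevalence                    21.43%  (19.80-23.06)
  Sensitivity                   85.05%  (81.93-88.16)
  Specificity                   80.67%  (78.90-82.45)
  Positive Predictive Value     54.56%  (51.12-58.00)
  Negative Predictive Value     95.19%  (94.13-96.25)
  Likelihood Ratio +             4.40  (3.99-4.85)
  Likelihood Ratio -             0.19  (0.15-0.23)

Cohen kappa (DR/NODR): 0.5462 (0.5109-0.5815)
Single-point AUC: 0.8286 (0.8111-0.8461)
Fagan post-test (positive): 21% -> 55% (LR 4.40)
Fagan post-test (negative): 21% -> 5% (LR 0.19)
```

(The output above is `retscreen report`'s first block — the battery applied
to the bundled study's algorithm-vs-reference table.)

## Quick start (library)

```python
import dataclasses
import numpy as np
from retscreen import synth, grading, diagstats
from retscreen.pipeline import analyze_image

# one synthetic capture with two known lesions
cfg = synth.SynthImageConfig(seed=5)
rng = np.random.default_rng(0)
lesions = synth.random_lesion_placements(cfg, ["MA", "EX"], rng)
cfg = dataclasses.replace(cfg, lesions=tuple(lesions))
image, truth = synth.generate_eye_image(cfg)

analysis = analyze_image(image)          # quality, frame, vessels, lesions
grade = grading.grade_eye([analysis])    # EyeGrade(status='DR', stage='MOD', ...)

# validation statistics on aligned per-patient call lists
report = diagstats.validation_report(["DR", "NODR", "DR"], ["DR", "DR", "NODR"])
```

## Testing

```
python -m pytest            # full suite, ~6 minutes (renders + analyzes images)
python -m pytest tests/test_diagstats.py tests/test_grading.py   # fast subset
```

`tests/test_acceptance.py` holds one test per release criterion: exact
fixtures for the published statistics, an imaging property suite (lesion
recall/typing, landmark localization, mirror equivariance, determinism), a
2000-patient end-to-end parameter recovery, a Monte-Carlo type-I-error check
of the homogeneity test, and tolerance-based approximate targets.

## Layout

```
src/retscreen/     library (types, synth, pipeline, grading, diagstats,
                   datasets, io, config, cli)
tests/             pytest suite (unit, property-based, acceptance)
scripts/           acceptance.py
docs/methods.md    methods note: models, statistics, calibration, limits
```

See `docs/methods.md` for the modelling and statistical choices, detector
calibration procedure, and known limitations.
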