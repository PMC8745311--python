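# Methods

This note documents the modelling and algorithmic choices behind
`retscreen`: the synthetic fundus model, the image-analysis pipeline and
its calibration, the diagnostic grading rules, and the statistical
estimators — including which published conventions each estimator follows
and the known limitations of the whole stack.

## 1. Synthetic fundus model (`retscreen.synth`)

### Single capture

Each capture is a 640×640 RGB 8-bit image of a circular 45°-style field
(field radius 0.47·min(h, w); background outside the field ≈ 6/255). The
anatomy is parametric and fully determined by a `SynthImageConfig`:

- **Optic disc**: a bright disk of radius `w/20` with a soft rim and a
  dimmer central cup, placed nasally on the horizontal midline. The unit
  "dd" (disc diameter, `2 × disc_radius`) is used everywhere downstream.
- **Fovea**: a smooth darkening centred 2.5 dd temporal to the disc on the
  horizontal raphe. `eye="OS"` mirrors the whole layout horizontally.
- **Vessels**: two arcades grown from the disc by a seeded recursive
  branching walk (per-step angle jitter, width taper, branch splits),
  stamped as dark anti-aliased segments. The exact stamped mask is
  retained as ground truth (`vessel_mask_for`).
- **Lesions**: placements of four types — microaneurysms (MA) and
  hemorrhages (HEM) are *dark* blobs (MA small and round, HEM larger and
  irregular); hard exudates (EX) and cotton-wool spots (CWS) are *bright*
  (EX sharp-edged, CWS diffuse). `random_lesion_placements` excludes the
  disc, the foveal pit, and the drawn vessels, so every placement is
  recoverable in principle.
- **Texture noise**: low-amplitude seeded grain, driven by a noise seed
  separate from the anatomy seed so the same eye can be re-imaged.

Degradations model capture failure: Gaussian **blur** (σ), multiplicative
**exposure** scaling, and radial **vignetting**. The documented gradability
envelope is

```
GRADABILITY_LIMITS = { blur_sigma_max: 4.0,
                       exposure_scale_min: 0.5,
                       vignette_strength_max: 0.85 }
```

A capture inside the envelope is gradable ground truth; the generator's
deliberately ungradable captures use a heavy combination (blur 8,
exposure 0.3, vignette 0.5). Every image returns a `GroundTruth` with
landmark coordinates, vessel mask, lesion placements, the per-image
gradability bit, and the eye-level lesion inventory.

All randomness flows through `numpy.random.default_rng` seeded from config
fields; string-labelled streams (patients, eyes, raters) derive integer
seeds via `zlib.crc32`, so output is byte-identical across processes and
platforms.

### Cohorts

`generate_cohort` draws, per patient: an ICDR stage for each eye from a
configurable severity distribution (default NODR .699 / MILD .081 /
MODERATE .199 / SEVERE .011 / PROLIFERATIVE .010), diabetic macular edema
(DME) with probability 0.3 given stage ≥ MODERATE, and ungradability with
rate 0.116. Each eye gets a lesion inventory *consistent with its stage by
construction* (`_plan_eye_inventory` inverts the staging rules), two eyes ×
three captures, and the patient-level truth is the worst-eye aggregate.
`simulate_rater` produces grader calls from a confusion model
(`RaterModel`: P(call DR | DR), P(call NODR | NODR), ungradable-call
behaviour), optionally conditioned on the latent stage, which lets the
statistics battery be exercised end-to-end with known operating points.

## 2. Image-analysis pipeline (`retscreen.pipeline`)

`analyze_image` runs: field mask → quality gate → vessel segmentation →
landmark localization → coordinate frame → lesion detection. It degrades
gracefully: an ungradable or landmark-free image yields an analysis with
the failure recorded in `quality.reasons` instead of raising.

### Field mask and quality gate

The field is pixels whose max channel exceeds a floor (12/255), largest
connected component only. Quality checks, each appending a named reason:

- **underexposed / overexposed**: mean field green below 35, or >20% of
  field pixels saturated;
- **vignetted / small field**: illuminated fraction of the field circle
  below 0.60;
- **blur**: a shading-corrected sharpness score below threshold. The green
  plane is divided by its own smoothed background (normalized convolution
  confined to the field, σ = max(h, w)/16), which cancels exposure level
  and vignetting multiplicatively; mean squared Sobel gradient (×10³) is
  then measured inside a 30-px-eroded field so the field-boundary step —
  which smears inward under blur — never contributes.

**Calibration.** The sharpness threshold was frozen from a sweep against
the generator's documented limits, *before* the test suite was written: at
the limit (σ = 4, must pass) the score spans 4.19–4.80 over seeds; just
beyond (σ = 4.5, must fail) it spans 3.54–4.01. `sharpness_min = 4.10` is
the gap midpoint. Earlier metric versions failed this sweep in two
instructive ways (exposure² scaling; non-monotonicity from the field-edge
step) — the fixes above are what the sweep forced.

**Known soft edge.** Vignette gating saturates above strength ≈ 0.9: the
rendered rim falls below the background level, the field mask absorbs the
darkened ring, and the illuminated fraction plateaus (~0.725 vs ~0.736 at
the legal 0.85) by less than anatomy-to-anatomy variation. We deliberately
do not gate on that 0.01 gap; vignette-only degradation slightly beyond
the limit can pass the gate. Combined ungradable captures are robustly
flagged (underexposed).

### Vessels

Vessels are dark, elongated structures: a multi-orientation black top-hat
(line footprints at 12 orientations) on the green plane, thresholded at a
fixed contrast (10/255), then filtered by component size and elongation.
A skeleton is derived for centreline queries.

### Landmarks and coordinate frame

The **disc** is the largest compact component of the brightest quantile
(0.99) of field pixels, refined by local re-thresholding; its equivalent
radius gives the measured dd. Failure raises `LandmarkNotFoundError`
(recorded as a quality reason by `analyze_image`). The **fovea** is the
darkest smoothed, vessel-free region within an annulus 2–3 dd from the
disc on the temporal side. The `CoordinateFrame` expresses any pixel in
fovea-centred polar coordinates (radius in dd, angle with 0° toward the
disc, positive toward superior), so laterality-independent rules like the
DME criterion read naturally.

### Lesion detection

Dark candidates come from a grey-closing residual (disk radius 14 px),
bright candidates from a grey-opening residual, each thresholded and
cleaned. Candidates overlapping the vessel mask, disc, or field edge are
suppressed. Typing is structural: dark blobs split into MA vs HEM by
area/roundness; bright blobs into EX vs CWS by edge sharpness (border
gradient) and size. Each `LesionCandidate` carries pixel and polar
coordinates. `render_overlay` draws the frame (fovea rings at 1 and 2 dd)
in yellow, dark lesions in red, bright in blue.

Measured on the generator (20-seed suite, 5 planted lesions each): recall
and dark/bright class agreement ≥ 0.8 with exact-type agreement ≥ 0.8
among recovered; disc localization error ≤ 0.25 dd, fovea ≤ 0.5 dd;
≤ 2 false candidates per clean image; exact mirror equivariance.

## 3. Grading rules (`retscreen.grading`)

- **Image status**: UNG if the quality gate failed, else DR if any lesion
  candidate, else NODR.
- **Eye stage** (ICDR, from a `LesionInventory`): NODR (nothing), MILD
  (MA only), MODERATE (more than MA only, less than severe), SEVERE by the
  4-2-1 rule (>20 hemorrhages in each of 4 quadrants, venous beading in
  ≥ 2, or IRMA in ≥ 1) without proliferative signs, PROLIFERATIVE
  (neovascularization or vitreous/preretinal hemorrhage).
- **DME**: any hard exudate within 1.0 dd of the fovea.
- **Eye from captures**: an eye is gradable if *any* capture is gradable;
  inventories of gradable captures are merged with deduplication of
  repeated detections across captures.
- **Patient**: worst eye (stage order NODR < MILD < MODERATE < SEVERE <
  PROLIFERATIVE). Status is DR/NODR/UNG; the UNG-vs-DR precedence when one
  eye is ungradable and the other shows DR is a configurable policy switch
  (default: DR evidence wins). **STDR** = severe or worse, or DME.

## 4. Statistics (`retscreen.diagstats`)

All estimators were chosen to match the conventions of the published
validation study whose cross-tabulations ship in `retscreen.datasets`;
each choice was verified by reproducing the printed values exactly.

- **Cross-tabs**: calls are DR/NODR/UNG; a 3×3 rater table collapses to
  (a) gradable/ungradable 2×2 for gradability agreement, and (b) a DR/NODR
  2×2 after excluding pairs with any UNG, which is the basis for validity
  indexes (n = 2496 for the bundled algorithm table).
- **Proportions** (Se, Sp, PPV, NPV, prevalence): point estimate with a
  continuity-corrected Wald 95% CI (± (z·√(p(1−p)/n) + 1/(2n))). This is
  the variant that reproduces the printed sensitivity CI 81.93–88.16.
- **Likelihood ratios**: LR± with Simel's log-method CI
  (exp(ln LR ± z·SE), SE from the standard delta-method formula);
  reproduces the printed LR+ CI 3.99–4.85.
- **Cohen's kappa**: point estimate on the square table; the standard
  error uses the Fleiss–Cohen–Everitt (1969) large-sample variance, which
  reproduces the printed kappa CI 0.5109–0.5815. Degenerate marginals
  (chance agreement 1) raise, and `validation_report` reports the kappa as
  undefined rather than a number.
- **Kappa homogeneity** across two independent tables: inverse-variance
  chi-square, χ² = (κ₁−κ₂)²/(v₁+v₂) on 1 df. A seeded Monte-Carlo check
  (2000 null replicates of paired n = 1000 tables) confirms a type-I error
  rate inside the 95% binomial interval around α = 0.05.
- **Single-point AUC**: with one operating point the ROC is the
  two-segment hull, AUC = (Se+Sp)/2, with variance (var(Se)+var(Sp))/4 and
  a normal CI; `compare_auc` is the corresponding z-test. This convention
  reproduces the printed 0.8286 / 0.7657 / 0.8287.
- **Fagan post-test probabilities**: odds(post) = odds(pre)·LR. At the
  sample prevalence the positive post-test probability equals the PPV —
  an identity used as a self-check.
- **Two-proportion test**: pooled two-sample z (optional Yates
  correction); applied to the ungradable rates 407/3520 vs 461/3520 it
  gives p ≈ 0.050, within ±0.002 of the published value (the published
  computation method is not fully identified, so the acceptance test for
  this and the gradability-homogeneity χ² carries explicit tolerances).

## 5. Verification strategy

- Statistical functions are tested against independent oracles
  (scikit-learn's `cohen_kappa_score`, statsmodels' `proportions_ztest`
  and `proportion_confint`), against exhaustive small-table enumeration,
  against Monte-Carlo standard errors, and with property-based tests
  (Hypothesis) for algebraic identities.
- The grading rules are tested against an exhaustive independent oracle
  over the full inventory grid.
- The pipeline is tested on generator output with pre-registered
  tolerances (recall/typing ≥ 0.8, landmark errors, mirror equivariance,
  determinism) and the quality gate is tested exactly at the documented
  degradation limits.
- End-to-end: a 2000-patient cohort graded by a (Se .85, Sp .81) simulated
  rater recovers those parameters within the 95% CIs.

## 6. Limitations

- The synthetic model is geometric, not photometric: no real-camera noise
  model, no media opacities, no peripheral fields; detector performance
  figures quantify agreement with *this* generator, not clinical accuracy.
- The vignette quality gate has the documented soft edge above
  strength ≈ 0.9 (§2).
- Single-point AUC is a convention for dichotomous raters, not an estimate
  of a full-ROC AUC.
- The staging oracle consumes lesion *inventories*; venous beading, IRMA
  and neovascularization are inventory flags the image pipeline does not
  detect (the renderer does not draw them), so image-derived stages top
  out at MODERATE plus the hemorrhage-count arm of the 4-2-1 rule.
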