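# Methods

## The measurement model

Left atrial (LA) longitudinal function is quantified from the distance
*D(t)* between an atrioventricular junction point and a user-defined point
at the mid posterior LA wall, tracked through one cardiac cycle on standard
cine long-axis views. Strain is referenced to LV end-diastole (frame 0):

    ε(t) = (D(t) − D₀) · 100 / D₀      [%]

and strain rate is the first derivative of fractional strain,
SR(t) = d(ε/100)/dt in s⁻¹. Because percent strain is divided by 100 before
differentiation, SR magnitudes land in the physiologic ±1–2 s⁻¹ range; a
derivative of raw percent strain would be 100× larger.

Each long-axis view contributes two walls (4-chamber: septal and lateral;
2-chamber: anterior and inferior), each defined by one junction paired with
the single mid-posterior point. Parameters are extracted per wall and
averaged arithmetically; a configuration switch (`average_curves_first`)
instead averages the two strain curves before extraction. The per-wall
default was chosen because extraction at per-wall phase indices is the more
conservative order; on the phantom the two agree to well under the tracking
tolerance.

### Phase detection and the six parameters

* **t_es** (LV end-systole) — the strain maximum.
* After t_es the SR curve must contain two negative lobes: early-diastolic
  conduit emptying and the late-diastolic atrial kick. If fewer are found
  the curve is monophasic (e.g. no atrial contraction) and an error is
  raised rather than a guess made.
* **t_diastasis / t_preA** — on the diastolic plateau these coincide up to
  noise; both are reported as the single index of minimum |SR| between the
  two diastolic lobe peaks. With more than two candidate lobes (noise), the
  two deepest are kept.

Parameters: ε_s = ε(t_es); ε_a = ε(t_preA); ε_e = ε_s − ε_a (the additive
convention, which makes ε_e + ε_a = ε_s an exact identity); SR_s = max SR on
[0, t_es]; SR_e = min SR on (t_es, t_preA]; SR_a = min SR on (t_preA, T).

### Strain-rate numerics

Central differences with **cyclic wrap** (the cine spans one complete cycle,
so frame T−1 neighbours frame 0), second-order accurate. Optional cyclic
moving-average smoothing of ε before differentiation (odd window, off by
default — the raw derivative is the faithful default). The cyclic
central-difference operator is circulant; `reconstruct_strain` inverts it
mode-by-mode in Fourier space (symbol i·sin(2πk/T)/Δt), fixing the DC mode
by ε(0) = 0 and dropping the Nyquist mode that the operator annihilates for
even T. For smooth strain curves both carry negligible energy and the
round-trip error stays below 0.1 absolute %; a naive running sum of central
differences would instead land on inter-frame midpoints with errors of half
the per-frame strain change.

## Tracking

A square template (the "mask", default half-width 5 px → 11×11 ≈ 14 mm at
1.25 mm spacing) centred on the annotated point is matched by **normalized
cross-correlation** — exact Pearson correlation per offset, computed
vectorised over sliding windows — within a search region (default half-width
10 px = 12.5 mm per frame, generous for annular excursion at 30–40
frames/cycle). The peak gives the new position; in adaptive mode the mask is
then re-extracted there and the procedure repeats frame by frame. The only
user input is the initial annotation.

Numerical choices:

* **Tie-breaking** — among equal correlation maxima (within 1e-12), the
  offset closest to the previous position wins; remaining ties resolve in
  row-major order. Deterministic and temporally coherent.
* **Subpixel refinement** (off by default) — separable 3-point parabolic fit
  around the integer peak, capped at ±0.5 px/axis. When enabled, the
  adaptive mask is sampled bilinearly at the exact fractional position so
  the chained displacement estimates carry no re-centring phase error.
* **Drift correction** (on by default in adaptive mode) — chaining
  frame-to-frame matches accumulates a random walk of small per-step errors.
  Each adaptive candidate is therefore re-anchored against the frame-0 mask
  in a ±(h+3)-px neighbourhood; the correction is accepted only if that
  match reaches `min_correlation` and moves the point ≤ 2 px. It engages
  while the tissue resembles its end-diastolic appearance and degrades
  gracefully to the pure mask update when it does not. On the phantom this
  reduces the 30-frame accumulated error from ~1.3 px to < 0.3 px.
* **Borders** — search regions are clipped to the image; positions are
  clamped to the template margin and flagged `clamped_to_border`, never
  extrapolated. Frames whose best correlation falls below `min_correlation`
  (default 0.5) are flagged `low_correlation`. Flagged frames are reported
  for external correction via the trajectory CSV round-trip; there is no
  interactive editor.
* A zero-variance template is an error (nothing to match); zero-variance
  search windows score 0.

## The phantom

The synthetic cine emulates exactly what this tracker consumes: two fixed
junction points and a posterior point whose per-wall distances follow a
prescribed triphasic programme, rendered as rigid textured patches over a
static textured background.

* **Strain programme** — piecewise-C¹ cosine smoothsteps: rise to ε_s on
  [0, 0.40]·T, fall to ε_a on [0.40, 0.60]·T, plateau to 0.75·T, decay to 0
  at the (virtual) frame T. Defaults ε_s = 35.3 %, ε_a = 17.2 % (a normal
  control); 30 frames; 1.25×1.25 mm spacing; 1000 ms RR.
* **Geometry** — the posterior point is placed per frame at the intersection
  of two circles centred on the junctions with radii D₀·(1 + ε/100), so the
  per-wall distance programmes are exact to machine precision and the two
  walls may carry distinct amplitudes.
* **Rendering** — patch textures are seeded Gaussian noise blurred to a 3-px
  correlation length (periodic, hence band-limited); subpixel translation
  uses an exact Fourier shift, and blending uses a flat-top (Tukey) window
  whose interior covers the tracker's template, so the observed template
  content translates strictly rigidly. Additive Gaussian noise (default
  σ = 2 % of the intensity range) is drawn from the same seeded generator;
  identical config + seed gives bit-identical frames.

What the phantom does **not** emulate: myocardial appearance change over the
cycle, through-plane motion, bSSFP banding or flow artefacts, anatomically
realistic LA geometry. Passing the recovery tests therefore demonstrates the
correctness of the estimator chain and its noise robustness — not clinical
accuracy on patient data.

Phase-timing note: with the default fractions the prescribed conduit and
booster SR lobes are longer and shallower than typical in-vivo curves, so
the phantom's peak SRs (≈ +1.4/−1.4/−1.1 s⁻¹) sit below typical normal
in-vivo magnitudes (≈ +1.8/−2.0/−2.3 s⁻¹); strains are unaffected. Detected
t_preA may fall anywhere on the flat plateau (|SR| is noise-dominated
there); recovery checks accept the plateau window, while t_es is sharp and
recovered exactly.

## Volumetry

Biplane area-length volumes V = 0.85·A_2C·A_4C/L with L the shorter of the
two view long-axis lengths, at the three phases (maximal, pre-atrial
contraction, minimal); total/passive/active emptying fractions follow. The
three fractions satisfy (1−P/100)(1−A/100) = 1−T/100 identically — a useful
invariant check. Planimetry is input, not computed: contour segmentation is
outside this method's scope. Optional BSA indexing divides volumes by a
supplied body-surface area; BSA estimation formulas are out of scope.

## Agreement statistics

* **Passing-Bablok** — slope as the shifted median of pairwise slopes (ties
  in x excluded; slopes of exactly −1 excluded; offset K = #slopes < −1),
  intercept = median(y − b·x); CIs from the rank-based normal approximation
  (deterministic, no bootstrap), with intercept bounds from the opposite
  slope bounds.
* **Bland-Altman** — bias = mean(x−y), limits bias ± 1.96·SD (n−1).
* **CV** — duplicate-measurement within-subject CV,
  √(mean(d²)/2)/grand-mean·100 by default (`rms`); SD-of-differences
  alternative exposed (`sd`) since conventions differ between labs.
* **ROC** — empirical curve (scikit-learn), trapezoidal AUC (identical to
  the Mann-Whitney pairwise estimator with ties counted ½); operating
  threshold maximizes Youden's J, ties broken toward higher sensitivity; a
  `direction` flag handles markers that decrease with disease, as strain
  does.

## Problem sizes and defaults used in validation

Recovery statistics use 128×128×30-frame phantoms; the cohort run in
`scripts/acceptance.py` uses 10 subjects × 2 views and the test suite's seed
sweep uses 20 single-view seeds — sizes at which the recovery bias/SD
estimates are stable to well under the tolerances they are compared against.
Subpixel refinement is enabled for recovery runs (integer tracking
quantizes ε by ~2 % per pixel at the default geometry, which would swamp
the subpixel-scale biases being measured).

## Known limitations

* Global longitudinal LA function only: no segmental/regional, radial or
  circumferential strain, no LV/RA strain.
* Phase detection requires a triphasic curve; arrhythmic or fused E/A
  patterns raise errors instead of producing silent nonsense.
* The drift-corrected adaptive tracker assumes the end-diastolic appearance
  remains informative somewhere along the cycle; with severe appearance
  change it reverts to pure mask update and inherits its drift.
* DICOM support targets secondary-capture cine series; multi-frame
  enhanced-CT/MR objects and short-axis stacks are out of scope.
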