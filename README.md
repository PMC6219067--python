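# fastla

Fast, semi-automated quantification of **left atrial (LA) phasic longitudinal
strain and strain rate** from standard cine cardiac MR long-axis views.

The LA modulates left-ventricular filling in three phases — **reservoir**
(filling during ventricular systole), **conduit** (passive early-diastolic
emptying) and **booster pump** (atrial contraction) — and its function is a
sensitive marker of cardiac dysfunction. Conventional feature tracking
requires delineating the whole LA contour, which the LA appendage and
pulmonary veins make fragile and slow. `fastla` instead tracks just **three
anatomical points** per view (the two atrioventricular-junction points and
the mid-posterior LA wall point) through the cardiac cycle with normalized
cross-correlation (NCC) template matching, and derives strain from the
junction-to-posterior-wall distance *D*:

```
ε(t)  = (D(t) − D₀) · 100 / D₀          [%],  D₀ = D at LV end-diastole
SR(t) = d(ε/100)/dt                      [s⁻¹]
```

Read off at LV end-systole, diastasis and pre-LA systole this yields the six
phasic parameters ε_s, ε_e, ε_a and SR_s, SR_e, SR_a, with the additive
decomposition ε_e + ε_a = ε_s. Parameters are computed per wall
(septal/lateral on the 4-chamber view, anterior/inferior on the 2-chamber
view) and averaged.

The package also implements biplane area-length LA volumetry
(`V = 0.85·A_2C·A_4C/L`, total/passive/active emptying fractions), the
method-comparison statistics used to validate such a measurement against an
established one (Pearson r, Passing-Bablok regression, Bland-Altman,
coefficient of variation, ROC with Youden operating point), and a synthetic
cine phantom with exact ground truth for every pipeline stage.

## Worked example

Simulate a phantom cine with the default normal-control deformation
(reservoir strain 35.3 %, booster strain 17.2 %, 30 frames/cycle, 1.25 mm
pixels, 2 % noise), then run the full analysis:

```bash
fastla simulate --out phantom --seed 5
fastla strain --cine phantom/cine.npz --landmarks phantom/landmarks.json \
              --out strained --subpixel
cat strained/phasic.json
```

```json
{
  "eps_s": 35.56415194619444,
  "eps_e": 18.221488804565382,
  "eps_a": 17.34266314162906,
  "sr_s": 1.367726344196516,
  "sr_e": -1.3455053340164622,
  "sr_a": -1.057621793484759,
  "phases": {"t_es": 12, "t_diastasis": 19, "t_preA": 19}
}
```

The tracked reservoir strain (35.56 %) recovers the prescribed 35.3 % to
within the tracker's subpixel accuracy; conduit strain is the
reservoir-booster difference (ε_e = ε_s − ε_a); end-systole is detected at
frame 12 of 30 (0.40 of the cycle, as prescribed); diastasis/pre-LA-systole
falls on the prescribed diastolic plateau. Strain rates are in s⁻¹
(fractional strain per second); their peaks are set by the prescribed phase
durations.

Volumetry works from external planimetry (areas cm², lengths cm):

```bash
fastla volume --planimetry planimetry.csv --out volumes.json
```

For a row `max: A_2C=20, A_4C=24, L_2C=6, L_4C=7` the maximal volume is
`0.85·20·24/6 = 68.0 ml` (the shorter of the two lengths is used).

The same stages are available as a library — see `fastla.analyze_view`,
`fastla.generate_phantom`, `fastla.agreement_report`, `fastla.roc_analysis`.

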