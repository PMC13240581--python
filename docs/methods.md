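# Methods

## The question and the model

A fractionated course (default 25 × 2 Gy) is delivered under one of six
image-guidance schedules. On an imaged fraction a CBCT is acquired,
translational setup error is corrected by the couch, and the fraction is
delivered with only a small residual error; on a non-imaged fraction the full
setup error of the day goes uncorrected. The analysis quantifies what each
schedule costs in target coverage (D95), tumor control probability, organ-at-
risk dose and complication probability, and what it saves in concomitant
imaging dose and direct imaging fees.

### Setup-error model

Rigid 3-D translations only; rotations and deformations are out of scope.
Per patient *p* and fraction *f*, per axis:

* pre-correction: `e_pre = mu_p + eps_f`, with `mu_p ~ N(0, sigma_systematic²)`
  drawn once per patient and `eps_f ~ N(0, sigma_random²)` per fraction;
* post-correction: `e_post ~ N(0, sigma_residual²)` per fraction.

Defaults 3 / 3 / 1 mm per axis. No institutional measurement of these
magnitudes exists for a synthetic cohort; 3 mm systematic and random with a
1 mm residual are typical published values for breast/chest-wall setups with
laser positioning and CBCT correction, and all three are configurable. All
draws derive from a single seed (per-patient generator seeded by
`(seed, patient_id)`), so a config fixes every emitted byte.

### Dose response to error: the invariant-dose approximation

The delivered dose of a fraction at error *s* is the planned dose rigidly
translated by −*s* in the planning frame (trilinear resampling, zero
background outside the grid, scaled 1/n_fractions). This replaces deformable
registration and per-fraction recalculation on daily anatomy: it is the
module's central simplification. It preserves exactly the property the
schedule comparison rests on — dose moves relative to static structures by
the setup error, more often corrected ⇒ less displacement — but ignores
tissue deformation, anatomy change, and dose perturbation by density changes.
Sign convention: the patient moves by +s relative to the beams, so the dose
pattern samples the planned field at coordinates +s (for zero-mean error
distributions the cohort statistics are insensitive to this sign).

### Phantom

Structures are defined in fractional grid coordinates, so one geometry
serves any grid size (default 48³ at 4 mm isotropic; the test and
scaled-down analyses use 24³ and 20³): a curved left anterior chest-wall
slab (PTVcw), a small superior supraclavicular box (PTVsc, disjoint from
PTVcw), the heart medial and deep to the slab, a large ipsilateral-lung
ellipsoid beneath it, and a right-sided contralateral breast. OAR masks
exclude target voxels. A structure that is empty or touches the grid
boundary raises a generation error.

The planned dose is prescription inside the PTV union, falling to zero
through a logistic penumbra whose 80–20 % distance is `penumbra_width`
(default 6 mm) and whose 50 % level sits 1.5 × `penumbra_width` outside the
PTV surface. The offset models the conformity margin a clinical optimizer
produces and is tuned so the plan-quality gate — D95 of each PTV ≥ 95 % of
prescription on the planned dose — holds at the default and scaled-down
grid sizes. `penumbra_width = 0` degenerates to a binary
prescription/background field. Out-of-field background dose is 0 Gy.
At the defaults this yields planned mean doses of ≈ 0.1 Gy (heart), ≈ 7 Gy
(ipsilateral lung) and ≈ 0.03 Gy (contralateral breast): OARs receive
incidental dose by proximity only.

### Schedules

Weeks are consecutive blocks of `fractions_per_week` fractions (no calendar
gaps). Within-week imaging days: WIG day 1; TIG days {1, 4}; THRIG days
{1, 3, 5}; 3D+WIG fractions 1–3 then day 1 of each later week; DIG all.
Fraction 1 is always imaged. These placements give F = 1, 5, 10, 15, 7, 25
for the 25-fraction default — the frequencies that make the published
dose/cost arithmetic (60 % of daily for THRIG, 25-fold daily:minimal cost
ratio) come out exactly. Custom policies can be supplied as explicit boolean
masks.

### DVH engine

Cumulative DVHs with uniform bins (default 0.05 Gy — binning error ≪ the
~1 %-of-50-Gy effects of interest). D95 is read from the cumulative curve by
linear interpolation, ties broken toward the lower dose; Dmean is the
volume-weighted mean of the differential bins; Dmax the top occupied bin
edge. All metrics are stable to bin refinement within one bin width, which
is also the tolerance used against brute-force sorted-voxel oracles.

### Radiobiology

The per-bin tumor response uses the Källman form
`P(D) = 2^(−exp(e·γ·(1 − D/TCD50)))` — the standard (TCD50, γ)
parameterization of the Poisson-LQ model; it is isolated behind a single
function so an alternative variant can be swapped in. Heterogeneous TCP is
the volume-weighted product over differential-DVH bins (uniform clonogen
density). NTCP is LKB: probit of `(gEUD − TD50)/(m·TD50)` with
`gEUD = (Σ vᵢ Dᵢ^{1/n})^n`, evaluated in log space so small `n` cannot
overflow. The dose axis is converted bin-wise to EQD2 (per-bin fraction size
`dᵢ = Dᵢ/n_fractions`) before **both** TCP and NTCP, because α/β is supplied
for every structure; at the 2 Gy/fraction reference this conversion is the
identity on the prescription. The exponential in the TCP response is clipped
at 700 so DVHs up to hundreds of Gy remain finite.

### Imaging dose and cost

`D_cum = D_single × F` per organ and `C_total = C_single × F`, exact
arithmetic. Per-scan organ doses are Monte-Carlo-tabulated constants for the
CBCT system (no patient-size scaling); the heart has no tabulated per-scan
dose and is deliberately omitted rather than invented. Scanner presets (kV,
collimator, filter, mAs, rotation) are carried as metadata only. Percent-of-
reference ratios reduce to F/F_ref, independent of the per-scan constants.
Indirect costs (staff time, depreciation) are out of scope.

### Statistics

Per metric: Shapiro–Wilk normality per schedule (logged as a caveat flag —
the paired t-tests run regardless, mirroring the intended workflow), the
Friedman omnibus test over the six related samples, and all 15 pairwise
paired t-tests with Bonferroni correction (raw p × 15, capped at 1),
α = 0.05. Deviation versus the reference schedule (DIG) is the per-patient
signed percent deviation `100·(x_ref − x)/x_ref`, averaged over patients
(mean of per-patient ratios, not ratio of means), positive meaning worse
than reference for higher-is-better metrics; patients with a zero reference
value are excluded with a warning. Identical paired samples are reported as
t = 0, p = 1 (the test statistic is undefined there and "no evidence" is the
correct reading).

## Problem sizes

Default analyses use 20 patients on 48³ grids (seconds on one core); the
test suite exercises the full pipeline at 10 patients × 24³ and 2 × 20³,
sizes at which every qualitative property of the model (schedule ordering,
zero-noise invariance, plan-quality gates) already holds.

## What the synthetic cohort does and does not show

The generator reproduces the statistical *structure* the analysis assumes:
per-fraction dose pairs whose pre-correction state carries
systematic-plus-random displacement and whose post-correction state carries
a small residual. Consequences that follow from that structure — monotone
improvement of D95/TCP with imaging frequency, schedule-invariance at zero
error, linear imaging dose/cost, THRIG's intermediate trade-off — are
meaningful on synthetic cohorts and are what the tests assert. Patient-
derived magnitudes (e.g. the published 1.38 % D95 / 0.83 % TCP deviations of
thrice-weekly vs daily imaging, or a minimum TCP of 0.49) depend on real
CBCT anatomy, deformable registration and planning detail, and are **not**
reproduced; the synthetic counterparts have the same structure but their
own magnitudes.

## Known limitations

* Rigid translations; no rotation, deformation, breathing or anatomy change.
* Invariant-dose approximation; no density-corrected recalculation.
* Uniform clonogen density; no repopulation or repair kinetics.
* Imaging dose is not added to the therapeutic dose grid; secondary-cancer
  risk modelling is out of scope.
* Single-institution fee constant; currency not converted.
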