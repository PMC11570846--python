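# Methods

This note records the models, numerical choices and open design decisions
behind `brachyaudit`, and what the synthetic generators do and do not
emulate.

## TG-43 dose engine (`brachyaudit.tg43`)

The engine implements the standard two-dimensional TG-43 dose-rate
equation for a single source position and superposes dwell positions
linearly (dose = Σ rate × dwell time). Conventions:

- **RAKR ≡ S_K.** The reference air kerma rate in U (µGy·m²·h⁻¹) is
  treated as numerically equal to the air-kerma strength in U, the
  standard equivalence for HDR sources.
- **Geometry function.** Point: 1/r². Line: β/(L·r·sinθ) with β the
  angle subtended by the active length at the calculation point,
  computed with `arctan2` so it is correct in all quadrants. On the
  long axis the limit form 1/(r² − L²/4) is used; the switch happens at
  sinθ < 1e-9, where both forms agree to well below measurement
  relevance. An independent oracle (numerical integration of 1/d² along
  the active length) pins the line form in the tests.
- **Tables.** g(r) is interpolated linearly in r; F(r,θ) bilinearly on
  its (r,θ) grid. Outside a table the nearest value is used (clamped)
  with a warning; more than 20 % beyond the tabulated range is an
  error. Clamping is conservative and irrelevant to the audit plan,
  whose geometry stays at r ≈ 2–3.6 cm, well inside all bundled tables.
- **Bundled datasets.** `toy` (Λ = 1, g ≡ F ≡ 1, point geometry) makes
  the engine exactly inverse-square, which the analytic tests exploit.
  `ir192_generic` (Λ = 1.109 cGy·h⁻¹·U⁻¹, L = 3.5 mm) and
  `co60_generic` (Λ = 1.087, L = 3.5 mm) carry *synthetic,
  representative* consensus-style tables — smooth g(r) and an
  anisotropy dip toward the source axis of realistic magnitude — not
  vendor characterizations; their JSON `metadata.provenance` says so.
  Audit results depend on these tables only through the near-constant
  dose across the small sensitive volume, so any physically reasonable
  table reproduces the plan metrics.

## Reference plan (`brachyaudit.plan`)

Frame: origin at the phantom centre = RPLD centre = control point;
catheters along +x at y = ±20 mm, z = 0. Dwells at x = −30 … +30 mm in
5 mm steps (13 per catheter), symmetric about the control point — the
published plan is symmetric but does not state the offset from the
catheter tip, which only matters for film fiducials, not dose.

The 2 Gy prescription is solved in closed form: dose at the control
point is linear in the single uniform dwell time, so
t = prescription / Σᵢ Ḋᵢ. Scale invariance (RAKR up, dwell time down)
is exact and tested.

Volume metrics sample a cylinder of the RPLD diameter (1.5 mm) and the
**sensitive length, default 6 mm** — the glass rod is 12 mm but only a
central section is read out and its exact length is not published; the
value is a configurable assumption (`PhantomGeometry.sensitive_length_mm`).
Sampling is a regular Cartesian grid (default 0.1 mm, must be ≤ 0.25 mm)
symmetric about the origin so the control point itself is always a
sample; grid-refinement convergence of the mean is below 0.001 Gy
between 0.2 and 0.1 mm.

## Correction factors (`brachyaudit.corrections`)

- **Ratio of means, not mean of ratios.** The 20 dosimeters per setup
  are distinct physical detectors, not pairs, so each factor is the
  ratio of setup means with u = value·√((SEM_n/μ_n)² + (SEM_d/μ_d)²),
  SEM = SD/√n. A 10⁵-replicate bootstrap cross-checks this in the tests.
- **Total factor.** k_tot = mean(k_m pair) · mean(k_s pair) · k_Q, pair
  uncertainty ½√(u₁²+u₂²), relative quadrature across the three terms,
  all treated as uncorrelated. Recomputing the published Ir-192 budget
  this way gives u ≈ 0.0087 against a printed ±0.009 — consistent, but
  the original correlation/rounding treatment is unpublished, so the
  module reports its own propagation and accepts an override.
- Whether the published per-factor uncertainties are SEM-based or
  include Type-B terms is likewise not stated; values here are
  SEM-based.
- Reported component values for the two audited source models are taken
  as inputs; reproducing the Monte-Carlo factors themselves is out of
  scope.

## RPLD dose chain (`brachyaudit.rpld`)

M = (raw − background) × sensitivity × fading × tray; D = M·N·k_Q·k_s·k_m.
Background is subtracted from the **raw** signal before the
multiplicative corrections — the shipped background dosimeter's
arithmetic is not published; since the corrections are per-dosimeter
multiplicative factors near 1, the alternative order differs only at
second order in (factor − 1) × background. No fading model is
implemented: audits are scheduled within a three-day window where
fading is negligible (its budget line is 0.01 %), and the factor is a
caller-supplied input.

## Uncertainty budget (`brachyaudit.uncertainty`)

Plain GUM quadrature of relative standard uncertainties in percent;
components are treated as uncorrelated (no correlation structure is
published) and one shared budget serves both radionuclides, budgeting
the larger component where they differ. No sensitivity-coefficient
propagation: all components are already expressed as relative standard
uncertainties of the final dose. The bundled ten-component budget
combines to 2.24 % (k = 1).

## Film analysis (`brachyaudit.film`)

The scanned strip (reflective scan: darker film → lower pixel value) is
normalized by dtype range, converted to net darkening against the image
median (the track occupies a minority of the strip area), and averaged
over the band of rows where the track runs (rows above 50 % of the
strongest row). Edges sit at 50 % of the profile plateau — the plateau
is the median of the top 20 % of the profile, robust to noise — with
linear sub-pixel interpolation; mm = px × 25.4/dpi.

Design decisions:

- The original analysis macro's internals are unpublished; the 50 %
  edge criterion is this package's choice, and the ±0.3 mm procedure
  uncertainty is adopted as a fixed Type-B floor rather than re-derived.
- **Sign convention:** positive shift = toward the proximal end
  (afterloader). The scan orientation is metadata
  (`axis_points_proximal`); with the default orientation,
  shift = track midpoint − fiducial.
- Two films per set: mean, and u = √(0.3² + SD²) with SD = |s₁−s₂|/√2,
  so u ≥ 0.3 mm always.
- Classification boundaries at 3.0/5.0 mm are **inclusive** ("within
  ±3 mm"), with a 1e-12 guard so exact boundaries survive floating-point
  representation.
- Colour scans are collapsed to mean luminance; the film's spectral
  response is not modelled (the film is positional QA, not dosimetry).

## Cohort aggregation (`brachyaudit.cohort`)

Statistics are per **dosimeter set**, not per centre (a centre may
irradiate several sets); SDs are sample SDs, reported as 0 with an
`insufficient_n` flag for a single set. Dose sets are within ±p % when
|ratio − 1| ≤ p/100, same inclusive-boundary rule as the shifts. The
proximal-outlier count (|shift| > 3 mm and positive) mirrors the
systematic catheter-tip dead-space error mode seen in practice.

## Synthetic world (`brachyaudit.synthetic`)

Generators are pure functions of (parameters, seed), with defaults set
to the stated pilot-world values: 59 sets, dose ratio ~ N(1.008, 0.014),
set shift ~ N(1.2 mm, 2.5 mm), mean intra-set RPLD difference 1.6 %
(implemented as a half-normal |δ| with that mean), 45/59 sets Ir-192,
user dose 2 Gy. Per-film repeatability around the set shift is 0.2 mm
(an assumption: below the 0.3 mm procedure floor, consistent with the
observed inter-film agreement). RPLD reading noise is lognormal by
default (doses are positive); a truncated-normal option exists.

Film renders use the physical 32 × 140 mm strip at the requested dpi,
an error-function edge profile (σ = 0.5 mm) and additive Gaussian pixel
noise. They emulate geometry and noise, **not** film physics: no
scanner lamp nonuniformity, no film-response nonlinearity, no dust or
fiducial-marking artifacts. A green recovery test therefore establishes
that the analysis is unbiased and sub-0.3 mm under the stated noise,
not that it is robust to every real-world scan artifact.

Cohort draws are normal and uncorrelated between dose and position;
real audits can correlate them (a grossly misplaced source lowers the
measured dose), a regime the reference plan is designed to suppress and
which the generator deliberately omits.

## Known limitations

- No Monte-Carlo transport, scatter or heterogeneity modelling: those
  effects enter only through the supplied correction factors.
- The correction-factor uncertainty treatment assumes independence
  between experimental and MC estimates.
- The film analyzer expects one track roughly parallel to the image
  axis; skewed catheters or double exposures are out of scope.
- The bundled source tables are representative, not source-model
  specific; do not use them for clinical dose calculation.
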