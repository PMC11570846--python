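# brachyaudit

A toolkit for **postal dosimetry audits of HDR brachytherapy sources**,
written for medical physicists who run (or study) remote quality-assurance
programmes. In such an audit a compact phantom is mailed to a hospital, the
local team steps their HDR afterloader source (¹⁹²Ir or ⁶⁰Co) through two
catheters to deliver a standardized 2 Gy plan to a radiophotoluminescent
glass dosimeter (RPLD), and the dosimeters plus two radiochromic film
strips are mailed back. The audit then answers two questions: *was the
delivered dose consistent with the reference air kerma rate (RAKR) the
centre states for its source?* and *was the source physically where the
plan put it?*

`brachyaudit` implements that whole computational chain, together with
seeded synthetic generators so the pipeline can be exercised — and its
recovery of known ground truth measured — without any physical data.

## The model

**Dose engine.** Dose around the source follows the AAPM TG-43 formalism

$$\dot D(r,\theta) = S_K\,\Lambda\,\frac{G(r,\theta)}{G(r_0,\theta_0)}\,g(r)\,F(r,\theta),$$

with $S_K$ numerically equal to the RAKR in U, geometry function
$G = 1/r^2$ (point) or $\beta/(L r \sin\theta)$ (line), radial dose
function $g$, anisotropy function $F$, and reference point
$r_0 = 1$ cm, $\theta_0 = 90°$. The reference plan (13 dwells per
catheter, 5 mm steps, catheters 40 mm apart) solves one uniform dwell
time so the control point at the RPLD centre receives exactly 2 Gy; by
design the RPLD sensitive volume then sits in a low-gradient region
(D_min 1.99, D_max 2.00, D_mean 2.00 Gy).

**Dose determination.** The audit setup is neither full-scatter nor
water-equivalent, so the measured dose is

$$D = M \times N \times k_Q \times k_s \times k_m,$$

where $M$ is the background-, sensitivity-, fading- and tray-corrected
RPLD signal, $N$ the ⁶⁰Co calibration coefficient, and $k_s$ (lack of
scatter), $k_m$ (phantom material) and $k_Q$ (beam quality) are measured
as ratios of mean doses between experimental setups. The total factor
averages experimental and Monte-Carlo estimates:

$$k_{tot} = \frac{k_m^{exp}+k_m^{MC}}{2}\times\frac{k_s^{exp}+k_s^{MC}}{2}\times k_Q
\;=\; 1.029\ (^{192}\mathrm{Ir}),\quad 1.059\ (^{60}\mathrm{Co}).$$

**Uncertainty.** A GUM budget of ten relative standard uncertainties
combines in quadrature to 2.24 % (k = 1).

**Position check.** Each scanned film strip is reduced to a darkening
profile along the catheter; track edges are found at 50 % of the plateau
with sub-pixel interpolation, and the track bisection minus the fiducial
(marking the RPLD centre) is the source-position shift, classified
against ±3 / ±5 mm with a fixed ±0.3 mm analysis-procedure uncertainty.

## Worked example

Build the reference plan with the bundled generic ¹⁹²Ir dataset for a
source of 40 820 U (≈ 10 Ci):

```sh
$ brachyaudit plan --source ir192_generic --rakr 40820 --out plan.json
dwell time 3.95 s; D_min 1.993 / D_max 2.004 / D_mean 1.999 Gy
```

Each of the 26 dwells stops 3.95 s, and the dose across the RPLD
sensitive volume stays within 0.01 Gy of the 2 Gy prescription — a
delivery error of a millimetre or two will not masquerade as a RAKR
error. The uncertainty budget:

```sh
$ brachyaudit budget --coverage-k 2
...
combined (k=1): 2.24 %
expanded (k=2): 4.48 %
```

Simulate a 59-set multicentre cohort and summarize it:

```sh
$ brachyaudit simulate cohort --n-sets 59 --seed 42 --out cohort.csv
$ brachyaudit cohort-report --records cohort.csv --out report
59 sets: ratio 1.009 ± 0.011 [0.981, 1.038]; 58/59 within ±3 %; shift 0.7 ± 1.9 mm
```

The ratio here is measured audit dose over the centre's stated dose; a
healthy cohort scatters around 1 within the ≈ 2 % measurement
uncertainty. Film strips can be generated and analysed the same way
(`brachyaudit simulate film`, `brachyaudit analyze-film`), recovering an
injected track shift to a few tenths of a millimetre.

All commands are thin wrappers over the library
(`brachyaudit.tg43`, `.plan`, `.corrections`, `.rpld`, `.uncertainty`,
`.film`, `.cohort`, `.synthetic`); see `docs/methods.md` for the methods
and assumptions.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch through the package: the total correction
factors for ¹⁹²Ir and ⁶⁰Co from their published components, and the
minimum dose over the RPLD sensitive volume of the normalized reference
plan sampled at 0.1 mm.
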