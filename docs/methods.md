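# Methods

## The measurement problem

A wound contaminated with a heavy atom (the application of interest is
plutonium; the model contaminant is stable lead) can be interrogated with a
portable X-ray fluorescence (XRF) device pressed to the skin. The L-shell
fluorescence lines of the contaminant identify it and their intensities
quantify it — but blood oozing over the wound attenuates the fluorescence,
and the allowable X-ray dose to the wound bounds the acquisition time. The
package answers three questions from a single spectrum: how much blood lies
over the wound, how much contaminant is underneath, and what the smallest
detectable amount would have been at those conditions.

## Intensity model

The window-integrated gross intensity of an analyte line over a bleeding
wound is modelled as

    I(c, t, d) = I1 · e^(−µt) · d · c + I0 · d

with

| symbol | meaning | units |
|---|---|---|
| c | contaminant concentration (mass fraction) | ppm |
| t | thickness of the blood layer | mm |
| d | maximal equivalent dose of the acquisition (∝ live time) | mSv |
| I1 | net line sensitivity at t = 0 | counts·mSv⁻¹·ppm⁻¹ |
| I0 | background rate in the line window | counts·mSv⁻¹ |
| µ | effective linear attenuation coefficient of blood at the line energy | mm⁻¹ |

Assumptions: the net signal and the device background are each strictly
proportional to live time (hence to d); the background originates in the
device and is **not** attenuated by the blood layer; µ is a single
*effective* exponential constant per line that lumps incident-beam and
fluorescence-path attenuation (no two-path geometry).

Peak intensities are window integrals, not Gaussian fits: each L line is a
cluster of unresolved subcomponents (Lα₁/Lα₂; Lβ₁–Lβ₄) with an asymmetric
composite shape. Default windows are Pb Lα [10.2, 10.9) keV and
Pb Lβ [12.2, 13.0) keV — about ±0.35 keV around the 10.55 / 12.61 keV
centroids, wide enough for the subcomponent structure, configurable via a
JSON line file. Window membership is half-open on bin centers so window
integrals are exactly additive. Negative net intensities (possible at low
concentration) are recorded raw, reported clamped to 0 with a flag;
detectability is judged by the detection-limit machinery, not by the sign of
a net count.

## Calibration

From a labelled factorial phantom design (concentrations including blanks ×
thicknesses including dry × doses, replicated):

1. **Dry fit** (t = 0): per dose level, ordinary least squares of gross
   intensity on concentration; the per-dose slopes (I1·d) and intercepts
   (I0·d) are then regressed on d *through the origin* (both are strictly
   proportional to live time). Unweighted by default; inverse-variance
   (Poisson) weighting is available.
2. **Attenuation fit**: per line, net intensity relative to the dry cell
   within each (c, d) stratum, aggregated across strata by geometric mean at
   each thickness (log-space averaging matches the log-linear model), then a
   through-origin fit of log relative intensity on t gives µ per line.
   Cells with non-positive nets are excluded with a warning (the log is
   undefined and such cells carry almost no information).
3. **Ratio fit**: the Lα/Lβ net ratio obeys R(t) = R0·e^(−Δµt), a straight
   line in semi-log coordinates. The fit is weighted least squares of
   log(net_Lα/net_Lβ) on t over replicate-averaged (c, t, d) cells.
   Averaging replicates before the log suppresses the log-transform bias of
   low-count cells; the inverse-variance weights
   (var[log R] ≈ gross_Lα/net_Lα² + gross_Lβ/net_Lβ² per replicate, from
   Poisson statistics) keep those same cells from dominating the variance of
   Δµ. With equal weights the sampling noise of Δµ on the default design is
   about 8% — dominated entirely by the weakest cells — versus about 2.6%
   weighted; since the design genuinely contains that information, the
   weighted fit is the default.

Backgrounds during calibration come from the c = 0 blanks pooled over
thickness at each dose (the device background is thickness-independent);
thickness-matched blanks are available via `t_matched_background=True`.

A consistency diagnostic compares the directly fitted Δµ with µ_Lα − µ_Lβ
from the per-line fits, using the combined standard errors of the three
fits; agreement within 3 SE is the expected state of a healthy calibration.

## Field evaluation

For one spectrum at known dose d (dose rate × live time — supplied by the
operator, never inferred):

1. nets from calibration backgrounds: net = gross − I0·d (a real wound has
   no matched blank);
2. thickness t = ln(R0 / (net_Lα/net_Lβ)) / Δµ, clamped at 0 when the
   observed ratio exceeds R0;
3. concentration c = (gross_Lα − I0·d) / (I1·e^(−µ_Lα t)·d), clamped at 0.

If the Lβ (or Lα) net is non-positive the ratio is not estimable and the
evaluation falls back to an operator-supplied assumed thickness, default
0 mm. A zero assumption applies no attenuation correction and therefore
*underestimates* concentration when blood is present; the assessment carries
explicit flags so this anti-conservative default is never silent. The
assessment keeps both raw (signed) and clamped estimates.

## Detection limit

The MDL is the concentration whose expected net signal equals three times
the background standard deviation. Under pure counting statistics the
background SD in the Lα window is √(I0·d), so

    MDL(d, t) = 3·√(I0·d) / (I1·e^(−µ_Lα t)·d)  ∝  d^(−1/2) · e^(µ_Lα t).

Only the Lα line is used: the Mo Kα Compton tail of the device inflates the
background under the Lβ window. No over-dispersion term is added and no
separate critical-level/detection-level distinction is made — the 3σ rule
is applied as stated. `empirical_mdl` re-derives the limit by simulating
blank acquisitions and measuring the background SD directly; it is the
package's independent oracle for the closed form. Note a useful identity:
the verdict `c_est ≥ MDL(t_est, d)` reduces to `net_Lα ≥ 3√(I0·d)`, so the
false-positive rate is insensitive to errors in the thickness estimate.

## Radiochemistry conversions

Dose ↔ time: d = 3.3 mSv/s × accumulation time by default, reproducing
16.5/33.0/49.5/66.0 mSv at 5/10/15/20 s. The manual's "less than 16.5 mSv
per 5 s" bound is treated as the working equality, which is why every dose
is labelled *maximal*.

Concentration → amount: the interrogated volume is the 8-mm beam footprint
through the 10-mm phantom depth at density 1.06 g/cm³ (0.503 cm³, 0.533 g);
1.2 ppm of lead is then 3.09 nmol. Amount → activity: A = (ln 2/T½)·n·N_A
with Julian years (3.15576×10⁷ s); 3.1 nmol of ²³⁹Pu (T½ = 24 110 y) is
1.70 kBq. Mapping a lead-scale concentration onto a radionuclide goes
through the *number of atoms*: lead molar mass (207.2 g/mol) in the amount
step, the nuclide's decay constant in the activity step — XRF counts atoms,
and the atom count is what transfers between elements of similar L-line
response. Nuclide constants ship in a small built-in table (standard
nuclear data, not fitted).

## Synthetic spectra

The simulator emulates the phantom study: an exponential continuum
(246·e^(−E/10 keV) counts·keV⁻¹·mSv⁻¹) plus narrow Gaussian device lines
(Ni Kα/Kβ, Mo Kα/Kβ, Ag Kα/Kβ) and broad Compton humps ~1 keV below the Mo
lines (σ = 1.8 keV), all scaling with d and independent of t; Pb Lα/Lβ
Gaussians (σ = 0.15 keV) whose *window-integrated* emission is exactly
I1·e^(−µt)·d·c (amplitudes are normalised within the integration window, so
configured truth and fitted constants live on the same scale); independent
Poisson noise per 0.02-keV bin over 0–40 keV.

Default truth: I1_Lα = 6.0, I1_Lβ = 4.0 counts·mSv⁻¹·ppm⁻¹; the continuum
level puts I0 ≈ 60.5 counts/mSv in the Lα window, placing the closed-form
MDL at (t = 0.5 mm, d = 16.5 mSv) near 1.2 ppm; µ_Lα = 0.45, µ_Lβ =
0.27 mm⁻¹ (water-like effective values at 10.6/12.6 keV); dose rate
3.3 mSv/s. The Mo Kα Compton amplitude (800 counts/mSv) makes the Lβ-window
background (~70 counts/mSv) exceed the Lα-window background, as the real
device's spectra show. Absolute count magnitudes are plausible for a
silicon-drift portable unit but are not calibrated to any physical device.

The default design is 6 concentrations × 5 thicknesses × 4 doses × 4
replicates = 480 spectra over 120 cases. Per-measurement seeds derive from
(master seed, case index, replicate), so enlarging the replicate count never
perturbs earlier draws.

What the simulator does **not** model: detector response artefacts (escape
peaks, pile-up, efficiency roll-off), secondary fluorescence and full
transport, energy-calibration drift, matrix differences between epoxy and
tissue, or any attenuation of the device background by the blood layer.
Passing tests therefore demonstrate the statistical soundness of the
estimation chain under the stated model, not device-level accuracy on real
wounds.

## Numerical and statistical choices

* Bias studies use the raw (unclamped) estimates; clamping is a reporting
  policy for physical outputs, and at t = 0 or c = 0 it necessarily
  introduces a positive reporting bias of order the estimator's σ.
* Quantification accuracy is assessed at grid level (mean bias over all
  cells with c ≥ 5 ppm, 50 noisy replicates each: ≈ +2% in c, ≈ −0.02 mm in
  t). Weak cells (c = 5 ppm at d = 16.5 mSv) are individually noisy — the
  single-measurement thickness σ reaches ~1.4 mm at t = 2 mm because
  Δµ = 0.18 mm⁻¹ is small — and the exp(µ·t_est) correction then carries an
  irreducible Jensen-type inflation of c at those cells (~+20%). This is a
  property of the estimator at low counts, not a defect of the fits; raising
  dose or concentration removes it.
* Monte-Carlo test sizes: 20 independent calibrations for parameter
  recovery; 50 replicates per grid cell for bias; 100–500 replicates for
  rate and oracle checks. These sizes keep each statistical assertion at
  ≥3 SE resolution while the full suite runs in well under a minute.
* Degenerate inputs: fits refuse designs missing blanks, the dry reference,
  or a second level of any swept variable, with errors naming the missing
  condition; adversarial data with inverted attenuation ordering fit
  successfully but trip a warning and the Δµ-consistency diagnostic.

## Known limitations

* Effective-µ lumping means fitted µ values are device-geometry-specific
  and not transferable tabulated attenuation coefficients.
* The thickness estimator degrades quickly once the Lβ net intensity
  approaches the background noise; the fallback assumed thickness is then
  the operator's responsibility.
* Uncertainties are carried as per-fit diagnostics only; they are not
  propagated into the concentration estimate.
* The lead→plutonium crosswalk assumes equal atom-count sensitivity between
  the model and target elements; a plutonium-phantom calibration would
  replace it for real use.
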