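# Methods

`optidens` implements a complete time-domain diffuse optical spectroscopy
(TD-DOS) analysis chain for breast tissue, together with a synthetic cohort
generator that emulates the in vivo measurement protocol it was designed
for.  This note records the models, the numerical choices, and what the
synthetic data can and cannot establish.

## Photon-migration forward model

Light transport is described by the diffusion equation (DE) for a
homogeneous medium with refractive index `n` (default 1.4; the tissue value
is not known per subject and is configurable).  The diffusion coefficient is
`D = 1/(3 musp)`, deliberately absorption-independent: with this modern
convention absorption enters the time-domain Green's function exactly as the
Beer–Lambert factor `exp(-mua * v * t)`, a property the test suite checks to
machine precision and that the fitting machinery implicitly relies on.

Boundaries are handled with extrapolated boundary conditions: a zero-fluence
plane at distance `ze = 2 A D` outside each physical surface, where the
boundary factor `A(n)` is computed from the Groenhuis–Ferwerda–Ten Bosch
polynomial approximation of the internal-reflection Fresnel integrals
(`A(1.4) ≈ 3.25`).  Two geometries are implemented by the method of images:

* **semi-infinite reflectance** (source–detector distance `rho`): one
  dipole pair — the isotropic source at depth `z0 = 1/musp` and its negative
  image at `-(z0 + 2 ze)`;
* **infinite slab transmittance** (thickness `d`, lateral offset
  configurable, default 0 — the protocol's 1–1.5 cm probe displacement can
  be emulated): the symmetric image-source series, summed in pairs
  `m = 0, ±1, ±2, …` until the next pair changes every channel by less than
  `1e-9` relative (cap 50 pairs).

The detected quantity is the normal photon flux at the boundary (Fick's
law).  The absolute scale is irrelevant downstream — every fit carries a
free amplitude — but the time integral of the reflectance curve equals the
closed-form continuous-wave (CW) dipole reflectance, which serves as an
independent quadrature oracle (agreement required within 1%, observed at
~1e-14 on the default axis).

The model curve is convolved with the instrument response function (IRF) by
discrete linear convolution scaled by the channel width, causally truncated
to the axis length.  The TCSPC axis defaults to 4096 channels × ~6.1 ps,
one 40 MHz laser repetition period (25 ns); channel width is configurable
and analyses in the tests run on coarser axes (e.g. 1024 × 25 ps) purely as
a problem-size choice.

Known model limits: near the 970 nm water peak of dense breasts
`mua` is no longer ≪ `musp` and the DE coupling biases the scattering
estimate, which is why the power-law initialisation below uses only
600–900 nm.  No layered media, no radiative-transfer corrections, no Monte
Carlo.

## Curve fitting

Both fitting procedures minimise a count-weighted least-squares objective
with per-channel weights `1/max(counts, 1)` — the Gaussian approximation to
Poisson counting statistics, the TCSPC standard — restricted to the fit
window running from 80% of the pulse peak on the leading edge to 5% of the
peak on the falling edge.  Windows narrower than 10 channels are refused.
A free multiplicative amplitude per DTOF absorbs the unknown
wavelength-dependent throughput; area normalisation is available behind a
flag.  No timing-shift parameter is fitted by default (the IRF carries the
system delay); an optional global shift exists in the standard fit.

* **Standard fit**: each wavelength independently, free parameters
  `(mua, musp)` with bounds `mua ∈ [1e-4, 1]`, `musp ∈ [1, 50]` cm⁻¹, the
  amplitude profiled out in closed form.
* **Spectrally-constrained fit**: all usable wavelengths at once, with
  `mua(λ) = Σ εᵢ(λ) Cᵢ + B` (Lambert–Beer over HbO2, Hb, water, lipid,
  collagen plus a wavelength-independent background absorber of unit
  extinction) and `musp(λ) = a (λ/λ₀)^(-b)`, `λ₀ = 600 nm`, substituted
  into the DE.  The per-wavelength amplitudes are profiled out (variable
  projection), leaving a bounded 8-parameter problem — equivalent optimum,
  far better conditioned than carrying ~51 amplitudes as free unknowns.

Optimisation uses bounded trust-region least squares (`scipy`'s `trf`) with
relative-objective convergence at `1e-8` (500 evaluation cap); fits are
deterministic given the data.  Non-convergence is flagged, never raised.
DTOFs with fewer than 1000 total counts are excluded with a reason code
(configurable threshold); a spectral fit requires at least 20 usable
wavelengths.  Initialisation, unless a starting composition is supplied:
standard fits per wavelength, non-negative unmixing (NNLS) of the resulting
`mua` spectrum on the extinction spectra plus a constant column for the
background, and a log–log line fit of `musp` over 600–900 nm for `(a, b)`.

Units are fixed throughout: µM for the hemoglobins, mg/cm³ for water, lipid
and collagen, cm⁻¹ for the background term, `a` in cm⁻¹ at 600 nm, `b`
dimensionless.

## Extinction library

The bundled 1 nm extinction grids over 600–1100 nm are **synthetic model
spectra**: sums of Gaussian bands and exponential edges placed at each
chromophore's canonical landmarks (water 970 nm, lipid 930 nm, Hb 758 nm,
an ~800 nm isosbestic region, collagen's short-wavelength rise and broad
~1030 nm band), with amplitudes chosen so protocol-typical compositions
yield breast-like absorption (`mua` ~ 0.03–0.3 cm⁻¹).  They are smooth,
non-negative, well conditioned — and not a published compilation.  The
library is swappable (`default_library(directory)`), file headers carry the
provenance, and evaluation is linear interpolation only; extrapolation
outside the grid span is an error, because real extinction spectra are
sharply structured and silent extrapolation corrupts fits.  Recovered
*absolute* concentrations on real data depend entirely on the extinction
compilation used; everything the tests establish is about the machinery,
not about spectral provenance.

## Derived indices

From a fitted composition: `tHb = HbO2 + Hb` (µM), `SO2 = HbO2/tHb`
(fraction; undefined and refused at `tHb = 0`),
`OI = water · collagen · b / lipid` (undefined at zero lipid) and
`CI = collagen · b`.  OI and CI are reported raw and unnormalised.

## Synthetic cohort generator

The generator is calibrated to the in vivo campaign's printed summary
statistics and emulates its protocol exactly: per subject, 18 spectral
acquisitions of 51 wavelengths (600:10:1100 nm) — sitting reflectance at 2
and 3 cm plus compressed cranio-caudal transmittance per breast, and supine
reflectance on the outer/lower/inner quadrants at both distances per
breast.

Constituent truths are drawn from truncated normals whose cohort mean/SD
are *moment-matched* to the printed values: the supine 3 cm quadrant
marginals use the printed quadrant statistics directly (water 314±189 /
279±180 / 228±145 mg/cm³ outer/lower/inner, and correspondingly for lipid
and collagen); the 2 cm marginals scale them by the printed overall
2-vs-3 cm ratios; sitting reflectance reuses the inner-quadrant marginal
(the sitting configuration retrieves the most adipose tissue); the
transmittance truth is the subject's 3 cm quadrant average with ~5%
independent jitter for the different probed volume.  Where a target SD
exceeds what a truncated normal can support on its range (the breast
thickness marginal), the closest achievable moments are used.

Within-subject structure comes from a Gaussian copula: one latent density
factor per subject (loading 0.8), a per-position factor (0.1) and
idiosyncratic noise (0.1), giving a quadrant correlation of 0.8 and near
left/right symmetry.  Lipid loads the density factor negatively.  Blood and
scattering truths are not printed in the source campaign, so they are
plausible, trend-faithful defaults: `tHb ~ N(15, 5)` µM truncated above 2,
`SO2 ~ N(0.75, 0.08)` in [0.4, 1], `a ~ N(12, 3)` cm⁻¹ in [5, 25],
background `~ N(0.018, 0.01)` in [0, 0.06] cm⁻¹, and
`b = 1.6 − 1.2 · lipid-fraction + N(0, 0.05)` clipped to [0.2, 1.6], which
reproduces the strong negative lipid–b coupling.  Transmittance scales
`tHb` by 0.7 (compression reduces breast blood volume) and `a` by 1.2
(amplitudes are observed noticeably higher in transmittance); slab
thickness is 0.85 × a per-subject draw from the 11–37 mm thickness range.

Histograms are simulated by scaling the IRF-convolved forward curve to a
total-count target (1e6 reflectance, 1e5 transmittance per DTOF,
emulating the 1 s integration with per-wavelength power optimisation) and
drawing per-channel Poisson counts.  Dense-archetype subjects get their
transmittance target attenuated ×0.005, pushing those DTOFs under the SNR
threshold — emulating the transmittance SNR failures observed in vivo for
the densest breasts.  The synthetic IRF is a Gaussian (FWHM 150 ps)
convolved with a 100 ps single-exponential tail, area-normalised; the real
system's IRF is dominated by fibre dispersion and detection, not the ~10 ps
laser pulse, so this is a modelled, configurable choice.  All randomness is
seeded; a cohort is bit-reproducible from one master seed.

What the generator does **not** emulate: anatomy (no 3D breast, no chest
wall layer), probe-pressure and motion artefacts, detector afterpulsing and
dark counts, wavelength-dependent IRF shape, and any model mismatch between
tissue and the homogeneous DE.  Passing round-trip tests therefore shows
the inversion is correct and well-conditioned *under the model the data
were generated from*; it does not bound errors on real tissue, where the
homogeneous model itself is the dominant approximation.

## Statistics

The comparison layer mirrors the study design: Pearson `r` with the exact
t-transform p-value (n−2 df) between transmittance and each of the four
reflectance configurations for seven parameters (28-cell report, Bonferroni
family = the report by default; raw p always retained alongside, since the
family size behind the original analysis is not stated and the correction
is conservative for correlated tests); Wilcoxon matched-pairs signed-rank
tests on breast-averaged subject values with exact two-sided p by full sign
enumeration for n ≤ 25 (computed by the subset-sum convolution equivalent,
midranks for ties) and the tie-corrected normal approximation above; and a
density ranking keyed on ascending OI in a reference configuration
(default: supine, right breast, outer quadrants, 3 cm), with per-column
Spearman (or Kendall) rank concordance and the lipid column entered with
inverted polarity.  Breast averaging precedes subject-level tests, and can
be disabled for left-vs-right analyses.

## Verification strategy

Every numerical component is checked against an independent oracle:
CW closed form vs time quadrature; brute-force O(N²) convolution; direct
high-order evaluation of the image series; full 2^n sign enumeration for
the signed-rank test; hand-computed values for interpolation, Lambert–Beer
sums, the power law and the indices.  The pipeline's master oracle is the
end-to-end round trip: noiseless simulated acquisitions are recovered by
the spectral fit within 1% (collagen 5%), the phantom (mua 0.05 cm⁻¹,
musp 10 cm⁻¹ at 800 nm) is recovered from Poisson data at 1e6 counts within
5%/10%, and seeded cohorts of 50–200 subjects reproduce the directional in
vivo findings (outer > inner and 3 cm > 2 cm water, transmittance–
reflectance water/lipid correlations > 0.8, OI ranking concordance > 0.8).
Round-trip and recovery tests run on reduced problem sizes (26-wavelength
grids, 1024-channel axes) chosen to keep the full suite fast while leaving
every wavelength's window well resolved.
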