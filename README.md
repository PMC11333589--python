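# optidens

Time-domain diffuse optical spectroscopy (TD-DOS) of breast tissue:
forward photon-migration models, IRF-convolved curve fitting,
spectrally-constrained retrieval of tissue composition, optical
breast-density indices, and the statistics used to compare measurement
configurations — plus a protocol-faithful synthetic cohort generator so the
whole chain is testable without any measurement data.

## The problem

Breast density — the proportion of fibro-glandular (water- and
collagen-rich) versus adipose tissue — is a major independent breast-cancer
risk factor, conventionally graded from X-ray mammograms.  TD-DOS offers a
non-ionising alternative: picosecond light pulses are injected into the
breast over 600–1100 nm and the distribution of photon times of flight
(DTOF) is recorded at each wavelength with time-correlated single photon
counting.  The temporal shape separates absorption from scattering, and the
absorption spectrum separates the tissue constituents.  `optidens` is aimed
at researchers building or evaluating such protocols: it implements the
analysis chain for a measurement session comprising reflectance
(source–detector distance ρ = 2 or 3 cm, sitting and supine, at three
breast quadrants) and mildly-compressed transmittance acquisitions — 18
spectra of 51 wavelengths per subject.

## The model

Each DTOF is fitted with the diffusion-equation solution for a
semi-infinite medium (reflectance) or an infinite slab (transmittance) with
extrapolated boundary conditions, convolved with the measured instrument
response function, over the window from 80% of the pulse peak (leading
edge) to 5% (falling edge):

* **standard fit** — per wavelength, free (μa, μ's);
* **spectrally-constrained fit** — all wavelengths at once, substituting

      μa(λ) = Σᵢ εᵢ(λ) Cᵢ + B          (Lambert–Beer + background)
      μ's(λ) = a (λ/λ₀)^(−b),  λ₀ = 600 nm   (Mie-type power law)

  so the free parameters are the concentrations of water, lipid, collagen,
  HbO₂ and Hb, the background absorber B, and the scattering amplitude and
  power (a, b).

Derived quantities: total hemoglobin `tHb = HbO₂ + Hb`, saturation
`SO₂ = HbO₂/tHb`, and the density indices

    OI = [water]·[collagen]·b / [lipids]        CI = [collagen]·b

which rise with the fibro-glandular fraction.  A statistics layer provides
Pearson correlations between configurations, exact Wilcoxon matched-pairs
signed-rank tests, Bonferroni adjustment, and an OI-keyed subject density
ranking with rank-concordance scores.

The bundled extinction spectra are synthetic model spectra (landmark bands
at the canonical wavelengths); swap in measured compilations via
`default_library(directory)` for quantitative work on real data.  See
`docs/methods.md` for models, parameters and limitations.

## Worked example

```python
import numpy as np
from optidens import *
from optidens.forward_model import OpticalPropertiesAtWavelength
from optidens.inversion import spectral_fit, standard_fit
from optidens.synthetic_cohort import (
    AcquisitionLabel, SimulationConfig, sample_subject, simulate_session,
    synthetic_irf,
)

# 1. Calibration-phantom round trip (mua = 0.05, mu's = 10 cm^-1 at 800 nm)
axis, medium = TimeAxis(), MediumModel()
geo = Geometry("reflectance", rho=2.0)
irf = synthetic_irf(axis)
curve = td_forward(OpticalPropertiesAtWavelength(0.05, 10.0), geo, medium, axis)
lam = convolve_with_irf(curve, irf, axis)
counts = np.random.default_rng(1).poisson(np.maximum(lam / lam.sum() * 1e6, 0))
fit = standard_fit(DTOF(800.0, counts, axis), irf, geo)
print(f"phantom: mua = {fit.parameters['mua']:.4f}, musp = {fit.parameters['musp']:.2f}")

# 2. Simulate one subject's 18-spectrum session and fit one acquisition
config = SimulationConfig(time_axis=TimeAxis(n_channels=1024, dt=25e-12))
subject = sample_subject(7)
session = simulate_session(subject, config)
acq = next(a for a in session.acquisitions
           if a.metadata["position"] == "O" and a.metadata["distance_cm"] == 3.0
           and a.metadata["breast"] == "R")
result = spectral_fit(acq, default_library())
comp, idx = result.composition, derive_indices(result.composition)
print(f"water {comp.c_water:.1f}, lipid {comp.c_lipid:.1f}, "
      f"collagen {comp.c_collagen:.1f} mg/cm^3, OI = {idx.oi:.1f}")
```

prints (the generating truth for this seed is water 313.6, lipid 469.9,
collagen 64.3 mg/cm³):

```
phantom: mua = 0.0499, musp = 10.00
water 314.4, lipid 469.2, collagen 63.1 mg/cm^3, OI = 37.5
```

The phantom's optical properties are recovered within 0.2% here (the
acceptance tolerances are 5% on μa and 10% on μ's over Poisson replicates),
and the spectral fit recovers the subject's generating composition to
within ~2% from noisy simulated histograms.

The same pipeline runs from the shell:

```bash
optidens simulate --subjects 20 --seed 1 --out sessions/
optidens fit --in sessions/ --mode spectral --out tables/
optidens analyze --tables tables/ --report report/
optidens report --tables tables/ --out summary/
```

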