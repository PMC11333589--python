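"""Shared round-trip fixtures: noiseless DTOFs/acquisitions at known truth."""

import numpy as np

from optidens.forward_model import (
    DTOF,
    OpticalPropertiesAtWavelength,
    SpectralAcquisition,
    convolve_with_irf,
    td_forward,
)
from optidens.inversion import TissueComposition
from optidens.synthetic_cohort import expected_curve

#: protocol-typical composition (values inside the in vivo ranges)
TRUTH = TissueComposition(
    c_hbo2=15.0, c_hb=5.0, c_water=300.0, c_lipid=600.0, c_collagen=60.0,
    background=0.018, a=12.0, b=0.8,
)
REDUCED_WAVELENGTHS = np.arange(600.0, 1101.0, 20.0)  # 26-point grid


def noiseless_dtof(mua, musp, geometry, medium, irf, axis, total=1e7):
    curve = td_forward(OpticalPropertiesAtWavelength(mua, musp), geometry, medium, axis)
    model = convolve_with_irf(curve, irf, axis)
    counts = np.round(np.maximum(model / model.sum() * total, 0.0)).astype(int)
    return DTOF(800.0, counts, axis)


def noiseless_acquisition(comp, geometry, medium, irf, axis, library,
                          wavelengths=REDUCED_WAVELENGTHS, total=1e7):
    curves = expected_curve(comp, np.asarray(wavelengths), geometry, medium, irf, axis, library)
    counts = np.round(np.maximum(curves / curves.sum(axis=1, keepdims=True) * total, 0.0))
    dtofs = [DTOF(float(w), c.astype(int), axis) for w, c in zip(wavelengths, counts)]
    return SpectralAcquisition(dtofs=dtofs, irf=irf, geometry=geometry, time_axis=axis)
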