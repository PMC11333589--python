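"""Blood parameters and optical density indices derived from a tissue fit.

Breast density -- the proportion of fibro-glandular (water/collagen-rich)
versus adipose tissue -- is summarised by two composite indices built from
the spectrally-fitted composition:

* Optical Index   OI = [water] * [collagen] * b / [lipids]
* Collagen Index  CI = [collagen] * b

with concentrations in mg/cm^3 and b the dimensionless scattering power.
Both rise with density; OI additionally penalises adipose content.  Blood
parameters are total hemoglobin tHb = HbO2 + Hb (uM) and oxygen saturation
SO2 = HbO2 / tHb (reported as a fraction in [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from optidens.inversion import TissueComposition


@dataclass(frozen=True)
class DerivedIndices:
    thb: float
    so2: float
    oi: float
    ci: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.so2 <= 1.0:
            raise ValueError(f"SO2 must lie in [0, 1], got {self.so2}")
        if self.thb < 0 or self.oi < 0 or self.ci < 0:
            raise ValueError("tHb, OI and CI must be non-negative")


def blood_params(c_hbo2: float, c_hb: float) -> tuple[float, float]:
    """(tHb, SO2) from oxy- and deoxy-hemoglobin concentrations (uM).

    Raises for tHb = 0, where saturation is undefined.
    """
    if c_hbo2 < 0 or c_hb < 0:
        raise ValueError("hemoglobin concentrations must be non-negative")
    thb = c_hbo2 + c_hb
    if thb == 0.0:
        raise ValueError("SO2 undefined at zero total hemoglobin")
    return thb, c_hbo2 / thb


def density_indices(comp: "TissueComposition") -> tuple[float, float]:
    """(OI, CI) = (water*collagen*b/lipid, collagen*b).

    OI is undefined (raises) at zero lipid concentration; CI is always
    defined.  Note the identity CI = OI * lipid / water for water > 0.
    """
    ci = comp.c_collagen * comp.b
    if comp.c_lipid <= 0.0:
        raise ValueError("OI undefined at zero lipid concentration")
    oi = comp.c_water * comp.c_collagen * comp.b / comp.c_lipid
    return oi, ci


def derive_indices(comp: "TissueComposition") -> DerivedIndices:
    """Full DerivedIndices record for one fitted composition."""
    thb, so2 = blood_params(comp.c_hbo2, comp.c_hb)
    oi, ci = density_indices(comp)
    return DerivedIndices(thb=thb, so2=so2, oi=oi, ci=ci)
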