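"""Chromophore extinction spectra and composition of tissue optical spectra.

The absorption spectrum of breast tissue in the 600-1100 nm window is modelled
as a Lambert-Beer sum over five constituents -- oxy-hemoglobin (HbO2),
deoxy-hemoglobin (Hb), water, lipid and collagen -- plus a wavelength
independent *background* absorber of unitary extinction (epsilon = 1 cm^-1 at
every wavelength) whose "concentration" (cm^-1) soaks up unmodelled
chromophores:

    mua(lambda) = sum_i eps_i(lambda) * C_i  +  B

Concentration units are fixed: uM for the hemoglobins, mg/cm^3 for water,
lipid and collagen, cm^-1 for the background term.  The reduced scattering
spectrum follows the empirical Mie-type power law

    musp(lambda) = a * (lambda / lambda0)^(-b),   lambda0 = 600 nm

with amplitude ``a`` (cm^-1, the value at the reference wavelength) tied to
the density of scattering centres and power ``b`` (dimensionless) to their
size.

The bundled extinction grids are *synthetic model spectra* (see
:func:`synthetic_extinction`): smooth Gaussian/exponential line-shape models
placed at the canonical landmark features of each chromophore (water peak at
970 nm, lipid at 930 nm, Hb at 758 nm, ~800 nm isosbestic point, collagen
short-wavelength rise and ~1030 nm band).  They are physically plausible and
well conditioned, but they are not a published compilation; the library is
swappable, so quantitative work on real measurements should load measured
extinction tables through :func:`load_extinction_csv`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from optidens.inversion import TissueComposition

#: canonical chromophore names and declared concentration units
CHROMOPHORE_UNITS: Mapping[str, str] = {
    "HbO2": "uM",
    "Hb": "uM",
    "water": "mg/cm^3",
    "lipid": "mg/cm^3",
    "collagen": "mg/cm^3",
    "background": "cm^-1",
}

#: default reference wavelength of the scattering power law (nm)
LAMBDA0_NM = 600.0

#: the acquisition wavelength grid of the measurement protocol (51 points)
PROTOCOL_WAVELENGTHS_NM = np.arange(600.0, 1101.0, 10.0)

_CANONICAL = {name.lower(): name for name in CHROMOPHORE_UNITS}


def _canonical_name(name: str) -> str:
    try:
        return _CANONICAL[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown chromophore {name!r}; expected one of {sorted(CHROMOPHORE_UNITS)}"
        ) from None


@dataclass(frozen=True)
class ExtinctionRecord:
    """One chromophore's extinction spectrum on a strictly increasing nm grid.

    ``epsilon`` carries the specific absorption per unit concentration
    (cm^-1 per uM for hemoglobins, cm^-1 per mg/cm^3 for the tissue
    constituents, exactly 1 at every wavelength for the background absorber).
    """

    chromophore_name: str
    wavelength_grid: np.ndarray
    epsilon: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromophore_name", _canonical_name(self.chromophore_name))
        wl = np.asarray(self.wavelength_grid, dtype=float)
        eps = np.asarray(self.epsilon, dtype=float)
        if wl.ndim != 1 or wl.shape != eps.shape:
            raise ValueError("wavelength_grid and epsilon must be 1-D and equally long")
        if wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength_grid must be strictly increasing with >= 2 points")
        if np.any(eps < 0) or not np.all(np.isfinite(eps)):
            raise ValueError("epsilon must be finite and non-negative")
        if self.chromophore_name == "background" and not np.allclose(eps, 1.0, rtol=0, atol=0):
            raise ValueError("background record must have epsilon == 1 at every grid point")
        object.__setattr__(self, "wavelength_grid", wl)
        object.__setattr__(self, "epsilon", eps)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavelength_grid[0]), float(self.wavelength_grid[-1])


@dataclass
class ChromophoreLibrary:
    """The full set of six extinction records used by the spectral fit."""

    records: dict[str, ExtinctionRecord]
    unit_registry: dict[str, str] = field(default_factory=lambda: dict(CHROMOPHORE_UNITS))

    def __post_init__(self) -> None:
        self.records = {_canonical_name(k): v for k, v in self.records.items()}
        missing = set(CHROMOPHORE_UNITS) - set(self.records)
        if missing:
            raise ValueError(f"library is missing chromophores: {sorted(missing)}")

    def __getitem__(self, name: str) -> ExtinctionRecord:
        return self.records[_canonical_name(name)]


def get_extinction(
    library: ChromophoreLibrary, name: str, wavelengths: Iterable[float]
) -> np.ndarray:
    """Evaluate one chromophore's extinction at ``wavelengths`` (nm).

    Linear interpolation on the stored grid; extrapolation outside the grid
    span is refused (extinction spectra are sharply structured and silent
    extrapolation would corrupt fits).
    """
    record = library[name]
    wl = np.atleast_1d(np.asarray(wavelengths, dtype=float))
    lo, hi = record.span
    if np.any(wl < lo) or np.any(wl > hi):
        raise ValueError(
            f"requested wavelengths outside the {record.chromophore_name} "
            f"grid span [{lo:g}, {hi:g}] nm (extrapolation refused)"
        )
    return np.interp(wl, record.wavelength_grid, record.epsilon)


def compose_mua(
    composition: "TissueComposition",
    library: ChromophoreLibrary,
    wavelengths: Iterable[float],
) -> np.ndarray:
    """Absorption spectrum mua(lambda) = sum_i eps_i(lambda) C_i + B, in cm^-1.

    Exactly linear in the concentration vector and the background term.
    """
    wl = np.atleast_1d(np.asarray(wavelengths, dtype=float))
    conc = {
        "HbO2": composition.c_hbo2,
        "Hb": composition.c_hb,
        "water": composition.c_water,
        "lipid": composition.c_lipid,
        "collagen": composition.c_collagen,
    }
    for name, c in conc.items():
        if c < 0:
            raise ValueError(f"negative concentration for {name}: {c}")
    if composition.background < 0:
        raise ValueError(f"negative background term: {composition.background}")
    mua = np.full(wl.shape, float(composition.background))
    for name, c in conc.items():
        if c != 0.0:
            mua += c * get_extinction(library, name, wl)
    return mua


def compose_musp(
    a: float, b: float, wavelengths: Iterable[float], lambda0: float = LAMBDA0_NM
) -> np.ndarray:
    """Reduced scattering spectrum musp(lambda) = a (lambda/lambda0)^(-b), cm^-1."""
    if not a > 0:
        raise ValueError(f"scattering amplitude must be positive, got {a}")
    if not lambda0 > 0:
        raise ValueError(f"reference wavelength must be positive, got {lambda0}")
    if not np.isfinite(b):
        raise ValueError(f"scattering power must be finite, got {b}")
    wl = np.atleast_1d(np.asarray(wavelengths, dtype=float))
    if np.any(wl <= 0):
        raise ValueError("wavelengths must be positive")
    return a * (wl / lambda0) ** (-b)


# ---------------------------------------------------------------------------
# synthetic model spectra (bundled defaults)
# ---------------------------------------------------------------------------


def _gauss(wl: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def synthetic_extinction(name: str, wavelengths: Iterable[float]) -> np.ndarray:
    """Synthetic model extinction spectrum for one chromophore.

    These are smooth analytic stand-ins for measured compilations: sums of
    Gaussian bands and exponential edges placed at each chromophore's
    canonical landmarks, with amplitudes chosen so that protocol-typical
    compositions yield breast-like absorption (mua ~ 0.03-0.3 cm^-1 over
    600-1100 nm).  Units: cm^-1 per uM (HbO2, Hb), cm^-1 per mg/cm^3
    (water, lipid, collagen), exactly 1 (background).
    """
    wl = np.atleast_1d(np.asarray(wavelengths, dtype=float))
    name = _canonical_name(name)
    if name == "water":
        # dominant 970 nm band, weak 740/836 nm overtones, far-IR edge
        return (
            4.4e-4 * _gauss(wl, 970.0, 42.0)
            + 2.6e-5 * _gauss(wl, 740.0, 28.0)
            + 1.1e-5 * _gauss(wl, 836.0, 25.0)
            + 6.0e-4 * _gauss(wl, 1190.0, 80.0)
            + 2.0e-6
        )
    if name == "lipid":
        # 930 nm CH-overtone peak, 1040 nm band, weak 760 nm band
        return (
            1.25e-4 * _gauss(wl, 930.0, 28.0)
            + 4.5e-5 * _gauss(wl, 1040.0, 45.0)
            + 2.0e-5 * _gauss(wl, 760.0, 30.0)
            + 9.0e-5 * _gauss(wl, 1210.0, 60.0)
            + 1.5e-6
        )
    if name == "collagen":
        # short-wavelength rise plus broad ~1030 nm band
        return (
            2.0e-4 * np.exp(-(wl - 600.0) / 80.0)
            + 1.6e-4 * _gauss(wl, 1035.0, 55.0)
            + 4.0e-5 * _gauss(wl, 880.0, 60.0)
            + 5.0e-6
        )
    if name == "HbO2":
        # steep red edge, broad NIR plateau peaking ~920 nm
        return (
            8.0e-3 * np.exp(-(wl - 600.0) / 40.0)
            + 6.0e-4 * _gauss(wl, 920.0, 110.0)
            + 1.2e-4
        )
    if name == "Hb":
        # red edge, 758 nm deoxy band, slow NIR decay
        return (
            1.1e-2 * np.exp(-(wl - 600.0) / 55.0)
            + 9.0e-4 * _gauss(wl, 758.0, 22.0)
            + 1.5e-4 * np.exp(-(wl - 600.0) / 400.0)
            + 6.0e-5
        )
    if name == "background":
        return np.ones_like(wl)
    raise KeyError(name)  # pragma: no cover - _canonical_name already raised


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------


def load_extinction_csv(path: str | Path, chromophore_name: str | None = None) -> ExtinctionRecord:
    """Read one extinction table (``# provenance`` header lines, then
    ``wavelength_nm,epsilon`` columns)."""
    path = Path(path)
    provenance: list[str] = []
    name = chromophore_name
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ").strip()
                if body.lower().startswith("chromophore:") and name is None:
                    name = body.split(":", 1)[1].strip()
                else:
                    provenance.append(body)
                continue
            if line.lower().startswith("wavelength_nm"):
                continue
            w, e = line.split(",")
            rows.append((float(w), float(e)))
    if name is None:
        raise ValueError(f"{path}: no chromophore name in header and none given")
    arr = np.asarray(rows, dtype=float)
    return ExtinctionRecord(
        chromophore_name=name,
        wavelength_grid=arr[:, 0],
        epsilon=arr[:, 1],
        provenance="; ".join(provenance),
    )


def save_extinction_csv(record: ExtinctionRecord, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# chromophore: {record.chromophore_name}\n")
        for line in record.provenance.split("; "):
            if line:
                fh.write(f"# {line}\n")
        fh.write("wavelength_nm,epsilon\n")
        for w, e in zip(record.wavelength_grid, record.epsilon):
            fh.write(f"{w:.1f},{e:.8e}\n")


def _bundled_dir() -> Path:
    return Path(resources.files("optidens.data") / "extinction")


def default_library(directory: str | Path | None = None) -> ChromophoreLibrary:
    """Load the bundled (synthetic-model) extinction library.

    Pass ``directory`` to swap in measured extinction tables with the same
    CSV layout (one ``<name>*.csv`` file per chromophore).
    """
    directory = Path(directory) if directory is not None else _bundled_dir()
    records: dict[str, ExtinctionRecord] = {}
    for path in sorted(directory.glob("*.csv")):
        rec = load_extinction_csv(path)
        records[rec.chromophore_name] = rec
    return ChromophoreLibrary(records=records)


def synthetic_library(
    wavelengths: Iterable[float] | None = None,
) -> ChromophoreLibrary:
    """Build the synthetic-model library directly in memory (1 nm default grid)."""
    wl = (
        np.arange(600.0, 1100.0 + 0.5, 1.0)
        if wavelengths is None
        else np.asarray(wavelengths, dtype=float)
    )
    prov = "synthetic model spectrum (Gaussian/exponential landmark bands); not a measured compilation"
    records = {
        name: ExtinctionRecord(name, wl, synthetic_extinction(name, wl), prov)
        for name in CHROMOPHORE_UNITS
    }
    return ChromophoreLibrary(records=records)
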