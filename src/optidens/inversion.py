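"""Curve fitting of IRF-convolved diffusion models to DTOFs.

Two procedures, mirroring the study's dual analysis:

* :func:`standard_fit` -- each wavelength's DTOF is fitted independently to
  the diffusion-equation solution with (mua, musp) free;
* :func:`spectral_fit` -- all DTOFs of a spectrum are fitted at once, with
  the Lambert-Beer law for mua and the scattering power law for musp
  substituted into the DE, so the free parameters are the five constituent
  concentrations, the background absorber, and the scattering amplitude and
  power.

Both minimise a count-weighted least-squares objective (per-channel weights
1/max(counts, 1), the Gaussian approximation to Poisson counting statistics)
restricted to the fit window (80% of peak on the leading edge to 5% on the
falling edge).  A free multiplicative amplitude per DTOF absorbs the unknown
wavelength-dependent throughput; it is profiled out in closed form (variable
projection), so the spectral fit solves a bounded 8-parameter problem
regardless of the number of wavelengths.  Fits are deterministic given the
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np
import pandas as pd
from scipy.optimize import least_squares, nnls

from optidens.chromophores import (
    LAMBDA0_NM,
    ChromophoreLibrary,
    compose_musp,
    get_extinction,
)
from optidens.forward_model import (
    DTOF,
    FitWindow,
    Geometry,
    MediumModel,
    SpectralAcquisition,
    TimeAxis,
    convolve_with_irf,
    determine_fit_window,
    td_curves,
)

#: optimisation bounds (cm^-1, uM, mg/cm^3 as appropriate)
MUA_BOUNDS = (1e-4, 1.0)
MUSP_BOUNDS = (1.0, 50.0)
HEMOGLOBIN_BOUNDS = (0.0, 200.0)
WATER_LIPID_BOUNDS = (0.0, 1100.0)
COLLAGEN_BOUNDS = (0.0, 400.0)
BACKGROUND_BOUNDS = (0.0, 0.2)
A_BOUNDS = (1.0, 50.0)
B_BOUNDS = (0.0, 4.0)

#: DTOFs with fewer total counts are excluded from fitting (low SNR)
DEFAULT_SNR_MIN_COUNTS = 1000
#: minimum usable fit-window width, channels
MIN_WINDOW_CHANNELS = 10
#: minimum usable wavelengths for a spectral fit
MIN_SPECTRAL_WAVELENGTHS = 20


@dataclass(frozen=True)
class TissueComposition:
    """Spectral-fit parameter vector.

    Hemoglobins in uM, tissue constituents in mg/cm^3, background absorber
    in cm^-1, scattering amplitude ``a`` in cm^-1 at the reference
    wavelength ``lambda0`` (600 nm), scattering power ``b`` dimensionless.
    """

    c_hbo2: float
    c_hb: float
    c_water: float
    c_lipid: float
    c_collagen: float
    background: float = 0.0
    a: float = 10.0
    b: float = 1.0
    lambda0: float = LAMBDA0_NM

    def __post_init__(self) -> None:
        for name in ("c_hbo2", "c_hb", "c_water", "c_lipid", "c_collagen", "background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.a <= 0:
            raise ValueError("scattering amplitude must be positive")
        if not np.isfinite(self.b):
            raise ValueError("scattering power must be finite")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.c_hbo2,
                self.c_hb,
                self.c_water,
                self.c_lipid,
                self.c_collagen,
                self.background,
                self.a,
                self.b,
            ]
        )

    @classmethod
    def from_array(cls, theta: np.ndarray, lambda0: float = LAMBDA0_NM) -> "TissueComposition":
        return cls(*(float(v) for v in theta), lambda0=lambda0)


@dataclass
class FitResult:
    """Outcome of a standard or spectral fit.

    ``parameters`` holds the recovered values: ``{"mua", "musp",
    "amplitude"}`` for a standard fit; the spectral fit additionally fills
    ``composition`` and per-wavelength ``amplitudes``.  Non-convergence is
    flagged, never raised.  Excluded wavelengths carry a reason code.
    """

    parameters: dict[str, float] = field(default_factory=dict)
    composition: TissueComposition | None = None
    amplitudes: np.ndarray | None = None
    objective_value: float = np.inf
    converged: bool = False
    n_iterations: int = 0
    excluded_wavelengths: list[tuple[float, str]] = field(default_factory=list)
    fit_windows: list[FitWindow] = field(default_factory=list)
    per_wavelength: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.converged and not np.isfinite(self.objective_value):
            raise ValueError("converged results must have a finite objective value")


def _profiled_amplitude(
    y: np.ndarray, m: np.ndarray, w: np.ndarray, mode: str = "free"
) -> float:
    """Closed-form optimal multiplicative amplitude of a model curve.

    ``free``: weighted LS scale sum(w y m)/sum(w m^2); ``area``: ratio of
    windowed areas (the area-normalisation alternative).
    """
    if mode == "area":
        denom = m.sum()
        return float(y.sum() / denom) if denom > 0 else 0.0
    denom = float(np.sum(w * m * m))
    if denom <= 0.0:
        return 0.0
    return max(0.0, float(np.sum(w * y * m) / denom))


def _shift_curve(curve: np.ndarray, shift_channels: float) -> np.ndarray:
    """Shift a curve by a fractional number of channels (linear interp)."""
    if shift_channels == 0.0:
        return curve
    idx = np.arange(curve.shape[-1], dtype=float) - shift_channels
    return np.interp(idx, np.arange(curve.shape[-1], dtype=float), curve, left=0.0, right=0.0)


def standard_fit(
    dtof: DTOF,
    irf: np.ndarray,
    geometry: Geometry,
    init: tuple[float, float] | None = None,
    medium: MediumModel | None = None,
    snr_min_counts: int = DEFAULT_SNR_MIN_COUNTS,
    amplitude_mode: str = "free",
    fit_time_shift: bool = False,
    ftol: float = 1e-8,
    max_nfev: int = 500,
) -> FitResult:
    """Fit (mua, musp, amplitude) to one wavelength's DTOF.

    The IRF-convolved DE curve, scaled by a free amplitude, is matched to
    the measured counts over the 80%-5% window with Poisson-approximate
    weights.  ``init`` is an optional (mua, musp) starting point (defaults
    to (0.1, 10) cm^-1).  Low-SNR histograms are excluded (flagged, not
    raised); non-convergence is flagged.
    """
    medium = medium or MediumModel()
    if dtof.total_counts < snr_min_counts:
        return FitResult(
            excluded_wavelengths=[(dtof.wavelength, "low_snr")],
            converged=False,
        )
    window = determine_fit_window(dtof.counts)
    if window.n_channels < MIN_WINDOW_CHANNELS:
        raise ValueError(
            f"fit window has {window.n_channels} channels "
            f"(< {MIN_WINDOW_CHANNELS}): histogram too narrow to fit"
        )
    y = dtof.counts[window.slice].astype(float)
    w = 1.0 / np.maximum(y, 1.0)
    sqrtw = np.sqrt(w)
    axis = dtof.time_axis

    mua0, musp0 = init if init is not None else (0.1, 10.0)
    x0 = [mua0, musp0] + ([0.0] if fit_time_shift else [])
    lo = [MUA_BOUNDS[0], MUSP_BOUNDS[0]] + ([-50.0] if fit_time_shift else [])
    hi = [MUA_BOUNDS[1], MUSP_BOUNDS[1]] + ([50.0] if fit_time_shift else [])

    amplitude_box = [1.0]

    def residuals(theta: np.ndarray) -> np.ndarray:
        curve = td_curves(theta[0], theta[1], geometry, medium, axis)
        model = convolve_with_irf(curve, irf, axis)
        if fit_time_shift:
            model = _shift_curve(model, theta[2])
        m = model[window.slice]
        amp = _profiled_amplitude(y, m, w, amplitude_mode)
        amplitude_box[0] = amp
        return sqrtw * (y - amp * m)

    res = least_squares(
        residuals,
        x0=np.clip(x0, lo, hi),
        bounds=(lo, hi),
        method="trf",
        x_scale=[0.05, 10.0] + ([5.0] if fit_time_shift else []),
        ftol=ftol,
        xtol=1e-12,
        gtol=1e-12,
        max_nfev=max_nfev,
    )
    params = {
        "mua": float(res.x[0]),
        "musp": float(res.x[1]),
        "amplitude": amplitude_box[0],
    }
    if fit_time_shift:
        params["time_shift_channels"] = float(res.x[2])
    return FitResult(
        parameters=params,
        objective_value=float(2.0 * res.cost),
        converged=bool(res.status > 0),
        n_iterations=int(res.nfev),
        fit_windows=[window],
    )


def fit_all_wavelengths(
    acq: SpectralAcquisition,
    init: tuple[float, float] | None = None,
    medium: MediumModel | None = None,
    snr_min_counts: int = DEFAULT_SNR_MIN_COUNTS,
) -> pd.DataFrame:
    """Standard fit at every wavelength of an acquisition.

    Returns a DataFrame (wavelength, mua, musp, amplitude, converged,
    excluded) -- the per-wavelength optical-property spectrum.
    """
    rows = []
    for dtof in acq.dtofs:
        result = standard_fit(
            dtof, acq.irf, acq.geometry, init=init, medium=medium,
            snr_min_counts=snr_min_counts,
        )
        excluded = bool(result.excluded_wavelengths)
        rows.append(
            {
                "wavelength": dtof.wavelength,
                "mua": result.parameters.get("mua", np.nan),
                "musp": result.parameters.get("musp", np.nan),
                "amplitude": result.parameters.get("amplitude", np.nan),
                "converged": result.converged,
                "excluded": excluded,
            }
        )
    return pd.DataFrame(rows)


def _spectral_init(
    acq: SpectralAcquisition,
    library: ChromophoreLibrary,
    usable: list[DTOF],
    medium: MediumModel,
    extinction: np.ndarray,
) -> np.ndarray:
    """Starting composition from per-wavelength fits.

    Concentrations: non-negative linear unmixing (NNLS) of the standard-fit
    mua spectrum on the extinction spectra (background included as a
    constant column).  Scattering: log-log line fit of musp over 600-900 nm,
    where the power-law estimate is reliable.
    """
    spectra = []
    for dtof in usable:
        r = standard_fit(dtof, acq.irf, acq.geometry, medium=medium)
        if r.converged:
            spectra.append((dtof.wavelength, r.parameters["mua"], r.parameters["musp"]))
    if len(spectra) < 3:
        raise ValueError("too few convergent per-wavelength fits to initialise")
    wl, mua, musp = (np.asarray(v) for v in zip(*spectra))

    wl_to_row = {d.wavelength: i for i, d in enumerate(usable)}
    idx = [wl_to_row[w] for w in wl]
    design = np.column_stack([extinction[idx], np.ones(len(wl))])
    conc, _ = nnls(design, mua)

    lo_band = wl <= 900.0
    if lo_band.sum() >= 2:
        slope, intercept = np.polyfit(np.log(wl[lo_band] / LAMBDA0_NM), np.log(musp[lo_band]), 1)
    else:  # pragma: no cover - degenerate wavelength set
        slope, intercept = -1.0, np.log(10.0)
    theta = np.array(
        [conc[0], conc[1], conc[2], conc[3], conc[4], conc[5], np.exp(intercept), -slope]
    )
    return theta


def spectral_fit(
    acq: SpectralAcquisition,
    library: ChromophoreLibrary,
    init: TissueComposition | None = None,
    medium: MediumModel | None = None,
    snr_min_counts: int = DEFAULT_SNR_MIN_COUNTS,
    min_wavelengths: int = MIN_SPECTRAL_WAVELENGTHS,
    amplitude_mode: str = "free",
    ftol: float = 1e-8,
    max_nfev: int = 500,
) -> FitResult:
    """Spectrally-constrained global fit of a full acquisition.

    All usable DTOFs are fitted at once: at each wavelength the DE forward
    curve is evaluated at mua from the Lambert-Beer sum and musp from the
    power law, convolved with the IRF, amplitude-profiled, and compared to
    the counts over that wavelength's fit window.  Returns one
    :class:`TissueComposition`.
    """
    medium = medium or MediumModel()
    excluded: list[tuple[float, str]] = []
    usable: list[DTOF] = []
    for dtof in acq.dtofs:
        if dtof.total_counts < snr_min_counts:
            excluded.append((dtof.wavelength, "low_snr"))
        else:
            usable.append(dtof)
    if len(usable) < min_wavelengths:
        raise ValueError(
            f"only {len(usable)} usable wavelengths after SNR exclusion "
            f"(need >= {min_wavelengths})"
        )

    wavelengths = np.asarray([d.wavelength for d in usable])
    chromos = ("HbO2", "Hb", "water", "lipid", "collagen")
    extinction = np.column_stack(
        [get_extinction(library, name, wavelengths) for name in chromos]
    )
    windows = [determine_fit_window(d.counts) for d in usable]
    for d, win in zip(usable, windows):
        if win.n_channels < MIN_WINDOW_CHANNELS:
            raise ValueError(
                f"fit window at {d.wavelength:g} nm has {win.n_channels} channels "
                f"(< {MIN_WINDOW_CHANNELS})"
            )
    ys = [d.counts[w.slice].astype(float) for d, w in zip(usable, windows)]
    ws = [1.0 / np.maximum(y, 1.0) for y in ys]
    sqrtws = [np.sqrt(w) for w in ws]
    axis = acq.time_axis

    if init is not None:
        theta0 = init.as_array()
    else:
        theta0 = _spectral_init(acq, library, usable, medium, extinction)

    lo = np.array(
        [
            HEMOGLOBIN_BOUNDS[0], HEMOGLOBIN_BOUNDS[0],
            WATER_LIPID_BOUNDS[0], WATER_LIPID_BOUNDS[0], COLLAGEN_BOUNDS[0],
            BACKGROUND_BOUNDS[0], A_BOUNDS[0], B_BOUNDS[0],
        ]
    )
    hi = np.array(
        [
            HEMOGLOBIN_BOUNDS[1], HEMOGLOBIN_BOUNDS[1],
            WATER_LIPID_BOUNDS[1], WATER_LIPID_BOUNDS[1], COLLAGEN_BOUNDS[1],
            BACKGROUND_BOUNDS[1], A_BOUNDS[1], B_BOUNDS[1],
        ]
    )
    theta0 = np.clip(theta0, lo, hi)
    amps = np.ones(len(usable))

    def residuals(theta: np.ndarray) -> np.ndarray:
        mua = extinction @ theta[:5] + theta[5]
        musp = compose_musp(theta[6], theta[7], wavelengths)
        curves = td_curves(mua, musp, acq.geometry, medium, axis)
        models = convolve_with_irf(curves, acq.irf, axis)
        out = []
        for i, (win, y, w, sw) in enumerate(zip(windows, ys, ws, sqrtws)):
            m = models[i, win.slice]
            amp = _profiled_amplitude(y, m, w, amplitude_mode)
            amps[i] = amp
            out.append(sw * (y - amp * m))
        return np.concatenate(out)

    res = least_squares(
        residuals,
        x0=theta0,
        bounds=(lo, hi),
        method="trf",
        x_scale=[10.0, 10.0, 100.0, 100.0, 50.0, 0.01, 5.0, 0.5],
        ftol=ftol,
        xtol=1e-12,
        gtol=1e-12,
        max_nfev=max_nfev,
    )
    composition = TissueComposition.from_array(res.x)
    return FitResult(
        parameters={
            name: float(v)
            for name, v in zip(
                ("c_hbo2", "c_hb", "c_water", "c_lipid", "c_collagen",
                 "background", "a", "b"),
                res.x,
            )
        },
        composition=composition,
        amplitudes=amps.copy(),
        objective_value=float(2.0 * res.cost),
        converged=bool(res.status > 0),
        n_iterations=int(res.nfev),
        excluded_wavelengths=excluded,
        fit_windows=windows,
    )
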