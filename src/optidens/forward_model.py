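"""Time-resolved diffusion forward models and fit-window logic.

Photon migration through breast tissue is modelled with the diffusion
equation (DE) for a homogeneous medium, solved by the method of images with
*extrapolated boundary conditions*: a zero-fluence plane is placed a distance
``ze = 2 A D`` outside each physical boundary and satisfied by mirror image
sources.  Two geometries are supported, matching the measurement protocol:

* **reflectance** on a semi-infinite half-space at source-detector distance
  ``rho`` (one dipole pair: the real isotropic source at depth
  ``z0 = 1/musp`` and its negative image at ``-(z0 + 2 ze)``);
* **transmittance** through an infinite slab of thickness ``d`` (an infinite
  symmetric series of image-source pairs, truncated once converged).

The detected signal is the normal component of the photon flux (Fick's law)
at the boundary.  The diffusion coefficient is ``D = 1/(3 musp)``
(absorption-independent), so absorption enters the time-domain Green's
function exactly as the Beer-Lambert factor ``exp(-mua * v * t)``.

The model curve has arbitrary amplitude: in fitting, a free multiplicative
factor absorbs the unknown wavelength-dependent system throughput, and the
theoretical curve is convolved with the measured instrument response
function (IRF) before comparison with the TCSPC histogram.  The fitting
range runs from 80% of the pulse peak on the leading edge to 5% of the peak
on the falling edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.signal import fftconvolve

#: vacuum speed of light, cm/s
C_LIGHT_CM_S = 2.99792458e10

#: default TCSPC axis: 4096 channels x ~6.1 ps  ->  one 40 MHz repetition
#: period (25 ns)
DEFAULT_N_CHANNELS = 4096
DEFAULT_DT_S = 25.0e-9 / 4096


def boundary_reflection_factor(n: float) -> float:
    """Boundary factor A(n) from the internal-reflection Fresnel integrals.

    Uses the Groenhuis-Ferwerda-Ten Bosch polynomial approximation of the
    effective reflection coefficient,
    r_d = -1.440 n^-2 + 0.710 n^-1 + 0.668 + 0.0636 n, A = (1+r_d)/(1-r_d).
    A(1.0) ~= 1 (matched boundary); A(1.4) ~= 3.25.
    """
    if n <= 0:
        raise ValueError(f"refractive index must be positive, got {n}")
    r_d = -1.440 * n**-2 + 0.710 / n + 0.668 + 0.0636 * n
    return (1.0 + r_d) / (1.0 - r_d)


@dataclass(frozen=True)
class Geometry:
    """Probing geometry of one acquisition.

    ``mode`` is ``"reflectance"`` (semi-infinite medium, source-detector
    distance ``rho`` in cm; 2 or 3 cm in the protocol) or ``"transmittance"``
    (infinite slab of ``thickness`` cm -- the mildly compressed breast --
    with the detector on the opposite face at ``lateral_offset`` cm from the
    source axis).
    """

    mode: str
    rho: float | None = None
    thickness: float | None = None
    lateral_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("reflectance", "transmittance"):
            raise ValueError(f"unknown geometry mode {self.mode!r}")
        if self.mode == "reflectance":
            if self.rho is None or self.rho <= 0:
                raise ValueError("reflectance geometry requires rho > 0")
        else:
            if self.thickness is None or self.thickness <= 0:
                raise ValueError("transmittance geometry requires thickness > 0")


@dataclass(frozen=True)
class MediumModel:
    """Optical-boundary description of the tissue medium.

    ``n`` is the tissue refractive index (1.4 by default); the boundary
    factor ``A`` is computed from ``n`` unless overridden.  The quantities
    that depend on the reduced scattering coefficient (D, z0, ze) are derived
    per wavelength via :meth:`derived`.
    """

    n: float = 1.4
    A: float | None = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("refractive index must be positive")
        if self.A is None:
            object.__setattr__(self, "A", boundary_reflection_factor(self.n))
        elif self.A <= 0:
            raise ValueError("boundary factor A must be positive")

    @property
    def v(self) -> float:
        """Speed of light in the medium, cm/s."""
        return C_LIGHT_CM_S / self.n

    def derived(self, musp: np.ndarray | float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(D, z0, ze) for given musp: D = 1/(3 musp), z0 = 1/musp, ze = 2 A D."""
        musp = np.asarray(musp, dtype=float)
        if np.any(musp <= 0):
            raise ValueError("musp must be positive")
        D = 1.0 / (3.0 * musp)
        z0 = 1.0 / musp
        ze = 2.0 * self.A * D
        return D, z0, ze


@dataclass(frozen=True)
class OpticalPropertiesAtWavelength:
    """(mua, musp) pair at one wavelength, cm^-1."""

    mua: float
    musp: float
    wavelength: float = float("nan")

    def __post_init__(self) -> None:
        if self.mua < 0:
            raise ValueError("mua must be non-negative")
        if self.musp <= 0:
            raise ValueError("musp must be positive")

    @property
    def diffusive(self) -> bool:
        """Validity flag of the diffusion approximation (mua << musp)."""
        return self.mua < 0.1 * self.musp


@dataclass(frozen=True)
class TimeAxis:
    """Uniform TCSPC channel grid: t0 (s, photon injection), dt, n_channels."""

    t0: float = 0.0
    dt: float = DEFAULT_DT_S
    n_channels: int = DEFAULT_N_CHANNELS

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_channels < 64:
            raise ValueError("need at least 64 channels for a TCSPC histogram")

    @property
    def times(self) -> np.ndarray:
        """Channel-centre times (s)."""
        return self.t0 + (np.arange(self.n_channels) + 0.5) * self.dt

    @property
    def span(self) -> float:
        return self.n_channels * self.dt


@dataclass
class DTOF:
    """One wavelength's distribution of times of flight (photon counts)."""

    wavelength: float
    counts: np.ndarray
    time_axis: TimeAxis

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.shape[0] != self.time_axis.n_channels:
            raise ValueError("counts length must equal n_channels")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        self.counts = counts.astype(np.int64)

    @property
    def total_counts(self) -> int:
        return int(self.counts.sum())


@dataclass
class SpectralAcquisition:
    """51 DTOFs (600-1100 nm in 10 nm steps) + IRF + geometry for one
    probing configuration."""

    dtofs: list[DTOF]
    irf: np.ndarray
    geometry: Geometry
    time_axis: TimeAxis
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.irf = np.asarray(self.irf, dtype=float)
        if self.irf.shape != (self.time_axis.n_channels,):
            raise ValueError("IRF must share the acquisition time axis")
        for d in self.dtofs:
            if d.time_axis != self.time_axis:
                raise ValueError("all DTOFs must share the acquisition time axis")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.asarray([d.wavelength for d in self.dtofs], dtype=float)

    @property
    def counts_matrix(self) -> np.ndarray:
        return np.stack([d.counts for d in self.dtofs])


@dataclass(frozen=True)
class FitWindow:
    """Inclusive channel-index window used for curve fitting."""

    start_index: int
    end_index: int

    def __post_init__(self) -> None:
        if self.start_index < 0 or self.end_index < self.start_index:
            raise ValueError("invalid fit window")

    @property
    def n_channels(self) -> int:
        return self.end_index - self.start_index + 1

    @property
    def slice(self) -> slice:
        return slice(self.start_index, self.end_index + 1)


# ---------------------------------------------------------------------------
# forward solutions
# ---------------------------------------------------------------------------

#: relative tolerance / cap for the slab image-source series
SLAB_SERIES_RTOL = 1e-9
SLAB_SERIES_MAX_PAIRS = 50


def _dipole_sum_reflectance(
    rho: float, z0: np.ndarray, ze: np.ndarray, four_Dvt: np.ndarray
) -> np.ndarray:
    """Image-source z-sum of the semi-infinite reflectance (flux detector)."""
    zp = z0
    zn = z0 + 2.0 * ze
    return zp * np.exp(-(zp**2) / four_Dvt) + zn * np.exp(-(zn**2) / four_Dvt)


def _image_sum_slab_transmittance(
    d: float, z0: np.ndarray, ze: np.ndarray, four_Dvt: np.ndarray
) -> np.ndarray:
    """Truncated symmetric image-source series for slab transmittance.

    Terms z1m = d(1-2m) - 4m ze - z0 and z2m = d(1-2m) - (4m-2) ze + z0,
    summed over pairs m = 0, +-1, +-2, ... until the next pair changes every
    channel by < SLAB_SERIES_RTOL relative (cap SLAB_SERIES_MAX_PAIRS).
    """
    total = np.zeros_like(four_Dvt)
    for m_abs in range(SLAB_SERIES_MAX_PAIRS + 1):
        ms = (0,) if m_abs == 0 else (m_abs, -m_abs)
        term = np.zeros_like(four_Dvt)
        for m in ms:
            z1 = d * (1 - 2 * m) - 4 * m * ze - z0
            z2 = d * (1 - 2 * m) - (4 * m - 2) * ze + z0
            term += z1 * np.exp(-(z1**2) / four_Dvt) - z2 * np.exp(-(z2**2) / four_Dvt)
        total += term
        scale = np.max(np.abs(total))
        if m_abs > 0 and (scale == 0.0 or np.max(np.abs(term)) < SLAB_SERIES_RTOL * scale):
            return total
    raise RuntimeError(
        f"slab image series did not converge within {SLAB_SERIES_MAX_PAIRS} pairs"
    )


def _image_sum_slab_reflectance(
    d: float, z0: np.ndarray, ze: np.ndarray, four_Dvt: np.ndarray
) -> np.ndarray:
    """Image-source series for the reflectance-side flux of a slab.

    For d -> large this converges to the semi-infinite dipole sum (the m = 0
    pair); used as an internal consistency check of the image construction.
    """
    total = np.zeros_like(four_Dvt)
    for m_abs in range(SLAB_SERIES_MAX_PAIRS + 1):
        ms = (0,) if m_abs == 0 else (m_abs, -m_abs)
        term = np.zeros_like(four_Dvt)
        for m in ms:
            zp = 2 * m * (d + 2 * ze) + z0
            zn = 2 * m * (d + 2 * ze) - 2 * ze - z0
            term += zp * np.exp(-(zp**2) / four_Dvt) - zn * np.exp(-(zn**2) / four_Dvt)
        total += term
        scale = np.max(np.abs(total))
        if m_abs > 0 and (scale == 0.0 or np.max(np.abs(term)) < SLAB_SERIES_RTOL * scale):
            return total
    raise RuntimeError(
        f"slab image series did not converge within {SLAB_SERIES_MAX_PAIRS} pairs"
    )


def td_curves(
    mua: np.ndarray | float,
    musp: np.ndarray | float,
    geometry: Geometry,
    medium: MediumModel,
    time_axis: TimeAxis,
) -> np.ndarray:
    """Vectorised time-domain DE solution for one or many (mua, musp) pairs.

    Returns shape ``(n_channels,)`` for scalar inputs, ``(n_props,
    n_channels)`` for 1-D inputs.  Amplitude is the physical photon-flux
    density (photons per unit area and time, per injected photon); in
    fitting only the shape matters.
    """
    mua_arr = np.atleast_1d(np.asarray(mua, dtype=float))
    musp_arr = np.atleast_1d(np.asarray(musp, dtype=float))
    mua_arr, musp_arr = np.broadcast_arrays(mua_arr, musp_arr)
    if np.any(mua_arr < 0):
        raise ValueError("mua must be non-negative")
    D, z0, ze = medium.derived(musp_arr)
    v = medium.v

    t = time_axis.times
    pos = t > 0
    tp = t[pos][None, :]  # (1, n_pos)
    D_, z0_, ze_, mua_ = (x[:, None] for x in (D, z0, ze, mua_arr))
    four_Dvt = 4.0 * D_ * v * tp

    if geometry.mode == "reflectance":
        r2 = geometry.rho**2
        zsum = _dipole_sum_reflectance(geometry.rho, z0_, ze_, four_Dvt)
    else:
        r2 = geometry.lateral_offset**2
        zsum = _image_sum_slab_transmittance(geometry.thickness, z0_, ze_, four_Dvt)

    prefac = 0.5 * (4.0 * np.pi * D_ * v) ** -1.5 * tp**-2.5
    curve_pos = prefac * np.exp(-mua_ * v * tp - r2 / four_Dvt) * zsum
    # slab series terms may individually go negative; clamp tiny negative residue
    curve_pos = np.maximum(curve_pos, 0.0)

    out = np.zeros((mua_arr.size, time_axis.n_channels))
    out[:, pos] = curve_pos
    if np.isscalar(mua) and np.isscalar(musp):
        return out[0]
    return out


def td_forward(
    props: OpticalPropertiesAtWavelength,
    geometry: Geometry,
    medium: MediumModel,
    time_axis: TimeAxis,
) -> np.ndarray:
    """Time-resolved diffuse reflectance/transmittance curve for one
    (mua, musp) pair on ``time_axis`` (zero for t <= 0, single-peaked for
    protocol-realistic parameters; absorption enters exactly as
    exp(-mua v t))."""
    return td_curves(props.mua, props.musp, geometry, medium, time_axis)


def cw_reflectance(mua: float, musp: float, rho: float, medium: MediumModel) -> float:
    """Steady-state (CW) diffuse reflectance of the semi-infinite medium.

    Closed-form flux solution of the same dipole model,
    R(rho) = (1/4pi) sum_i (+-) z_i (mueff + 1/r_i) exp(-mueff r_i) / r_i^2;
    equals the time integral of :func:`td_forward` and serves as its
    independent quadrature oracle.
    """
    D, z0, ze = medium.derived(musp)
    mueff = np.sqrt(mua / D)
    zp, zn = z0, z0 + 2.0 * ze
    out = 0.0
    for z in (zp, zn):
        r = np.hypot(z, rho)
        out += z * (mueff + 1.0 / r) * np.exp(-mueff * r) / r**2
    return float(out / (4.0 * np.pi))


# ---------------------------------------------------------------------------
# IRF convolution and fit window
# ---------------------------------------------------------------------------


def convolve_with_irf(
    model: np.ndarray, irf: np.ndarray, time_axis: TimeAxis
) -> np.ndarray:
    """Discrete linear convolution of model curve(s) with the IRF, scaled by dt.

    ``model`` may be 1-D (n_channels) or 2-D (n_curves, n_channels); the IRF
    is 1-D on the same axis.  The output is causally truncated to
    ``n_channels``.  Linear in both arguments; when no tail truncation
    occurs, sum(out) * dt = (sum(model) * dt) * (sum(irf) * dt).
    """
    model = np.asarray(model, dtype=float)
    irf = np.asarray(irf, dtype=float)
    n = time_axis.n_channels
    if model.shape[-1] != n or irf.shape != (n,):
        raise ValueError("model and IRF must share the time axis")
    if model.ndim == 1:
        full = fftconvolve(model, irf)
    else:
        full = fftconvolve(model, irf[None, :], axes=-1)
    return full[..., :n] * time_axis.dt


def determine_fit_window(
    counts: Sequence[float] | np.ndarray,
    leading_fraction: float = 0.80,
    trailing_fraction: float = 0.05,
) -> FitWindow:
    """Fitting window from 80% of the pulse peak on the leading edge to 5%
    on the falling edge.

    ``start`` is the first channel (scanning from the left, hence at or
    before the first peak) with counts >= leading_fraction * max; ``end`` is
    the last channel (at or after the peak) with counts >=
    trailing_fraction * max, clamped to the last channel when the curve
    never falls below threshold.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1 or c.size == 0:
        raise ValueError("counts must be a non-empty 1-D histogram")
    peak = float(c.max())
    if peak <= 0:
        raise ValueError("all-zero histogram: no peak to window around")
    start = int(np.argmax(c >= leading_fraction * peak))
    end = int(len(c) - 1 - np.argmax(c[::-1] >= trailing_fraction * peak))
    return FitWindow(start_index=start, end_index=end)
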