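"""Diffusion-equation forward curves, IRF convolution and fit windows."""

import numpy as np
import pytest

from optidens.forward_model import (
    DTOF,
    FitWindow,
    Geometry,
    MediumModel,
    OpticalPropertiesAtWavelength,
    TimeAxis,
    boundary_reflection_factor,
    convolve_with_irf,
    cw_reflectance,
    determine_fit_window,
    td_curves,
    td_forward,
)


def slab_transmittance_sum_oracle(d, z0, ze, four_Dvt, n_pairs):
    """Direct evaluation of the image-source series with a fixed pair count."""
    total = np.zeros_like(four_Dvt)
    for m in range(-n_pairs, n_pairs + 1):
        z1 = d * (1 - 2 * m) - 4 * m * ze - z0
        z2 = d * (1 - 2 * m) - (4 * m - 2) * ze + z0
        total += z1 * np.exp(-(z1**2) / four_Dvt) - z2 * np.exp(-(z2**2) / four_Dvt)
    return total


class TestTdForward:
    def test_causality_zero_before_injection(self, medium):
        axis = TimeAxis(t0=-2e-9, dt=25e-12, n_channels=1024)
        curve = td_forward(
            OpticalPropertiesAtWavelength(0.05, 10.0),
            Geometry("reflectance", rho=2.0),
            medium,
            axis,
        )
        assert np.all(curve[axis.times <= 0] == 0.0)
        assert curve[axis.times > 1e-10].max() > 0.0

    def test_beer_lambert_factorisation_exact(self, medium, fast_axis, reflectance_3cm):
        mua = 0.08
        with_abs = td_forward(
            OpticalPropertiesAtWavelength(mua, 11.0), reflectance_3cm, medium, fast_axis
        )
        without = td_forward(
            OpticalPropertiesAtWavelength(0.0, 11.0), reflectance_3cm, medium, fast_axis
        )
        expected = without * np.exp(-mua * medium.v * fast_axis.times)
        np.testing.assert_allclose(with_abs, expected, rtol=1e-12)

    @pytest.mark.parametrize("mua,musp,rho", [(0.05, 10.0, 2.0), (0.1, 15.0, 3.0), (0.02, 8.0, 2.0)])
    def test_time_integral_matches_cw_closed_form(self, medium, mua, musp, rho):
        axis = TimeAxis(dt=25.0e-9 / 4096, n_channels=4096)  # long axis: tail < 1e-10
        curve = td_forward(
            OpticalPropertiesAtWavelength(mua, musp), Geometry("reflectance", rho=rho),
            medium, axis,
        )
        td_integral = curve.sum() * axis.dt
        cw = cw_reflectance(mua, musp, rho, medium)
        assert td_integral == pytest.approx(cw, rel=0.01)

    def test_monotone_in_absorption(self, medium, fast_axis, reflectance_2cm):
        lo = td_forward(OpticalPropertiesAtWavelength(0.02, 10.0), reflectance_2cm, medium, fast_axis)
        hi = td_forward(OpticalPropertiesAtWavelength(0.05, 10.0), reflectance_2cm, medium, fast_axis)
        mask = lo > 1e-30
        assert np.all(hi[mask] < lo[mask])

    @pytest.mark.parametrize("thickness", [2.0, 3.0, 4.0])
    def test_slab_series_truncation_converged(self, medium, fast_axis, thickness):
        """Adding 5 more image pairs changes the series by < 1e-6 relative."""
        D, z0, ze = medium.derived(10.0)
        t = fast_axis.times
        four_Dvt = 4.0 * D * medium.v * t[t > 0]
        s8 = slab_transmittance_sum_oracle(thickness, z0, ze, four_Dvt, 8)
        s13 = slab_transmittance_sum_oracle(thickness, z0, ze, four_Dvt, 13)
        scale = np.abs(s13).max()
        assert np.abs(s13 - s8).max() < 1e-6 * scale

    def test_slab_matches_image_series_oracle(self, medium, fast_axis):
        """The slab transmittance curve equals a direct high-order evaluation
        of the image-source formula."""
        geo = Geometry("transmittance", thickness=3.0)
        curve = td_forward(OpticalPropertiesAtWavelength(0.05, 10.0), geo, medium, fast_axis)
        D, z0, ze = medium.derived(10.0)
        t = fast_axis.times
        pos = t > 0
        four_Dvt = 4.0 * D * medium.v * t[pos]
        zsum = slab_transmittance_sum_oracle(3.0, z0, ze, four_Dvt, 20)
        expected = (
            0.5 * (4 * np.pi * D * medium.v) ** -1.5 * t[pos] ** -2.5
            * np.exp(-0.05 * medium.v * t[pos]) * zsum
        )
        np.testing.assert_allclose(curve[pos], np.maximum(expected, 0.0), rtol=1e-8)

    def test_slab_reciprocity_in_lateral_offset(self, medium, fast_axis):
        props = OpticalPropertiesAtWavelength(0.05, 10.0)
        plus = td_forward(
            props, Geometry("transmittance", thickness=3.0, lateral_offset=1.2), medium, fast_axis
        )
        minus = td_forward(
            props, Geometry("transmittance", thickness=3.0, lateral_offset=-1.2), medium, fast_axis
        )
        np.testing.assert_array_equal(plus, minus)

    def test_thick_slab_reflectance_approaches_semi_infinite(self, medium, fast_axis):
        """The reflectance-side image series of a very thick slab reduces to
        the semi-infinite dipole solution."""
        from optidens.forward_model import (
            _dipole_sum_reflectance,
            _image_sum_slab_reflectance,
        )

        D, z0, ze = medium.derived(10.0)
        t = fast_axis.times
        sel = (t > 0) & (t <= 10e-9)  # the DTOF window actually measured
        four_Dvt = 4.0 * D * medium.v * t[sel]
        semi = _dipole_sum_reflectance(2.0, z0, ze, four_Dvt)
        slab = _image_sum_slab_reflectance(12.0, z0, ze, four_Dvt)  # 4x typical thickness
        np.testing.assert_allclose(slab, semi, rtol=1e-4)

    def test_vectorised_curves_match_scalar(self, medium, fast_axis, reflectance_3cm):
        muas = np.array([0.02, 0.05, 0.1])
        musps = np.array([8.0, 10.0, 14.0])
        stacked = td_curves(muas, musps, reflectance_3cm, medium, fast_axis)
        for i in range(3):
            single = td_forward(
                OpticalPropertiesAtWavelength(muas[i], musps[i]), reflectance_3cm, medium, fast_axis
            )
            np.testing.assert_array_equal(stacked[i], single)

    def test_boundary_factor_matched_interface(self):
        assert boundary_reflection_factor(1.0) == pytest.approx(1.0, abs=0.02)
        assert boundary_reflection_factor(1.4) == pytest.approx(3.25, abs=0.05)


class TestConvolveWithIrf:
    def test_delta_irf_shifts_model(self, fast_axis, medium, reflectance_3cm):
        model = td_forward(
            OpticalPropertiesAtWavelength(0.05, 10.0), reflectance_3cm, medium, fast_axis
        )
        k = 7
        delta = np.zeros(fast_axis.n_channels)
        delta[k] = 1.0 / fast_axis.dt  # unit-area impulse
        out = convolve_with_irf(model, delta, fast_axis)
        np.testing.assert_allclose(out[k:], model[: fast_axis.n_channels - k], rtol=1e-9, atol=1e-12 * model.max())

    def test_matches_direct_double_sum(self, rng):
        axis = TimeAxis(dt=1e-10, n_channels=128)
        model = rng.random(128)
        irf = rng.random(128)
        direct = np.zeros(128)
        for i in range(128):
            for j in range(i + 1):
                direct[i] += model[j] * irf[i - j]
        direct *= axis.dt
        out = convolve_with_irf(model, irf, axis)
        np.testing.assert_allclose(out, direct, rtol=1e-10)

    def test_area_preservation_without_truncation(self, rng):
        axis = TimeAxis(dt=1e-10, n_channels=256)
        model = np.zeros(256)
        irf = np.zeros(256)
        model[10:40] = rng.random(30)
        irf[5:25] = rng.random(20)
        out = convolve_with_irf(model, irf, axis)
        assert out.sum() * axis.dt == pytest.approx(
            (model.sum() * axis.dt) * (irf.sum() * axis.dt), rel=1e-12
        )

    def test_mismatched_axes_rejected(self, fast_axis):
        with pytest.raises(ValueError):
            convolve_with_irf(np.ones(fast_axis.n_channels), np.ones(512), fast_axis)


class TestDetermineFitWindow:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([0, 10, 80, 100, 50, 20, 5, 1], (2, 6)),  # 80% and 5% thresholds
            ([0, 100, 100, 10, 1], (1, 3)),  # flat top: first channel at max
            ([1, 2, 4, 8, 16, 32, 64, 128], (7, 7)),  # rising edge only: clamp to last
        ],
    )
    def test_threshold_examples(self, counts, expected):
        win = determine_fit_window(counts)
        assert (win.start_index, win.end_index) == expected

    def test_all_zero_histogram_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            determine_fit_window([0, 0, 0, 0])

    def test_window_contains_peak(self, rng):
        counts = np.convolve(rng.poisson(50, 200), np.ones(5)).astype(float)
        win = determine_fit_window(counts)
        assert win.start_index <= int(np.argmax(counts)) <= win.end_index


class TestDomainTypes:
    def test_geometry_validation(self):
        with pytest.raises(ValueError):
            Geometry("reflectance")
        with pytest.raises(ValueError):
            Geometry("transmittance", thickness=-1.0)
        with pytest.raises(ValueError):
            Geometry("tomography")

    def test_dtof_length_must_match_axis(self, fast_axis):
        with pytest.raises(ValueError):
            DTOF(800.0, np.ones(12), fast_axis)

    def test_fit_window_ordering(self):
        with pytest.raises(ValueError):
            FitWindow(5, 3)

    def test_time_axis_validation(self):
        with pytest.raises(ValueError):
            TimeAxis(dt=-1e-12)
        with pytest.raises(ValueError):
            TimeAxis(n_channels=16)
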