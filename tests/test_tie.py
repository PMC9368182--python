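"""TIE solver: axial derivative, Neumann inverse Laplacian, phase recovery."""

import dataclasses

import numpy as np
import pytest

from qpigan.optics import (
    DefocusStack,
    IntensityImage,
    PhaseMap,
    acquire_defocus_stack,
    image_through_system,
    make_sphere_phantom,
    random_sphere_spec,
)
from qpigan.tie import TieParams, axial_derivative, inverse_laplacian, solve_tie


def _stack(minus, focus, plus, pitch=0.2, dz=3.0):
    return DefocusStack(
        minus=IntensityImage(minus, pitch, -dz),
        focus=IntensityImage(focus, pitch, 0.0),
        plus=IntensityImage(plus, pitch, +dz),
    )


def _neumann_modes(n, pitch, modes):
    """Sum of cos(pi m x / L) Neumann eigenfunctions at half-sample pixels."""
    x = (np.arange(n) + 0.5) * pitch
    lth = n * pitch
    out = np.zeros((n, n))
    lam = 0.0
    for (m, k, amp) in modes:
        out += amp * np.outer(np.cos(np.pi * m * x / lth), np.cos(np.pi * k * x / lth))
    return out


def _mode_laplacian(n, pitch, modes):
    x = (np.arange(n) + 0.5) * pitch
    lth = n * pitch
    out = np.zeros((n, n))
    for (m, k, amp) in modes:
        ev = -((np.pi * m / lth) ** 2 + (np.pi * k / lth) ** 2)
        out += ev * amp * np.outer(np.cos(np.pi * m * x / lth), np.cos(np.pi * k * x / lth))
    return out


class TestAxialDerivative:
    def test_symmetric_stack_gives_zero(self, rng):
        i = rng.random((32, 32)) + 0.5
        d = axial_derivative(_stack(i, i, i))
        np.testing.assert_array_equal(d.values, 0.0)

    def test_linear_ramp_gives_constant(self):
        c, dz = 0.07, 3.0
        ones = np.ones((16, 16))
        d = axial_derivative(_stack((1 - c * dz) * ones, ones, (1 + c * dz) * ones, dz=dz))
        np.testing.assert_allclose(d.values, c, rtol=1e-12)

    def test_matches_fourth_order_difference_for_simulated_object(self, cfg_40x_coherent):
        # central difference at +-h vs the 4-point Richardson estimate built
        # from propagated intensities at +-h and +-h/2
        y, x = np.mgrid[0:64, 0:64] * 0.1625
        pm = PhaseMap(0.3 * np.exp(-((x - 5.2) ** 2 + (y - 5.2) ** 2) / 1.5), 0.1625)
        h = 0.1
        def inten(z):
            return image_through_system(pm, cfg_40x_coherent, z).values
        d1 = (inten(h) - inten(-h)) / (2 * h)
        d_half = (inten(h / 2) - inten(-h / 2)) / h
        d4 = (4 * d_half - d1) / 3
        cfg = dataclasses.replace(cfg_40x_coherent, defocus_dz=h)
        stack = acquire_defocus_stack(pm, cfg)
        ours = axial_derivative(stack).values
        err = np.linalg.norm(ours - d4) / np.linalg.norm(d4)
        assert err < 0.02


class TestInverseLaplacian:
    def test_zero_field_maps_to_zero(self):
        out = inverse_laplacian(np.zeros((24, 24)), pitch=0.3)
        np.testing.assert_array_equal(out, 0.0)

    def test_neumann_eigenfunction_scaled_by_eigenvalue(self):
        n, pitch, m = 64, 0.25, 2
        lth = n * pitch
        f = _neumann_modes(n, pitch, [(m, 0, 1.0)])
        out = inverse_laplacian(f, pitch, epsilon_dc=0.0)
        expected = -f / (np.pi * m / lth) ** 2
        np.testing.assert_allclose(out, expected, rtol=1e-6, atol=1e-9)

    def test_discrete_laplacian_round_trip(self, rng):
        from numpy.fft import fft2, ifft2, fftfreq
        n, pitch = 96, 0.2
        # smooth zero-mean field (band-limited so the 5-point stencil is accurate)
        noise = rng.standard_normal((n, n))
        f = fftfreq(n, d=pitch)
        fx, fy = np.meshgrid(f, f)
        field = np.real(ifft2(fft2(noise) * np.exp(-(fx**2 + fy**2) * 10.0)))
        field -= field.mean()
        out = inverse_laplacian(field, pitch, epsilon_dc=0.0)
        lap = (np.roll(out, 1, 0) + np.roll(out, -1, 0) + np.roll(out, 1, 1)
               + np.roll(out, -1, 1) - 4 * out) / pitch**2
        interior = (slice(2, -2), slice(2, -2))
        err = (np.linalg.norm(lap[interior] - field[interior])
               / np.linalg.norm(field[interior]))
        assert err < 0.01


class TestSolveTie:
    def test_uniform_stack_gives_zero_phase(self):
        ones = np.ones((32, 32))
        phase = solve_tie(_stack(ones, ones, ones))
        np.testing.assert_allclose(phase.values, 0.0, atol=1e-9)

    def _weak_phase_stack(self, amp=0.05, n=64, pitch=0.25, dz=1.0, lam=0.55):
        modes = [(2, 3, amp), (1, 1, 0.4 * amp)]
        phi = _neumann_modes(n, pitch, modes)
        lap = _mode_laplacian(n, pitch, modes)
        k = 2 * np.pi / lam
        plus = 1.0 - (dz / k) * lap
        minus = 1.0 + (dz / k) * lap
        stack = _stack(minus, np.ones((n, n)), plus, pitch=pitch, dz=dz)
        return phi - phi.mean(), stack, TieParams(wavelength=lam, dz=dz)

    def test_weak_phase_closed_form_recovery(self):
        phi, stack, params = self._weak_phase_stack()
        rec = solve_tie(stack, params)
        err = np.linalg.norm(rec.values - phi) / np.linalg.norm(phi)
        assert err < 0.01

    def test_linearity_in_weak_phase_regime(self):
        phi1, stack1, params = self._weak_phase_stack(amp=0.02)
        phi2, stack2, _ = self._weak_phase_stack(amp=0.04)
        rec1 = solve_tie(stack1, params).values
        rec2 = solve_tie(stack2, params).values
        assert np.linalg.norm(rec2 - 2 * rec1) / np.linalg.norm(rec2) < 0.01

    def test_invariant_to_exposure_scale(self):
        phi, stack, params = self._weak_phase_stack()
        scaled = _stack(7.3 * stack.minus.values, 7.3 * stack.focus.values,
                        7.3 * stack.plus.values, pitch=stack.pitch, dz=stack.dz)
        np.testing.assert_allclose(solve_tie(scaled, params).values,
                                   solve_tie(stack, params).values,
                                   rtol=1e-9, atol=1e-12)

    def test_mirror_symmetry(self):
        phi, stack, params = self._weak_phase_stack()
        flipped = _stack(stack.minus.values[::-1, :], stack.focus.values[::-1, :],
                         stack.plus.values[::-1, :], pitch=stack.pitch, dz=stack.dz)
        rec = solve_tie(stack, params).values
        rec_flip = solve_tie(flipped, params).values
        np.testing.assert_allclose(rec_flip, rec[::-1, :], rtol=1e-7, atol=1e-10)

    def test_full_round_trip_recovers_sphere_peak(self, cfg_40x_coherent):
        # simulator as oracle: phantom -> defocus stack -> TIE -> peak phase
        spec = random_sphere_spec(1, 128, cfg_40x_coherent.camera_pitch, seed=11)
        pm = make_sphere_phantom(spec, cfg_40x_coherent.wavelength)
        stack = acquire_defocus_stack(pm, cfg_40x_coherent)
        rec = solve_tie(stack, TieParams(wavelength=cfg_40x_coherent.wavelength,
                                         dz=cfg_40x_coherent.defocus_dz))
        # robust peak: 95th percentile of the above-half-max component minus
        # the background median (tolerant of finite-defocus ringing)
        v = rec.values - np.median(rec.values)
        comp = v > 0.5 * np.percentile(v, 99)
        rec_peak = np.percentile(v[comp], 95) - np.median(v[~comp])
        true_peak = pm.values.max()
        assert abs(rec_peak - true_peak) / true_peak < 0.06
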