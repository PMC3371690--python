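"""Energy-loss function, kinematics and inelastic cross-section checks.

The quadrature oracles below re-derive channel quantities directly from the
Drude lineshape (re-implemented here from the channel parameters), so they
exercise a different code path than the production tables.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nanodos import dielectric as dl
from nanodos.constants import BOHR_RADIUS_NM, RYDBERG_EV


def drude_term(ch: dl.DrudeChannel, q_au, e_ev, ep2: float, truncated=True):
    """Independent re-implementation of one channel's loss term."""
    q = np.asarray(q_au, float)
    e = np.asarray(e_ev, float)
    ek = ch.transition_energy_ev + ch.dispersion_coefficient * RYDBERG_EV * q * q
    g = ch.damping_width_ev
    val = ch.oscillator_strength * ep2 * g * e / ((ek * ek - e * e) ** 2 + (g * e) ** 2)
    if truncated:
        val = np.where(e >= ch.threshold_ev, val, 0.0)
    return val


class TestOpticalELF:
    def test_zero_energy_gives_zero(self, model):
        assert dl.optical_elf(model, 0.0) == 0.0

    def test_negative_energy_rejected(self, model):
        with pytest.raises(ValueError):
            dl.optical_elf(model, -1.0)

    def test_vanishes_at_high_energy(self, model):
        assert dl.optical_elf(model, 1.0e6) < 1.0e-4

    def test_optical_limit_equals_bethe_surface_at_q0(self, model):
        e = np.geomspace(0.5, 5000.0, 200)
        np.testing.assert_allclose(
            dl.bethe_surface(model, 0.0, e),
            dl.optical_elf(model, e),
            rtol=1e-14,
        )


class TestBetheSurface:
    def test_negative_arguments_rejected(self, model):
        with pytest.raises(ValueError):
            dl.bethe_surface(model, -0.1, 10.0)

    @pytest.mark.parametrize("q", [5.0, 8.0])
    def test_ridge_crest_follows_free_electron_locus(self, model, q):
        # the crest sits at E_k + q^2 Ry under impulse dispersion, so the
        # relative offset from the free-electron locus shrinks as 1/q^2
        e = np.geomspace(1.0, 3.0e3, 4000)
        surf = np.asarray(dl.bethe_surface(model, q, e))
        crest = e[np.argmax(surf)]
        assert abs(crest - RYDBERG_EV * q * q) / (RYDBERG_EV * q * q) < 0.10

    def test_surface_non_negative_on_grid(self, model):
        q = np.linspace(0.0, 20.0, 200)
        e = np.linspace(0.0, 2000.0, 200)
        surf = np.asarray(dl.bethe_surface(model, q[:, None], e[None, :]))
        assert np.all(surf >= 0.0)

    @settings(max_examples=50, deadline=None)
    @given(
        q=st.floats(0.0, 50.0),
        e=st.floats(0.0, 1.0e4),
    )
    def test_positivity_property(self, model, q, e):
        assert dl.bethe_surface(model, q, e) >= 0.0


class TestKinematics:
    def test_invalid_states_rejected(self):
        with pytest.raises(ValueError):
            dl.InelasticKinematics(-5.0, 1.0, 0.1)
        with pytest.raises(ValueError):
            dl.InelasticKinematics(100.0, 150.0, 0.1)  # E > T
        with pytest.raises(ValueError):
            dl.InelasticKinematics(100.0, 10.0, -0.1)

    def test_q_bounds_formula(self):
        t, e = 1000.0, 100.0
        lo, hi = dl.kinematic_q_bounds(t, e)
        assert lo == pytest.approx(math.sqrt(t / RYDBERG_EV) - math.sqrt((t - e) / RYDBERG_EV))
        assert hi == pytest.approx(math.sqrt(t / RYDBERG_EV) + math.sqrt((t - e) / RYDBERG_EV))

    def test_forbidden_momentum_gives_zero(self, model):
        kin = dl.InelasticKinematics(1000.0, 100.0, 60.0)  # far above q_+
        assert dl.differential_inverse_mfp(model, kin) == 0.0

    def test_singular_q0_rejected(self, model):
        kin = dl.InelasticKinematics(1000.0, 100.0, 0.0)
        with pytest.raises(ValueError):
            dl.differential_inverse_mfp(model, kin)

    def test_ratio_identity(self, model):
        # d2L(q1)/d2L(q2) = (q2/q1) ELF(q1)/ELF(q2) at fixed (T, E)
        t, e = 2000.0, 50.0
        q1, q2 = 1.0, 2.5
        r = dl.differential_inverse_mfp(
            model, dl.InelasticKinematics(t, e, q1)
        ) / dl.differential_inverse_mfp(model, dl.InelasticKinematics(t, e, q2))
        expected = (q2 / q1) * (
            dl.bethe_surface(model, q1, e) / dl.bethe_surface(model, q2, e)
        )
        assert r == pytest.approx(expected, rel=1e-12)


class TestChannelIMFP:
    def test_below_threshold_all_channels_closed(self, model):
        for ch in model.channels:
            assert dl.channel_inverse_mfp(model, 5.0, ch) == 0.0

    def test_unknown_channel_rejected(self, model):
        alien = dl.DrudeChannel("excitation", "alien", 9.0, 0.01, 1.0)
        with pytest.raises(ValueError):
            dl.channel_inverse_mfp(model, 100.0, alien)

    def test_oscillator_strength_linearity(self, model):
        ch = model.channels[7]
        doubled = dl.DrudeChannel(
            ch.kind, ch.label, ch.transition_energy_ev,
            2.0 * ch.oscillator_strength, ch.damping_width_ev,
            ch.binding_energy_ev, ch.dispersion_coefficient,
        )
        m2 = model.with_channels(
            [doubled if c is ch else c for c in model.channels]
        )
        l1 = dl.channel_inverse_mfp(model, 500.0, ch)
        l2 = dl.channel_inverse_mfp(m2, 500.0, doubled)
        assert l2 == pytest.approx(2.0 * l1, rel=1e-9)

    def test_single_peaked_over_energy(self, model):
        ch = model.channels[7]  # dominant ionization shell
        ts = np.geomspace(ch.threshold_ev * 1.2, 1.0e4, 40)
        lam = np.array([dl.channel_inverse_mfp(model, float(t), ch) for t in ts])
        assert np.all(lam >= 0)
        peak = int(np.argmax(lam))
        rising = np.diff(lam[: peak + 1])
        falling = np.diff(lam[peak:])
        assert np.all(rising > -1e-3 * lam.max())
        assert np.all(falling < 1e-3 * lam.max())

    def test_double_integral_matches_channel_imfp(self, model):
        """Independent 2-D trapezoid quadrature of the doubly differential
        inverse mean free path reproduces the channel integral within 1%."""
        t = 1000.0
        ep2 = model.plasma_energy_ev**2
        total_oracle = 0.0
        for ch in model.channels:
            thr = ch.threshold_ev
            if t <= thr:
                continue
            e = np.geomspace(thr, t, 600)
            q_lo, q_hi = dl.kinematic_q_bounds(t, e)
            frac = np.linspace(0.0, 1.0, 400)[:, None]
            q = q_lo[None, :] * (q_hi / q_lo)[None, :] ** frac
            integrand = drude_term(ch, q, e[None, :], ep2) / q
            inner = np.trapezoid(integrand, x=q, axis=0)
            dlde = inner / (math.pi * BOHR_RADIUS_NM * t)
            total_oracle += float(np.trapezoid(dlde, x=e))
        total = sum(dl.channel_inverse_mfp(model, t, ch) for ch in model.channels)
        assert total == pytest.approx(total_oracle, rel=0.01)

    def test_table_total_is_exact_channel_sum(self, xs_table):
        np.testing.assert_allclose(
            xs_table.lambda_total, xs_table.lambda_k.sum(axis=0), rtol=0, atol=0
        )


class TestStoppingPower:
    def test_monotone_decreasing_1_to_10_kev(self, model):
        ts = np.geomspace(1.0e3, 1.0e4, 8)
        s = [dl.collision_stopping_power(model, float(t)) for t in ts]
        assert all(a > b for a, b in zip(s, s[1:]))

    def test_density_proportionality(self, model):
        dense = model.rescaled(2.0)
        s1 = dl.collision_stopping_power(model, 5000.0)
        s2 = dl.collision_stopping_power(dense, 5000.0)
        assert s2 == pytest.approx(2.0 * s1, rel=1e-6)

    def test_below_threshold_warns_and_returns_zero(self, model):
        with pytest.warns(UserWarning):
            assert dl.collision_stopping_power(model, 5.0) == 0.0


class TestSampler:
    def test_bounds_hold_for_all_samples(self, model, xs_table):
        rng = np.random.default_rng(123)
        ch = model.channels[7]
        e, q = dl.sample_energy_momentum(xs_table, 1000.0, ch, rng, size=10_000)
        lo, hi = dl.kinematic_q_bounds(1000.0, e)
        assert np.all(e <= 1000.0)
        assert np.all(e >= ch.threshold_ev)
        assert np.all(q >= lo - 1e-9)
        assert np.all(q <= hi + 1e-9)

    def test_identical_seeds_identical_streams(self, model, xs_table):
        ch = model.channels[7]
        e1, q1 = dl.sample_energy_momentum(
            xs_table, 500.0, ch, np.random.default_rng(7), size=500
        )
        e2, q2 = dl.sample_energy_momentum(
            xs_table, 500.0, ch, np.random.default_rng(7), size=500
        )
        np.testing.assert_array_equal(e1, e2)
        np.testing.assert_array_equal(q1, q2)

    def test_closed_channel_rejected(self, model, xs_table):
        ch = model.channels[-1]  # K shell, closed at 100 eV
        with pytest.raises(ValueError):
            dl.sample_energy_momentum(xs_table, 100.0, ch, np.random.default_rng(1))
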