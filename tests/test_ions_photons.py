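"""Ion (proton/alpha) and photon transport physics checks."""

import math
import random

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import chisquare

from nanodos.constants import ELECTRON_REST_EV, PROTON_REST_EV, ALPHA_REST_EV
from nanodos.electron import ParticleState, TransportConfig
from nanodos.ions import (
    IonModel,
    IonSamplerTable,
    IonTransportConfig,
    ion_ionization_ddcs,
    transport_ion,
)
from nanodos.photons import (
    PhotonModel,
    PhotonTransportConfig,
    klein_nishina_dcs,
    klein_nishina_total_nm2,
    photon_interact,
    sample_compton_energy,
    transport_photon,
)
from nanodos.sources import disc_beam_source, pencil_beam_source


@pytest.fixture(scope="module")
def proton(model):
    return IonModel.for_species("proton", model)


@pytest.fixture(scope="module")
def alpha(model):
    return IonModel.for_species("alpha", model)


class TestIonDDCS:
    def test_beyond_kinematic_maximum_is_zero(self, proton):
        t = 1.0  # MeV
        wmax = proton.w_max_ev(1.0e6)
        assert ion_ionization_ddcs(proton, t, wmax * 1.01) == 0.0
        assert ion_ionization_ddcs(proton, t, wmax * 0.5) > 0.0

    def test_negative_delta_energy_rejected(self, proton):
        with pytest.raises(ValueError):
            ion_ionization_ddcs(proton, 1.0, -5.0)

    def test_one_over_w_squared_tail(self, proton):
        t_ev = 100.0e6
        w1, w2 = 20_000.0, 80_000.0  # far above every binding energy
        r = proton.ddcs_nm2_per_ev(t_ev, w1) / proton.ddcs_nm2_per_ev(t_ev, w2)
        assert r == pytest.approx((w2 / w1) ** 2, rel=0.05)

    def test_alpha_scales_as_effective_charge_squared(self, proton, alpha):
        # equal velocity: T_alpha = T_p * (M_alpha / M_p)
        t_p = 0.755e6
        t_a = t_p * ALPHA_REST_EV / PROTON_REST_EV
        for w in (10.0, 100.0, 1000.0):
            ratio = alpha.ddcs_nm2_per_ev(t_a, w) / proton.ddcs_nm2_per_ev(t_p, w)
            assert ratio == pytest.approx(alpha.z_eff(t_a) ** 2, rel=0.01)

    def test_first_moment_matches_quadrature_oracle(self, proton):
        """Mean delta-ray energy from dense-grid integration of the DDCS
        agrees with the model's closed-form accounting within 1%."""
        t_ev = 2.0e6
        wmax = proton.w_max_ev(t_ev)
        num, _ = quad(lambda w: w * proton.ddcs_nm2_per_ev(t_ev, w), 0, wmax,
                      limit=200)
        den, _ = quad(lambda w: proton.ddcs_nm2_per_ev(t_ev, w), 0, wmax,
                      limit=200)
        mean_w_oracle = num / den
        mean_b = (
            proton.mean_vertex_loss_ev(t_ev)
            - mean_w_oracle
        )
        # closed-form <W+B> minus oracle <W> must equal the weighted <B>
        weights = proton.shell_weights(t_ev)
        b_avg = sum(
            w * b for w, b in zip(weights, proton.binding_energies_ev)
        ) / sum(weights)
        assert mean_b == pytest.approx(b_avg, rel=0.01)

    def test_sampled_vertices_match_analytic_mean(self, proton):
        t_ev = 2.0e6
        sampler = IonSamplerTable(proton, 1.9e6, 2.1e6)
        row, lam, sexc, wmax = sampler.at(t_ev)
        rng = random.Random(12)
        draws = [sampler.sample_vertex(row, wmax, rng) for _ in range(200_000)]
        mean_loss = np.mean([w + b for w, b in draws])
        se = np.std([w + b for w, b in draws]) / math.sqrt(len(draws))
        assert abs(mean_loss - proton.mean_vertex_loss_ev(t_ev)) < 4 * se


class TestIonTransport:
    def test_thin_slab_energy_loss_matches_stopping(self, proton, etables):
        """CSDA oracle: mean loss through 1 um = S * dx within 5%."""
        box = (0.0, 1.0e3, -1e9, 1e9, -1e9, 1e9)
        cfg = IonTransportConfig(
            box_nm=box, track_secondaries_at=lambda *a: False, terminate_ev=1e4
        )
        sampler = IonSamplerTable(proton, 5e5, 1.1e6)
        rng = random.Random(3)
        n = 1000
        total = 0.0
        for st in pencil_beam_source("proton", 1.0e6, n):
            h = transport_ion(st, proton, cfg, etables, rng, sampler=sampler)
            assert h.closure_residual < 1e-9
            total += h.energy_deposited_ev
        expected = proton.stopping_power_ev_nm(1.0e6) * 1.0e3
        assert total / n == pytest.approx(expected, rel=0.05)

    def test_vertex_density_uniform_along_thin_slab(self, proton, etables):
        """200 MeV protons lose a negligible fraction over 50 um, so vertex
        positions are uniform (chi-square)."""
        box = (0.0, 5.0e4, -1e9, 1e9, -1e9, 1e9)
        xs = []

        class S:
            def add_deposit(self, *a):
                pass

            def add_ionization(self, x, y, z, pid, gen):
                if gen == 0:
                    xs.append(x)

        cfg = IonTransportConfig(
            box_nm=box, track_secondaries_at=lambda *a: False,
            multiple_scattering=False,
        )
        rng = random.Random(5)
        for st in pencil_beam_source("proton", 200.0e6, 40):
            transport_ion(st, proton, cfg, etables, rng, scorer=S())
        counts, _ = np.histogram(xs, bins=10, range=(0, 5.0e4))
        _, p = chisquare(counts)
        assert p > 0.01

    def test_vacuum_produces_no_vertices(self, proton, etables):
        box = (0.0, 1.0e4, -1e9, 1e9, -1e9, 1e9)
        cfg = IonTransportConfig(
            box_nm=box, material_lookup=lambda x, y, z: (0.0, 0.0),
            bulk_step_nm=1e3,
        )
        h = transport_ion(
            next(pencil_beam_source("proton", 1.0e6, 1)),
            proton, cfg, etables, random.Random(1),
        )
        assert h.n_vertices == 0
        assert h.energy_escaped_ev == pytest.approx(1.0e6)

    def test_effective_charge_below_bare_charge(self, alpha):
        z = alpha.z_eff(3.0e6)
        assert 0.0 < z < 2.0
        assert alpha.z_eff(30.0e6) > z  # approaches 2 with speed


class TestPhotons:
    def test_compton_energy_bounds(self):
        e = 100.0e3
        k = e / ELECTRON_REST_EV
        emin = e / (1.0 + 2.0 * k)
        rng = random.Random(9)
        for _ in range(100_000):
            es, cos_t = sample_compton_energy(e, rng)
            assert emin - 1e-9 <= es <= e + 1e-9
            assert -1.0 <= cos_t <= 1.0

    def test_mean_scattered_fraction_matches_klein_nishina(self):
        """Sampled mean scattered energy vs the analytic KN expectation."""
        e = 100.0e3
        k = e / ELECTRON_REST_EV
        emin = e / (1.0 + 2.0 * k)
        num, _ = quad(lambda ep: ep * klein_nishina_dcs(e, ep), emin, e)
        mean_expected = num / klein_nishina_total_nm2(e)
        rng = random.Random(21)
        n = 100_000
        mean = np.mean([sample_compton_energy(e, rng)[0] for _ in range(n)])
        assert mean == pytest.approx(mean_expected, rel=0.01)

    def test_rayleigh_deposits_nothing(self):
        model = PhotonModel()
        rng = random.Random(4)
        st = ParticleState("photon", (0, 0, 0), (1, 0, 0), 30.0e3)
        for _ in range(300):
            act = photon_interact(model, st, rng)
            if act.kind == "rayleigh":
                assert act.local_deposit_ev == 0.0
                assert act.electron_energy_ev == 0.0
                assert act.scattered_energy_ev == 30.0e3
                break
        else:
            pytest.fail("no Rayleigh event sampled in 300 draws")

    def test_photoelectron_energy(self):
        model = PhotonModel()
        rng = random.Random(8)
        st = ParticleState("photon", (0, 0, 0), (1, 0, 0), 12.0e3)
        for _ in range(500):
            act = photon_interact(model, st, rng)
            if act.kind == "photoelectric":
                assert act.electron_energy_ev == pytest.approx(12.0e3 - 543.1)
                break
        else:
            pytest.fail("no photoelectric event sampled")

    def test_pair_production_below_threshold_is_hard_error(self):
        model = PhotonModel()
        with pytest.raises(ValueError):
            model.mu_pair(500.0e3)

    def test_energy_outside_domain_rejected(self):
        model = PhotonModel()
        st = ParticleState("photon", (0, 0, 0), (1, 0, 0), 2.0e6)
        with pytest.raises(ValueError):
            photon_interact(model, st, random.Random(1))

    def test_compton_is_modal_interaction_at_100kev(self):
        model = PhotonModel()
        mu_c = model.mu_compton(100.0e3)
        assert mu_c > model.mu_photoelectric(100.0e3)
        assert mu_c > model.mu_rayleigh(100.0e3)

    def test_attenuation_through_40mm(self, etables):
        model = PhotonModel()
        cube = 40.0e6
        box = (0.0, cube, -cube / 2, cube / 2, -cube / 2, cube / 2)
        cfg = PhotonTransportConfig(
            box_nm=box, track_secondaries_at=lambda *a: False
        )
        rng = random.Random(6)
        n = 3000
        uncollided = 0
        for st in pencil_beam_source("photon", 100.0e3, n):
            h = transport_photon(st, model, cfg, etables, rng)
            uncollided += h.primary_uncollided
        p = math.exp(-model.mu_total(100.0e3) * cube)
        sigma = math.sqrt(p * (1 - p) / n)
        assert abs(uncollided / n - p) < 4 * sigma

    def test_zero_density_no_interactions(self, etables):
        model = PhotonModel(electron_density_nm3=0.0, density_g_cm3=0.0)
        cfg = PhotonTransportConfig(box_nm=(0, 1e6, -1e6, 1e6, -1e6, 1e6))
        h = transport_photon(
            next(pencil_beam_source("photon", 100.0e3, 1)),
            model, cfg, etables, random.Random(2),
        )
        assert h.n_interactions == 0
        assert h.energy_escaped_ev == pytest.approx(100.0e3)

    def test_energy_closure_with_tracked_electrons(self, etables):
        model = PhotonModel()
        cube = 40.0e6
        box = (0.0, cube, -cube / 2, cube / 2, -cube / 2, cube / 2)
        cfg = PhotonTransportConfig(
            box_nm=box,
            electron_config=TransportConfig(box_nm=box, record_events=False),
        )
        rng = random.Random(77)
        for st in pencil_beam_source("photon", 100.0e3, 60):
            h = transport_photon(st, model, cfg, etables, rng)
            assert h.closure_residual < 1e-9


class TestSources:
    def test_pencil_beam_direction_energy_count(self):
        states = list(pencil_beam_source("proton", 200.0e6, 25))
        assert len(states) == 25
        assert all(s.direction == (1.0, 0.0, 0.0) for s in states)
        assert all(s.kinetic_energy_ev == 200.0e6 for s in states)

    def test_unsupported_species_rejected(self):
        with pytest.raises(ValueError):
            list(pencil_beam_source("muon", 1.0e6, 1))

    def test_disc_beam_within_footprint(self):
        rng = random.Random(1)
        states = list(
            disc_beam_source("alpha", 3.0e6, 500, rng, radius_nm=2500.0,
                             center_yz_nm=(8000.0, 0.0))
        )
        for s in states:
            _, y, z = s.position_nm
            assert math.hypot(y - 8000.0, z) <= 2500.0 + 1e-9
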