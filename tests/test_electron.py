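"""Event-by-event electron transport: flights, collisions, full tracks."""

import math
import random

import numpy as np
import pytest

from nanodos import dielectric as dl
from nanodos.electron import (
    ElectronTables,
    ParticleState,
    TransportConfig,
    apply_inelastic,
    binary_collision_cosines,
    sample_flight_and_channel,
    transport_electron,
)


class TestFlightAndChannel:
    def test_mean_free_flight(self, etables):
        t = 500.0
        lam = etables.inelastic_imfp(t) + etables.elastic_imfp(t)
        rng = random.Random(5)
        st = ParticleState("electron", (0, 0, 0), (0, 0, 1), t)
        n = 100_000
        paths = [sample_flight_and_channel(st, etables, rng)[0] for _ in range(n)]
        assert np.mean(paths) == pytest.approx(1.0 / lam, rel=0.02)

    def test_channel_frequencies_match_imfp_ratios(self, etables, xs_table):
        t = 500.0
        rng = random.Random(17)
        st = ParticleState("electron", (0, 0, 0), (0, 0, 1), t)
        n = 100_000
        labels = [sample_flight_and_channel(st, etables, rng)[1] for _ in range(n)]
        lam_el = etables.elastic_imfp(t)
        lam_k = xs_table.channel_imfp(t)
        lam_tot = lam_el + lam_k.sum()
        counts = {lab: labels.count(lab) for lab in set(labels)}
        # elastic plus every open inelastic channel within 5 sigma binomial
        expect = {"elastic": lam_el / lam_tot}
        for ch, lk in zip(xs_table.channels, lam_k):
            if lk > 0:
                expect[ch.label] = lk / lam_tot
        for lab, p in expect.items():
            if p < 5e-4:
                continue
            sigma = math.sqrt(p * (1 - p) / n)
            assert abs(counts.get(lab, 0) / n - p) < 5 * sigma, lab

    def test_doubled_density_halves_mean_path(self, model, elastic_model):
        dense = dl.CrossSectionTable(model.rescaled(2.0), points_per_decade=16)
        base = dl.CrossSectionTable(model, points_per_decade=16)
        td = ElectronTables(dense, elastic_model)
        tb = ElectronTables(base, elastic_model)
        # compare inelastic-only mean free paths (elastic table is fixed)
        assert td.inelastic_imfp(800.0) == pytest.approx(
            2.0 * tb.inelastic_imfp(800.0), rel=1e-6
        )

    def test_all_channels_closed_signals_termination(self, etables):
        st = ParticleState("electron", (0, 0, 0), (0, 0, 1), 4.0)
        with pytest.raises(ValueError):
            sample_flight_and_channel(st, etables, random.Random(1),
                                      include_elastic=False)


class TestApplyInelastic:
    def test_excitation_bookkeeping(self, model):
        ch = model.channels[0]  # 8.23 eV excitation
        st = ParticleState("electron", (0, 0, 0), (0, 0, 1), 100.0)
        new, ev, sec = apply_inelastic(st, ch, (ch.transition_energy_ev, 0.5),
                                       random.Random(2))
        assert new.kinetic_energy_ev == pytest.approx(91.77)
        assert new.direction == st.direction
        assert sec is None
        assert ev.event_type == "excitation"
        assert ev.local_deposit_ev == pytest.approx(8.23)

    def test_ionization_energy_conservation(self, model):
        ch = model.channels[7]
        b = ch.binding_energy_ev
        st = ParticleState("electron", (0, 0, 0), (0, 0, 1), 1000.0)
        e_loss = 60.0
        new, ev, sec = apply_inelastic(st, ch, (e_loss, 1.5), random.Random(3))
        assert sec is not None
        assert new.kinetic_energy_ev + sec.kinetic_energy_ev + b == pytest.approx(1000.0)
        assert sec.kinetic_energy_ev == pytest.approx(e_loss - b)
        assert ev.local_deposit_ev == pytest.approx(b)

    def test_inconsistent_kinematics_rejected(self, model):
        ch = model.channels[7]
        st = ParticleState("electron", (0, 0, 0), (0, 0, 1), 1000.0)
        with pytest.raises(ValueError):
            apply_inelastic(st, ch, (5.0, 1.0), random.Random(1))  # E < B

    def test_deflection_cosines_bounded(self):
        rng = np.random.default_rng(11)
        for _ in range(10_000):
            t = float(rng.uniform(20.0, 5000.0))
            e = float(rng.uniform(10.0, t))
            lo, hi = dl.kinematic_q_bounds(t, e)
            q = float(rng.uniform(lo, hi))
            cp, cs = binary_collision_cosines(t, e, q)
            assert -1.0 <= cp <= 1.0
            assert -1.0 <= cs <= 1.0


class TestTransport:
    def test_zero_energy_degenerate_input(self, etables):
        st = ParticleState("electron", (1, 1, 1), (1, 0, 0), 0.0)
        tr = transport_electron(st, TransportConfig(), etables, random.Random(1))
        assert len(tr.events) == 1
        assert tr.events[0].event_type == "local-deposit"
        assert tr.energy_deposited_ev == 0.0

    def test_100ev_track_contained_in_10nm(self, etables):
        """A 100 eV electron's track stays on the 10 nm scale."""
        cfg = TransportConfig(record_events=False)
        rng = random.Random(99)
        disp = []
        for _ in range(200):
            st = ParticleState("electron", (0, 0, 0), (1, 0, 0), 100.0)
            tr = transport_electron(st, cfg, etables, rng)
            disp.append(tr.max_displacement_nm)
        assert np.median(disp) < 10.0

    def test_energy_closure_random_tracks(self, etables):
        rng = random.Random(123)
        for _ in range(100):
            e0 = 10.0 ** rng.uniform(1.0, 3.5)
            st = ParticleState("electron", (0, 0, 0), (0, 0, 1), e0)
            tr = transport_electron(
                st, TransportConfig(record_events=False), etables, rng
            )
            assert tr.closure_residual < 1e-9

    def test_reproducible_event_sequences(self, etables):
        cfg = TransportConfig(box_nm=(0, 50, 0, 50, 0, 50))
        def run():
            st = ParticleState("electron", (25, 25, 25), (1, 0, 0), 800.0)
            return transport_electron(st, cfg, etables, random.Random(4242))
        t1, t2 = run(), run()
        assert t1.events == t2.events
        assert t1.energy_deposited_ev == t2.energy_deposited_ev

    def test_mean_ionization_count_vs_independent_cascade(self, etables, xs_table):
        """Duplicate-implementation oracle: a straightforward energy-space
        cascade built from the CrossSectionTable samplers gives the same mean
        ionization count per 1 keV track within 3 sigma."""
        gen = np.random.default_rng(2024)

        def cascade_ionizations(t0: float) -> int:
            n = 0
            stack = [t0]
            while stack:
                t = stack.pop()
                while t >= 8.23:
                    lam_k = xs_table.channel_imfp(t)
                    # guard against interpolation leakage just below threshold
                    for k, ch in enumerate(xs_table.channels):
                        if t <= ch.threshold_ev:
                            lam_k[k] = 0.0
                    tot = lam_k.sum()
                    if tot <= 0:
                        break
                    k = int(gen.choice(len(lam_k), p=lam_k / tot))
                    ch = xs_table.channels[k]
                    if ch.kind == dl.IONIZATION:
                        e_loss = float(
                            xs_table.sample_energy_transfer(t, k, gen, 1)[0]
                        )
                        w = max(e_loss - ch.binding_energy_ev, 0.0)
                        n += 1
                        if w >= 8.23:
                            stack.append(w)
                        t -= e_loss
                    else:
                        t -= ch.transition_energy_ev
            return n

        n_hist = 150
        oracle = np.array([cascade_ionizations(1000.0) for _ in range(n_hist)])

        rng = random.Random(77)
        cfg = TransportConfig(record_events=False)
        counts = []
        for _ in range(n_hist):
            st = ParticleState("electron", (0, 0, 0), (0, 0, 1), 1000.0)
            counts.append(transport_electron(st, cfg, etables, rng).n_ionizations)
        counts = np.array(counts)

        se = math.sqrt(counts.var() / n_hist + oracle.var() / n_hist)
        assert abs(counts.mean() - oracle.mean()) < 3.0 * se

    def test_ionization_yield_stable_with_energy(self, etables):
        """Mean ionizations per unit energy (1/W) varies by <5% over 1-10 keV."""
        rng = random.Random(8)
        cfg = TransportConfig(record_events=False)
        w_values = []
        for e0, n in ((1000.0, 120), (10_000.0, 40)):
            total = 0
            for _ in range(n):
                st = ParticleState("electron", (0, 0, 0), (0, 0, 1), e0)
                total += transport_electron(st, cfg, etables, rng).n_ionizations
            w_values.append(e0 * n / total)
        assert abs(w_values[0] - w_values[1]) / w_values[0] < 0.05

    def test_track_extent_monotone_in_energy(self, etables):
        rng = random.Random(31)
        cfg = TransportConfig(record_events=False)
        medians = []
        for e0 in (100.0, 300.0, 1000.0, 3000.0):
            d = []
            for _ in range(200):
                st = ParticleState("electron", (0, 0, 0), (0, 0, 1), e0)
                d.append(transport_electron(st, cfg, etables, rng).max_displacement_nm)
            medians.append(np.median(d))
        assert all(a < b for a, b in zip(medians, medians[1:]))
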