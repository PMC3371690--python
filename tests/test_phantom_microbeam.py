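"""Materials, cell phantom construction and microbeam irradiation."""

import math
import random

import numpy as np
import pytest

from nanodos import dielectric as dl
from nanodos.materials import (
    CYTOPLASM,
    NUCLEUS,
    ORGANELLE,
    bragg_mean_excitation_energy,
    material_from_composition,
)
from nanodos.microbeam import (
    MicrobeamSpec,
    organelle_density_experiment,
    run_microbeam,
    summarize_microbeam,
)
from nanodos.phantom import (
    CellGeometry,
    ID_CYTOPLASM,
    ID_NUCLEUS,
    ID_ORGANELLE,
    ID_VACUUM,
    build_cell_phantom,
    read_phantom,
    write_phantom,
)


class TestMaterials:
    def test_cytoplasm_fractions_renormalised(self):
        m = material_from_composition(
            {"O": 58.0, "C": 20.0, "H": 9.0, "N": 8.5, "P": 4.5}, 1.0, "cyto"
        )
        assert sum(m.mass_fractions.values()) == pytest.approx(1.0, abs=1e-12)
        assert m.mass_fractions["O"] == pytest.approx(0.58)

    def test_all_zero_fractions_rejected(self):
        with pytest.raises(ValueError):
            material_from_composition({"O": 0.0, "H": 0.0}, 1.0)

    def test_water_bragg_rule_close_to_dielectric_log_moment(self, model):
        """Bragg-additivity I of the water proxy vs the f-sum log-moment of
        the Drude model (independent routes to the same physical quantity)."""
        i_bragg = bragg_mean_excitation_energy({"H": 0.1119, "O": 0.8881})
        i_model = dl.mean_excitation_energy(model)
        assert abs(i_model - i_bragg) / i_bragg < 0.10

    def test_density_doubling_doubles_electron_density(self):
        m1 = material_from_composition({"O": 0.6, "H": 0.4}, 1.0)
        m2 = material_from_composition({"O": 0.6, "H": 0.4}, 2.0)
        assert m2.electron_density_nm3 == pytest.approx(2 * m1.electron_density_nm3)
        assert m2.mass_fractions == m1.mass_fractions

    def test_organelle_material_is_dense_nuclear_composition(self):
        assert ORGANELLE.density_g_cm3 == 10.0
        assert ORGANELLE.mass_fractions == NUCLEUS.mass_fractions
        assert ORGANELLE.inelastic_scale() == pytest.approx(
            10.0 * NUCLEUS.inelastic_scale(), rel=1e-12
        )


class TestPhantom:
    def test_default_phantom_invariants(self):
        ph = build_cell_phantom(CellGeometry(), random.Random(1))
        g = ph.geometry
        r = g.organelle_radius_um
        for c in ph.organelle_centers_um:
            # organelle fully inside the cell
            assert sum(
                (ci / (s - r)) ** 2
                for ci, s in zip(c, g.cell_semiaxes_um)
            ) <= 1.0
            # clear of the nucleus
            assert sum(
                (ci / (s + r)) ** 2
                for ci, s in zip(c, g.nucleus_semiaxes_um)
            ) > 1.0
        # mutually non-overlapping
        cs = ph.organelle_centers_um
        for i in range(len(cs)):
            for j in range(i + 1, len(cs)):
                d = math.dist(cs[i], cs[j])
                assert d >= 2 * r - 1e-9
        # nucleus voxels exist and are strictly inside the cell extent
        assert (ph.material_ids == ID_NUCLEUS).sum() > 0

    def test_zero_organelles_two_material_phantom(self):
        ph = build_cell_phantom(
            CellGeometry(n_organelles=0), random.Random(2)
        )
        ids = np.unique(ph.material_ids)
        assert set(ids) == {ID_VACUUM, ID_CYTOPLASM, ID_NUCLEUS}

    def test_organelle_volume_bookkeeping(self):
        """Monte Carlo integration of the continuous geometry around each
        organelle reproduces the analytic total volume within 1%."""
        ph = build_cell_phantom(CellGeometry(), random.Random(3))
        r = ph.geometry.organelle_radius_um
        rng = np.random.default_rng(10)
        vol = 0.0
        n = 20_000
        for c in ph.organelle_centers_um:
            pts = rng.uniform(-r, r, size=(n, 3)) + np.asarray(c)
            inside = sum(
                ph.continuous_region(*p) == ID_ORGANELLE for p in pts
            )
            vol += inside / n * (2 * r) ** 3
        assert vol == pytest.approx(ph.analytic_organelle_volume_um3(), rel=0.01)

    def test_infeasible_packing_raises(self):
        geo = CellGeometry(
            cell_semiaxes_um=(2.0, 2.0, 2.0),
            nucleus_semiaxes_um=(1.5, 1.5, 1.5),
            n_organelles=200,
            organelle_radius_um=0.4,
        )
        with pytest.raises(RuntimeError):
            build_cell_phantom(geo, random.Random(4), max_attempts=2000)

    def test_deterministic_given_seed(self):
        a = build_cell_phantom(CellGeometry(), random.Random(9))
        b = build_cell_phantom(CellGeometry(), random.Random(9))
        np.testing.assert_array_equal(a.material_ids, b.material_ids)

    def test_write_read_round_trip(self, tmp_path):
        ph = build_cell_phantom(CellGeometry(n_organelles=3), random.Random(5))
        p1 = tmp_path / "ph.txt"
        p2 = tmp_path / "ph2.txt"
        write_phantom(ph, p1)
        ph2 = read_phantom(p1)
        np.testing.assert_array_equal(ph.material_ids, ph2.material_ids)
        assert ph2.materials[1].mass_fractions == pytest.approx(
            ph.materials[1].mass_fractions
        )
        write_phantom(ph2, p2)
        assert p1.read_bytes() == p2.read_bytes()


@pytest.fixture(scope="module")
def small_run(etables):
    ph = build_cell_phantom(CellGeometry(), random.Random(11))
    spec = MicrobeamSpec(histories=30, seed=5)
    return run_microbeam(ph, spec, etables)


class TestMicrobeam:
    def test_zero_histories_empty_result(self, etables):
        ph = build_cell_phantom(CellGeometry(), random.Random(1))
        res = run_microbeam(ph, MicrobeamSpec(histories=0, seed=1), etables)
        assert res.specific_energy_j_per_kg() == 0.0
        assert res.ion_map.sum() == 0

    def test_beam_overlapping_nucleus_rejected(self, etables):
        ph = build_cell_phantom(CellGeometry(), random.Random(1))
        with pytest.raises(ValueError):
            run_microbeam(
                ph, MicrobeamSpec(histories=1, seed=1, offset_um=(3.0, 0.0)),
                etables,
            )

    def test_projection_sums_match_3d_totals(self, small_run):
        s = summarize_microbeam(small_run)
        assert s.energy_cross_section.sum() == pytest.approx(
            small_run.energy_map.sum()
        )
        assert s.ion_cross_section.sum() == small_run.ion_map.sum()
        assert s.ion_longitudinal.sum() == small_run.ion_map.sum()

    def test_histogram_totals(self, small_run):
        s = summarize_microbeam(small_run)
        assert s.histogram.sum() == s.n_events_with_cyto_ionization
        assert s.n_events_with_cyto_ionization == int(
            (small_run.ionizations_per_event > 0).sum()
        )

    def test_energy_and_ionization_projections_correlated(self, small_run):
        s = summarize_microbeam(small_run)
        assert s.energy_ionization_correlation > 0.5

    def test_nucleus_untouched_by_offset_beam(self, small_run):
        assert small_run.gen0_nucleus_vertices == 0
        assert small_run.nucleus_ion_total < 0.01 * small_run.cyto_ion_total

    def test_lateral_containment(self, small_run):
        """Ionizations stay within the beam footprint plus a scatter margin."""
        ph = small_run.phantom
        ny, nz = ph.shape[1], ph.shape[2]
        v = ph.voxel_size_um
        y0 = ph.origin_um[1] + (np.arange(ny) + 0.5) * v
        z0 = ph.origin_um[2] + (np.arange(nz) + 0.5) * v
        yy, zz = np.meshgrid(y0, z0, indexing="ij")
        r_beam = small_run.spec.beam_diameter_um / 2.0
        oy, oz = small_run.spec.offset_um
        margin = 2.0 * v + 0.1  # voxel discretisation + max delta-ray range
        dist = np.hypot(yy - oy, zz - oz)
        cross = small_run.ion_map.sum(axis=0)
        inside = cross[dist <= r_beam + margin].sum()
        assert inside >= 0.95 * cross.sum()

    def test_ionizations_increase_with_organelle_density(self, etables):
        lo = organelle_density_experiment(
            31, histories=12, tables=etables, organelle_density_g_cm3=3.0
        )
        hi = organelle_density_experiment(
            31, histories=12, tables=etables, organelle_density_g_cm3=10.0
        )
        assert (
            hi["ionizations_region_organelle"]
            > lo["ionizations_region_organelle"]
            > lo["ionizations_region_uniform"]
        )
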