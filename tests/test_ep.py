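"""Eikonal activation, conduction velocity, AF surrogate and PS detection."""

import numpy as np
import pytest

from lamp import ep
from lamp.uac import UACField

from conftest import make_disk, make_strip, strip_uac


class TestElementSpeeds:
    def test_anisotropy_ratio_two(self):
        cfg = ep.ConductionSettings(sigma_l=0.4, sigma_t=0.1)
        vl, vt = ep.element_speeds(np.zeros((5, 3)), cfg)
        np.testing.assert_allclose(vl / vt, 2.0)

    def test_isotropic_limit(self):
        cfg = ep.ConductionSettings(sigma_l=0.2, sigma_t=0.2)
        vl, vt = ep.element_speeds(np.zeros((3, 3)), cfg)
        np.testing.assert_allclose(vl, vt)

    def test_invalid_conductivities_rejected(self):
        with pytest.raises(ValueError):
            ep.ConductionSettings(sigma_l=0.1, sigma_t=0.4)
        with pytest.raises(ValueError):
            ep.ConductionSettings(sigma_l=0.4, sigma_t=0.0)


class TestEikonal:
    def test_flat_sheet_matches_distance_field(self):
        # isotropic unit speed: LAT must equal Euclidean distance within 5%
        mesh = make_strip(34, 34, 10.0, 10.0)  # ≈0.3 mm edges
        centre = int(np.argmin(np.linalg.norm(mesh.vertices - [5.0, 5.0, 0.0], axis=1)))
        m = mesh.n_triangles
        speeds = (np.ones(m), np.ones(m))
        lat = ep.eikonal_lat(mesh, speeds, np.array([centre]))
        d = np.linalg.norm(mesh.vertices - mesh.vertices[centre], axis=1)
        h = mesh.mean_edge_length()
        assert np.abs(lat.times - d).max() < h  # absolute error is O(h)
        far = d > 10 * h
        rel = np.abs(lat.times[far] - d[far]) / d[far]
        assert rel.max() < 0.05
        assert lat.times[centre] == 0.0

    def test_dijkstra_upper_bound(self):
        mesh = make_strip(21, 21, 10.0, 10.0)
        m = mesh.n_triangles
        rng = np.random.default_rng(0)
        fib = np.zeros((m, 3))
        fib[:, 0] = 1.0
        cfg = ep.ConductionSettings()
        speeds = ep.element_speeds(fib, cfg)
        stim = np.array([0])
        lat = ep.eikonal_lat(mesh, speeds, stim, fibres=fib)
        dj = ep.dijkstra_lat(mesh, speeds, stim, fibres=fib)
        assert np.all(lat.times <= dj.times + 1e-9)

    def test_unreached_component_flagged(self):
        a = make_strip(4, 4, 1.0, 1.0)
        b = make_strip(4, 4, 1.0, 1.0)
        b.vertices[:, 0] += 10.0
        from lamp.mesh import LabelledSurfaceMesh

        both = LabelledSurfaceMesh(
            vertices=np.vstack([a.vertices, b.vertices]),
            triangles=np.vstack([a.triangles, b.triangles + a.n_vertices]),
        )
        m = both.n_triangles
        lat = ep.eikonal_lat(both, (np.ones(m), np.ones(m)), np.array([0]))
        assert np.isfinite(lat.times[: a.n_vertices]).all()
        assert np.isinf(lat.times[a.n_vertices :]).all()


class TestConductionVelocity:
    def test_planar_wave_closed_form(self):
        mesh = make_strip(21, 11, 10.0, 5.0)
        lat = ep.LATMap(times=mesh.vertices[:, 0] / 0.5, stimulus=np.array([0]))
        cv = ep.cv_map(lat, mesh)
        np.testing.assert_allclose(cv, 0.5, atol=1e-9)

    def test_longitudinal_transverse_ratio(self):
        mesh = make_strip(41, 41, 10.0, 10.0)
        m = mesh.n_triangles
        fib = np.zeros((m, 3))
        fib[:, 0] = 1.0  # fibres along +x
        cfg = ep.ConductionSettings()
        speeds = ep.element_speeds(fib, cfg)
        x0 = np.flatnonzero(np.isclose(mesh.vertices[:, 0], 0.0))
        y0 = np.flatnonzero(np.isclose(mesh.vertices[:, 1], 0.0))
        lat_l = ep.eikonal_lat(mesh, speeds, x0, fibres=fib)  # along fibres
        lat_t = ep.eikonal_lat(mesh, speeds, y0, fibres=fib)  # across fibres
        cv_l = np.nanmedian(ep.cv_map(lat_l, mesh))
        cv_t = np.nanmedian(ep.cv_map(lat_t, mesh))
        assert abs(cv_l / cv_t - 2.0) < 0.05


class TestSpiralInitiation:
    def test_four_spirals_have_four_singularities(self):
        mesh = make_strip(41, 41, 1.0, 1.0)
        uac = strip_uac(mesh, 1.0, 1.0)
        phi = ep.spiral_phase(uac, ep.FOUR_SPIRAL_CENTRES, ep.FOUR_SPIRAL_CHIRALITY, pitch=0.2)
        det = ep.detect_phase_singularities(phi, mesh)
        assert len(det) == 4
        assert det[:, 2].sum() == 0  # alternating chirality: net charge zero
        found = np.array([[uac.alpha[v], uac.beta[v]] for _, v, _ in det])
        d = np.linalg.norm(found[:, None, :] - ep.FOUR_SPIRAL_CENTRES[None], axis=2)
        # each detection sits at a distinct centre, with the centre's chirality
        assert sorted(d.argmin(axis=1)) == [0, 1, 2, 3]
        assert d.min(axis=1).max() < 0.05
        np.testing.assert_array_equal(
            det[:, 2], ep.FOUR_SPIRAL_CHIRALITY[d.argmin(axis=1)]
        )

    def test_single_spiral_single_singularity(self):
        mesh = make_strip(41, 41, 1.0, 1.0)
        uac = strip_uac(mesh, 1.0, 1.0)
        init = ep.init_single_spiral(uac)
        det = ep.detect_phase_singularities(init["phase"], mesh)
        assert len(det) == 1 and det[0, 2] == 1

    def test_state_lies_on_pulse_cycle(self):
        mesh = make_strip(11, 11, 1.0, 1.0)
        uac = strip_uac(mesh, 1.0, 1.0)
        init = ep.init_four_spirals(uac)
        assert init["u"].min() > -0.2 and init["u"].max() < 1.2
        assert init["w"].min() >= 0.0


class TestPhaseSingularityDetector:
    def test_uniform_phase_no_detections(self):
        mesh = make_disk(5.0, 0.5)
        det = ep.detect_phase_singularities(np.full(mesh.n_vertices, 0.3), mesh)
        assert len(det) == 0

    def test_planted_vortex_detected_once_with_charge(self):
        mesh = make_disk(5.0, 0.4)
        phi = np.arctan2(mesh.vertices[:, 1], mesh.vertices[:, 0])
        det = ep.detect_phase_singularities(phi, mesh)
        assert len(det) == 1
        frame, vertex, charge = det[0]
        assert charge == 1
        assert np.linalg.norm(mesh.vertices[vertex][:2]) < 1.0

    def test_binning_places_vortex_in_centre_cell(self):
        mesh = make_disk(5.0, 0.4)
        phi = np.arctan2(mesh.vertices[:, 1], mesh.vertices[:, 0])
        det = ep.detect_phase_singularities(phi, mesh)
        uac = UACField(
            alpha=(mesh.vertices[:, 0] + 5.0) / 10.0, beta=(mesh.vertices[:, 1] + 5.0) / 10.0
        )
        ps = ep.bin_ps(det, uac, grid_size=101)
        assert ps.grid.sum() == len(det)
        i, j = np.unravel_index(np.argmax(ps.grid), ps.grid.shape)
        assert abs(i - 50) <= 2 and abs(j - 50) <= 2


class TestMonodomain:
    def test_rest_state_stays_at_rest(self):
        mesh = make_strip(11, 11, 5.0, 5.0)
        m = mesh.n_triangles
        fib = np.zeros((m, 3))
        fib[:, 0] = 1.0
        init = {"u": np.zeros(mesh.n_vertices), "w": np.zeros(mesh.n_vertices)}
        out = ep.simulate_af(mesh, fib, ep.ConductionSettings(), init, duration=50.0, dt=0.1)
        assert np.abs(out["u"][-1]).max() < 1e-12

    def test_bit_deterministic(self):
        mesh = make_strip(11, 11, 5.0, 5.0)
        fib = np.zeros((mesh.n_triangles, 3))
        fib[:, 0] = 1.0
        uac = strip_uac(mesh, 5.0, 5.0)
        uac = UACField(alpha=uac.alpha * 5, beta=uac.beta * 5)  # rescale to [0,1]
        init = ep.init_single_spiral(UACField(mesh.vertices[:, 0] / 5, mesh.vertices[:, 1] / 5))
        a = ep.simulate_af(mesh, fib, ep.ConductionSettings(), init, duration=20.0, dt=0.1)
        b = ep.simulate_af(mesh, fib, ep.ConductionSettings(), init, duration=20.0, dt=0.1)
        np.testing.assert_array_equal(a["u"], b["u"])

    def test_planar_pulse_travels_at_constant_speed(self):
        # long thin strip; pulse initiated at one end via the cycle state
        mesh = make_strip(101, 6, 50.0, 2.5)
        m = mesh.n_triangles
        fib = np.zeros((m, 3))
        fib[:, 0] = 1.0
        x = mesh.vertices[:, 0]
        u = np.where(x < 3.0, 1.0, 0.0)
        w = np.where((x >= 3.0) & (x < 6.0), 1.5, 0.0)
        out = ep.simulate_af(
            mesh, fib, ep.ConductionSettings(), {"u": u, "w": w},
            duration=120.0, dt=0.05, sample_dt=10.0,
        )
        fronts = []
        for frame in out["u"]:
            active = x[frame > 0.5]
            fronts.append(active.max() if len(active) else np.nan)
        fronts = np.array(fronts)
        ok = np.isfinite(fronts) & (fronts < 45.0)
        speeds = np.diff(fronts[ok]) / 10.0
        speeds = speeds[2:]  # discard initiation transient
        assert len(speeds) >= 3
        assert speeds.std() / speeds.mean() < 0.05

    def test_instability_aborts_with_diagnostic(self):
        mesh = make_strip(11, 11, 2.0, 2.0)  # 0.2 mm edges
        fib = np.zeros((mesh.n_triangles, 3))
        fib[:, 0] = 1.0
        init = {"u": np.ones(mesh.n_vertices), "w": np.zeros(mesh.n_vertices)}
        with pytest.raises(ep.SimulationError, match="CFL"):
            ep.simulate_af(mesh, fib, ep.ConductionSettings(), init, duration=50.0, dt=5.0)
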