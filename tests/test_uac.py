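"""Universal atrial coordinates and fibre transport."""

import numpy as np
import pytest

from lamp.uac import (
    FibreAtlas,
    FibreField,
    LandmarkSet,
    UACError,
    build_builtin_atlas,
    classify_boundary_loops,
    compute_uac,
    construct_boundary_paths,
    cotangent_laplacian,
    generate_rule_based_fibres,
    map_fibres_from_atlas,
    smooth_varying_fibres,
    solve_laplace,
    uac_frames,
)

from conftest import make_strip, strip_uac


class TestLaplace:
    def test_flat_strip_reproduces_linear_field(self):
        mesh = make_strip(21, 11, 1.0, 0.5)
        x = mesh.vertices[:, 0]
        left = np.flatnonzero(np.isclose(x, 0.0))
        right = np.flatnonzero(np.isclose(x, 1.0))
        field = solve_laplace(mesh, left, right)
        np.testing.assert_allclose(field, x, atol=1e-8)

    def test_constant_is_harmonic(self):
        mesh = make_strip(11, 11, 1.0, 1.0)
        L = cotangent_laplacian(mesh)
        np.testing.assert_allclose(L @ np.zeros(mesh.n_vertices), 0.0, atol=1e-12)
        np.testing.assert_allclose(L @ np.ones(mesh.n_vertices), 0.0, atol=1e-10)

    def test_rejects_overlapping_or_empty_sets(self):
        mesh = make_strip(5, 5, 1.0, 1.0)
        with pytest.raises(UACError):
            solve_laplace(mesh, np.array([0, 1]), np.array([1, 2]))
        with pytest.raises(UACError):
            solve_laplace(mesh, np.array([], dtype=int), np.array([1]))


class TestBoundaryPaths:
    def test_paths_connect_mv_rim_to_superior_pv_rims(self, atrium):
        mesh, truth = atrium["mesh"], atrium["truth"]
        rims = classify_boundary_loops(mesh)
        assert {"MV", "LSPV", "LIPV", "RSPV", "RIPV"} <= set(rims)
        (septal, lateral), (posterior, anterior) = construct_boundary_paths(
            mesh, truth.landmarks
        )
        mv = set(rims["MV"].tolist())
        assert septal[0] in mv and lateral[0] in mv
        assert septal[-1] in set(rims["RSPV"].tolist())
        assert lateral[-1] in set(rims["LSPV"].tolist())
        sets = [set(s.tolist()) for s in (septal, lateral, posterior, anterior)]
        for i in range(4):
            for j in range(i + 1, 4):
                assert not sets[i] & sets[j]

    def test_landmark_on_mv_rim_rejected(self, atrium):
        mesh, truth = atrium["mesh"], atrium["truth"]
        rims = classify_boundary_loops(mesh)
        on_rim = mesh.vertices[rims["MV"][0]]
        bad = LandmarkSet(
            lspv_junction=truth.landmarks.lspv_junction,
            rspv_junction=truth.landmarks.rspv_junction,
            lateral=truth.landmarks.lateral,
            septal=on_rim,
        )
        with pytest.raises(UACError):
            construct_boundary_paths(mesh, bad)

    def test_distant_landmark_rejected(self, atrium):
        mesh, truth = atrium["mesh"], atrium["truth"]
        bad = LandmarkSet(
            lspv_junction=truth.landmarks.lspv_junction,
            rspv_junction=truth.landmarks.rspv_junction,
            lateral=truth.landmarks.lateral,
            septal=truth.landmarks.septal + 500.0,
        )
        with pytest.raises(UACError):
            construct_boundary_paths(mesh, bad)


class TestComputeUAC:
    def test_boundary_values_and_maximum_principle(self, atrium):
        mesh, uac = atrium["mesh"], atrium["uac"]
        (septal, lateral), (posterior, anterior) = construct_boundary_paths(
            mesh, atrium["truth"].landmarks
        )
        np.testing.assert_allclose(uac.alpha[septal], 0.0, atol=1e-12)
        np.testing.assert_allclose(uac.alpha[lateral], 1.0, atol=1e-12)
        np.testing.assert_allclose(uac.beta[posterior], 0.0, atol=1e-12)
        np.testing.assert_allclose(uac.beta[anterior], 1.0, atol=1e-12)
        interior = np.ones(mesh.n_vertices, dtype=bool)
        interior[septal] = interior[lateral] = False
        assert uac.alpha[interior].min() > 0.0 and uac.alpha[interior].max() < 1.0
        interior_b = np.ones(mesh.n_vertices, dtype=bool)
        interior_b[posterior] = interior_b[anterior] = False
        assert uac.beta[interior_b].min() > 0.0 and uac.beta[interior_b].max() < 1.0

    def test_alpha_semantics_at_landmarks(self, atrium):
        mesh, uac, truth = atrium["mesh"], atrium["uac"], atrium["truth"]
        tree = mesh.vertex_tree()
        _, sep = tree.query(truth.landmarks.septal)
        _, lat = tree.query(truth.landmarks.lateral)
        assert uac.alpha[sep] < 0.05
        assert uac.alpha[lat] > 0.95

    def test_invariant_to_vertex_reordering(self, atrium):
        mesh, truth = atrium["mesh"], atrium["truth"]
        rng = np.random.default_rng(0)
        perm = rng.permutation(mesh.n_vertices)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        from lamp.mesh import LabelledSurfaceMesh

        shuffled = LabelledSurfaceMesh(
            vertices=mesh.vertices[perm],
            triangles=inv[mesh.triangles],
            element_labels=mesh.element_labels.copy(),
        )
        uac0 = atrium["uac"]
        uac1 = compute_uac(shuffled, truth.landmarks)
        np.testing.assert_allclose(uac1.alpha, uac0.alpha[perm], atol=1e-8)
        np.testing.assert_allclose(uac1.beta, uac0.beta[perm], atol=1e-8)


class TestFibreMapping:
    def test_self_mapping_recovers_fibres(self, atrium):
        mesh, uac = atrium["mesh"], atrium["uac"]
        atlas = build_builtin_atlas(mesh, uac)
        original = atlas.fields["l"].vectors
        mapped = map_fibres_from_atlas(mesh, uac, atlas, "l").vectors
        dots = np.abs(np.einsum("ij,ij->i", mapped, original))
        angles = np.degrees(np.arccos(np.clip(dots, -1.0, 1.0)))
        assert angles.max() < 1.0

    def test_constant_alpha_field_transports_to_alpha_direction(self, atrium):
        mesh, uac = atrium["mesh"], atrium["uac"]
        e_a, _, _, valid = uac_frames(mesh, uac)
        atlas = FibreAtlas(mesh=mesh, uac=uac, fields={"a": FibreField(vectors=e_a)})
        mapped = map_fibres_from_atlas(mesh, uac, atlas, "a").vectors
        dots = np.abs(np.einsum("ij,ij->i", mapped[valid], e_a[valid]))
        angles = np.degrees(np.arccos(np.clip(dots, -1.0, 1.0)))
        assert angles.mean() < 5.0

    def test_transport_commutes_with_rigid_motion(self, atrium):
        mesh, uac = atrium["mesh"], atrium["uac"]
        atlas = build_builtin_atlas(mesh, uac)
        mapped = map_fibres_from_atlas(mesh, uac, atlas, "1").vectors
        theta = 0.7
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0.0],
                [np.sin(theta), np.cos(theta), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        moved = mesh.copy()
        moved.vertices = mesh.vertices @ R.T
        mapped_moved = map_fibres_from_atlas(moved, uac, atlas, "1").vectors
        dots = np.abs(np.einsum("ij,ij->i", mapped_moved, mapped @ R.T))
        angles = np.degrees(np.arccos(np.clip(dots, -1.0, 1.0)))
        assert np.median(angles) < 0.5

    def test_missing_field_rejected(self, atrium):
        mesh, uac = atrium["mesh"], atrium["uac"]
        atlas = build_builtin_atlas(mesh, uac)
        with pytest.raises(UACError):
            map_fibres_from_atlas(mesh, uac, atlas, "nope")


class TestRuleBasedFibres:
    def test_deterministic(self, atrium):
        mesh, uac = atrium["mesh"], atrium["uac"]
        f1 = generate_rule_based_fibres(uac, mesh).vectors
        f2 = generate_rule_based_fibres(uac, mesh).vectors
        np.testing.assert_array_equal(f1, f2)

    def test_tangent_and_unit(self, atrium):
        mesh, uac = atrium["mesh"], atrium["uac"]
        for fld in (generate_rule_based_fibres(uac, mesh), smooth_varying_fibres(uac, mesh)):
            v = fld.vectors
            np.testing.assert_allclose(np.linalg.norm(v, axis=1), 1.0, atol=1e-6)
            n = mesh.normals()
            assert np.abs(np.einsum("ij,ij->i", v, n)).max() < 1e-3

    def test_flat_square_regions(self):
        # on an identity-UAC flat sheet the rule regions are exact
        mesh = make_strip(21, 21, 1.0, 1.0)
        uac = strip_uac(mesh, 1.0, 1.0)
        f = generate_rule_based_fibres(uac, mesh).vectors
        c = mesh.centroids()
        near_mv = (c[:, 1] < 0.14) | (c[:, 1] > 0.86)
        # circumferential near the mitral rim: along +x (the α direction)
        assert np.abs(np.abs(f[near_mv, 0]) - 1.0).max() < 1e-6
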