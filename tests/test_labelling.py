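"""Segmentation labelling, junction detection, surfacing and clipping."""

import numpy as np
import pytest

from lamp.labelling import (
    ClippingError,
    ClippingSphere,
    DetectionError,
    LabellingError,
    MultilabelSegmentation,
    PROVISIONAL_BASE,
    StructureSeed,
    assign_naive_labels,
    clip_structures,
    extract_labelled_surface,
    identify_structure,
    verify_labels,
)
from lamp.mesh import STRUCTURE_LABELS
from lamp.volume import Volume

from conftest import make_icosphere


def _seg(data):
    return MultilabelSegmentation(volume=Volume(data=data.astype(np.int16)))


def _ball(shape, centre, r):
    idx = np.indices(shape).reshape(3, -1).T
    return (np.linalg.norm(idx - np.asarray(centre), axis=1) <= r).reshape(shape)


class TestNaiveLabels:
    def test_single_component(self):
        data = np.zeros((10, 10, 10))
        data[2:4, 2:4, 2:4] = 2
        out = assign_naive_labels(_seg(data))
        assert set(np.unique(out.data)) == {0, PROVISIONAL_BASE}

    def test_components_ordered_by_size(self):
        # five blocks of 500 > 400 > 300 > 200 > 100 voxels
        data = np.zeros((60, 40, 12))
        sizes = []
        blocks = [(10, 10, 5), (10, 8, 5), (10, 6, 5), (10, 5, 4), (5, 5, 4)]
        x = 0
        for bx, by, bz in blocks:
            data[x : x + bx, :by, :bz] = 2
            sizes.append(bx * by * bz)
            x += bx + 2
        assert sizes == sorted(sizes, reverse=True)
        out = assign_naive_labels(_seg(data))
        # brute-force oracle: count voxels per provisional label
        for rank in range(5):
            assert (out.data == PROVISIONAL_BASE + rank).sum() == sizes[rank]

    def test_empty_class_errors(self):
        with pytest.raises(LabellingError):
            assign_naive_labels(_seg(np.ones((5, 5, 5))))


class TestIdentifyStructure:
    def _tube_and_ball(self):
        """Cylinder r=5 along +x joined to a sphere r=20; analytic junction."""
        shape = (100, 60, 60)
        idx = np.indices(shape).reshape(3, -1).T.astype(float)
        sphere_c = np.array([65.0, 30.0, 30.0])
        ball = np.linalg.norm(idx - sphere_c, axis=1) <= 20.0
        rad = np.linalg.norm(idx[:, 1:] - 30.0, axis=1)
        tube = (rad <= 5.0) & (idx[:, 0] >= 8) & (idx[:, 0] <= 65)
        data = np.zeros(shape)
        data.reshape(-1)[ball] = 1
        data.reshape(-1)[tube & ~ball] = 2
        return _seg(data), sphere_c

    def test_junction_found_near_analytic_position(self):
        seg, sphere_c = self._tube_and_ball()
        # RAI affine is identity here; world == index space
        seed = StructureSeed(point=[9.0, 30.0, 30.0], structure="LSPV")
        centre, radius = identify_structure(seg, seed)
        # tube meets the sphere at x = 65 - sqrt(20² - 5²) ≈ 45.6
        x_true = 65.0 - np.sqrt(20.0**2 - 5.0**2)
        assert abs(centre[0] - x_true) <= 2.0
        assert abs(radius - 5.0) <= 2.0

    def test_uniform_cylinder_has_no_inflection(self):
        shape = (60, 30, 30)
        idx = np.indices(shape).reshape(3, -1).T.astype(float)
        rad = np.linalg.norm(idx[:, 1:] - 15.0, axis=1)
        data = np.zeros(shape)
        data.reshape(-1)[(rad <= 5.0)] = 1
        seed = StructureSeed(point=[2.0, 15.0, 15.0], structure="LAA")
        with pytest.raises(DetectionError):
            identify_structure(_seg(data), seed)

    def test_translation_invariance(self):
        seg, _ = self._tube_and_ball()
        shifted = MultilabelSegmentation(
            volume=Volume(data=np.roll(seg.volume.data, 3, axis=2))
        )
        c0, _ = identify_structure(seg, StructureSeed([9.0, 30.0, 30.0], "LSPV"))
        c1, _ = identify_structure(shifted, StructureSeed([9.0, 30.0, 33.0], "LSPV"))
        assert np.linalg.norm((c1 - [0, 0, 3]) - c0) <= 1.0


class TestExtractSurface:
    def test_ball_gives_closed_genus0_surface_with_area(self):
        r = 10
        mask = _ball((32, 32, 32), (16, 16, 16), r)
        data = np.where(mask, 1, 0)
        mesh = extract_labelled_surface(_seg(data))
        assert len(mesh.boundary_loops()) == 0
        v, e, f = mesh.n_vertices, len(mesh.edges()), mesh.n_triangles
        assert v - e + f == 2  # genus 0
        assert set(np.unique(mesh.element_labels)) == {STRUCTURE_LABELS["LA"]}
        area = mesh.areas().sum()
        assert abs(area - 4 * np.pi * r**2) / (4 * np.pi * r**2) < 0.10

    def test_two_labels_partition_along_plane(self):
        mask = _ball((32, 32, 32), (16, 16, 16), 10)
        labels = np.where(mask, 1, 0)
        labels[16:][mask[16:]] = STRUCTURE_LABELS["LAA"]
        seg = _seg(np.where(mask, 1, 0))
        mesh = extract_labelled_surface(seg, Volume(data=labels.astype(np.int16)))
        cent = mesh.centroids()
        la = mesh.element_labels == 1
        # voxel-centre plane between index 15 and 16: world x = ±15.5-ish
        assert np.all(np.abs(cent[la, 0]) <= 16.5)

    def test_empty_segmentation_errors(self):
        with pytest.raises(LabellingError):
            extract_labelled_surface(_seg(np.zeros((5, 5, 5))))


class TestVerifyLabels:
    def test_clean_mesh_unchanged(self):
        mesh = make_icosphere(5.0, 2)
        mesh.element_labels[:] = STRUCTURE_LABELS["LA"]
        out = verify_labels(mesh)
        np.testing.assert_array_equal(out.element_labels, mesh.element_labels)

    def test_disconnected_island_relabelled(self):
        mesh = make_icosphere(5.0, 3)
        labels = np.full(mesh.n_triangles, STRUCTURE_LABELS["LA"])
        cent = mesh.centroids()
        # genuine LAA patch at the north pole, plus a far island near the south
        labels[cent[:, 2] > 4.5] = STRUCTURE_LABELS["LAA"]
        island = np.argsort(cent[:, 2])[:10]
        labels[island] = STRUCTURE_LABELS["LAA"]
        mesh.element_labels = labels
        out = verify_labels(mesh)
        assert np.all(out.element_labels[island] == STRUCTURE_LABELS["LA"])
        assert (out.element_labels == STRUCTURE_LABELS["LAA"]).sum() > 0
        # idempotent
        again = verify_labels(out)
        np.testing.assert_array_equal(again.element_labels, out.element_labels)


class TestClipStructures:
    def test_empty_sphere_list_identity(self):
        mesh = make_icosphere(5.0, 2)
        assert clip_structures(mesh, []) is mesh

    def test_clip_opens_one_loop_inside_sphere(self, atrium):
        surface = atrium["surface"]
        sphere = [s for s in atrium["truth"].clip_spheres if s.target == "LSPV"]
        clipped = clip_structures(surface, sphere)
        loops = clipped.boundary_loops()
        assert len(loops) == 1
        centroid = clipped.vertices[loops[0]].mean(axis=0)
        assert np.linalg.norm(centroid - sphere[0].centre) < sphere[0].radius

    def test_no_new_vertices_added(self, atrium):
        surface = atrium["surface"]
        clipped = clip_structures(surface, atrium["truth"].clip_spheres)
        assert clipped.n_vertices <= surface.n_vertices

    def test_oversized_sphere_rejected(self):
        mesh = make_icosphere(5.0, 2)
        sphere = ClippingSphere(centre=[0.0, 0.0, 0.0], radius=100.0, target="MV")
        with pytest.raises(ClippingError):
            clip_structures(mesh, [sphere])

    def test_five_openings_after_full_clip(self, atrium):
        assert len(atrium["clipped"].boundary_loops()) == 5
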