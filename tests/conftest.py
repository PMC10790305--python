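"""Shared fixtures: analytic meshes and a small synthetic atrium bundle."""

from __future__ import annotations

import numpy as np
import pytest

from lamp.labelling import (
    clip_structures,
    extract_labelled_surface,
    label_from_seeds,
    verify_labels,
)
from lamp.mesh import LabelledSurfaceMesh
from lamp.refine import remesh_to_edge_length
from lamp.synthetic import generate_case
from lamp.uac import compute_uac, UACField


def make_strip(nx: int, ny: int, lx: float, ly: float) -> LabelledSurfaceMesh:
    """Flat rectangular sheet in the z=0 plane, criss-cross triangulation.

    Each grid cell is split into four triangles around its centre, which
    gives eight propagation directions and near-isotropic discretisation.
    """
    xs = np.linspace(0.0, lx, nx)
    ys = np.linspace(0.0, ly, ny)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    corners = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
    cx, cy = np.meshgrid(
        (xs[:-1] + xs[1:]) / 2.0, (ys[:-1] + ys[1:]) / 2.0, indexing="ij"
    )
    centres = np.column_stack([cx.ravel(), cy.ravel(), np.zeros(cx.size)])
    verts = np.concatenate([corners, centres])
    n0 = len(corners)

    def cidx(i, j):
        return i * ny + j

    tris = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            c = n0 + i * (ny - 1) + j
            a, b = cidx(i, j), cidx(i + 1, j)
            d, e = cidx(i + 1, j + 1), cidx(i, j + 1)
            tris += [(a, b, c), (b, d, c), (d, e, c), (e, a, c)]
    return LabelledSurfaceMesh(vertices=verts, triangles=np.array(tris))


def strip_uac(mesh: LabelledSurfaceMesh, lx: float, ly: float) -> UACField:
    """Identity UAC on a flat strip: α = x/lx, β = y/ly."""
    return UACField(alpha=mesh.vertices[:, 0] / lx, beta=mesh.vertices[:, 1] / ly)


def make_disk(radius: float, h: float) -> LabelledSurfaceMesh:
    """Flat disk: strip mesh restricted to triangles inside the radius."""
    n = int(round(2 * radius / h)) + 1
    strip = make_strip(n, n, 2 * radius, 2 * radius)
    strip.vertices[:, :2] -= radius
    cent = strip.centroids()
    keep = np.linalg.norm(cent[:, :2], axis=1) <= radius
    return strip.submesh(keep)


def make_icosphere(radius: float = 5.0, subdivisions: int = 3) -> LabelledSurfaceMesh:
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
            [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
            [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
        ],
        dtype=float,
    )
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ]
    )
    for _ in range(subdivisions):
        mid: dict[tuple[int, int], int] = {}
        vlist = list(verts)

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in mid:
                vlist.append((vlist[i] + vlist[j]) / 2.0)
                mid[key] = len(vlist) - 1
            return mid[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        verts = np.array(vlist)
        faces = np.array(new_faces)
    verts = verts / np.linalg.norm(verts, axis=1)[:, None] * radius
    return LabelledSurfaceMesh(vertices=verts, triangles=faces)


@pytest.fixture(scope="session")
def atrium():
    """One small synthetic case taken through labelling, clipping, remeshing
    and UAC — shared across modules to keep the suite fast."""
    truth = generate_case(1)
    labels = label_from_seeds(truth.seg, truth.seeds)
    surface = verify_labels(extract_labelled_surface(truth.seg, labels))
    clipped = clip_structures(surface, truth.clip_spheres)
    remeshed = remesh_to_edge_length(clipped, target=0.8)
    uac = compute_uac(remeshed, truth.landmarks)
    return {
        "truth": truth,
        "surface": surface,
        "clipped": clipped,
        "mesh": remeshed,
        "uac": uac,
    }
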