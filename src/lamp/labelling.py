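"""From a multilabel segmentation to a labelled, clipped atrial surface.

The segmentation distinguishes background, the left-atrial body bloodpool,
a pulmonary-vein/appendage class and a mitral-valve disc.  Veins and the
appendage are first given provisional labels by component size, then
identified from user (or synthetic-operator) seed points: a line is drawn
from each seed to the atrial centre of mass, the cross-sectional radius of
the bloodpool is profiled along it, and the inflection of that profile
marks the structure/body junction.  The surface is extracted by marching
cubes, labels projected onto it, verified for connectivity, and finally
clipped open at the four pulmonary veins and the mitral valve with spheres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure

from lamp.mesh import LabelledSurfaceMesh, STRUCTURE_LABELS
from lamp.volume import Volume

#: Segmentation class codes.
SEG_CLASSES = {"background": 0, "LA": 1, "PVLAA": 2, "MV": 3}

#: Provisional labels start here, assigned largest component first.
PROVISIONAL_BASE = 100


class LabellingError(ValueError):
    pass


class DetectionError(ValueError):
    """No radius inflection found; the junction disk must be placed manually."""


class ClippingError(ValueError):
    pass


@dataclass
class MultilabelSegmentation:
    """Integer class volume: {0 background, 1 LA body, 2 PV∪LAA, 3 MV}."""

    volume: Volume

    def __post_init__(self) -> None:
        if not self.volume.is_label:
            raise LabellingError("segmentation volume must hold integer classes")
        present = set(np.unique(self.volume.data).tolist())
        if not present <= set(SEG_CLASSES.values()):
            raise LabellingError(f"unexpected class codes {sorted(present)}")

    def class_mask(self, name: str) -> np.ndarray:
        return self.volume.data == SEG_CLASSES[name]

    def bloodpool_mask(self) -> np.ndarray:
        """Body plus veins/appendage; the MV disc is a marker, not bloodpool."""
        return self.class_mask("LA") | self.class_mask("PVLAA")


@dataclass
class StructureSeed:
    point: np.ndarray  # world mm, distal end of a vein/appendage
    structure: str  # one of LAA, LSPV, LIPV, RSPV, RIPV

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        if self.structure not in ("LAA", "LSPV", "LIPV", "RSPV", "RIPV"):
            raise ValueError(f"unknown structure {self.structure!r}")


@dataclass
class ClippingSphere:
    centre: np.ndarray  # world mm
    radius: float  # mm
    target: str  # LSPV, LIPV, RSPV, RIPV or MV

    def __post_init__(self) -> None:
        self.centre = np.asarray(self.centre, dtype=float).reshape(3)
        if self.radius <= 0:
            raise ValueError("clipping sphere radius must be positive")


# --------------------------------------------------------------- naive labelling
def assign_naive_labels(seg: MultilabelSegmentation) -> Volume:
    """Enumerate PV∪LAA components largest-first into provisional labels.

    Components are sorted by voxel count descending (ties by lexicographic
    order of their centroids) and assigned ``PROVISIONAL_BASE + rank``.
    The provisional labels must later be identified against user seeds.
    """
    mask = seg.class_mask("PVLAA")
    if not mask.any():
        raise LabellingError("PV/LAA class is empty; nothing to label")
    comp, n = ndimage.label(mask)
    sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
    centroids = np.array(ndimage.center_of_mass(mask, comp, index=np.arange(1, n + 1)))
    order = sorted(
        range(n), key=lambda i: (-sizes[i], tuple(centroids[i]))
    )
    out = seg.volume.data.copy()
    for rank, ci in enumerate(order):
        out[comp == ci + 1] = PROVISIONAL_BASE + rank
    return Volume(data=out, affine=seg.volume.affine.copy())


# --------------------------------------------------------- structure identification
def _radius_profile(mask: np.ndarray, volume: Volume, seed_w, com_w, n_stations: int):
    """Inscribed-disk radius of the bloodpool cross-section at stations along
    the seed→centre-of-mass line (station spacing one voxel)."""
    spacing = float(volume.spacing.min())
    d = np.asarray(com_w, float) - np.asarray(seed_w, float)
    length = np.linalg.norm(d)
    d = d / length
    # in-plane orthonormal basis
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    half = 30.0  # mm search window in the cross-section plane
    grid = np.arange(-half, half + 1e-9, spacing)
    uu, vv = np.meshgrid(grid, grid, indexing="ij")
    stations = np.arange(0.0, length, spacing)[:n_stations] if n_stations else np.arange(0.0, length, spacing)
    radii = np.full(len(stations), np.nan)
    centre_idx = len(grid) // 2
    for k, s in enumerate(stations):
        c = np.asarray(seed_w, float) + s * d
        pts = c + uu[..., None] * e1 + vv[..., None] * e2
        vox = volume.world_to_voxel(pts.reshape(-1, 3)).T
        inside = ndimage.map_coordinates(mask.astype(np.uint8), vox, order=0, mode="constant")
        section = inside.reshape(uu.shape).astype(bool)
        comp, _ = ndimage.label(section)
        cid = comp[centre_idx, centre_idx]
        if cid == 0:
            continue
        region = comp == cid
        edt = ndimage.distance_transform_edt(region, sampling=spacing)
        radii[k] = float(edt.max())
    return stations, radii, d


def identify_structure(
    seg: MultilabelSegmentation,
    seed: StructureSeed,
    smooth_window: int = 3,
    min_curvature: float = 0.15,
):
    """Locate the junction between a vein/appendage and the atrial body.

    Walking from the seed toward the bloodpool centre of mass, the smoothed
    cross-sectional radius profile is second-differenced; the first station
    attaining the maximum second difference is the junction.  Returns
    ``(junction_centre, junction_radius)`` — a disk the caller may move.

    Raises
    ------
    DetectionError
        If the profile has no inflection (e.g. a uniform cylinder).
    """
    mask = seg.bloodpool_mask()
    if not mask.any():
        raise LabellingError("empty bloodpool")
    vol = seg.volume
    idx = np.argwhere(mask)
    com = vol.voxel_to_world(idx.mean(axis=0)[None, :])[0]
    stations, radii, d = _radius_profile(mask, vol, seed.point, com, n_stations=0)
    valid = ~np.isnan(radii)
    if valid.sum() < smooth_window + 2:
        raise DetectionError("radius profile too short to locate a junction")
    radii = np.interp(stations, stations[valid], radii[valid])
    kernel = np.ones(smooth_window) / smooth_window
    smooth = np.convolve(radii, kernel, mode="same")
    d2 = np.diff(smooth, 2)  # second difference, index i -> station i+1
    if len(d2) == 0 or d2.max() < min_curvature:
        raise DetectionError(
            "radius profile is monotone within tolerance; place the junction disk manually"
        )
    k = int(np.argmax(d2 >= d2.max() - 1e-12)) + 1
    centre = np.asarray(seed.point, float) + stations[k] * d
    return centre, float(radii[k])


def label_from_seeds(
    seg: MultilabelSegmentation,
    seeds: list[StructureSeed],
    junctions: dict[str, tuple[np.ndarray, float]] | None = None,
) -> Volume:
    """Final label volume: each PV∪LAA component takes its seed's structure.

    If a junction disk is supplied for a structure, component voxels on the
    body side of the junction plane revert to the LA label (the disk defines
    the label boundary along the centreline).
    """
    mask = seg.class_mask("PVLAA")
    comp, n = ndimage.label(mask)
    out = seg.volume.data.copy()
    out[seg.class_mask("LA")] = STRUCTURE_LABELS["LA"]
    out[seg.class_mask("MV")] = 0
    idx = np.argwhere(mask)
    world = seg.volume.voxel_to_world(idx)
    comp_of_voxel = comp[mask]
    com = seg.volume.voxel_to_world(np.argwhere(seg.bloodpool_mask()).mean(axis=0)[None, :])[0]
    for seed in seeds:
        vox = np.round(seg.volume.world_to_voxel(seed.point[None, :])[0]).astype(int)
        vox = np.clip(vox, 0, np.array(comp.shape) - 1)
        cid = comp[tuple(vox)]
        if cid == 0:
            # snap to the nearest component voxel
            tree = cKDTree(world)
            _, j = tree.query(seed.point)
            cid = comp_of_voxel[j]
        sel = comp_of_voxel == cid
        code = STRUCTURE_LABELS[seed.structure]
        labels = np.full(sel.sum(), code, dtype=out.dtype)
        if junctions and seed.structure in junctions:
            jc, _ = junctions[seed.structure]
            d = com - seed.point
            d = d / np.linalg.norm(d)
            beyond = (world[sel] - jc) @ d > 0
            labels[beyond] = STRUCTURE_LABELS["LA"]
        out[tuple(idx[sel].T)] = labels
    return Volume(data=out, affine=seg.volume.affine.copy())


# ------------------------------------------------------------- surface extraction
def extract_labelled_surface(
    seg: MultilabelSegmentation, labels: Volume | None = None
) -> LabelledSurfaceMesh:
    """Iso-surface the bloodpool at 0.5 and project voxel labels onto it.

    Each triangle takes the label of the labelled voxel nearest its
    centroid.  The volume must be in a axis-aligned (e.g. canonical RAI)
    frame.
    """
    mask = seg.bloodpool_mask()
    if not mask.any():
        raise LabellingError("empty segmentation: no bloodpool to surface")
    vol = seg.volume
    lin = vol.affine[:3, :3]
    if not np.allclose(lin, np.diag(np.diag(lin))):
        raise LabellingError("volume must be reoriented to the canonical frame first")
    verts, faces, _, _ = measure.marching_cubes(mask.astype(np.float32), level=0.5)
    verts = vol.voxel_to_world(verts)
    label_data = labels.data if labels is not None else np.where(mask, STRUCTURE_LABELS["LA"], 0)
    lab_idx = np.argwhere(label_data > 0)
    if len(lab_idx) == 0:
        raise LabellingError("label volume has no labelled voxels")
    src = labels if labels is not None else vol
    lab_world = src.voxel_to_world(lab_idx)
    tree = cKDTree(lab_world)
    mesh = LabelledSurfaceMesh(vertices=verts, triangles=faces)
    _, nearest = tree.query(mesh.centroids())
    mesh.element_labels = label_data[tuple(lab_idx[nearest].T)].astype(np.int64)
    return mesh


# --------------------------------------------------------------- label verification
def verify_labels(mesh: LabelledSurfaceMesh, max_iter: int = 10) -> LabelledSurfaceMesh:
    """Fix label connectivity: each non-LA label keeps only its largest patch.

    Disconnected minority patches are re-assigned to the label of their
    largest edge-neighbouring patch.  Idempotent; clean meshes pass through
    unchanged.
    """
    out = mesh.copy()
    la = STRUCTURE_LABELS["LA"]
    for _ in range(max_iter):
        labels = out.element_labels
        areas = out.areas()
        changed = False
        # patches = connected components within each label
        patch_id = np.full(out.n_triangles, -1, dtype=np.int64)
        next_id = 0
        patch_label = {}
        patch_area = {}
        for lab in np.unique(labels):
            comp = out.triangle_adjacency_components(mask=labels == lab)
            sel = labels == lab
            ids = comp[sel] + next_id
            patch_id[sel] = ids
            for pid in np.unique(ids):
                patch_label[pid] = lab
                patch_area[pid] = areas[patch_id == pid].sum()
            next_id = patch_id.max() + 1
        # adjacency between patches across shared edges
        t = out.triangles
        e = np.sort(np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]]), axis=1)
        tri_of_edge = np.tile(np.arange(out.n_triangles), 3)
        order = np.lexsort((e[:, 1], e[:, 0]))
        e, tri_of_edge = e[order], tri_of_edge[order]
        same = np.all(e[1:] == e[:-1], axis=1)
        pa = patch_id[tri_of_edge[:-1][same]]
        pb = patch_id[tri_of_edge[1:][same]]
        neighbours: dict[int, set[int]] = {}
        for x, y in zip(pa, pb):
            if x != y:
                neighbours.setdefault(int(x), set()).add(int(y))
                neighbours.setdefault(int(y), set()).add(int(x))
        for lab in np.unique(labels):
            if lab == la:
                continue
            pids = [p for p, l in patch_label.items() if l == lab]
            if len(pids) <= 1:
                continue
            keep = max(pids, key=lambda p: patch_area[p])
            for pid in pids:
                if pid == keep:
                    continue
                nbrs = neighbours.get(pid, set())
                if not nbrs:
                    new_lab = la
                else:
                    new_lab = patch_label[max(nbrs, key=lambda p: patch_area[p])]
                out.element_labels[patch_id == pid] = new_lab
                changed = True
        if not changed:
            break
    return out


# ------------------------------------------------------------------------ clipping
def clip_structures(
    mesh: LabelledSurfaceMesh, spheres: list[ClippingSphere]
) -> LabelledSurfaceMesh:
    """Open the mesh at the PVs and MV by removing triangles inside spheres.

    Triangle centroids inside any sphere are removed, the largest remaining
    connected component is kept and the openings are left uncapped.
    """
    if not spheres:
        return mesh
    cent = mesh.centroids()
    areas = mesh.areas()
    total = areas.sum()
    remove = np.zeros(mesh.n_triangles, dtype=bool)
    n_before = len(mesh.boundary_loops())
    effective = 0
    for s in spheres:
        inside = np.linalg.norm(cent - s.centre, axis=1) < s.radius
        if areas[inside].sum() > 0.5 * total:
            raise ClippingError(
                f"sphere for {s.target} would remove more than half the surface area"
            )
        if inside.any():
            effective += 1
        remove |= inside
    keep = ~remove
    if not keep.any():
        raise ClippingError("clipping removed the whole mesh")
    comp = mesh.triangle_adjacency_components(mask=keep)
    comp_areas = np.bincount(comp[keep], weights=areas[keep])
    largest = int(np.argmax(comp_areas))
    if len(comp_areas) > 1:
        second = np.sort(comp_areas)[-2]
        if second > 0.3 * comp_areas[largest]:
            raise ClippingError(
                "clipping disconnected the mesh into comparable halves; check sphere placement"
            )
    out = mesh.submesh(keep & (comp == largest))
    n_after = len(out.boundary_loops())
    if n_after < n_before:
        raise ClippingError("clipping removed existing boundary loops unexpectedly")
    return out
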