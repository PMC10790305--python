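"""Universal atrial coordinates and fibre mapping.

The UAC parameterise the open left-atrial surface by two discrete harmonic
fields: α spans septal → lateral, β spans posterior mitral-valve rim →
roof → anterior rim.  Both are obtained by solving a Laplace equation with
cotangent weights and Dirichlet boundary conditions on mesh-edge paths
constructed from four user landmarks (LSPV-body junction, RSPV-body
junction, a lateral-wall point and a septal point near the fossa ovalis).

Fibre orientations are transported from an atlas surface through UAC
space: each atlas fibre is expressed in the atlas element's local UAC
frame (tangent-plane directions of increasing α and β) and reconstructed
in the corresponding target frame.  A deterministic rule-based field is
provided as a built-in atlas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse import linalg as sla
from scipy.spatial import cKDTree

from lamp.mesh import LabelledSurfaceMesh, STRUCTURE_LABELS, PV_NAMES


class UACError(ValueError):
    pass


@dataclass
class LandmarkSet:
    """Four landmarks anchoring the UAC boundary conditions (world mm)."""

    lspv_junction: np.ndarray
    rspv_junction: np.ndarray
    lateral: np.ndarray  # between LSPV, MV and LAA
    septal: np.ndarray  # near the fossa ovalis

    def __post_init__(self) -> None:
        for name in ("lspv_junction", "rspv_junction", "lateral", "septal"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        pts = self.as_array()
        if len(np.unique(np.round(pts, 6), axis=0)) < 4:
            raise UACError("landmark points must be pairwise distinct")

    def as_array(self) -> np.ndarray:
        return np.stack([self.lspv_junction, self.rspv_junction, self.lateral, self.septal])

    def to_dict(self) -> dict:
        return {
            "lspv_junction": self.lspv_junction.tolist(),
            "rspv_junction": self.rspv_junction.tolist(),
            "lateral": self.lateral.tolist(),
            "septal": self.septal.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkSet":
        return cls(**{k: np.asarray(v, float) for k, v in d.items()})


@dataclass
class UACField:
    """Per-vertex universal atrial coordinates (α, β) ∈ [0, 1]²."""

    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float).reshape(-1)
        self.beta = np.asarray(self.beta, dtype=float).reshape(-1)
        if len(self.alpha) != len(self.beta):
            raise ValueError("alpha and beta must have equal length")

    def as_points(self) -> np.ndarray:
        return np.column_stack([self.alpha, self.beta])


@dataclass
class FibreField:
    """Per-element unit tangent vectors with a layer tag."""

    vectors: np.ndarray  # (m, 3)
    layer: str = "endo"  # endo or epi

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float).reshape(-1, 3)
        if self.layer not in ("endo", "epi"):
            raise ValueError("layer must be 'endo' or 'epi'")


@dataclass
class FibreAtlas:
    """Reference surface with UAC and one or more named fibre fields."""

    mesh: LabelledSurfaceMesh
    uac: UACField
    fields: dict = field(default_factory=dict)  # id -> FibreField

    def field_ids(self) -> list[str]:
        return sorted(self.fields)


# ------------------------------------------------------------- boundary paths
def _loop_structure(mesh: LabelledSurfaceMesh, loop: np.ndarray) -> int:
    """Majority element label among triangles touching a boundary loop."""
    on_loop = np.isin(mesh.triangles, loop).any(axis=1)
    labels = mesh.element_labels[on_loop]
    vals, counts = np.unique(labels, return_counts=True)
    return int(vals[np.argmax(counts)])


def classify_boundary_loops(mesh: LabelledSurfaceMesh) -> dict:
    """Map rim name (MV, LSPV, LIPV, RSPV, RIPV) -> ordered loop vertex array.

    PV rims are recognised by the structure label of their incident
    triangles; the loop bordered by LA-body elements is the mitral rim.
    """
    loops = mesh.boundary_loops()
    out: dict[str, np.ndarray] = {}
    la_loops = []
    for loop in loops:
        lab = _loop_structure(mesh, loop)
        name = {v: k for k, v in STRUCTURE_LABELS.items()}.get(lab)
        if name in PV_NAMES and name not in out:
            out[name] = loop
        elif name == "LA" or name is None or name in out:
            la_loops.append(loop)
    if la_loops:
        out["MV"] = max(la_loops, key=len)
    return out


def _snap(mesh: LabelledSurfaceMesh, point: np.ndarray, max_dist: float = 10.0) -> int:
    d, idx = mesh.vertex_tree().query(point)
    if d > max_dist:
        raise UACError(f"landmark {point} is {d:.1f} mm from the mesh (limit {max_dist} mm)")
    return int(idx)


def _geodesic_path(graph: sparse.csr_matrix, src: int, dst: int) -> list[int]:
    _, pred = sparse.csgraph.dijkstra(
        graph, directed=False, indices=src, return_predecessors=True
    )
    if pred[dst] < 0 and src != dst:
        raise UACError("boundary path failed to connect (disconnected mesh?)")
    path = [dst]
    while path[-1] != src:
        path.append(int(pred[path[-1]]))
    return path[::-1]


def construct_boundary_paths(
    mesh: LabelledSurfaceMesh, landmarks: LandmarkSet
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Dirichlet boundary vertex sets for the two Laplace solves.

    Returns ``((septal_path, lateral_path), (posterior_rim, anterior_rim))``.
    The α paths are shortest edge paths MV rim → landmark → superior-PV rim;
    the mitral rim is split into posterior/anterior halves at the two points
    where the α paths meet it.  The four sets are pairwise disjoint.
    """
    rims = classify_boundary_loops(mesh)
    for need in ("MV", "LSPV", "RSPV"):
        if need not in rims:
            raise UACError(f"mesh has no {need} opening; clip the mesh first")
    graph = mesh.edge_graph()
    mv = rims["MV"]
    mv_set = set(mv.tolist())

    def alpha_path(landmark_point: np.ndarray, pv_rim: np.ndarray) -> list[int]:
        lm = _snap(mesh, landmark_point)
        if lm in mv_set:
            raise UACError("landmark lies on the mitral rim; zero-length boundary path")
        dist_from_lm, pred = sparse.csgraph.dijkstra(
            graph, directed=False, indices=lm, return_predecessors=True
        )
        mv_end = int(mv[np.argmin(dist_from_lm[mv])])
        pv_end = int(pv_rim[np.argmin(dist_from_lm[pv_rim])])
        if not np.isfinite(dist_from_lm[mv_end]) or not np.isfinite(dist_from_lm[pv_end]):
            raise UACError("boundary path failed to connect (disconnected mesh?)")

        def backtrack(end: int) -> list[int]:
            p = [end]
            while p[-1] != lm:
                p.append(int(pred[p[-1]]))
            return p

        # MV rim → landmark → PV rim, landmark appearing once
        return backtrack(mv_end) + backtrack(pv_end)[::-1][1:]

    septal = alpha_path(landmarks.septal, rims["RSPV"])
    lateral = alpha_path(landmarks.lateral, rims["LSPV"])
    if set(septal) & set(lateral):
        raise UACError("septal and lateral boundary paths intersect")

    # split the MV rim at the α-path endpoints
    s_end = next(v for v in septal if v in mv_set)
    l_end = next(v for v in lateral if v in mv_set)
    mv_list = mv.tolist()
    i, j = mv_list.index(s_end), mv_list.index(l_end)
    if i == j:
        raise UACError("α paths meet the mitral rim at the same vertex")
    if i > j:
        i, j = j, i
    arc1 = mv_list[i + 1 : j]
    arc2 = mv_list[j + 1 :] + mv_list[:i]
    if not arc1 or not arc2:
        raise UACError("mitral rim split produced an empty arc")
    # meshes live in RAS world mm: +y is anterior, so posterior = smaller mean y
    y1 = mesh.vertices[arc1, 1].mean()
    y2 = mesh.vertices[arc2, 1].mean()
    posterior, anterior = (arc1, arc2) if y1 <= y2 else (arc2, arc1)
    return (
        (np.array(septal, dtype=np.int64), np.array(lateral, dtype=np.int64)),
        (np.array(posterior, dtype=np.int64), np.array(anterior, dtype=np.int64)),
    )


# ------------------------------------------------------------- Laplace solver
def cotangent_laplacian(mesh: LabelledSurfaceMesh) -> sparse.csr_matrix:
    """Symmetric cotangent-weight Laplacian (positive semi-definite)."""
    v = mesh.vertices
    t = mesh.triangles
    n = mesh.n_vertices
    rows, cols, vals = [], [], []
    for k in range(3):
        i = t[:, k]
        j = t[:, (k + 1) % 3]
        o = t[:, (k + 2) % 3]  # vertex opposite edge (i, j)
        a = v[i] - v[o]
        b = v[j] - v[o]
        cross = np.linalg.norm(np.cross(a, b), axis=1)
        cross = np.maximum(cross, 1e-12)
        cot = np.einsum("ij,ij->i", a, b) / cross
        w = 0.5 * cot
        rows.extend([i, j])
        cols.extend([j, i])
        vals.extend([-w, -w])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    off = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    diag = -np.asarray(off.sum(axis=1)).ravel()
    return (off + sparse.diags(diag)).tocsr()


def solve_laplace(
    mesh: LabelledSurfaceMesh, set0: np.ndarray, set1: np.ndarray
) -> np.ndarray:
    """Discrete harmonic field: 0 on ``set0``, 1 on ``set1``.

    Cotangent weights with Dirichlet elimination and a direct sparse solve;
    the relative residual of the reduced system is checked to 1e-10.
    """
    set0 = np.asarray(set0, dtype=np.int64).reshape(-1)
    set1 = np.asarray(set1, dtype=np.int64).reshape(-1)
    if len(set0) == 0 or len(set1) == 0:
        raise UACError("both Dirichlet sets must be non-empty")
    if np.intersect1d(set0, set1).size:
        raise UACError("Dirichlet sets overlap")
    n = mesh.n_vertices
    L = cotangent_laplacian(mesh)
    fixed = np.zeros(n, dtype=bool)
    fixed[set0] = True
    fixed[set1] = True
    values = np.zeros(n)
    values[set1] = 1.0
    free = ~fixed
    if not free.any():
        return values
    A = L[free][:, free]
    rhs = -L[free][:, fixed] @ values[fixed]
    sol = sla.spsolve(A.tocsc(), rhs)
    denom = max(np.linalg.norm(rhs), 1e-30)
    residual = np.linalg.norm(A @ sol - rhs) / denom
    if residual > 1e-10:
        raise UACError(f"Laplace solve residual {residual:.2e} exceeds 1e-10")
    values[free] = sol
    return values


def compute_uac(mesh: LabelledSurfaceMesh, landmarks: LandmarkSet) -> UACField:
    """α = harmonic(septal→0, lateral→1); β = harmonic(posterior→0, anterior→1)."""
    (septal, lateral), (posterior, anterior) = construct_boundary_paths(mesh, landmarks)
    alpha = solve_laplace(mesh, septal, lateral)
    beta = solve_laplace(mesh, posterior, anterior)
    uac = UACField(alpha=alpha, beta=beta)
    mesh.point_data["alpha"] = alpha
    mesh.point_data["beta"] = beta
    return uac


# ---------------------------------------------------------------- UAC frames
def uac_frames(mesh: LabelledSurfaceMesh, uac: UACField):
    """Per-element orthonormal tangent frames (e_α, e_β) from UAC gradients.

    e_α is the unit in-plane gradient of α; e_β is the β gradient
    orthonormalised against e_α (Gram–Schmidt).  Elements with degenerate
    gradients are flagged invalid.
    """
    v = mesh.vertices
    t = mesh.triangles
    normals = mesh.normals()

    def tangent_gradient(f: np.ndarray) -> np.ndarray:
        # linear shape-function gradient on each triangle
        a, b, c = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
        fa, fb, fc = f[t[:, 0]], f[t[:, 1]], f[t[:, 2]]
        n = np.cross(b - a, c - a)
        nn = np.einsum("ij,ij->i", n, n)
        nn = np.maximum(nn, 1e-30)
        # rotate edge vectors by 90° in-plane: grad = (fa*(c-b)^⊥ + ...)/2A
        grad = (
            fa[:, None] * np.cross(n, c - b)
            + fb[:, None] * np.cross(n, a - c)
            + fc[:, None] * np.cross(n, b - a)
        ) / nn[:, None]
        return grad

    ga = tangent_gradient(uac.alpha)
    gb = tangent_gradient(uac.beta)
    na = np.linalg.norm(ga, axis=1)
    e_a = ga / np.maximum(na, 1e-30)[:, None]
    gb_t = gb - np.einsum("ij,ij->i", gb, e_a)[:, None] * e_a
    nb = np.linalg.norm(gb_t, axis=1)
    e_b = gb_t / np.maximum(nb, 1e-30)[:, None]
    valid = (na > 1e-10) & (nb > 1e-10)
    # orient e_b so (e_a, e_b, n) is right-handed for a consistent frame
    flip = np.einsum("ij,ij->i", np.cross(e_a, e_b), normals) < 0
    e_b[flip] *= -1.0
    return e_a, e_b, normals, valid


def element_uac_centroids(mesh: LabelledSurfaceMesh, uac: UACField) -> np.ndarray:
    t = mesh.triangles
    pts = uac.as_points()
    return (pts[t[:, 0]] + pts[t[:, 1]] + pts[t[:, 2]]) / 3.0


# --------------------------------------------------------------- fibre mapping
def _fill_invalid_by_neighbours(mesh: LabelledSurfaceMesh, vectors: np.ndarray,
                                invalid: np.ndarray) -> np.ndarray:
    if not invalid.any():
        return vectors
    normals = mesh.normals()
    t = mesh.triangles
    e = np.sort(np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]]), axis=1)
    tri_of = np.tile(np.arange(mesh.n_triangles), 3)
    order = np.lexsort((e[:, 1], e[:, 0]))
    e, tri_of = e[order], tri_of[order]
    same = np.all(e[1:] == e[:-1], axis=1)
    pairs = np.column_stack([tri_of[:-1][same], tri_of[1:][same]])
    vectors = vectors.copy()
    for _ in range(20):
        bad = np.flatnonzero(invalid)
        if not len(bad):
            break
        progressed = False
        for b in bad:
            nbrs = np.concatenate([pairs[pairs[:, 0] == b, 1], pairs[pairs[:, 1] == b, 0]])
            good = nbrs[~invalid[nbrs]] if len(nbrs) else nbrs
            if len(good):
                ref = vectors[good[0]]
                acc = sum(v if np.dot(v, ref) >= 0 else -v for v in vectors[good])
                n = normals[b]
                acc = acc - np.dot(acc, n) * n  # keep the fill tangent
                norm = np.linalg.norm(acc)
                if norm > 1e-12:
                    vectors[b] = acc / norm
                    invalid[b] = False
                    progressed = True
        if not progressed:
            break
    return vectors


def map_fibres_from_atlas(
    mesh: LabelledSurfaceMesh,
    uac: UACField,
    atlas: FibreAtlas,
    field_id: str,
    max_uac_distance: float = 0.1,
) -> FibreField:
    """Transport an atlas fibre field onto the target through UAC space.

    For each target element the atlas element nearest in (α, β) supplies a
    fibre, decomposed in the atlas local UAC frame and reconstructed in the
    target frame, then projected to the target tangent plane and
    re-normalised.  Elements without an atlas counterpart within
    ``max_uac_distance`` in UAC space are filled from neighbours.
    """
    if field_id not in atlas.fields:
        raise UACError(f"atlas has no fibre field {field_id!r}; available: {atlas.field_ids()}")
    src = atlas.fields[field_id]
    a_ea, a_eb, _, a_valid = uac_frames(atlas.mesh, atlas.uac)
    t_ea, t_eb, t_n, t_valid = uac_frames(mesh, uac)
    atlas_pts = element_uac_centroids(atlas.mesh, atlas.uac)
    target_pts = element_uac_centroids(mesh, uac)
    tree = cKDTree(atlas_pts)
    dist, nearest = tree.query(target_pts)
    f = src.vectors[nearest]
    c1 = np.einsum("ij,ij->i", f, a_ea[nearest])
    c2 = np.einsum("ij,ij->i", f, a_eb[nearest])
    out = c1[:, None] * t_ea + c2[:, None] * t_eb
    out -= np.einsum("ij,ij->i", out, t_n)[:, None] * t_n
    norms = np.linalg.norm(out, axis=1)
    invalid = (
        (dist > max_uac_distance)
        | ~t_valid
        | ~a_valid[nearest]
        | (norms < 1e-8)
    )
    out = np.where(norms[:, None] > 1e-30, out / np.maximum(norms, 1e-30)[:, None], out)
    if invalid.any():
        import warnings

        warnings.warn(f"{invalid.sum()} elements without atlas counterpart; filled from neighbours")
        out = _fill_invalid_by_neighbours(mesh, out, invalid.copy())
    return FibreField(vectors=out, layer=src.layer)


def generate_rule_based_fibres(
    uac: UACField, mesh: LabelledSurfaceMesh, layer: str = "endo"
) -> FibreField:
    """Deterministic region-wise fibre field in UAC space.

    Circumferential (along α) near the mitral rim, longitudinal (along β)
    near the septal/lateral edges where the PV ostia sit, oblique on the
    roof.  Always tangent and unit length; serves as the built-in atlas.
    """
    e_a, e_b, normals, valid = uac_frames(mesh, uac)
    ac = element_uac_centroids(mesh, uac)
    alpha, beta = ac[:, 0], ac[:, 1]
    vec = np.empty_like(e_a)
    near_mv = (beta < 0.15) | (beta > 0.85)
    near_pv = (~near_mv) & ((np.minimum(alpha, 1 - alpha) < 0.15))
    roof = ~(near_mv | near_pv)
    vec[near_mv] = e_a[near_mv]
    vec[near_pv] = e_b[near_pv]
    vec[roof] = (e_a[roof] + e_b[roof]) / np.sqrt(2.0)
    vec -= np.einsum("ij,ij->i", vec, normals)[:, None] * normals
    norms = np.linalg.norm(vec, axis=1)
    vec = vec / np.maximum(norms, 1e-30)[:, None]
    vec = _fill_invalid_by_neighbours(mesh, vec, (~valid | (norms < 1e-8)).copy())
    return FibreField(vectors=vec, layer=layer)


def smooth_varying_fibres(
    uac: UACField, mesh: LabelledSurfaceMesh, layer: str = "endo"
) -> FibreField:
    """A smoothly rotating fibre field, θ(α, β) = π(α + β) in the local frame.

    Stands in for a DTMRI-derived atlas file: unlike the rule-based field it
    has no regional discontinuities, so the pair exercises fibre-agreement
    metrics the way two genuinely different atlas fields would.
    """
    e_a, e_b, normals, valid = uac_frames(mesh, uac)
    ac = element_uac_centroids(mesh, uac)
    theta = np.pi * (ac[:, 0] + ac[:, 1])
    vec = np.cos(theta)[:, None] * e_a + np.sin(theta)[:, None] * e_b
    norms = np.linalg.norm(vec, axis=1)
    vec = vec / np.maximum(norms, 1e-30)[:, None]
    vec = _fill_invalid_by_neighbours(mesh, vec, (~valid | (norms < 1e-8)).copy())
    return FibreField(vectors=vec, layer=layer)


def build_builtin_atlas(mesh: LabelledSurfaceMesh, uac: UACField) -> FibreAtlas:
    """Atlas with the rule-based field ('l') and the smooth stand-in ('1')."""
    return FibreAtlas(
        mesh=mesh,
        uac=uac,
        fields={
            "l": generate_rule_based_fibres(uac, mesh),
            "1": smooth_varying_fibres(uac, mesh),
        },
    )
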