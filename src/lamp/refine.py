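"""Simulation-ready meshes: cleaning, isotropic remeshing, openCARP export.

Remeshing follows the classic incremental scheme: split edges longer than
4/3 of the target, collapse edges shorter than 4/5 of the target, flip
edges to equalise vertex valences, then relax vertices tangentially.
Boundary loops and label-boundary (feature) edges are preserved so the
pulmonary-vein and mitral-valve openings and the structure labelling
survive refinement.  Export writes the plain-text openCARP triple
(``.pts`` in μm, ``.elem`` with region tags, ``.lon`` with fibre vectors).
"""

from __future__ import annotations

import numpy as np

from lamp.mesh import LabelledSurfaceMesh, TopologyError


# ---------------------------------------------------------------------- cleaning
def clean_mesh(mesh: LabelledSurfaceMesh, merge_tol: float = 1e-6) -> LabelledSurfaceMesh:
    """Merge duplicate vertices, drop degenerate/duplicate triangles and
    unreferenced vertices.  Raises :class:`TopologyError` if the result is
    not manifold-with-boundary."""
    v = mesh.vertices
    key = np.round(v / merge_tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    tris = inverse[mesh.triangles]
    # degenerate: repeated indices or (numerically) zero area
    ok = (tris[:, 0] != tris[:, 1]) & (tris[:, 1] != tris[:, 2]) & (tris[:, 0] != tris[:, 2])
    newv = v[first]
    a, b, c = newv[tris[:, 0]], newv[tris[:, 1]], newv[tris[:, 2]]
    areas = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
    ok &= areas > 1e-12
    tris = tris[ok]
    labels = mesh.element_labels[ok]
    cd = {k: np.asarray(val)[ok] for k, val in mesh.cell_data.items()}
    # duplicate triangles (same vertex set)
    sorted_t = np.sort(tris, axis=1)
    _, keep_idx = np.unique(sorted_t, axis=0, return_index=True)
    keep_idx = np.sort(keep_idx)
    tris, labels = tris[keep_idx], labels[keep_idx]
    cd = {k: val[keep_idx] for k, val in cd.items()}
    out = LabelledSurfaceMesh(vertices=newv, triangles=tris, element_labels=labels, cell_data=cd)
    out = _drop_unreferenced(out)
    if not out.is_manifold():
        uniq, counts = out.edge_counts()
        bad = uniq[counts > 2]
        raise TopologyError(f"non-manifold edges after cleaning: {bad.tolist()[:10]}")
    return out


def _drop_unreferenced(mesh: LabelledSurfaceMesh) -> LabelledSurfaceMesh:
    used = np.unique(mesh.triangles)
    if len(used) == mesh.n_vertices:
        return mesh
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    pd = {k: np.asarray(v)[used] for k, v in mesh.point_data.items()}
    return LabelledSurfaceMesh(
        vertices=mesh.vertices[used],
        triangles=remap[mesh.triangles],
        element_labels=mesh.element_labels,
        point_data=pd,
        cell_data=mesh.cell_data,
    )


# --------------------------------------------------------------------- remeshing
def _feature_vertices(mesh: LabelledSurfaceMesh) -> np.ndarray:
    """Vertices on label-boundary edges (kept in place during remeshing)."""
    t = mesh.triangles
    e = np.sort(np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]]), axis=1)
    lab = np.tile(mesh.element_labels, 3)
    order = np.lexsort((e[:, 1], e[:, 0]))
    e, lab = e[order], lab[order]
    same = np.all(e[1:] == e[:-1], axis=1)
    diff = same & (lab[1:] != lab[:-1])
    feat = np.unique(e[:-1][diff])
    return feat


def _split_pass(verts, tris, labels, threshold):
    vlist = [verts]
    nv = len(verts)
    midpoint: dict[tuple[int, int], int] = {}
    pos = verts

    def mid(i, j):
        nonlocal nv
        key = (i, j) if i < j else (j, i)
        if key not in midpoint:
            vlist.append(((pos[i] + pos[j]) / 2.0)[None, :])
            midpoint[key] = nv
            nv += 1
        return midpoint[key]

    el = np.linalg.norm(
        pos[tris][:, [1, 2, 0], :] - pos[tris], axis=2
    )  # lengths of edges (0-1, 1-2, 2-0)
    long = el > threshold
    new_tris, new_labels = [], []
    for t, flags, lab in zip(tris, long, labels):
        n_long = flags.sum()
        if n_long == 0:
            new_tris.append(tuple(t))
            new_labels.append(lab)
            continue
        # rotate so a long edge is (v0, v1)
        r = int(np.argmax(flags))
        v0, v1, v2 = t[r], t[(r + 1) % 3], t[(r + 2) % 3]
        f01, f12, f20 = flags[r], flags[(r + 1) % 3], flags[(r + 2) % 3]
        m01 = mid(v0, v1)
        if n_long == 1:
            pieces = [(v0, m01, v2), (m01, v1, v2)]
        elif n_long == 2:
            if f12:
                m12 = mid(v1, v2)
                pieces = [(v0, m01, v2), (m01, v1, m12), (m01, m12, v2)]
            else:
                m20 = mid(v2, v0)
                pieces = [(v0, m01, m20), (m01, v1, v2), (m01, v2, m20)]
        else:
            m12, m20 = mid(v1, v2), mid(v2, v0)
            pieces = [(v0, m01, m20), (m01, v1, m12), (m20, m12, v2), (m01, m12, m20)]
        new_tris.extend(pieces)
        new_labels.extend([lab] * len(pieces))
    return (
        np.concatenate(vlist),
        np.array(new_tris, dtype=np.int64),
        np.array(new_labels, dtype=np.int64),
    )


def _collapse_pass(verts, tris, labels, threshold, boundary, feature):
    e = np.sort(np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]]), axis=1)
    e = np.unique(e, axis=0)
    lens = np.linalg.norm(verts[e[:, 0]] - verts[e[:, 1]], axis=1)
    order = np.argsort(lens)
    protected = set(boundary.tolist()) | set(feature.tolist())
    # neighbour sets for the link condition
    nbr: dict[int, set[int]] = {}
    for i, j in e:
        nbr.setdefault(int(i), set()).add(int(j))
        nbr.setdefault(int(j), set()).add(int(i))
    parent = np.arange(len(verts))
    newpos = verts.copy()
    dirty: set[int] = set()
    for k in order:
        if lens[k] >= threshold:
            break
        a, b = int(e[k, 0]), int(e[k, 1])
        if a in dirty or b in dirty:
            continue
        pa, pb = a in protected, b in protected
        if pa and pb:
            continue
        if len(nbr[a] & nbr[b]) > 2:
            continue  # link condition: collapse would pinch the surface
        if pa:
            a, b = a, b  # keep a in place
            target_pos = newpos[a]
        elif pb:
            a, b = b, a
            target_pos = newpos[a]
        else:
            target_pos = 0.5 * (newpos[a] + newpos[b])
        parent[b] = a
        newpos[a] = target_pos
        dirty.update(nbr[a] | nbr[b] | {a, b})
    tris = parent[tris]
    ok = (tris[:, 0] != tris[:, 1]) & (tris[:, 1] != tris[:, 2]) & (tris[:, 0] != tris[:, 2])
    return newpos, tris[ok], labels[ok]


def _flip_pass(verts, tris, labels):
    """Valence-equalising edge flips on interior, same-label edge pairs."""
    edge_tris: dict[tuple[int, int], list[int]] = {}
    for ti, t in enumerate(tris):
        for i, j in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
            key = (int(i), int(j)) if i < j else (int(j), int(i))
            edge_tris.setdefault(key, []).append(ti)
    valence = np.zeros(len(verts), dtype=np.int64)
    for key in edge_tris:
        valence[key[0]] += 1
        valence[key[1]] += 1
    boundary_v = set()
    for key, ts in edge_tris.items():
        if len(ts) == 1:
            boundary_v.update(key)
    tris = tris.copy()
    touched = set()
    for (a, b), ts in edge_tris.items():
        if len(ts) != 2 or ts[0] in touched or ts[1] in touched:
            continue
        t1, t2 = ts
        if labels[t1] != labels[t2]:
            continue
        c = int([v for v in tris[t1] if v not in (a, b)][0])
        d = int([v for v in tris[t2] if v not in (a, b)][0])
        if c == d:
            continue
        ck = (c, d) if c < d else (d, c)
        if ck in edge_tris:
            continue
        def ideal(v):
            return 4 if v in boundary_v else 6

        def dev(va, vb, vc, vd):
            return (
                abs(va - ideal(a)) + abs(vb - ideal(b)) + abs(vc - ideal(c)) + abs(vd - ideal(d))
            )

        before = dev(valence[a], valence[b], valence[c], valence[d])
        after = dev(valence[a] - 1, valence[b] - 1, valence[c] + 1, valence[d] + 1)
        if after >= before:
            continue
        # geometric sanity: keep normals pointing the same way
        n_old = np.cross(verts[b] - verts[a], verts[c] - verts[a])
        n1 = np.cross(verts[d] - verts[c], verts[a] - verts[c])
        n2 = np.cross(verts[b] - verts[c], verts[d] - verts[c])
        if np.dot(n1, n_old) <= 0 or np.dot(n2, n_old) <= 0:
            continue
        tris[t1] = (c, a, d)
        tris[t2] = (c, d, b)
        valence[a] -= 1
        valence[b] -= 1
        valence[c] += 1
        valence[d] += 1
        touched.update((t1, t2))
    return tris


def _tangential_relax(mesh: LabelledSurfaceMesh, fixed: np.ndarray, lam: float = 0.5):
    verts = mesh.vertices
    adj = mesh.vertex_adjacency()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1
    centroid = adj @ verts / deg[:, None]
    disp = centroid - verts
    # per-vertex normals: area-weighted average of incident triangle normals
    tn = mesh.normals() * mesh.areas()[:, None]
    vn = np.zeros_like(verts)
    for k in range(3):
        np.add.at(vn, mesh.triangles[:, k], tn)
    norm = np.linalg.norm(vn, axis=1)
    norm[norm == 0] = 1.0
    vn /= norm[:, None]
    disp -= (np.sum(disp * vn, axis=1))[:, None] * vn  # tangential part only
    disp[fixed] = 0.0
    mesh.vertices = verts + lam * disp


def remesh_to_edge_length(
    mesh: LabelledSurfaceMesh, target: float = 0.3, n_iter: int = 5
) -> LabelledSurfaceMesh:
    """Isotropic remesh to a target mean edge length (mm).

    Labels are carried to the children of split triangles; boundary loops
    and label boundaries act as features whose vertices are not moved.
    """
    if not mesh.is_manifold():
        raise TopologyError("remeshing requires a manifold-with-boundary input")
    if target <= 0:
        raise ValueError("target edge length must be positive")
    out = mesh.copy()
    out.point_data, out.cell_data = {}, {}
    for _ in range(n_iter):
        verts, tris, labels = out.vertices, out.triangles, out.element_labels
        verts, tris, labels = _split_pass(verts, tris, labels, threshold=4.0 / 3.0 * target)
        out = LabelledSurfaceMesh(vertices=verts, triangles=tris, element_labels=labels)
        boundary = out.boundary_vertices()
        feature = _feature_vertices(out)
        verts, tris, labels = _collapse_pass(
            out.vertices, out.triangles, out.element_labels,
            threshold=0.8 * target, boundary=boundary, feature=feature,
        )
        out = clean_mesh(LabelledSurfaceMesh(vertices=verts, triangles=tris, element_labels=labels))
        tris = _flip_pass(out.vertices, out.triangles, out.element_labels)
        out = LabelledSurfaceMesh(vertices=out.vertices, triangles=tris,
                                  element_labels=out.element_labels)
        fixed = np.zeros(out.n_vertices, dtype=bool)
        fixed[out.boundary_vertices()] = True
        fixed[_feature_vertices(out)] = True
        _tangential_relax(out, fixed)
        mean = out.mean_edge_length()
        if abs(mean - target) < 0.1 * target:
            break
    return clean_mesh(out)


# ------------------------------------------------------------------- CARP export
def export_carp(
    mesh: LabelledSurfaceMesh,
    fibres: np.ndarray | None,
    out_prefix,
    allow_no_fibres: bool = False,
    mm_to_um: bool = True,
) -> None:
    """Write openCARP ``.pts`` / ``.elem`` / ``.lon`` files.

    Coordinates are scaled mm → μm (×1000) unless disabled.  ``fibres`` is
    an (m, 3) array (one direction per element) or an (m, 6) array for two
    directions (fibre + sheet).
    """
    if fibres is None and not allow_no_fibres:
        raise ValueError("fibres missing; pass allow_no_fibres=True to export without them")
    prefix = str(out_prefix)
    scale = 1000.0 if mm_to_um else 1.0
    pts = mesh.vertices * scale
    with open(prefix + ".pts", "w") as fh:
        fh.write(f"{len(pts)}\n")
        for p in pts:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
    with open(prefix + ".elem", "w") as fh:
        fh.write(f"{mesh.n_triangles}\n")
        for t, tag in zip(mesh.triangles, mesh.element_labels):
            fh.write(f"Tr {t[0]} {t[1]} {t[2]} {tag}\n")
    with open(prefix + ".lon", "w") as fh:
        if fibres is None:
            fh.write("1\n")
            for _ in range(mesh.n_triangles):
                fh.write("1.000000 0.000000 0.000000\n")
        else:
            fibres = np.asarray(fibres, dtype=float)
            ndir = fibres.shape[1] // 3
            fh.write(f"{ndir}\n")
            for row in fibres:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")


def read_carp(prefix) -> tuple[LabelledSurfaceMesh, np.ndarray]:
    """Parse openCARP files back into a mesh (μm → mm) and fibre array."""
    prefix = str(prefix)
    with open(prefix + ".pts") as fh:
        n = int(fh.readline())
        pts = np.array([[float(x) for x in fh.readline().split()] for _ in range(n)])
    with open(prefix + ".elem") as fh:
        m = int(fh.readline())
        tris, tags = [], []
        for _ in range(m):
            parts = fh.readline().split()
            if parts[0] != "Tr":
                raise ValueError("only triangle (Tr) elements supported")
            tris.append([int(x) for x in parts[1:4]])
            tags.append(int(parts[4]))
    with open(prefix + ".lon") as fh:
        ndir = int(fh.readline())
        lon = np.array([[float(x) for x in fh.readline().split()] for _ in range(m)])
        lon = lon.reshape(m, 3 * ndir)
    mesh = LabelledSurfaceMesh(
        vertices=pts / 1000.0, triangles=np.array(tris), element_labels=np.array(tags)
    )
    return mesh, lon
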