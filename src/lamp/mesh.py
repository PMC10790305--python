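"""Labelled triangle surface meshes.

The central in-memory object of the pipeline: a triangle mesh in mm with one
structure label per element (atrial body, appendage, four pulmonary veins),
plus optional per-element scalars (projected intensity, fibrosis) and
vectors (fibres), and per-vertex scalars (universal atrial coordinates,
activation times).  Meshes are stored on disk as legacy-ASCII VTK polydata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

#: Default structure label codes used throughout the pipeline.
STRUCTURE_LABELS = {"LA": 1, "LSPV": 11, "LIPV": 13, "RSPV": 15, "RIPV": 17, "LAA": 19}
LABEL_NAMES = {v: k for k, v in STRUCTURE_LABELS.items()}
PV_NAMES = ("LSPV", "LIPV", "RSPV", "RIPV")


class TopologyError(ValueError):
    """Raised on non-manifold or otherwise irreparable mesh topology."""


@dataclass
class LabelledSurfaceMesh:
    vertices: np.ndarray  # (n, 3) float mm
    triangles: np.ndarray  # (m, 3) int
    element_labels: np.ndarray | None = None  # (m,) int
    point_data: dict = field(default_factory=dict)
    cell_data: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise ValueError("triangles reference invalid vertex indices")
        if self.element_labels is None:
            self.element_labels = np.full(len(self.triangles), STRUCTURE_LABELS["LA"], dtype=np.int64)
        else:
            self.element_labels = np.asarray(self.element_labels, dtype=np.int64).reshape(-1)
            if len(self.element_labels) != len(self.triangles):
                raise ValueError("one label per triangle required")

    # ------------------------------------------------------------------ geometry
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_corners(self):
        v = self.vertices
        t = self.triangles
        return v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]

    def centroids(self) -> np.ndarray:
        a, b, c = self.triangle_corners()
        return (a + b + c) / 3.0

    def areas(self) -> np.ndarray:
        a, b, c = self.triangle_corners()
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def normals(self) -> np.ndarray:
        """Unit per-element normals (orientation as wound)."""
        a, b, c = self.triangle_corners()
        n = np.cross(b - a, c - a)
        norm = np.linalg.norm(n, axis=1)
        norm[norm == 0] = 1.0
        return n / norm[:, None]

    def edges(self, unique: bool = True) -> np.ndarray:
        t = self.triangles
        e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e = np.sort(e, axis=1)
        if unique:
            e = np.unique(e, axis=0)
        return e

    def edge_lengths(self) -> np.ndarray:
        e = self.edges()
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)

    def mean_edge_length(self) -> float:
        return float(self.edge_lengths().mean())

    def edge_counts(self):
        """Unique undirected edges and the number of incident triangles."""
        t = self.triangles
        e = np.sort(np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]]), axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq, counts

    def boundary_edges(self) -> np.ndarray:
        uniq, counts = self.edge_counts()
        return uniq[counts == 1]

    def boundary_vertices(self) -> np.ndarray:
        be = self.boundary_edges()
        return np.unique(be) if len(be) else np.array([], dtype=np.int64)

    def is_manifold(self) -> bool:
        """Edge-manifold with boundary: every edge on 1 or 2 triangles."""
        if self.n_triangles == 0:
            return True
        _, counts = self.edge_counts()
        return bool(counts.max() <= 2)

    def boundary_loops(self) -> list[np.ndarray]:
        """Connected cycles of boundary vertices, each as an ordered array."""
        be = self.boundary_edges()
        if len(be) == 0:
            return []
        nbr: dict[int, list[int]] = {}
        for i, j in be:
            nbr.setdefault(int(i), []).append(int(j))
            nbr.setdefault(int(j), []).append(int(i))
        seen: set[int] = set()
        loops = []
        for start in sorted(nbr):
            if start in seen:
                continue
            loop = [start]
            seen.add(start)
            prev, cur = None, start
            while True:
                nxt = [n for n in nbr[cur] if n != prev and n not in seen]
                if not nxt:
                    break
                prev, cur = cur, nxt[0]
                loop.append(cur)
                seen.add(cur)
            loops.append(np.array(loop, dtype=np.int64))
        return loops

    # --------------------------------------------------------------- connectivity
    def vertex_adjacency(self) -> sparse.csr_matrix:
        e = self.edges()
        n = self.n_vertices
        data = np.ones(len(e))
        adj = sparse.coo_matrix((data, (e[:, 0], e[:, 1])), shape=(n, n))
        return (adj + adj.T).tocsr()

    def edge_graph(self, weights: np.ndarray | None = None) -> sparse.csr_matrix:
        """Sparse vertex graph weighted by edge length (or given weights)."""
        e = self.edges()
        if weights is None:
            weights = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
        n = self.n_vertices
        g = sparse.coo_matrix((weights, (e[:, 0], e[:, 1])), shape=(n, n))
        return (g + g.T).tocsr()

    def triangle_adjacency_components(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Connected-component id per triangle (edge-adjacency), restricted to mask."""
        t = self.triangles
        m = self.n_triangles
        idx = np.arange(m) if mask is None else np.flatnonzero(mask)
        edges = np.sort(
            np.concatenate([t[idx][:, [0, 1]], t[idx][:, [1, 2]], t[idx][:, [2, 0]]]), axis=1
        )
        tri_of_edge = np.tile(idx, 3)
        order = np.lexsort((edges[:, 1], edges[:, 0]))
        edges, tri_of_edge = edges[order], tri_of_edge[order]
        same = np.all(edges[1:] == edges[:-1], axis=1)
        a = tri_of_edge[:-1][same]
        b = tri_of_edge[1:][same]
        g = sparse.coo_matrix((np.ones(len(a)), (a, b)), shape=(m, m))
        n_comp, labels = sparse.csgraph.connected_components(g + g.T, directed=False)
        out = np.full(m, -1, dtype=np.int64)
        out[idx] = labels[idx]
        # renumber components present in mask contiguously
        uniq = np.unique(out[idx])
        remap = {int(u): i for i, u in enumerate(uniq)}
        out[idx] = [remap[int(v)] for v in out[idx]]
        return out

    def submesh(self, tri_mask: np.ndarray) -> "LabelledSurfaceMesh":
        """Triangles where mask is True, with vertices compacted."""
        tri_mask = np.asarray(tri_mask, dtype=bool)
        tris = self.triangles[tri_mask]
        used = np.unique(tris)
        remap = np.full(self.n_vertices, -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        pd = {k: np.asarray(v)[used] for k, v in self.point_data.items()}
        cd = {k: np.asarray(v)[tri_mask] for k, v in self.cell_data.items()}
        return LabelledSurfaceMesh(
            vertices=self.vertices[used],
            triangles=remap[tris],
            element_labels=self.element_labels[tri_mask],
            point_data=pd,
            cell_data=cd,
        )

    def copy(self) -> "LabelledSurfaceMesh":
        return LabelledSurfaceMesh(
            vertices=self.vertices.copy(),
            triangles=self.triangles.copy(),
            element_labels=self.element_labels.copy(),
            point_data={k: np.asarray(v).copy() for k, v in self.point_data.items()},
            cell_data={k: np.asarray(v).copy() for k, v in self.cell_data.items()},
        )

    def vertex_tree(self) -> cKDTree:
        return cKDTree(self.vertices)

    def structure_mask(self, name: str) -> np.ndarray:
        return self.element_labels == STRUCTURE_LABELS[name]


# ----------------------------------------------------------------------- VTK I/O
def write_vtk_polydata(mesh: LabelledSurfaceMesh, path) -> None:
    """Write legacy-ASCII VTK polydata with labels and any attached data."""
    lines = [
        "# vtk DataFile Version 3.0",
        "lamp surface mesh",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {mesh.n_vertices} float",
    ]
    for p in mesh.vertices:
        lines.append(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}")
    m = mesh.n_triangles
    lines.append(f"POLYGONS {m} {4 * m}")
    for t in mesh.triangles:
        lines.append(f"3 {t[0]} {t[1]} {t[2]}")

    def emit_data(section: str, count: int, arrays: dict) -> None:
        if not arrays:
            return
        lines.append(f"{section} {count}")
        for name, arr in arrays.items():
            arr = np.asarray(arr)
            if arr.ndim == 2 and arr.shape[1] == 3:
                lines.append(f"VECTORS {name} float")
                for v in arr:
                    lines.append(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
            else:
                kind = "int" if np.issubdtype(arr.dtype, np.integer) else "float"
                lines.append(f"SCALARS {name} {kind} 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.9g}" if kind == "float" else str(int(v)) for v in arr)

    cell = {"labels": mesh.element_labels, **mesh.cell_data}
    emit_data("CELL_DATA", m, cell)
    emit_data("POINT_DATA", mesh.n_vertices, mesh.point_data)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vtk_polydata(path) -> LabelledSurfaceMesh:
    with open(path) as fh:
        tokens = fh.read().split("\n")
    i = 0

    def next_line():
        nonlocal i
        while i < len(tokens) and not tokens[i].strip():
            i += 1
        line = tokens[i].strip()
        i += 1
        return line

    vertices = triangles = None
    labels = None
    point_data: dict = {}
    cell_data: dict = {}
    section = None
    section_n = 0
    while i < len(tokens):
        try:
            line = next_line()
        except IndexError:
            break
        parts = line.split()
        if not parts:
            continue
        key = parts[0].upper()
        if key == "POINTS":
            n = int(parts[1])
            vals = []
            while len(vals) < 3 * n:
                vals.extend(float(x) for x in next_line().split())
            vertices = np.array(vals).reshape(n, 3)
        elif key == "POLYGONS":
            m = int(parts[1])
            total = int(parts[2])
            vals = []
            while len(vals) < total:
                vals.extend(int(x) for x in next_line().split())
            arr = np.array(vals)
            if not np.all(arr[:: 4] == 3):
                raise ValueError("only triangle polydata supported")
            triangles = arr.reshape(m, 4)[:, 1:]
        elif key == "CELL_DATA":
            section, section_n = "cell", int(parts[1])
        elif key == "POINT_DATA":
            section, section_n = "point", int(parts[1])
        elif key == "SCALARS":
            name, kind = parts[1], parts[2]
            next_line()  # LOOKUP_TABLE
            vals = []
            while len(vals) < section_n:
                vals.extend(next_line().split())
            arr = np.array(vals, dtype=np.int64 if kind == "int" else float)
            if section == "cell" and name == "labels":
                labels = arr.astype(np.int64)
            elif section == "cell":
                cell_data[name] = arr
            else:
                point_data[name] = arr
        elif key == "VECTORS":
            name = parts[1]
            vals = []
            while len(vals) < 3 * section_n:
                vals.extend(float(x) for x in next_line().split())
            arr = np.array(vals).reshape(section_n, 3)
            (cell_data if section == "cell" else point_data)[name] = arr
    if vertices is None or triangles is None:
        raise ValueError(f"{path!s}: not a triangle VTK polydata file")
    return LabelledSurfaceMesh(
        vertices=vertices,
        triangles=triangles,
        element_labels=labels,
        point_data=point_data,
        cell_data=cell_data,
    )
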