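"""Desk-scale electrophysiology surrogate.

Paced activation is computed with an anisotropic eikonal solver on the
triangle mesh (iterative per-triangle quadratic updates under each
element's speed ellipse), stimulus at a pulmonary-vein rim, conduction
velocity as 1/‖∇LAT‖.  Fibrillation-like dynamics use a two-variable
excitable monodomain model (cubic activation, linear recovery —
Aliev–Panfilov kinetics) on the surface, initiated from an arrangement of
four Archimedean spirals laid out in UAC space, with phase-singularity
detection by one-ring winding numbers and binning onto a UAC grid.

Longitudinal/transverse conductivities default to 0.4/0.1 S/m; speeds are
speed_scale·√σ so the anisotropy ratio is √(σl/σt) = 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import sparse

from lamp.mesh import LabelledSurfaceMesh
from lamp.uac import UACField


class SimulationError(RuntimeError):
    pass


@dataclass
class ConductionSettings:
    """Conductivities (S/m) and the √conductivity → speed map (mm/ms per √(S/m))."""

    sigma_l: float = 0.4
    sigma_t: float = 0.1
    speed_scale: float = 0.95  # gives v_long ≈ 0.6 m/s at σl = 0.4 S/m

    def __post_init__(self) -> None:
        if self.sigma_t <= 0 or self.sigma_l < self.sigma_t:
            raise ValueError("need σl ≥ σt > 0")


@dataclass
class LATMap:
    """Per-vertex activation time in ms; unreached vertices are +inf."""

    times: np.ndarray
    stimulus: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).reshape(-1)
        self.stimulus = np.asarray(self.stimulus, dtype=np.int64).reshape(-1)

    @property
    def total_activation_time(self) -> float:
        finite = self.times[np.isfinite(self.times)]
        return float(finite.max()) if len(finite) else float("nan")


@dataclass
class PSMap:
    """Phase-singularity counts on a regular UAC grid."""

    grid: np.ndarray  # (n, n) non-negative counts
    n_detections: int


def element_speeds(fibres: np.ndarray, cfg: ConductionSettings) -> tuple[np.ndarray, np.ndarray]:
    """Longitudinal/transverse wave speeds (mm/ms) per element."""
    fibres = np.asarray(fibres, dtype=float).reshape(-1, 3)
    v_long = cfg.speed_scale * np.sqrt(cfg.sigma_l)
    v_trans = cfg.speed_scale * np.sqrt(cfg.sigma_t)
    m = len(fibres)
    return np.full(m, v_long), np.full(m, v_trans)


def _element_metrics(mesh: LabelledSurfaceMesh, fibres: np.ndarray,
                     v_long: np.ndarray, v_trans: np.ndarray) -> np.ndarray:
    """Per-element travel-time metric M: time(e) = √(eᵀMe) for in-plane e."""
    n = mesh.normals()
    f = np.asarray(fibres, dtype=float).reshape(-1, 3)
    # ensure tangency; fall back to an arbitrary tangent direction if degenerate
    f = f - np.einsum("ij,ij->i", f, n)[:, None] * n
    norms = np.linalg.norm(f, axis=1)
    bad = norms < 1e-8
    if bad.any():
        a, b, _ = mesh.triangle_corners()
        edge = b - a
        edge -= np.einsum("ij,ij->i", edge, n)[:, None] * n
        f[bad] = edge[bad]
        norms = np.linalg.norm(f, axis=1)
    f = f / norms[:, None]
    t = np.cross(n, f)
    M = (
        f[:, :, None] * f[:, None, :] / (v_long**2)[:, None, None]
        + t[:, :, None] * t[:, None, :] / (v_trans**2)[:, None, None]
        + n[:, :, None] * n[:, None, :] / (v_trans**2)[:, None, None]
    )
    return M


def eikonal_lat(
    mesh: LabelledSurfaceMesh,
    speeds: tuple[np.ndarray, np.ndarray],
    stimulus: np.ndarray,
    fibres: np.ndarray | None = None,
    tol: float = 1e-6,
    max_sweeps: int = 10000,
) -> LATMap:
    """Anisotropic eikonal activation times from a stimulus vertex set.

    Iterative local solves: each vertex is updated from every incident
    triangle by minimising (1−λ)T_a + λT_b + √(eᵀMe) over the opposite
    edge; sweeps repeat until the largest update falls below ``tol`` ms.
    Vertices in components without stimulus stay +inf (unreached).
    """
    stimulus = np.asarray(stimulus, dtype=np.int64).reshape(-1)
    if len(stimulus) == 0:
        raise ValueError("stimulus set is empty")
    v_long, v_trans = speeds
    if fibres is None:
        fibres = np.zeros((mesh.n_triangles, 3))
    M = _element_metrics(mesh, fibres, np.asarray(v_long, float), np.asarray(v_trans, float))
    verts = mesh.vertices
    tris = mesh.triangles
    # combos: vertex C updated from edge (A, B), three per triangle
    combos = []
    for k in range(3):
        A = tris[:, k]
        B = tris[:, (k + 1) % 3]
        C = tris[:, (k + 2) % 3]
        combos.append((A, B, C))
    A = np.concatenate([c[0] for c in combos])
    B = np.concatenate([c[1] for c in combos])
    C = np.concatenate([c[2] for c in combos])
    Mrep = np.concatenate([M, M, M], axis=0)
    P = verts[C] - verts[A]
    Q = verts[B] - verts[A]
    MP = np.einsum("nij,nj->ni", Mrep, P)
    MQ = np.einsum("nij,nj->ni", Mrep, Q)
    c0 = np.einsum("ni,ni->n", P, MP)
    c1 = np.einsum("ni,ni->n", P, MQ)
    c2 = np.einsum("ni,ni->n", Q, MQ)

    T = np.full(mesh.n_vertices, np.inf)
    T[stimulus] = 0.0
    for _ in range(max_sweeps):
      with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        Ta, Tb = T[A], T[B]
        u = Tb - Ta
        # interior minimiser: (c1 − c2λ)² = u²(c0 − 2c1λ + c2λ²)
        aa = c2**2 - np.where(np.isfinite(u), u, 0.0) ** 2 * c2
        bb = -2 * c1 * c2 + 2 * np.where(np.isfinite(u), u, 0.0) ** 2 * c1
        cc = c1**2 - np.where(np.isfinite(u), u, 0.0) ** 2 * c0
        with np.errstate(invalid="ignore", divide="ignore"):
            disc = bb**2 - 4 * aa * cc
            sq = np.sqrt(np.maximum(disc, 0.0))
            lam1 = np.where(np.abs(aa) > 1e-30, (-bb + sq) / (2 * aa), np.nan)
            lam2 = np.where(np.abs(aa) > 1e-30, (-bb - sq) / (2 * aa), np.nan)
        cand_T = []
        for lam in (np.zeros_like(u), np.ones_like(u), lam1, lam2):
            ok = np.isfinite(lam) & (lam >= 0.0) & (lam <= 1.0)
            lam = np.where(ok, lam, 0.0)
            g = np.maximum(c0 - 2 * c1 * lam + c2 * lam**2, 0.0)
            base = np.where(
                lam <= 0.0, Ta, np.where(lam >= 1.0, Tb, (1 - lam) * Ta + lam * Tb)
            )
            val = base + np.sqrt(g)
            val = np.where(ok | (lam == 0.0), val, np.inf)
            cand_T.append(np.where(np.isfinite(base), val, np.inf))
        best = np.minimum.reduce(cand_T)
        T_new = T.copy()
        np.minimum.at(T_new, C, best)
        T_new[stimulus] = 0.0
        finite = np.isfinite(T) & np.isfinite(T_new)
        delta = np.abs(T[finite] - T_new[finite]).max() if finite.any() else 0.0
        newly = np.isfinite(T_new) & ~np.isfinite(T)
        T = T_new
        if delta < tol and not newly.any():
            break
    return LATMap(times=T, stimulus=stimulus)


def dijkstra_lat(
    mesh: LabelledSurfaceMesh,
    speeds: tuple[np.ndarray, np.ndarray],
    stimulus: np.ndarray,
    fibres: np.ndarray | None = None,
) -> LATMap:
    """Edge-graph Dijkstra travel times under the same element metric.

    Restricting propagation to mesh edges, this is an upper bound on the
    eikonal activation time at every vertex; used as a cross-check.
    """
    v_long, v_trans = speeds
    if fibres is None:
        fibres = np.zeros((mesh.n_triangles, 3))
    M = _element_metrics(mesh, fibres, np.asarray(v_long, float), np.asarray(v_trans, float))
    t = mesh.triangles
    e = np.sort(np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]]), axis=1)
    tri_of = np.tile(np.arange(mesh.n_triangles), 3)
    vec = mesh.vertices[e[:, 1]] - mesh.vertices[e[:, 0]]
    w = np.sqrt(np.einsum("ni,nij,nj->n", vec, M[tri_of], vec))
    order = np.lexsort((e[:, 1], e[:, 0]))
    e, w = e[order], w[order]
    uniq, inverse = np.unique(e, axis=0, return_inverse=True)
    wmin = np.full(len(uniq), np.inf)
    np.minimum.at(wmin, inverse, w)  # edge time = min over adjacent elements
    n = mesh.n_vertices
    g = sparse.coo_matrix((wmin, (uniq[:, 0], uniq[:, 1])), shape=(n, n))
    g = g + g.T
    dist = sparse.csgraph.dijkstra(g.tocsr(), directed=False, indices=np.asarray(stimulus))
    return LATMap(times=dist.min(axis=0), stimulus=np.asarray(stimulus))


def cv_map(lat: LATMap, mesh: LabelledSurfaceMesh, eps: float = 1e-9) -> np.ndarray:
    """Per-element conduction velocity 1/‖∇LAT‖ in m/s (mm/ms ≡ m/s).

    Elements with near-zero LAT gradient or non-finite vertex times are NaN.
    """
    v = mesh.vertices
    t = mesh.triangles
    T = lat.times
    a, b, c = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
    fa, fb, fc = T[t[:, 0]], T[t[:, 1]], T[t[:, 2]]
    n = np.cross(b - a, c - a)
    nn = np.maximum(np.einsum("ij,ij->i", n, n), 1e-30)
    grad = (
        np.nan_to_num(fa, posinf=np.nan)[:, None] * np.cross(n, c - b)
        + np.nan_to_num(fb, posinf=np.nan)[:, None] * np.cross(n, a - c)
        + np.nan_to_num(fc, posinf=np.nan)[:, None] * np.cross(n, b - a)
    ) / nn[:, None]
    mag = np.linalg.norm(grad, axis=1)
    finite = np.isfinite(fa) & np.isfinite(fb) & np.isfinite(fc)
    cv = np.full(mesh.n_triangles, np.nan)
    ok = finite & (mag > eps)
    cv[ok] = 1.0 / mag[ok]
    return cv


# --------------------------------------------------------- two-variable model
@dataclass
class ReactionParams:
    """Aliev–Panfilov kinetics: cubic activation u, linear recovery w."""

    k: float = 8.0
    a: float = 0.1
    eps0: float = 0.01
    mu1: float = 0.12
    mu2: float = 0.3
    time_scale: float = 12.9  # ms per dimensionless time unit
    diffusion: float = 0.25  # mm²/ms per (S/m) of conductivity


def _reaction(u: np.ndarray, w: np.ndarray, p: ReactionParams):
    du = (p.k * u * (1.0 - u) * (u - p.a) - u * w) / p.time_scale
    eps = p.eps0 + p.mu1 * w / (u + p.mu2)
    dw = eps * (-w - p.k * u * (u - p.a - 1.0)) / p.time_scale
    return du, dw


@lru_cache(maxsize=4)
def _pulse_cycle(params_key: tuple) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float]:
    """Travelling-pulse cycle (u(φ), w(φ)) from a 1-D periodic-ring run.

    A pulse is initiated on a ring and run to a steady rotation; the
    snapshot profile, parameterised by phase around the (u, w) loop centre,
    supplies the state for any requested initial phase.
    """
    p = ReactionParams(*params_key)
    n = 300
    dx = 0.5  # mm
    D = p.diffusion * 0.4  # isotropic ring at the longitudinal conductivity
    dt = 0.05
    u = np.zeros(n)
    w = np.zeros(n)
    u[:20] = 1.0
    w[-30:] = 1.5  # refractory tail behind the front, sets direction
    lap = np.zeros(n)
    steps = int(800.0 / dt)
    for _ in range(steps):
        lap[:] = (np.roll(u, 1) - 2 * u + np.roll(u, -1)) / dx**2
        du, dw = _reaction(u, w, p)
        u = u + dt * (D * lap + du)
        w = w + dt * dw
    if u.max() < 0.5:
        raise SimulationError("ring pulse died; reaction parameters unsuitable")
    u0, w0 = 0.5 * (u.max() + u.min()), 0.5 * (w.max() + w.min())
    phi = np.arctan2(w - w0, u - u0)
    order = np.argsort(phi)
    phi_s, u_s, w_s = phi[order], u[order], w[order]
    keep = np.concatenate([[True], np.diff(phi_s) > 1e-9])
    return phi_s[keep], u_s[keep], w_s[keep], u0, w0


def _cycle_state(phi: np.ndarray, p: ReactionParams):
    key = (p.k, p.a, p.eps0, p.mu1, p.mu2, p.time_scale, p.diffusion)
    cyc_phi, cyc_u, cyc_w, _, _ = _pulse_cycle(key)
    phi = np.mod(phi + np.pi, 2 * np.pi) - np.pi
    ext_phi = np.concatenate([cyc_phi - 2 * np.pi, cyc_phi, cyc_phi + 2 * np.pi])
    u = np.interp(phi, ext_phi, np.tile(cyc_u, 3))
    w = np.interp(phi, ext_phi, np.tile(cyc_w, 3))
    return u, w


def spiral_phase(
    uac: UACField,
    centres: np.ndarray,
    chirality: np.ndarray,
    pitch: float = 0.2,
) -> np.ndarray:
    """Continuous phase field whose only singularities are the spiral cores.

    φ = Σ_k s_k·θ_k − Σ_k s_k·r_k / b: the angular terms fix the winding
    (one ±1 singularity per centre), the smooth radial terms give each core
    an Archimedean-spiral structure with pitch parameter b.
    """
    pts = uac.as_points()
    phi = np.zeros(len(pts))
    for (cx, cy), s in zip(centres, chirality):
        dx, dy = pts[:, 0] - cx, pts[:, 1] - cy
        r = np.hypot(dx, dy)
        phi += s * np.arctan2(dy, dx) - s * r / pitch
    return np.mod(phi + np.pi, 2 * np.pi) - np.pi


FOUR_SPIRAL_CENTRES = np.array([[0.25, 0.25], [0.25, 0.75], [0.75, 0.25], [0.75, 0.75]])
FOUR_SPIRAL_CHIRALITY = np.array([1, -1, -1, 1])


def init_four_spirals(
    uac: UACField, params: ReactionParams | None = None, pitch: float = 0.2
) -> dict:
    """Initial (u, w) state: four alternating-chirality Archimedean spirals.

    Spiral cores sit at UAC (0.25, 0.25), (0.25, 0.75), (0.75, 0.25),
    (0.75, 0.75); the state at each vertex is taken from the travelling-
    pulse cycle at the spiral phase.
    """
    if uac is None:
        raise ValueError("UAC required for spiral initiation")
    p = params or ReactionParams()
    phi = spiral_phase(uac, FOUR_SPIRAL_CENTRES, FOUR_SPIRAL_CHIRALITY, pitch=pitch)
    u, w = _cycle_state(phi, p)
    return {"u": u, "w": w, "phase": phi}


def init_single_spiral(
    uac: UACField, centre=(0.5, 0.5), params: ReactionParams | None = None, pitch: float = 0.2
) -> dict:
    p = params or ReactionParams()
    phi = spiral_phase(uac, np.array([centre]), np.array([1]), pitch=pitch)
    u, w = _cycle_state(phi, p)
    return {"u": u, "w": w, "phase": phi}


def _stiffness_matrix(mesh: LabelledSurfaceMesh, fibres: np.ndarray,
                      cfg: ConductionSettings, p: ReactionParams) -> sparse.csr_matrix:
    """FEM stiffness for ∇·(D∇u), D = d·[σt·I + (σl−σt)·ffᵀ] in the tangent plane."""
    v = mesh.vertices
    t = mesh.triangles
    n = mesh.normals()
    f = np.asarray(fibres, dtype=float).reshape(-1, 3)
    f = f - np.einsum("ij,ij->i", f, n)[:, None] * n
    norms = np.maximum(np.linalg.norm(f, axis=1), 1e-12)
    f = f / norms[:, None]
    d = p.diffusion
    D = d * (
        cfg.sigma_t * np.eye(3)[None, :, :]
        + (cfg.sigma_l - cfg.sigma_t) * f[:, :, None] * f[:, None, :]
    )
    a, b, c = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
    nvec = np.cross(b - a, c - a)
    nn = np.maximum(np.einsum("ij,ij->i", nvec, nvec), 1e-30)
    area = 0.5 * np.sqrt(nn)
    grads = np.stack(
        [
            np.cross(nvec, c - b) / nn[:, None],
            np.cross(nvec, a - c) / nn[:, None],
            np.cross(nvec, b - a) / nn[:, None],
        ],
        axis=1,
    )  # (m, 3 local vertices, 3 xyz)
    Dg = np.einsum("mij,mkj->mki", D, grads)
    K_local = np.einsum("mki,mli->mkl", grads, Dg) * area[:, None, None]
    rows = np.repeat(t, 3, axis=1).ravel()
    cols = np.tile(t, (1, 3)).ravel()
    vals = K_local.ravel()
    nvert = mesh.n_vertices
    return sparse.coo_matrix((vals, (rows, cols)), shape=(nvert, nvert)).tocsr()


def _lumped_mass(mesh: LabelledSurfaceMesh) -> np.ndarray:
    area = mesh.areas()
    m = np.zeros(mesh.n_vertices)
    for k in range(3):
        np.add.at(m, mesh.triangles[:, k], area / 3.0)
    m[m == 0] = 1.0
    return m


def simulate_af(
    mesh: LabelledSurfaceMesh,
    fibres: np.ndarray,
    cfg: ConductionSettings,
    init: dict,
    duration: float = 500.0,
    dt: float = 0.05,
    sample_dt: float = 5.0,
    params: ReactionParams | None = None,
) -> dict:
    """Explicit-Euler monodomain run; returns sampled (u, w) frames.

    Deterministic for fixed inputs.  Aborts with a CFL diagnostic if the
    activation variable leaves the excitable range (|u| > 10).
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    p = params or ReactionParams()
    K = _stiffness_matrix(mesh, fibres, cfg, p)
    Minv = 1.0 / _lumped_mass(mesh)
    u = np.asarray(init["u"], dtype=float).copy()
    w = np.asarray(init["w"], dtype=float).copy()
    nsteps = int(round(duration / dt))
    every = max(1, int(round(sample_dt / dt)))
    frames_u, frames_w, times = [], [], []
    for step in range(nsteps + 1):
        if step % every == 0:
            frames_u.append(u.copy())
            frames_w.append(w.copy())
            times.append(step * dt)
        if step == nsteps:
            break
        du, dw = _reaction(u, w, p)
        u = u + dt * (du - Minv * (K @ u))
        w = w + dt * dw
        if np.abs(u).max() > 10.0:
            raise SimulationError(
                f"instability at t = {step * dt:.2f} ms (|u| > 10): reduce dt "
                f"(CFL limit ~ h²/2D with h the min edge length)"
            )
    return {"u": np.array(frames_u), "w": np.array(frames_w), "t": np.array(times), "params": p}


def phase_from_states(u: np.ndarray, w: np.ndarray, p: ReactionParams | None = None) -> np.ndarray:
    """Activation phase: atan2 of the centred (w, u) state pair."""
    p = p or ReactionParams()
    key = (p.k, p.a, p.eps0, p.mu1, p.mu2, p.time_scale, p.diffusion)
    _, _, _, u0, w0 = _pulse_cycle(key)
    return np.arctan2(w - w0, u - u0)


# ------------------------------------------------------ phase singularities
def _ordered_rings(mesh: LabelledSurfaceMesh):
    """For each interior vertex, its one-ring neighbours sorted by tangent angle."""
    n = mesh.n_vertices
    adj = [[] for _ in range(n)]
    for t in mesh.triangles:
        for k in range(3):
            adj[t[k]].extend((t[(k + 1) % 3], t[(k + 2) % 3]))
    boundary = set(mesh.boundary_vertices().tolist())
    # vertex normals for a consistent in-plane orientation
    tn = mesh.normals() * mesh.areas()[:, None]
    vn = np.zeros((n, 3))
    for k in range(3):
        np.add.at(vn, mesh.triangles[:, k], tn)
    norms = np.maximum(np.linalg.norm(vn, axis=1), 1e-30)
    vn /= norms[:, None]
    rings = []
    verts = mesh.vertices
    for vi in range(n):
        if vi in boundary or not adj[vi]:
            rings.append(None)
            continue
        nbrs = np.unique(adj[vi])
        nvec = vn[vi]
        ref = verts[nbrs[0]] - verts[vi]
        ref -= np.dot(ref, nvec) * nvec
        rn = np.linalg.norm(ref)
        if rn < 1e-12:
            rings.append(None)
            continue
        ref /= rn
        e2 = np.cross(nvec, ref)
        d = verts[nbrs] - verts[vi]
        ang = np.arctan2(d @ e2, d @ ref)
        rings.append(nbrs[np.argsort(ang)])
    return rings


def detect_phase_singularities(
    phases: np.ndarray, mesh: LabelledSurfaceMesh, tol: float = 0.2
) -> np.ndarray:
    """Vertices where the one-ring phase winding is ±2π (within ``tol`` rad).

    ``phases`` is (n,) for one frame or (F, n) for a stack; returns an array
    of (frame, vertex, charge) rows.  Boundary vertices are skipped.
    """
    phases = np.atleast_2d(np.asarray(phases, dtype=float))
    rings = _ordered_rings(mesh)
    adj = {tuple(sorted(e)) for e in mesh.edges().tolist()}
    detections = []
    for frame, phi in enumerate(phases):
        hits: list[tuple[int, int]] = []
        for vi, ring in enumerate(rings):
            if ring is None:
                continue
            vals = phi[ring]
            diffs = np.diff(np.concatenate([vals, vals[:1]]))
            wrapped = np.mod(diffs + np.pi, 2 * np.pi) - np.pi
            total = wrapped.sum()
            if np.abs(np.abs(total) - 2 * np.pi) <= tol:
                hits.append((vi, int(np.sign(total))))
        # a core inside a triangle trips every vertex of that triangle:
        # merge edge-adjacent detections of equal charge into one
        for charge in (1, -1):
            verts = sorted(v for v, c in hits if c == charge)
            parent = {v: v for v in verts}

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for i, vi in enumerate(verts):
                for vj in verts[i + 1 :]:
                    if (vi, vj) in adj:
                        parent[find(vj)] = find(vi)
            groups: dict[int, list[int]] = {}
            for v in verts:
                groups.setdefault(find(v), []).append(v)
            for members in groups.values():
                detections.append((frame, min(members), charge))
    return np.array(sorted(detections), dtype=np.int64).reshape(-1, 3)


def bin_ps(detections: np.ndarray, uac: UACField, grid_size: int = 101) -> PSMap:
    """Bin PS detections into a regular UAC grid (counts over all frames)."""
    grid = np.zeros((grid_size, grid_size))
    detections = np.asarray(detections).reshape(-1, 3)
    for _, vi, _ in detections:
        i = int(np.clip(uac.alpha[vi] * grid_size, 0, grid_size - 1))
        j = int(np.clip(uac.beta[vi] * grid_size, 0, grid_size - 1))
        grid[i, j] += 1
    return PSMap(grid=grid, n_detections=len(detections))


def rim_stimulus(mesh: LabelledSurfaceMesh, structure: str = "RSPV") -> np.ndarray:
    """Vertex set of a pulmonary-vein rim (full boundary loop) for pacing."""
    from lamp.uac import classify_boundary_loops

    rims = classify_boundary_loops(mesh)
    if structure not in rims:
        raise ValueError(f"mesh has no {structure} rim; openings found: {sorted(rims)}")
    return rims[structure]
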