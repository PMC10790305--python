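"""Synthetic test cohort with planted ground truth.

Each case is an ellipsoidal atrial-body blob with four tubular pulmonary
veins, an appendage lobe and a mitral-valve disc marker, rendered into a
bright-bloodpool MRA-like volume and an LGE-like volume whose wall carries
a fibrotic patch of known surface fraction.  Everything an operator would
supply — structure seeds, clipping spheres, UAC landmarks — is recorded as
ground truth, and :func:`perturb_operator` emulates inter/intra-operator
variability by Gaussian jitter of those inputs.

All volumes are 1 mm isotropic in the canonical RAI frame.  Generation is
deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from lamp.labelling import ClippingSphere, MultilabelSegmentation, SEG_CLASSES, StructureSeed
from lamp.mesh import STRUCTURE_LABELS
from lamp.uac import LandmarkSet
from lamp.volume import Volume

#: The canonical RAI affine: data axes run Right→left, Anterior→posterior,
#: Inferior→superior, i.e. index (i, j, k) maps to RAS world (−i, −j, k).
RAI_AFFINE = np.diag([-1.0, -1.0, 1.0, 1.0])


def _to_world(p: np.ndarray) -> np.ndarray:
    """Index-space point (1 mm voxels) → RAS world mm under the RAI affine."""
    p = np.asarray(p, dtype=float)
    return p * np.array([-1.0, -1.0, 1.0])


#: Unit directions (index axes of an RAI volume: +i left, +j posterior,
#: +k superior) along which each structure leaves the atrial body.
_STRUCTURE_DIRS = {
    "LSPV": (0.75, 0.45, 0.50),
    "LIPV": (0.80, 0.55, -0.25),
    "RSPV": (-0.75, 0.45, 0.50),
    "RIPV": (-0.80, 0.55, -0.25),
    "LAA": (0.80, -0.55, 0.25),
}
_MV_DIR = (0.0, -0.35, -0.95)
_LATERAL_DIR = (0.95, -0.30, 0.05)
_SEPTAL_DIR = (-0.95, -0.20, 0.10)


@dataclass
class CaseParams:
    """Generator settings; defaults are the study conditions."""

    grid_size: int = 112
    body_axes_range: tuple = (15.0, 20.0)  # semi-axes, mm
    vein_radius_range: tuple = (4.0, 6.0)  # mm (supported range 4–8)
    vein_length_range: tuple = (15.0, 22.0)  # mm (supported range 15–30)
    laa_radius_range: tuple = (6.0, 8.0)
    laa_length_range: tuple = (14.0, 18.0)
    mv_radius: float = 12.0
    mv_thickness: float = 3.0
    patch_fraction: float = 0.3
    mra_background: float = 100.0
    mra_bloodpool: float = 600.0
    mra_noise: float = 20.0
    lge_background: float = 80.0
    lge_bloodpool: float = 200.0
    lge_wall: float = 160.0
    lge_fibrosis: float = 400.0
    lge_noise: float = 5.0
    wall_thickness: int = 3  # voxels

    def validate(self) -> None:
        if not (0.0 <= self.patch_fraction <= 0.85):
            raise ValueError("patch_fraction must be in [0, 0.85]")
        for lo, hi, rng in [
            (4.0, 8.0, self.vein_radius_range),
            (15.0, 30.0, self.vein_length_range),
        ]:
            if rng[0] < lo - 1e-9 or rng[1] > hi + 1e-9 or rng[0] > rng[1]:
                raise ValueError(f"range {rng} outside supported [{lo}, {hi}]")
        if self.grid_size < 64:
            raise ValueError("grid too small to contain the atrium")


@dataclass
class SyntheticCaseTruth:
    """A generated case: volumes plus every planted ground-truth quantity."""

    seg: MultilabelSegmentation
    mra: Volume
    lge: Volume
    final_labels: Volume  # structure-labelled bloodpool (construction truth)
    seeds: list  # StructureSeed per vein/appendage
    junctions: dict  # structure -> world point where it meets the body
    clip_spheres: list  # ClippingSphere per PV + MV
    landmarks: LandmarkSet
    patch_fraction: float
    body_centre: np.ndarray
    seed: int
    params: CaseParams


@dataclass
class OperatorPerturbation:
    """Gaussian jitter scales (mm) emulating one operator's manual input."""

    mode: str  # "inter" or "intra"
    seed_jitter: float
    clip_centre_jitter: float
    clip_radius_jitter: float
    mv_centre_jitter: float
    landmark_jitter: float
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("inter", "intra"):
            raise ValueError("mode must be 'inter' or 'intra'")
        for v in (self.seed_jitter, self.clip_centre_jitter, self.clip_radius_jitter,
                  self.mv_centre_jitter, self.landmark_jitter):
            if v < 0:
                raise ValueError("jitter scales must be non-negative")

    @classmethod
    def inter(cls, rng_seed: int = 0) -> "OperatorPerturbation":
        # MV placement dominates inter-operator shape differences: σ = 3 mm
        return cls("inter", 2.0, 2.0, 1.0, 3.0, 3.0, rng_seed)

    @classmethod
    def intra(cls, rng_seed: int = 0) -> "OperatorPerturbation":
        return cls("intra", 1.0, 1.0, 0.5, 1.0, 1.0, rng_seed)


@dataclass
class OperatorInputs:
    """What a (synthetic) operator hands to the pipeline."""

    seeds: list
    clip_spheres: list
    landmarks: LandmarkSet
    mode: str


def _surface_point(centre: np.ndarray, axes: np.ndarray, direction) -> np.ndarray:
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    t = 1.0 / np.sqrt(np.sum((d / axes) ** 2))
    return centre + t * d, d


def _capsule_mask(coords, p0, p1, radius) -> np.ndarray:
    """Voxels within ``radius`` of the segment p0–p1."""
    seg = p1 - p0
    L2 = max(np.dot(seg, seg), 1e-12)
    rel = coords - p0
    t = np.clip((rel @ seg) / L2, 0.0, 1.0)
    closest = p0 + t[:, None] * seg
    return np.linalg.norm(coords - closest, axis=1) <= radius


def generate_case(seed: int, params: CaseParams | None = None) -> SyntheticCaseTruth:
    """Build one deterministic synthetic case (1 mm isotropic, RAI)."""
    p = params or CaseParams()
    p.validate()
    rng = np.random.default_rng(seed)
    n = p.grid_size
    centre = np.full(3, n / 2.0)
    axes = rng.uniform(*p.body_axes_range, size=3)
    idx = np.indices((n, n, n)).reshape(3, -1).T.astype(float)  # spacing 1, origin 0

    body = np.sum(((idx - centre) / axes) ** 2, axis=1) <= 1.0

    struct_masks: dict[str, np.ndarray] = {}
    seeds_out: list[StructureSeed] = []
    junctions: dict[str, np.ndarray] = {}
    spheres: list[ClippingSphere] = []
    radii: dict[str, float] = {}
    for name, direction in _STRUCTURE_DIRS.items():
        if name == "LAA":
            r = rng.uniform(*p.laa_radius_range)
            length = rng.uniform(*p.laa_length_range)
        else:
            r = rng.uniform(*p.vein_radius_range)
            length = rng.uniform(*p.vein_length_range)
        surf, d = _surface_point(centre, axes, direction)
        p0 = centre + 0.6 * (surf - centre)  # start inside the body: solid attachment
        p1 = surf + length * d
        struct_masks[name] = _capsule_mask(idx, p0, p1, r)
        junctions[name] = _to_world(surf)
        radii[name] = r
        seeds_out.append(StructureSeed(point=_to_world(p1), structure=name))
        if name != "LAA":  # the appendage is never clipped
            spheres.append(
                ClippingSphere(centre=_to_world(p1 + 1.0 * d), radius=1.8 * r, target=name)
            )

    mv_centre, mv_d = _surface_point(centre, axes, _MV_DIR)
    mv_centre = mv_centre + 1.0 * mv_d  # disc marker just outside the wall
    rel = idx - mv_centre
    axial = rel @ mv_d
    radial = np.linalg.norm(rel - axial[:, None] * mv_d, axis=1)
    mv_mask = (np.abs(axial) <= p.mv_thickness / 2.0) & (radial <= p.mv_radius)

    pvlaa = np.zeros(len(idx), dtype=bool)
    for m in struct_masks.values():
        pvlaa |= m
    pvlaa &= ~body
    mv_mask &= ~(body | pvlaa)

    seg_data = np.zeros(len(idx), dtype=np.int16)
    seg_data[body] = SEG_CLASSES["LA"]
    seg_data[pvlaa] = SEG_CLASSES["PVLAA"]
    seg_data[mv_mask] = SEG_CLASSES["MV"]

    final = np.zeros(len(idx), dtype=np.int16)
    final[body] = STRUCTURE_LABELS["LA"]
    for name, m in struct_masks.items():
        final[m & ~body] = STRUCTURE_LABELS[name]

    bloodpool = body | pvlaa
    shape = (n, n, n)
    bp3 = bloodpool.reshape(shape)
    body3 = body.reshape(shape)

    # wall shell and the fibrotic patch on the body wall
    shell_all = ndimage.binary_dilation(bp3, iterations=p.wall_thickness) & ~bp3
    shell_body = ndimage.binary_dilation(body3, iterations=p.wall_thickness) & ~bp3
    mv_sphere_r = p.mv_radius
    dist_to_mv = np.linalg.norm(idx - mv_centre, axis=1).reshape(shape)
    scoreable = shell_body & (dist_to_mv > mv_sphere_r)
    vein_zone = np.zeros(shape, dtype=bool)
    for name, m in struct_masks.items():
        vein_zone |= ndimage.binary_dilation(m.reshape(shape), iterations=2)
    eligible = scoreable & ~vein_zone

    patch = np.zeros(shape, dtype=bool)
    if p.patch_fraction > 0:
        axis = np.asarray([0.1, 1.0, 0.2]) + rng.normal(0.0, 0.15, size=3)
        axis /= np.linalg.norm(axis)
        elig_idx = np.argwhere(eligible)
        rel_dir = elig_idx - centre
        ang = np.arccos(
            np.clip(rel_dir @ axis / np.linalg.norm(rel_dir, axis=1), -1.0, 1.0)
        )
        target = int(round(p.patch_fraction * scoreable.sum()))
        if target > len(ang):
            raise ValueError("patch fraction too large for the eligible wall area")
        if target > 0:
            cut = np.sort(ang)[target - 1]
            sel = elig_idx[ang <= cut]
            patch[tuple(sel.T)] = True

    mra = np.full(shape, p.mra_background, dtype=np.float32)
    mra[bp3] = p.mra_bloodpool
    mra += rng.normal(0.0, p.mra_noise, size=shape).astype(np.float32)

    lge = np.full(shape, p.lge_background, dtype=np.float32)
    lge[shell_all] = p.lge_wall
    lge[bp3] = p.lge_bloodpool
    lge[patch] = p.lge_fibrosis
    lge += rng.normal(0.0, p.lge_noise, size=shape).astype(np.float32)

    spheres.append(ClippingSphere(centre=_to_world(mv_centre), radius=mv_sphere_r, target="MV"))
    lat_pt, _ = _surface_point(centre, axes, _LATERAL_DIR)
    sep_pt, _ = _surface_point(centre, axes, _SEPTAL_DIR)
    landmarks = LandmarkSet(
        lspv_junction=junctions["LSPV"],
        rspv_junction=junctions["RSPV"],
        lateral=_to_world(lat_pt),
        septal=_to_world(sep_pt),
    )
    affine = RAI_AFFINE.copy()
    seg_vol = Volume(data=seg_data.reshape(shape), affine=affine)
    return SyntheticCaseTruth(
        seg=MultilabelSegmentation(volume=seg_vol),
        mra=Volume(data=mra, affine=affine.copy()),
        lge=Volume(data=lge, affine=affine.copy()),
        final_labels=Volume(data=final.reshape(shape), affine=affine.copy()),
        seeds=seeds_out,
        junctions=junctions,
        clip_spheres=spheres,
        landmarks=landmarks,
        patch_fraction=p.patch_fraction,
        body_centre=_to_world(centre),
        seed=seed,
        params=p,
    )


def perturb_operator(truth: SyntheticCaseTruth, pert: OperatorPerturbation) -> OperatorInputs:
    """Jitter the truth's manual inputs with the perturbation's scales.

    Deterministic per (truth seed, perturbation seed).  Zero scales return
    the truth inputs unchanged.
    """
    rng = np.random.default_rng((truth.seed + 1) * 1_000_003 + pert.rng_seed)
    seeds = [
        StructureSeed(point=s.point + rng.normal(0.0, pert.seed_jitter, 3), structure=s.structure)
        for s in truth.seeds
    ]
    spheres = []
    for s in truth.clip_spheres:
        centre_scale = pert.mv_centre_jitter if s.target == "MV" else pert.clip_centre_jitter
        radius = max(1.0, s.radius + rng.normal(0.0, pert.clip_radius_jitter))
        spheres.append(
            ClippingSphere(
                centre=s.centre + rng.normal(0.0, centre_scale, 3),
                radius=radius,
                target=s.target,
            )
        )
    lm = truth.landmarks
    landmarks = LandmarkSet(
        lspv_junction=lm.lspv_junction + rng.normal(0.0, pert.landmark_jitter, 3),
        rspv_junction=lm.rspv_junction + rng.normal(0.0, pert.landmark_jitter, 3),
        lateral=lm.lateral + rng.normal(0.0, pert.landmark_jitter, 3),
        septal=lm.septal + rng.normal(0.0, pert.landmark_jitter, 3),
    )
    return OperatorInputs(seeds=seeds, clip_spheres=spheres, landmarks=landmarks, mode=pert.mode)
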