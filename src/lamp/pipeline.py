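"""Case orchestration: volumes → mesh → UAC → fibres → fibrosis → simulation.

A :class:`CaseConfig` (YAML/JSON-serialisable) drives :func:`run_case`,
which executes the stages in order, writes every artefact under the case
output directory and keeps a per-stage wall-clock time log.
:func:`compare_pair` runs the full agreement-metric suite on two completed
cases.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from lamp import fibrosis as fib
from lamp import ep
from lamp.labelling import (
    DetectionError,
    MultilabelSegmentation,
    assign_naive_labels,
    clip_structures,
    extract_labelled_surface,
    identify_structure,
    label_from_seeds,
    verify_labels,
)
from lamp.mesh import LabelledSurfaceMesh, read_vtk_polydata, write_vtk_polydata
from lamp.metrics import (
    ComparisonReport,
    correspond,
    cv_compare,
    distance_stats,
    fibre_agreement,
    lat_compare,
    ps_compare,
)
from lamp.refine import clean_mesh, export_carp, remesh_to_edge_length
from lamp.synthetic import OperatorPerturbation, generate_case, perturb_operator
from lamp.uac import (
    FibreField,
    LandmarkSet,
    UACField,
    compute_uac,
    generate_rule_based_fibres,
    smooth_varying_fibres,
)
from lamp.volume import read_volume, reorient_to_rai, resample_isotropic, write_volume


class StageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class CaseConfig:
    """All settings for one case run.

    Either ``synthetic_seed`` is set (a case is generated) or the three
    input paths point at NIfTI volumes.  Operator inputs (seeds, spheres,
    landmarks) default to the synthetic truth, optionally jittered.
    """

    output_dir: str = "case_out"
    synthetic_seed: int | None = 1
    mra_path: str | None = None
    lge_path: str | None = None
    seg_path: str | None = None
    operator_mode: str | None = None  # None (truth), "inter" or "intra"
    operator_seed: int = 0
    iir_factors: tuple = fib.DEFAULT_IIR_FACTORS
    fibre_field: str = "l"  # "l" rule-based, "1" smooth stand-in
    remesh_edge: float = 0.8  # mm; the clinical profile uses 0.3
    projection_depth: float = 3.0
    sim_duration: float = 500.0
    sim_dt: float = 0.05
    sim_sample_dt: float = 5.0
    sim_transient: float = 200.0
    spiral_pitch: float = 0.2
    uac_grid: int = 101
    run_simulation: bool = True
    stages: tuple = ("volumes", "labelling", "refine", "fibrosis", "uac", "ep")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "CaseConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        cfg = cls(**data)
        for key in ("mra_path", "lge_path", "seg_path"):
            p = getattr(cfg, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{key} = {p} does not exist")
        if any(f <= 0 for f in cfg.iir_factors):
            raise ValueError("IIR factors must be positive")
        return cfg


@dataclass
class CaseResult:
    """In-memory artefacts of a completed (or partial) case run."""

    config: CaseConfig
    mesh: LabelledSurfaceMesh | None = None
    uac: UACField | None = None
    fibres: FibreField | None = None
    intensity: np.ndarray | None = None
    fibrosis_scores: dict = field(default_factory=dict)  # factor -> score
    lat: np.ndarray | None = None
    cv: np.ndarray | None = None
    ps_map: np.ndarray | None = None
    time_log: dict = field(default_factory=dict)
    truth: object = None

    def output_dir(self) -> Path:
        return Path(self.config.output_dir)


def _case_inputs(cfg: CaseConfig):
    """Volumes + operator inputs, from the generator or from files."""
    if cfg.synthetic_seed is not None:
        truth = generate_case(cfg.synthetic_seed)
        if cfg.operator_mode is None:
            op = perturb_operator(
                truth, OperatorPerturbation("intra", 0, 0, 0, 0, 0, cfg.operator_seed)
            )
        elif cfg.operator_mode == "inter":
            op = perturb_operator(truth, OperatorPerturbation.inter(cfg.operator_seed))
        else:
            op = perturb_operator(truth, OperatorPerturbation.intra(cfg.operator_seed))
        return truth.seg, truth.mra, truth.lge, op, truth
    if not (cfg.mra_path and cfg.lge_path and cfg.seg_path):
        raise ValueError("either synthetic_seed or all three input paths must be set")
    mra = resample_isotropic(reorient_to_rai(read_volume(cfg.mra_path)))
    lge = resample_isotropic(reorient_to_rai(read_volume(cfg.lge_path)))
    seg_vol = resample_isotropic(reorient_to_rai(read_volume(cfg.seg_path)))
    seg = MultilabelSegmentation(volume=seg_vol)
    case_dir = Path(cfg.output_dir)
    op_file = case_dir / "operator.json"
    if not op_file.exists():
        raise ValueError("file-based cases need an operator.json with seeds/spheres/landmarks")
    from lamp.labelling import ClippingSphere, StructureSeed
    from lamp.synthetic import OperatorInputs

    data = json.loads(op_file.read_text())
    op = OperatorInputs(
        seeds=[StructureSeed(np.asarray(s["point"]), s["structure"]) for s in data["seeds"]],
        clip_spheres=[
            ClippingSphere(np.asarray(s["centre"]), s["radius"], s["target"])
            for s in data["clip_spheres"]
        ],
        landmarks=LandmarkSet.from_dict(data["landmarks"]),
        mode=data.get("mode", "manual"),
    )
    return seg, mra, lge, op, None


def run_case(config: CaseConfig) -> CaseResult:
    """Execute the pipeline stages in order, writing artefacts and timings."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = CaseResult(config=config)
    log: dict[str, float] = {}

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                log[name] = round(time.perf_counter() - self.t0, 3)
                result.time_log = log
                (out / "time_log.json").write_text(json.dumps(log, indent=1))
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, exc) from exc

        return _Timer()

    stages = config.stages
    with stage("volumes"):
        seg, mra, lge, op, truth = _case_inputs(config)
        result.truth = truth
        if config.synthetic_seed is not None:
            write_volume(seg.volume, out / "segmentation.nii.gz")
            write_volume(lge, out / "lge.nii.gz")

    if "labelling" not in stages:
        return result
    with stage("labelling"):
        assign_naive_labels(seg)  # provisional pass, superseded by seed identification
        junctions = {}
        for s in op.seeds:
            try:
                junctions[s.structure] = identify_structure(seg, s)
            except DetectionError as exc:
                warnings.warn(f"{s.structure}: {exc}; using seed-side default")
        labels = label_from_seeds(seg, op.seeds, junctions)
        surface = extract_labelled_surface(seg, labels)
        surface = verify_labels(surface)
        mesh = clip_structures(surface, op.clip_spheres)
        result.mesh = mesh

    if "refine" in stages:
        with stage("refine"):
            mesh = remesh_to_edge_length(mesh, target=config.remesh_edge)
            mesh = clean_mesh(mesh)
            result.mesh = mesh

    if "fibrosis" in stages:
        with stage("fibrosis"):
            imap = fib.project_max_intensity(mesh, lge, depth=config.projection_depth)
            result.intensity = imap.values
            bp = fib.bloodpool_mask_from_body(seg.class_mask("LA"))
            rows = []
            for factor in config.iir_factors:
                thr = fib.iir_threshold(lge, bp, factor)
                summary = fib.fibrosis_score(imap, mesh, thr, iir_factor=factor)
                result.fibrosis_scores[factor] = summary.score
                rows.append(
                    {"factor": factor, "threshold": thr, "score": summary.score}
                )
            pd.DataFrame(rows).to_csv(out / "fibrosis.csv", index=False)
            mesh.cell_data["intensity"] = imap.values

    if "uac" in stages:
        with stage("uac"):
            uac = compute_uac(mesh, op.landmarks)
            result.uac = uac
            if config.fibre_field == "1":
                fibres = smooth_varying_fibres(uac, mesh)
            else:
                fibres = generate_rule_based_fibres(uac, mesh)
            result.fibres = fibres
            mesh.cell_data["fibres"] = fibres.vectors
            export_carp(mesh, fibres.vectors, out / "carp")

    if "ep" in stages and config.run_simulation:
        with stage("ep"):
            cfg_ep = ep.ConductionSettings()
            speeds = ep.element_speeds(fibres.vectors, cfg_ep)
            stim = ep.rim_stimulus(mesh, "RSPV")
            lat = ep.eikonal_lat(mesh, speeds, stim, fibres=fibres.vectors)
            result.lat = lat.times
            mesh.point_data["lat"] = np.where(np.isfinite(lat.times), lat.times, -1.0)
            result.cv = ep.cv_map(lat, mesh)
            init = ep.init_four_spirals(uac, pitch=config.spiral_pitch)
            sim = ep.simulate_af(
                mesh,
                fibres.vectors,
                cfg_ep,
                init,
                duration=config.sim_duration,
                dt=config.sim_dt,
                sample_dt=config.sim_sample_dt,
            )
            keep = sim["t"] >= config.sim_transient
            phases = ep.phase_from_states(sim["u"][keep], sim["w"][keep])
            det = ep.detect_phase_singularities(phases, mesh)
            ps = ep.bin_ps(det, uac, grid_size=config.uac_grid)
            result.ps_map = ps.grid
            np.savetxt(out / "ps_map.csv", ps.grid, delimiter=",", fmt="%g")

    write_vtk_polydata(mesh, out / "mesh.vtk")
    config.to_yaml(out / "config.yaml")
    return result


def load_case(case_dir) -> CaseResult:
    """Reload a completed case's artefacts from its output directory."""
    case_dir = Path(case_dir)
    missing = [f for f in ("mesh.vtk", "config.yaml") if not (case_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"{case_dir}: missing artefacts: {missing}")
    config = CaseConfig.from_yaml(case_dir / "config.yaml")
    config.output_dir = str(case_dir)
    mesh = read_vtk_polydata(case_dir / "mesh.vtk")
    result = CaseResult(config=config, mesh=mesh)
    if "alpha" in mesh.point_data:
        result.uac = UACField(mesh.point_data["alpha"], mesh.point_data["beta"])
    if "fibres" in mesh.cell_data:
        result.fibres = FibreField(vectors=mesh.cell_data["fibres"])
    if "intensity" in mesh.cell_data:
        result.intensity = mesh.cell_data["intensity"]
    if "lat" in mesh.point_data:
        lat = np.asarray(mesh.point_data["lat"], dtype=float)
        result.lat = np.where(lat < 0, np.inf, lat)
    fib_csv = case_dir / "fibrosis.csv"
    if fib_csv.exists():
        df = pd.read_csv(fib_csv)
        result.fibrosis_scores = dict(zip(df["factor"], df["score"]))
    ps_csv = case_dir / "ps_map.csv"
    if ps_csv.exists():
        result.ps_map = np.loadtxt(ps_csv, delimiter=",")
    return result


def compare_pair(a: CaseResult, b: CaseResult, cutoff: float = 1.0) -> ComparisonReport:
    """Full agreement-metric suite between two completed cases."""
    missing = []
    for name, res in (("A", a), ("B", b)):
        if res.mesh is None:
            missing.append(f"{name}: mesh")
    if missing:
        raise ValueError(f"cannot compare; missing artefacts: {missing}")
    report = ComparisonReport()
    report.shape = distance_stats(a.mesh, b.mesh)
    corr = correspond(a.mesh, b.mesh, cutoff=cutoff)
    if a.fibres is not None and b.fibres is not None:
        report.fibre = {
            k: v
            for k, v in fibre_agreement(
                corr, a.fibres.vectors, b.fibres.vectors, labelsA=a.mesh.element_labels
            ).items()
            if k != "abs_dot"
        }
    report.fibrosis_scores_a = dict(a.fibrosis_scores)
    report.fibrosis_scores_b = dict(b.fibrosis_scores)
    if a.lat is not None and b.lat is not None and a.uac is not None and b.uac is not None:
        report.lat = lat_compare(a.lat, b.lat, a.uac, b.uac)
    if a.cv is None and a.lat is not None:
        a.cv = ep.cv_map(ep.LATMap(a.lat, np.array([0])), a.mesh)
    if b.cv is None and b.lat is not None:
        b.cv = ep.cv_map(ep.LATMap(b.lat, np.array([0])), b.mesh)
    if a.cv is not None and b.cv is not None:
        report.cv = cv_compare(a.cv, b.cv)
    if a.ps_map is not None and b.ps_map is not None:
        report.ps = ps_compare(a.ps_map, b.ps_map)
    return report


def make_cohort(n_cases: int, seed: int, out_dir, modes=("inter", "intra")) -> pd.DataFrame:
    """Write a cohort manifest: per truth case, an A/B replicate pair per mode."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    rng = np.random.default_rng(seed)
    for i in range(n_cases):
        truth_seed = int(rng.integers(1, 2**31 - 1))
        for mode in modes:
            for replicate in ("a", "b"):
                rows.append(
                    {
                        "case_id": f"case{i:03d}_{mode}_{replicate}",
                        "truth_seed": truth_seed,
                        "mode": mode,
                        "replicate": replicate,
                        "operator_seed": int(rng.integers(0, 2**31 - 1)),
                    }
                )
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "manifest.csv", index=False)
    return df
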