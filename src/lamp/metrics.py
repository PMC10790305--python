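"""Paired-model agreement statistics.

Shape metrics (Hausdorff, mean, median of symmetric minimum distances) use
all points; every other comparison is restricted to correspondences closer
than the cutoff (default 1 mm, the image resolution).  Fibrosis agreement
uses a two-way random-effects, absolute-agreement, average-measures ICC;
fibre agreement is the fraction of matched element pairs with |a·b| above
cos(π/8) (0° and 180° both count as aligned); activation and
phase-singularity maps are compared on a common UAC grid with Pearson
correlation and a uniform-window SSIM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from scipy.interpolate import griddata
from scipy.spatial import cKDTree

from lamp.mesh import LabelledSurfaceMesh, LABEL_NAMES
from lamp.uac import UACField


@dataclass
class Correspondence:
    """Nearest-neighbour maps between two meshes, both directions."""

    dist_ab: np.ndarray  # per A-vertex distance to nearest B vertex
    idx_ab: np.ndarray
    dist_ba: np.ndarray
    idx_ba: np.ndarray
    elem_dist_ab: np.ndarray  # per A-element centroid distance to nearest B centroid
    elem_idx_ab: np.ndarray
    cutoff: float

    @property
    def within_ab(self) -> np.ndarray:
        return self.dist_ab <= self.cutoff

    @property
    def elem_within_ab(self) -> np.ndarray:
        return self.elem_dist_ab <= self.cutoff


def correspond(
    meshA: LabelledSurfaceMesh, meshB: LabelledSurfaceMesh, cutoff: float = 1.0
) -> Correspondence:
    """Exact nearest neighbours (points and element centroids), symmetric."""
    if meshA.n_vertices == 0 or meshB.n_vertices == 0:
        raise ValueError("cannot build correspondences with an empty mesh")
    treeB = cKDTree(meshB.vertices)
    treeA = cKDTree(meshA.vertices)
    dist_ab, idx_ab = treeB.query(meshA.vertices)
    dist_ba, idx_ba = treeA.query(meshB.vertices)
    ctreeB = cKDTree(meshB.centroids())
    elem_dist_ab, elem_idx_ab = ctreeB.query(meshA.centroids())
    return Correspondence(
        dist_ab=dist_ab,
        idx_ab=idx_ab,
        dist_ba=dist_ba,
        idx_ba=idx_ba,
        elem_dist_ab=elem_dist_ab,
        elem_idx_ab=elem_idx_ab,
        cutoff=cutoff,
    )


def _vertex_labels(mesh: LabelledSurfaceMesh) -> np.ndarray:
    """Per-vertex structure label: smallest incident element label (stable)."""
    lab = np.full(mesh.n_vertices, np.iinfo(np.int64).max, dtype=np.int64)
    for k in range(3):
        np.minimum.at(lab, mesh.triangles[:, k], mesh.element_labels)
    return lab


def distance_stats(
    meshA: LabelledSurfaceMesh, meshB: LabelledSurfaceMesh
) -> dict[str, dict[str, float]]:
    """Per-structure and whole-mesh {hausdorff, mean, median} distances (mm).

    Uses the symmetric array of point-to-nearest-point distances without
    any cutoff (shape metrics consider all points).  A structure absent
    from either mesh is skipped with a warning.
    """
    labA = _vertex_labels(meshA)
    labB = _vertex_labels(meshB)
    out: dict[str, dict[str, float]] = {}

    def stats_for(ptsA: np.ndarray, ptsB: np.ndarray) -> dict[str, float]:
        dab = cKDTree(ptsB).query(ptsA)[0]
        dba = cKDTree(ptsA).query(ptsB)[0]
        both = np.concatenate([dab, dba])
        return {
            "hausdorff": float(both.max()),
            "mean": float(both.mean()),
            "median": float(np.median(both)),
        }

    out["all"] = stats_for(meshA.vertices, meshB.vertices)
    for code, name in sorted(LABEL_NAMES.items()):
        selA = labA == code
        selB = labB == code
        if not selA.any() or not selB.any():
            if selA.any() != selB.any():
                import warnings

                warnings.warn(f"structure {name} present in only one mesh; skipped")
            continue
        out[name] = stats_for(meshA.vertices[selA], meshB.vertices[selB])
    return out


# ----------------------------------------------------------------------- ICC
@dataclass
class ICCResult:
    icc: float
    ci95: tuple[float, float]
    p_value: float
    degenerate: bool = False


def icc_absolute_agreement(ratings: np.ndarray) -> ICCResult:
    """Two-way random-effects, absolute-agreement, average-measures ICC.

    ``ratings`` is subjects × raters with no missing cells.  The point
    estimate is (MS_R − MS_E) / (MS_R + (MS_C − MS_E)/n) from the two-way
    ANOVA decomposition; the confidence interval is the standard F-based
    one, and the p-value tests ICC = 0 via F = MS_R / MS_E.
    """
    X = np.asarray(ratings, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    if not np.all(np.isfinite(X)):
        raise ValueError("ratings contain missing values")
    n, k = X.shape
    if np.allclose(X, X.flat[0]):
        return ICCResult(icc=1.0, ci95=(1.0, 1.0), p_value=0.0, degenerate=True)
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (msc - mse) / n)
    # F-based CI (McGraw & Wong): interval for single measures, Spearman-Brown to average
    if mse <= 0:
        return ICCResult(icc=float(icc), ci95=(float("nan"), float("nan")),
                         p_value=0.0, degenerate=True)
    icc_single = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    a = k * icc_single / (n * (1 - icc_single)) if icc_single < 1 else np.inf
    b = 1 + k * icc_single * (n - 1) / (n * (1 - icc_single)) if icc_single < 1 else np.inf
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_upper = stats.f.ppf(0.975, n - 1, v)
    f_lower = stats.f.ppf(0.975, v, n - 1)
    lo_single = n * (msr - f_upper * mse) / (
        f_upper * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    hi_single = n * (f_lower * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_lower * msr
    )

    def spearman_brown(r: float) -> float:
        return k * r / (1 + (k - 1) * r)

    ci = (float(spearman_brown(lo_single)), float(spearman_brown(hi_single)))
    fstat = msr / mse
    p = float(stats.f.sf(fstat, n - 1, (n - 1) * (k - 1)))
    return ICCResult(icc=float(icc), ci95=ci, p_value=p)


# -------------------------------------------------------------- fibre metrics
FIBRE_ANGLE_TOL = np.pi / 8  # 22.5°: |a·b| ≥ cos(π/8) counts as agreement


def fibre_agreement(
    corr: Correspondence,
    fibresA: np.ndarray,
    fibresB: np.ndarray,
    labelsA: np.ndarray | None = None,
    angle_tol: float = FIBRE_ANGLE_TOL,
) -> dict:
    """Fraction of matched element pairs with |a·b| ≥ cos(angle_tol).

    Only element correspondences within the distance cutoff enter; the
    co-linearity rule makes 0° and 180° both perfect alignment.  Returns
    the overall fraction, the |dot| values and per-structure histograms.
    """
    fibresA = np.asarray(fibresA, dtype=float).reshape(-1, 3)
    fibresB = np.asarray(fibresB, dtype=float).reshape(-1, 3)
    sel = corr.elem_within_ab
    if not sel.any():
        raise ValueError("no element correspondences within the cutoff")
    a = fibresA[sel]
    b = fibresB[corr.elem_idx_ab[sel]]
    dots = np.abs(np.einsum("ij,ij->i", a, b))
    dots = np.clip(dots, 0.0, 1.0)
    threshold = np.cos(angle_tol)
    result = {
        "fraction": float(np.mean(dots >= threshold)),
        "threshold": float(threshold),
        "abs_dot": dots,
        "per_structure": {},
    }
    if labelsA is not None:
        labelsA = np.asarray(labelsA)[sel]
        for code in np.unique(labelsA):
            name = LABEL_NAMES.get(int(code), str(int(code)))
            sub = dots[labelsA == code]
            hist, edges = np.histogram(sub, bins=10, range=(0.0, 1.0))
            result["per_structure"][name] = {
                "fraction": float(np.mean(sub >= threshold)),
                "hist": hist.tolist(),
                "bin_edges": edges.tolist(),
            }
    return result


# ------------------------------------------------------------- LAT/CV/PS maps
def lat_to_uac_grid(
    lat_times: np.ndarray, uac: UACField, grid_size: int = 101
) -> np.ndarray:
    """Resample per-vertex LAT onto the regular UAC grid (linear, NaN outside)."""
    g = np.linspace(0.0, 1.0, grid_size)
    gx, gy = np.meshgrid(g, g, indexing="ij")
    finite = np.isfinite(lat_times)
    pts = uac.as_points()[finite]
    vals = np.asarray(lat_times, dtype=float)[finite]
    return griddata(pts, vals, (gx, gy), method="linear")


def lat_compare(
    latA: np.ndarray,
    latB: np.ndarray,
    uacA: UACField,
    uacB: UACField,
    grid_size: int = 101,
) -> dict:
    """Pearson r over common valid UAC cells plus total-activation times."""
    gA = lat_to_uac_grid(latA, uacA, grid_size)
    gB = lat_to_uac_grid(latB, uacB, grid_size)
    valid = np.isfinite(gA) & np.isfinite(gB)
    if valid.sum() < 10:
        raise ValueError(f"only {valid.sum()} common valid UAC cells (< 10)")
    a, b = gA[valid], gB[valid]
    if np.std(a) == 0 or np.std(b) == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(a, b)[0, 1])
    tatA = float(np.nanmax(latA[np.isfinite(latA)]))
    tatB = float(np.nanmax(latB[np.isfinite(latB)]))
    return {
        "pearson_r": r,
        "tat_a_ms": tatA,
        "tat_b_ms": tatB,
        "abs_tat_diff_ms": abs(tatA - tatB),
        "n_cells": int(valid.sum()),
    }


def cv_compare(cvA: np.ndarray, cvB: np.ndarray, n_bins: int = 30) -> dict:
    """Difference of mean conduction velocities plus per-map histograms."""
    a = np.asarray(cvA, dtype=float)
    b = np.asarray(cvB, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("conduction velocity undefined on an entire map")
    top = max(a.max(), b.max())
    ha, edges = np.histogram(a, bins=n_bins, range=(0.0, top))
    hb, _ = np.histogram(b, bins=n_bins, range=(0.0, top))
    return {
        "mean_cv_a": float(a.mean()),
        "mean_cv_b": float(b.mean()),
        "mean_diff": float(a.mean() - b.mean()),
        "hist_a": ha.tolist(),
        "hist_b": hb.tolist(),
        "bin_edges": edges.tolist(),
    }


def ssim_uniform(mapA: np.ndarray, mapB: np.ndarray, win: int = 7) -> float:
    """Mean SSIM with a sliding uniform window.

    Constants c1 = (0.01·L)², c2 = (0.03·L)² with L the maximum cell value
    across both maps; sample (N−1) covariance normalisation; the mean is
    taken over windows fully inside the maps.  Two all-zero maps are
    defined as identical (SSIM 1).
    """
    A = np.asarray(mapA, dtype=float)
    B = np.asarray(mapB, dtype=float)
    if A.shape != B.shape:
        raise ValueError("maps must share grid dimensions")
    L = max(A.max(), B.max())
    if L == 0:
        return 1.0
    c1 = (0.01 * L) ** 2
    c2 = (0.03 * L) ** 2
    n = win * win
    cov_norm = n / (n - 1)
    filt = {"size": win, "mode": "reflect"}
    muA = ndimage.uniform_filter(A, **filt)
    muB = ndimage.uniform_filter(B, **filt)
    muAA = ndimage.uniform_filter(A * A, **filt)
    muBB = ndimage.uniform_filter(B * B, **filt)
    muAB = ndimage.uniform_filter(A * B, **filt)
    varA = cov_norm * (muAA - muA * muA)
    varB = cov_norm * (muBB - muB * muB)
    cov = cov_norm * (muAB - muA * muB)
    ssim_map = ((2 * muA * muB + c1) * (2 * cov + c2)) / (
        (muA**2 + muB**2 + c1) * (varA + varB + c2)
    )
    pad = win // 2
    core = ssim_map[pad:-pad, pad:-pad] if min(A.shape) > 2 * pad else ssim_map
    return float(core.mean())


def ps_compare(mapA, mapB, win: int = 7) -> dict:
    """Pearson correlation and uniform-window SSIM between two PS maps."""
    A = np.asarray(getattr(mapA, "grid", mapA), dtype=float)
    B = np.asarray(getattr(mapB, "grid", mapB), dtype=float)
    if A.shape != B.shape:
        raise ValueError("PS maps must share grid dimensions")
    if np.std(A) == 0 or np.std(B) == 0:
        r = float("nan")  # correlation undefined for a constant map
    else:
        r = float(np.corrcoef(A.ravel(), B.ravel())[0, 1])
    return {"pearson_r": r, "ssim": ssim_uniform(A, B, win=win)}


# -------------------------------------------------------------------- report
@dataclass
class ComparisonReport:
    """All paired-model agreement statistics for one comparison."""

    shape: dict = field(default_factory=dict)
    fibre: dict = field(default_factory=dict)
    fibrosis_scores_a: dict = field(default_factory=dict)  # factor -> score
    fibrosis_scores_b: dict = field(default_factory=dict)
    lat: dict = field(default_factory=dict)
    cv: dict = field(default_factory=dict)
    ps: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {str(k): clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return clean(
            {
                "shape": self.shape,
                "fibre": {k: v for k, v in self.fibre.items() if k != "abs_dot"},
                "fibrosis_scores_a": self.fibrosis_scores_a,
                "fibrosis_scores_b": self.fibrosis_scores_b,
                "lat": self.lat,
                "cv": self.cv,
                "ps": self.ps,
            }
        )
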