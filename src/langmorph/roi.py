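"""Sphere ROIs at published MNI peaks, regional extraction, and group tests.

Replication-style analysis: a 6-mm-radius sphere is built around each peak
coordinate reported by earlier studies, mean regional volume is extracted
per subject, and groups are compared with pooled-variance t-tests.  A set
of canonical language regions can be tested jointly with a MANCOVA
(Hotelling–Lawley trace) with age and scan center as nuisance covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .volumes import CohortMatrix, VolumeGrid
from .summary_stats import GroupSummary, cohens_d_from_summary

__all__ = [
    "SphereROI",
    "make_sphere_roi",
    "extract_roi_means",
    "roi_group_test",
    "mancova_hotelling",
    "NOMINAL_LANGUAGE_ROIS",
]

logger = logging.getLogger(__name__)

#: Nominal MNI centroids for 13 canonical language-network regions.
#: SYNTHETIC stand-in coordinates (typical atlas locations) for a functional
#: parcellation whose original definition is not bundled — for testing the
#: extraction machinery only, not authoritative region definitions.
NOMINAL_LANGUAGE_ROIS: list[tuple[str, float, float, float]] = [
    ("L_angular_gyrus", -46.0, -62.0, 32.0),
    ("L_anterior_temporal", -52.0, 8.0, -22.0),
    ("L_cerebellum", -32.0, -66.0, -30.0),
    ("L_inferior_frontal_gyrus", -50.0, 20.0, 14.0),
    ("L_inferior_frontal_gyrus_orbital", -46.0, 30.0, -10.0),
    ("L_middle_frontal_gyrus", -42.0, 8.0, 44.0),
    ("L_mid_anterior_temporal", -58.0, -14.0, -10.0),
    ("L_mid_posterior_temporal", -58.0, -40.0, 0.0),
    ("L_posterior_temporal", -50.0, -54.0, 14.0),
    ("L_superior_frontal_gyrus", -8.0, 30.0, 54.0),
    ("R_cerebellum", 32.0, -66.0, -30.0),
    ("R_mid_anterior_temporal", 58.0, -14.0, -10.0),
    ("R_mid_posterior_temporal", 58.0, -40.0, 0.0),
]


@dataclass
class SphereROI:
    """A sphere ROI: MNI center (mm), radius (mm), member voxel indices."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    voxel_index: np.ndarray   # (N, 3) int


def make_sphere_roi(center_mm, radius_mm: float, grid: VolumeGrid) -> SphereROI:
    """Voxels whose center lies within ``radius_mm`` (closed ball) of the center.

    The voxel containing the center is always a member, so a zero radius
    returns exactly that voxel.  An out-of-grid center is an error.
    """
    center_mm = np.asarray(center_mm, dtype=float)
    if radius_mm < 0:
        raise ValueError("radius must be >= 0")
    cvox = grid.mm_to_vox(center_mm)[0]
    shape = np.asarray(grid.shape)
    if np.any(cvox < -0.5) or np.any(cvox > shape - 0.5):
        raise ValueError(f"ROI center {tuple(center_mm)} mm lies outside the grid")
    vsize = grid.voxel_size
    lo = np.maximum(np.floor(cvox - radius_mm / vsize).astype(int), 0)
    hi = np.minimum(np.ceil(cvox + radius_mm / vsize).astype(int), shape - 1)
    ranges = [np.arange(lo[k], hi[k] + 1) for k in range(3)]
    cand = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    mm = grid.vox_to_mm(cand)
    d = np.sqrt(((mm - center_mm) ** 2).sum(axis=1))
    members = cand[d <= radius_mm + 1e-9]
    containing = np.clip(np.round(cvox).astype(int), 0, shape - 1)
    if not (members == containing).all(axis=1).any():
        members = np.vstack([members, containing]) if members.size else containing[None, :]
    return SphereROI(tuple(center_mm), float(radius_mm), members.astype(int))


def extract_roi_means(matrix: CohortMatrix, roi: SphereROI) -> np.ndarray:
    """Per-subject mean value over the ROI's in-mask voxels.

    ROI voxels outside the cohort mask are dropped (count logged); an ROI
    fully outside the mask is an error.
    """
    lut = {tuple(v): j for j, v in enumerate(matrix.mask_index)}
    cols = [lut[tuple(v)] for v in roi.voxel_index if tuple(v) in lut]
    dropped = roi.voxel_index.shape[0] - len(cols)
    if not cols:
        raise ValueError("ROI lies entirely outside the cohort mask")
    if dropped:
        logger.info("ROI at %s: %d of %d voxels outside mask dropped",
                    roi.center_mm, dropped, roi.voxel_index.shape[0])
    return matrix.data[:, cols].mean(axis=1)


def roi_group_test(values: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """Pooled-variance two-sample t-test plus Cohen's d for one ROI.

    Group order follows first appearance in ``labels``; t is signed
    (first group minus second), d is reported as a magnitude.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    levels = list(pd.unique(labels))
    if len(levels) != 2:
        raise ValueError("exactly two group labels required")
    a = values[labels == levels[0]]
    b = values[labels == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 subjects per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("zero pooled variance")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    d = cohens_d_from_summary(
        GroupSummary(len(a), a.mean(), a.std(ddof=1)),
        GroupSummary(len(b), b.mean(), b.std(ddof=1)))
    return {"t": float(t), "df": len(a) + len(b) - 2, "p": float(p), "d": d}


def mancova_hotelling(responses: np.ndarray, labels: np.ndarray,
                      covariates: np.ndarray | None = None) -> dict[str, float]:
    """MANCOVA for a two-level group effect: Hotelling–Lawley trace and F.

    Fits the multivariate linear model responses ~ intercept + group +
    covariates and tests the group effect.  For a single-df hypothesis the
    exact F transform is F = trace · (ν − p + 1) / p with df (p, ν − p + 1),
    where p is the number of response variables and ν the error df.
    """
    Y = np.asarray(responses, dtype=float)
    labels = np.asarray(labels)
    n, p = Y.shape
    levels = list(pd.unique(labels))
    if len(levels) != 2:
        raise ValueError("exactly two group labels required")
    g = (labels == levels[0]).astype(float)
    cols = [np.ones(n), g]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        cols.extend(C.T)
    X = np.column_stack(cols)
    k = np.linalg.matrix_rank(X)
    nu = n - k
    if n <= p + X.shape[1] + 1:
        raise ValueError("too few subjects for the number of responses and covariates")
    XtX = X.T @ X
    B = np.linalg.solve(XtX, X.T @ Y)
    E = Y.T @ Y - B.T @ XtX @ B
    c = np.zeros(X.shape[1]); c[1] = 1.0
    cb = c @ B
    denom = float(c @ np.linalg.solve(XtX, c))
    H = np.outer(cb, cb) / denom
    try:
        trace = float(np.trace(np.linalg.solve(E, H)))
    except np.linalg.LinAlgError as err:
        raise ValueError("singular within-group covariance") from err
    df1, df2 = p, nu - p + 1
    if df2 <= 0:
        raise ValueError("error df too small for the F approximation")
    F = trace * df2 / df1
    pval = float(stats.f.sf(F, df1, df2))
    return {"hotelling_trace": trace, "F": F, "df1": df1, "df2": df2, "p": pval}
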