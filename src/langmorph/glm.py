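"""Voxel-wise group-difference GLM with permutation cluster-level inference.

Each masked voxel gets an ordinary least-squares fit of relative tissue
volume on a binary group indicator plus nuisance covariates (age as
continuous, scan center as categorical fixed effects).  Inference:

* voxel level — t = cᵀβ̂ / SE(cᵀβ̂) with one-tailed p maps per direction;
* cluster level — suprathreshold voxels (one-tailed p below the
  cluster-forming height threshold, default 0.025) are grouped by
  18-connectivity; each observed cluster's extent is referred to a
  permutation null of the *maximum* cluster extent (group labels permuted
  within scan-center strata), and Benjamini–Hochberg FDR over the cluster
  p-values yields q, thresholded at q < 0.05 by default.

The permutation-extent + BH route plays the role that random-field
topological FDR plays in standard VBM software; it keeps the same height
and q thresholds while making no stationarity or RFT assumptions.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .volumes import CohortMatrix

__all__ = ["make_design", "VoxelwiseGLM", "VBMResults", "StatMap"]

#: SPM-convention 18-neighbor connectivity (faces + edges).
CONNECTIVITY_18 = ndimage.generate_binary_structure(3, 2)


def make_design(table: pd.DataFrame, group_col: str, group_level: str,
                age_col: str | None = "age",
                center_col: str | None = "center") -> pd.DataFrame:
    """Build a named design matrix: intercept, group indicator, age, center dummies.

    ``group_level`` is coded 1 (so the contrast on the ``group`` column reads
    ``group_level > other``); centers are reference-coded against the first
    level.  Raises when the result is rank deficient, naming the collinear
    columns.
    """
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(table))}
    cols["group"] = (table[group_col].to_numpy() == group_level).astype(float)
    if age_col is not None:
        age = table[age_col].to_numpy(dtype=float)
        cols["age"] = age - age.mean()
    if center_col is not None:
        levels = sorted(pd.unique(table[center_col]))
        for lev in levels[1:]:
            cols[f"center[{lev}]"] = (table[center_col].to_numpy() == lev).astype(float)
    X = pd.DataFrame(cols, index=table.index)
    _check_rank(X)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank == arr.shape[1]:
        return
    guilty = [c for c in X.columns
              if np.linalg.matrix_rank(arr[:, [i for i, cc in enumerate(X.columns) if cc != c]]) == rank]
    raise ValueError(f"design matrix is rank deficient; collinear columns: {guilty}")


@dataclass
class StatMap:
    """Voxel-wise t/p maps on a mask register, with metadata."""

    t: np.ndarray
    p: np.ndarray                       # one-tailed, in the stated direction
    df: int
    direction: str                      # "A>B" or "B>A" style label
    mask_index: np.ndarray
    grid_shape: tuple[int, int, int]
    affine: np.ndarray
    fwhm_estimate: np.ndarray | None = None


class VoxelwiseGLM:
    """Mass-univariate OLS over a :class:`~langmorph.volumes.CohortMatrix`.

    Parameters
    ----------
    matrix : CohortMatrix
        Subjects × masked voxels (relative volumes).
    design : DataFrame
        Named regressors, rows aligned with ``matrix.subjects``; must contain
        a ``group`` column for label permutation.
    """

    def __init__(self, matrix: CohortMatrix, design: pd.DataFrame):
        if len(design) != matrix.n_subjects:
            raise ValueError("design rows must match matrix subjects")
        _check_rank(design)
        self.matrix = matrix
        self.design = design

    @classmethod
    def from_dataframe(cls, matrix: CohortMatrix, table: pd.DataFrame,
                       group_col: str, group_level: str,
                       age_col: str | None = "age",
                       center_col: str | None = "center") -> "VoxelwiseGLM":
        """Build design from a subject table aligned on ``matrix.subjects``."""
        table = table.set_index("id").loc[matrix.subjects].reset_index()
        model = cls(matrix, make_design(table, group_col, group_level, age_col, center_col))
        model._strata = (table[center_col].to_numpy() if center_col is not None
                         else np.zeros(len(table), dtype=int))
        return model

    _strata: np.ndarray | None = None

    def fit(self, contrast: np.ndarray | str = "group") -> "VBMResults":
        """OLS at every voxel; returns t and one-tailed p maps for the contrast."""
        X = self.design.to_numpy(dtype=float)
        c = self._contrast_vector(contrast)
        t, df = _contrast_t(X, self.matrix.data, c)
        return VBMResults(self, c, t, df)

    def _contrast_vector(self, contrast: np.ndarray | str) -> np.ndarray:
        if isinstance(contrast, str):
            c = np.zeros(self.design.shape[1])
            c[list(self.design.columns).index(contrast)] = 1.0
            return c
        c = np.asarray(contrast, dtype=float)
        if c.shape[0] != self.design.shape[1]:
            raise ValueError("contrast length must equal the number of design columns")
        return c


def _contrast_t(X: np.ndarray, Y: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, int]:
    n, k = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    df = n - np.linalg.matrix_rank(X)
    sigma2 = (resid ** 2).sum(axis=0) / df
    var_c = float(c @ xtx_inv @ c)
    se = np.sqrt(sigma2 * var_c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (c @ beta) / se, 0.0)
    return t, df


class VBMResults:
    """t/p maps plus cluster formation and permutation cluster-level FDR."""

    def __init__(self, model: VoxelwiseGLM, contrast: np.ndarray,
                 t: np.ndarray, df: int):
        self.model = model
        self.contrast = contrast
        self.t = t
        self.df = df

    def p(self, direction: str = "greater") -> np.ndarray:
        """One-tailed p map: ``greater`` tests contrast > 0, ``less`` the reverse."""
        if direction == "greater":
            return stats.t.sf(self.t, self.df)
        if direction == "less":
            return stats.t.cdf(self.t, self.df)
        raise ValueError("direction must be 'greater' or 'less'")

    def stat_map(self, direction: str = "greater") -> StatMap:
        m = self.model.matrix
        label = "A>B" if direction == "greater" else "B>A"
        return StatMap(self.t.copy(), self.p(direction), self.df, label,
                       m.mask_index, m.grid_shape, m.affine)

    # ---------------------------------------------------------------- clusters

    def form_clusters(self, height_p: float = 0.025,
                      direction: str = "greater") -> pd.DataFrame:
        """Group suprathreshold voxels (one-tailed p < ``height_p``) by 18-connectivity.

        Returns one row per cluster: extent ``k_e`` (voxels), peak t, peak
        voxel index and MNI mm coordinate.  Empty table when nothing survives.
        """
        if not (0 < height_p <= 0.5):
            raise ValueError("height_p must lie in (0, 0.5]")
        supra = self.p(direction) < height_p
        labels, extents, peaks = _label_clusters(
            supra, self.t if direction == "greater" else -self.t,
            self.model.matrix)
        rows = []
        aff = self.model.matrix.affine
        for cid, (k_e, peak_idx) in enumerate(zip(extents, peaks), start=1):
            mm = (aff @ np.append(peak_idx, 1.0))[:3]
            rows.append({"cluster": cid, "extent": int(k_e),
                         "peak_x_mm": mm[0], "peak_y_mm": mm[1], "peak_z_mm": mm[2],
                         "peak_t": float(self.t[_flat_voxel_pos(self.model.matrix, peak_idx)])})
        df = pd.DataFrame(rows, columns=["cluster", "extent", "peak_x_mm", "peak_y_mm",
                                         "peak_z_mm", "peak_t"])
        df.attrs["direction"] = direction
        df.attrs["height_p"] = height_p
        return df

    def cluster_fdr(self, height_p: float = 0.025, direction: str = "greater",
                    n_perm: int = 1000, q_level: float = 0.05,
                    seed: int | None = None) -> pd.DataFrame:
        """Permutation cluster-extent p-values with Benjamini–Hochberg q.

        Group labels are permuted within scan-center strata (exchangeability
        respects the fixed-effect nuisance); each permutation is refit and
        the maximum cluster extent recorded.  A cluster's p is the fraction
        of permutations whose maximum extent is at least its observed
        extent; BH over cluster p-values gives q, flagged at ``q_level``.
        """
        if n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        clusters = self.form_clusters(height_p, direction)
        if clusters.empty:
            clusters["p"] = pd.Series(dtype=float)
            clusters["q"] = pd.Series(dtype=float)
            clusters["significant"] = pd.Series(dtype=bool)
            return clusters
        null_max = self._null_max_extents(height_p, direction, n_perm, seed)
        extents = clusters["extent"].to_numpy()
        p = (null_max[None, :] >= extents[:, None]).mean(axis=1)
        _, q, _, _ = multipletests(p, method="fdr_bh")
        clusters = clusters.assign(p=p, q=q, significant=q < q_level)
        return clusters

    def _null_max_extents(self, height_p: float, direction: str,
                          n_perm: int, seed: int | None) -> np.ndarray:
        model = self.model
        X0 = model.design.to_numpy(dtype=float).copy()
        gcol = list(model.design.columns).index("group")
        group = X0[:, gcol].copy()
        strata = model._strata if model._strata is not None else np.zeros(len(X0), dtype=int)
        perms = _strata_permutations(group, strata, n_perm, seed)
        out = np.empty(len(perms))
        matrix = model.matrix
        Y = matrix.data
        for i, g in enumerate(perms):
            X = X0.copy()
            X[:, gcol] = g
            t, df = _contrast_t(X, Y, self.contrast)
            if direction == "greater":
                supra = t > stats.t.isf(height_p, df)
            else:
                supra = t < stats.t.ppf(height_p, df)
            out[i] = _max_extent(supra, matrix)
        return out

    def summary(self) -> str:
        m = self.model.matrix
        lines = [
            "Voxel-wise GLM group contrast",
            f"  subjects: {m.n_subjects}   masked voxels: {m.n_voxels}   tissue: {m.tissue}",
            f"  design columns: {list(self.model.design.columns)}",
            f"  error df: {self.df}",
            f"  max |t|: {np.abs(self.t).max():.3f}",
        ]
        return "\n".join(lines)


# ------------------------------------------------------------------ helpers

def _voxel_pos_lut(matrix: CohortMatrix) -> dict[tuple[int, int, int], int]:
    return {tuple(v): j for j, v in enumerate(matrix.mask_index)}


def _flat_voxel_pos(matrix: CohortMatrix, ijk: np.ndarray) -> int:
    return _voxel_pos_lut(matrix)[tuple(int(x) for x in ijk)]


def _label_clusters(supra: np.ndarray, score: np.ndarray, matrix: CohortMatrix):
    """Label suprathreshold mask voxels; return (labels3d, extents, peak voxel per cluster)."""
    vol = matrix.scatter(supra.astype(float)) > 0.5
    labels3d, n = ndimage.label(vol, structure=CONNECTIVITY_18)
    extents, peaks = [], []
    score3d = matrix.scatter(score, fill=-np.inf)
    for cid in range(1, n + 1):
        where = np.argwhere(labels3d == cid)
        extents.append(len(where))
        vals = score3d[tuple(where.T)]
        peaks.append(where[int(np.argmax(vals))])
    order = np.argsort(extents)[::-1]
    return labels3d, [extents[i] for i in order], [peaks[i] for i in order]


def _max_extent(supra: np.ndarray, matrix: CohortMatrix) -> int:
    if not supra.any():
        return 0
    vol = matrix.scatter(supra.astype(float)) > 0.5
    labels3d, n = ndimage.label(vol, structure=CONNECTIVITY_18)
    if n == 0:
        return 0
    return int(np.bincount(labels3d.ravel())[1:].max())


def _strata_permutations(group: np.ndarray, strata: np.ndarray, n_perm: int,
                         seed: int | None) -> list[np.ndarray]:
    """Group-label permutations within strata; exhaustive when few are distinct."""
    rng = np.random.default_rng(seed)
    levels = pd.unique(strata)
    n_distinct = 1.0
    for lev in levels:
        idx = strata == lev
        n1 = int(group[idx].sum())
        n_distinct *= math.comb(int(idx.sum()), n1)
        if n_distinct > 10 * n_perm:
            break
    if n_distinct <= n_perm:
        warnings.warn(f"only {int(n_distinct)} distinct within-strata permutations; "
                      "using the exhaustive set")
        per_stratum = []
        for lev in levels:
            idx = np.where(strata == lev)[0]
            vals = group[idx]
            uniq = sorted({tuple(p) for p in itertools.permutations(vals)})
            per_stratum.append((idx, uniq))
        perms = []
        for combo in itertools.product(*(u for _, u in per_stratum)):
            g = group.copy()
            for (idx, _), vals in zip(per_stratum, combo):
                g[idx] = vals
            perms.append(g)
        return perms
    perms = []
    for _ in range(n_perm):
        g = group.copy()
        for lev in levels:
            idx = np.where(strata == lev)[0]
            g[idx] = g[rng.permutation(idx)]
        perms.append(g)
    return perms
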