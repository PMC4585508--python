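"""Behavioral Partial Least Squares on brain–behavior correlation matrices.

The decomposition: for each block (group × tissue condition) the Pearson
correlation of every behavioral measure with every masked voxel is
computed across subjects; blocks are stacked row-wise into a correlation
matrix R (blocks·measures × voxels) and R = U S Vᵀ extracts latent
variable (LV) pairs.  Columns of V are the brain saliences (one weight per
voxel, unit norm), rows of U the behavior saliences, and S²/ΣS² the
fraction of summed squared covariance each LV explains.

Inference:

* permutation test — behavior rows are shuffled across subjects (within
  group for the multi-group variant), the stack rebuilt and re-decomposed;
  each LV's p is the fraction of permuted singular values at the same rank
  position at least as large as the observed one;
* bootstrap — subjects are resampled with replacement (within group), the
  resampled saliences are sign-aligned (optionally Procrustes-rotated) to
  the original, and the voxel-wise bootstrap ratio BR = salience / SE(salience)
  acts as a reliability score (|BR| > 2.5 ≈ p < 0.012 is the conventional
  display threshold, with a minimum cluster size for visualization only).
"""

from __future__ import annotations

import logging
import math
from itertools import permutations as _iter_permutations, product as _iter_product

import numpy as np
import pandas as pd
from scipy import ndimage

from .glm import CONNECTIVITY_18
from .volumes import CohortMatrix

__all__ = ["BehavioralPLS", "PLSResults", "build_correlation_stack", "visualize_threshold"]

logger = logging.getLogger(__name__)


def _zscore_cols(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Column z-scores (population SD); zero-variance columns map to 0."""
    mu = X.mean(axis=0, keepdims=True)
    sd = X.std(axis=0, keepdims=True)
    bad = sd[0] == 0
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd
    Z[:, bad] = 0.0
    return Z, int(bad.sum())


def build_correlation_stack(brain: dict[str, np.ndarray], behavior: np.ndarray,
                            group_rows: list[np.ndarray]) -> np.ndarray:
    """Stacked brain–behavior correlation matrix.

    ``brain`` maps condition name -> (subjects × voxels); ``behavior`` is
    subjects × measures; ``group_rows`` lists the subject-row indices of
    each group block.  Rows are ordered group-major, then condition, then
    measure.
    """
    blocks = []
    zero_voxels = 0
    for rows in group_rows:
        B = behavior[rows]
        Zb, _ = _zscore_cols(B)
        n = len(rows)
        for cond, X in brain.items():
            Zx, nz = _zscore_cols(X[rows])
            zero_voxels += nz
            blocks.append(Zb.T @ Zx / n)
    if zero_voxels:
        logger.info("correlation stack: %d zero-variance voxel columns set to r=0",
                    zero_voxels)
    return np.vstack(blocks)


class BehavioralPLS:
    """Behavioral PLS model over one or more tissue conditions.

    Parameters
    ----------
    brain : dict[str, CohortMatrix]
        Condition name (e.g. ``"GM"``, ``"WM"``) -> cohort matrix; all
        conditions must share the subject order.
    behavior : DataFrame
        Subjects × measures, aligned with the brain matrices.  Missing
        values are rejected — subjects with incomplete scores must be
        excluded upstream.
    groups : array-like, optional
        Per-subject group labels for the multi-group variant.
    """

    def __init__(self, brain: dict[str, CohortMatrix], behavior: pd.DataFrame,
                 groups: np.ndarray | None = None):
        conds = list(brain)
        first = brain[conds[0]]
        for c in conds[1:]:
            if brain[c].subjects != first.subjects:
                raise ValueError("all conditions must share the subject order")
            if not np.array_equal(brain[c].mask_index, first.mask_index):
                raise ValueError("all conditions must share the voxel register (mask)")
        if len(behavior) != first.n_subjects:
            raise ValueError("behavior rows must align with brain subjects")
        if behavior.isna().any().any():
            raise ValueError("behavior matrix contains missing values")
        if (behavior.std(ddof=0) == 0).any():
            raise ValueError("behavioral measure with zero variance")
        self.brain = brain
        self.behavior = behavior
        self.conditions = conds
        self.measures = list(behavior.columns)
        if groups is None:
            self.group_labels = ["all"]
            self._group_rows = [np.arange(first.n_subjects)]
        else:
            groups = np.asarray(groups)
            self.group_labels = list(pd.unique(groups))
            self._group_rows = [np.flatnonzero(groups == g) for g in self.group_labels]
        for g, rows in zip(self.group_labels, self._group_rows):
            if len(rows) < 3:
                raise ValueError(f"group block '{g}' has fewer than 3 subjects")
        self._groups = groups

    # row labels of the stacked correlation matrix
    @property
    def block_rows(self) -> list[tuple[str, str, str]]:
        return [(g, c, m) for g in self.group_labels for c in self.conditions
                for m in self.measures]

    def _brain_arrays(self) -> dict[str, np.ndarray]:
        return {c: self.brain[c].data for c in self.conditions}

    def _stack(self, behavior: np.ndarray) -> np.ndarray:
        return build_correlation_stack(self._brain_arrays(), behavior, self._group_rows)

    def fit(self) -> "PLSResults":
        """Decompose the observed correlation stack."""
        R = self._stack(self.behavior.to_numpy(dtype=float))
        if not np.isfinite(R).all():
            raise ValueError("correlation stack contains non-finite values")
        if not R.any():
            raise ValueError("all-zero correlation stack")
        U, s, Vt = np.linalg.svd(R, full_matrices=False)
        return PLSResults(self, U, s, Vt.T)


class PLSResults:
    """Fitted LVs: singular values, saliences, scores, and resampling inference."""

    def __init__(self, model: BehavioralPLS, U: np.ndarray, s: np.ndarray, V: np.ndarray):
        self.model = model
        self.behavior_saliences = U          # (blocks·measures) × LV
        self.singular_values = s
        self.brain_saliences = V             # voxels × LV
        self.perm_p: np.ndarray | None = None
        self.bootstrap_ratio: np.ndarray | None = None
        self.behavior_corr_ci: pd.DataFrame | None = None

    @property
    def n_lv(self) -> int:
        return self.singular_values.size

    @property
    def covariance_explained(self) -> np.ndarray:
        s2 = self.singular_values ** 2
        return s2 / s2.sum()

    # ------------------------------------------------------------- scores

    def brain_scores(self, condition: str) -> np.ndarray:
        """Per-subject LV scores: dot of block-standardized voxel data with saliences."""
        m = self.model
        X = m.brain[condition].data
        Z = np.empty_like(X)
        for rows in m._group_rows:
            Z[rows], _ = _zscore_cols(X[rows])
        return Z @ self.brain_saliences

    def behavior_score_correlations(self, lv: int = 0) -> pd.DataFrame:
        """Pearson r between LV brain scores and each measure, per block."""
        m = self.model
        rows_out = []
        B = m.behavior.to_numpy(dtype=float)
        for g, rows in zip(m.group_labels, m._group_rows):
            for cond in m.conditions:
                sc = self.brain_scores(cond)[rows, lv]
                for j, meas in enumerate(m.measures):
                    rows_out.append({"group": g, "condition": cond, "measure": meas,
                                     "r": _pearson(sc, B[rows, j])})
        return pd.DataFrame(rows_out)

    # -------------------------------------------------------- permutation

    def permutation_test(self, n_perm: int = 10000, seed: int | None = None) -> np.ndarray:
        """Permutation p per LV, comparing singular values by rank position."""
        if n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        m = self.model
        B = m.behavior.to_numpy(dtype=float)
        perms = _behavior_permutations(m._group_rows, B.shape[0], n_perm, seed)
        count = np.zeros(self.n_lv)
        for order in perms:
            s = np.linalg.svd(m._stack(B[order]), compute_uv=False)
            count += s[:self.n_lv] >= self.singular_values
        self.perm_p = count / len(perms)
        return self.perm_p

    # ---------------------------------------------------------- bootstrap

    def bootstrap(self, n_boot: int = 10000, seed: int | None = None,
                  align: str = "sign") -> np.ndarray:
        """Bootstrap ratios (salience / bootstrap SE) and behavior-correlation CIs.

        Subjects are resampled with replacement within group; a block whose
        resample contains a single unique subject is redrawn.  Resampled
        saliences are aligned to the original by per-LV sign correction
        (``align="procrustes"`` applies an orthogonal rotation instead)
        before the voxel-wise SE is computed.
        """
        if n_boot < 100:
            raise ValueError("n_boot must be >= 100")
        if align not in ("sign", "procrustes"):
            raise ValueError("align must be 'sign' or 'procrustes'")
        m = self.model
        rng = np.random.default_rng(seed)
        B = m.behavior.to_numpy(dtype=float)
        L = self.n_lv
        sal_sum = np.zeros_like(self.brain_saliences)
        sal_sq = np.zeros_like(self.brain_saliences)
        corr_samples = []
        for _ in range(n_boot):
            rows = _resample_within_groups(rng, m._group_rows)
            brain_rs = {c: m.brain[c].data[rows] for c in m.conditions}
            Rb = build_correlation_stack(brain_rs, B[rows],
                                         _resampled_group_rows(m._group_rows))
            Ub, sb, Vbt = np.linalg.svd(Rb, full_matrices=False)
            Vb = Vbt.T[:, :L]
            Ub = Ub[:, :L]
            if align == "sign":
                signs = np.sign(np.einsum("vl,vl->l", Vb, self.brain_saliences))
                signs[signs == 0] = 1.0
                Vb = Vb * signs
                Ub = Ub * signs
            else:
                M = Vb.T @ self.brain_saliences
                uu, _, ww = np.linalg.svd(M)
                Q = uu @ ww
                Vb = Vb @ Q
                Ub = Ub @ Q
            sal_sum += Vb
            sal_sq += Vb ** 2
            corr_samples.append(self._boot_behavior_corr(rows, Vb, B))
        se = np.sqrt(np.maximum(sal_sq / n_boot - (sal_sum / n_boot) ** 2, 0.0))
        sal = self.brain_saliences
        br = np.zeros_like(sal)
        nz = se > 0
        br[nz] = sal[nz] / se[nz]
        br[~nz & (sal != 0)] = np.sign(sal[~nz & (sal != 0)]) * np.inf
        self.bootstrap_ratio = br
        self.behavior_corr_ci = self._corr_ci_table(np.array(corr_samples))
        return br

    def _boot_behavior_corr(self, rows: np.ndarray, Vb: np.ndarray,
                            B: np.ndarray, lv: int = 0) -> np.ndarray:
        """LV-1 brain-score/behavior correlations on one bootstrap resample."""
        m = self.model
        out = []
        start = 0
        for g_rows in m._group_rows:
            sub = rows[start:start + len(g_rows)]
            start += len(g_rows)
            for cond in m.conditions:
                Z, _ = _zscore_cols(m.brain[cond].data[sub])
                sc = Z @ Vb[:, lv]
                for j in range(B.shape[1]):
                    out.append(_pearson(sc, B[sub, j]))
        return np.asarray(out)

    def _corr_ci_table(self, samples: np.ndarray) -> pd.DataFrame:
        m = self.model
        obs = self.behavior_score_correlations(lv=0)
        lo, hi = np.percentile(samples, [2.5, 97.5], axis=0)
        obs["ci_low"] = lo
        obs["ci_high"] = hi
        return obs

    # ------------------------------------------------------------ display

    def salience_map(self, lv: int = 0) -> np.ndarray:
        first = self.model.brain[self.model.conditions[0]]
        return first.scatter(self.brain_saliences[:, lv])

    def bootstrap_ratio_map(self, lv: int = 0) -> np.ndarray:
        if self.bootstrap_ratio is None:
            raise ValueError("run .bootstrap() first")
        first = self.model.brain[self.model.conditions[0]]
        return first.scatter(self.bootstrap_ratio[:, lv])

    def summary(self) -> str:
        lines = ["Behavioral PLS",
                 f"  blocks: {len(self.model.group_labels)} group(s) × "
                 f"{len(self.model.conditions)} condition(s) × "
                 f"{len(self.model.measures)} measure(s)",
                 "  LV  singular value  % covariance" +
                 ("  perm p" if self.perm_p is not None else "")]
        for i in range(self.n_lv):
            row = (f"  {i + 1:>2}  {self.singular_values[i]:>14.4f}  "
                   f"{100 * self.covariance_explained[i]:>12.2f}")
            if self.perm_p is not None:
                row += f"  {self.perm_p[i]:.4f}"
            lines.append(row)
        return "\n".join(lines)

    def lv_table(self) -> pd.DataFrame:
        d = {"lv": np.arange(1, self.n_lv + 1),
             "singular_value": self.singular_values,
             "covariance_explained_pct": 100 * self.covariance_explained}
        if self.perm_p is not None:
            d["perm_p"] = self.perm_p
        return pd.DataFrame(d)


def visualize_threshold(br_map: np.ndarray, br_cut: float = 2.5,
                        min_cluster: int = 400) -> np.ndarray:
    """Display-only thresholding of a 3D bootstrap-ratio map.

    Keeps voxels with |BR| > ``br_cut`` belonging to an 18-connected
    cluster of at least ``min_cluster`` voxels (positive and negative
    saliences clustered separately); everything else is zeroed.  This is a
    visualization convention and plays no role in LV inference.
    """
    out = np.zeros_like(br_map)
    for sgn in (1.0, -1.0):
        supra = (sgn * br_map) > br_cut
        labels, n = ndimage.label(supra, structure=CONNECTIVITY_18)
        if n == 0:
            continue
        sizes = np.bincount(labels.ravel())
        good = np.flatnonzero(sizes >= min_cluster)
        good = good[good != 0]  # 0 is background
        keep = np.isin(labels, good)
        out[keep & supra] = br_map[keep & supra]
    return out


# ------------------------------------------------------------------ helpers

def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def _behavior_permutations(group_rows: list[np.ndarray], n_subjects: int,
                           n_perm: int, seed: int | None) -> list[np.ndarray]:
    """Row orders permuting behavior within each group block."""
    rng = np.random.default_rng(seed)
    n_distinct = 1.0
    for rows in group_rows:
        n_distinct *= math.factorial(len(rows))
        if n_distinct > 10 * n_perm:
            break
    if n_distinct <= n_perm:
        per = [list(_iter_permutations(rows)) for rows in group_rows]
        orders = []
        idx = np.concatenate(group_rows)
        for combo in _iter_product(*per):
            order = np.empty(n_subjects, dtype=int)
            order[idx] = np.concatenate([np.asarray(c) for c in combo])
            orders.append(order)
        return orders
    orders = []
    for _ in range(n_perm):
        order = np.arange(n_subjects)
        for rows in group_rows:
            order[rows] = rng.permutation(order[rows])
        orders.append(order)
    return orders


def _resample_within_groups(rng: np.random.Generator,
                            group_rows: list[np.ndarray],
                            max_retries: int = 100) -> np.ndarray:
    """Concatenated bootstrap rows, group blocks in order; degenerate blocks redrawn."""
    out = []
    for rows in group_rows:
        for _ in range(max_retries):
            draw = rng.choice(rows, size=len(rows), replace=True)
            if np.unique(draw).size > 1:
                break
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap resample")
        out.append(np.sort(draw))
    return np.concatenate(out)


def _resampled_group_rows(group_rows: list[np.ndarray]) -> list[np.ndarray]:
    """Block row indices after concatenating resampled blocks in order."""
    out, start = [], 0
    for rows in group_rows:
        out.append(np.arange(start, start + len(rows)))
        start += len(rows)
    return out
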