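"""Tissue-volume containers and preparation steps.

Raw inputs are modulated gray/white-matter probability-density maps in a
common template space (NIfTI-1).  Before any group statistics they are

1. masked to voxels where the study template exceeds a tissue-probability
   threshold (strictly greater than, default 0.25),
2. rescaled voxel-wise by the subject's total tissue volume so values
   express *relative* regional volume, and
3. optionally standardized by age (linear residualization per voxel with
   the voxel mean restored) before entering PLS.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "CohortMatrix",
    "build_mask",
    "total_tissue_volume",
    "scale_to_relative",
    "standardize_by_age",
    "assemble_cohort_matrix",
    "relative_cohort_matrix",
]


@dataclass
class VolumeGrid:
    """A 3D scalar lattice with an affine mapping voxel indices to MNI mm.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values (e.g. modulated tissue density).
    affine : ndarray, shape (4, 4)
        Voxel-index -> MNI-mm map, NIfTI convention.
    """

    values: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.values.ndim}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.isfinite(self.values).all():
            raise ValueError("volume contains non-finite values")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (per axis)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def vox_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map (…, 3) voxel indices to MNI mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def mm_to_vox(self, xyz: np.ndarray) -> np.ndarray:
        """Map (…, 3) MNI mm coordinates to (fractional) voxel indices."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    @classmethod
    def from_nifti(cls, path: str | Path) -> "VolumeGrid":
        img = nib.load(str(path))
        return cls(np.asarray(img.get_fdata(), dtype=float), np.asarray(img.affine))

    def to_nifti(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), self.affine), str(path))


def build_mask(template: VolumeGrid, threshold: float = 0.25) -> np.ndarray:
    """Voxels where the template tissue probability is strictly > ``threshold``.

    Returns an ordered ``(V, 3)`` integer index array (C order).  An empty
    mask raises: downstream statistics are meaningless without voxels.
    """
    vals = template.values
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError("template values must lie in [0, 1]")
    idx = np.argwhere(vals > threshold)
    if idx.shape[0] == 0:
        raise ValueError(f"mask is empty at threshold {threshold} (strict inequality)")
    return idx


def total_tissue_volume(grid: VolumeGrid) -> float:
    """Total tissue volume in cm³: sum of partial-volume estimates × voxel volume."""
    if grid.values.min() < 0:
        raise ValueError("negative voxel values: not a tissue density map")
    return float(grid.values.sum() * grid.voxel_volume_mm3 / 1000.0)


def scale_to_relative(grid: VolumeGrid, total_cm3: float) -> VolumeGrid:
    """Divide every voxel by the subject's total tissue volume (cm³).

    The product integrates to 1 (in cm³ units) when ``total_cm3`` was
    computed from the same map, so relative maps are comparable across
    subjects with different head sizes.
    """
    if total_cm3 <= 0:
        raise ValueError(f"total volume must be positive, got {total_cm3}")
    return VolumeGrid(grid.values / total_cm3, grid.affine.copy())


@dataclass
class CohortMatrix:
    """Subjects × masked-voxels data for one tissue class.

    ``data[s, j]`` is subject ``s``'s value at the voxel ``mask_index[j]``.
    """

    data: np.ndarray
    mask_index: np.ndarray
    tissue: str
    subjects: list[str]
    grid_shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask_index = np.asarray(self.mask_index, dtype=int)
        if self.data.ndim != 2:
            raise ValueError("data must be subjects × voxels")
        if self.data.shape[1] != self.mask_index.shape[0]:
            raise ValueError("columns must correspond 1:1 to mask_index")
        if self.data.shape[0] != len(self.subjects):
            raise ValueError("rows must correspond 1:1 to subjects")
        if np.isnan(self.data).any():
            raise ValueError("NaN in assembled cohort matrix")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def scatter(self, vector: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Place a per-voxel vector back into the 3D grid (``fill`` elsewhere)."""
        vector = np.asarray(vector)
        if vector.shape[0] != self.n_voxels:
            raise ValueError("vector length must equal the number of masked voxels")
        out = np.full(self.grid_shape, fill, dtype=float)
        out[tuple(self.mask_index.T)] = vector
        return out

    def subset(self, rows: np.ndarray) -> "CohortMatrix":
        rows = np.asarray(rows)
        subj = [self.subjects[i] for i in rows]
        return CohortMatrix(self.data[rows], self.mask_index, self.tissue, subj,
                            self.grid_shape, self.affine)

    def save(self, prefix: str | Path) -> None:
        """Cache as ``<prefix>.npy`` plus a JSON sidecar naming subjects and mask."""
        prefix = Path(prefix)
        np.save(str(prefix) + ".npy", self.data)
        sidecar = {
            "tissue": self.tissue,
            "subjects": list(self.subjects),
            "grid_shape": list(self.grid_shape),
            "affine": self.affine.tolist(),
            "mask_index": self.mask_index.tolist(),
        }
        Path(str(prefix) + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, prefix: str | Path) -> "CohortMatrix":
        prefix = Path(prefix)
        data = np.load(str(prefix) + ".npy")
        meta = json.loads(Path(str(prefix) + ".json").read_text())
        return cls(data, np.asarray(meta["mask_index"]), meta["tissue"],
                   list(meta["subjects"]), tuple(meta["grid_shape"]),
                   np.asarray(meta["affine"]))


def assemble_cohort_matrix(grids: dict[str, VolumeGrid], mask_index: np.ndarray,
                           tissue: str) -> CohortMatrix:
    """Gather each subject's masked voxels into a subjects × voxels matrix."""
    subjects = list(grids)
    first = grids[subjects[0]]
    rows = np.empty((len(subjects), mask_index.shape[0]))
    sel = tuple(np.asarray(mask_index, dtype=int).T)
    for i, sid in enumerate(subjects):
        g = grids[sid]
        if g.shape != first.shape:
            raise ValueError(f"grid shape mismatch for subject {sid}")
        rows[i] = g.values[sel]
    return CohortMatrix(rows, mask_index, tissue, subjects, first.shape, first.affine)


def relative_cohort_matrix(grids: dict[str, VolumeGrid], tissue: str,
                           threshold: float = 0.25,
                           mask_index: np.ndarray | None = None) -> CohortMatrix:
    """Mask + relative-volume pipeline in one step.

    Builds the study template as the voxel-wise mean of the raw maps
    (clipped to [0, 1]), thresholds it into a mask unless one is given,
    rescales each subject by their own total tissue volume, and assembles
    the cohort matrix.
    """
    first = next(iter(grids.values()))
    if mask_index is None:
        template = VolumeGrid(np.clip(np.mean([g.values for g in grids.values()], axis=0),
                                      0.0, 1.0), first.affine)
        mask_index = build_mask(template, threshold)
    rel = {sid: scale_to_relative(g, total_tissue_volume(g)) for sid, g in grids.items()}
    return assemble_cohort_matrix(rel, mask_index, tissue)


def standardize_by_age(matrix: CohortMatrix, ages: np.ndarray) -> CohortMatrix:
    """Remove the linear age trend per voxel, restoring each voxel's mean.

    For each voxel, residuals of an ordinary least-squares fit of value on
    age are computed and the voxel's cross-subject mean is added back.  The
    residual scale is kept (no division by residual SD).  Idempotent.
    """
    ages = np.asarray(ages, dtype=float)
    if matrix.n_subjects < 3:
        raise ValueError("need at least 3 subjects to residualize on age")
    if ages.shape[0] != matrix.n_subjects:
        raise ValueError("ages must align with matrix subjects")
    if np.var(ages) == 0:
        raise ValueError("constant age vector: cannot standardize by age")
    X = np.column_stack([np.ones_like(ages), ages])
    beta, *_ = np.linalg.lstsq(X, matrix.data, rcond=None)
    resid = matrix.data - X @ beta
    out = resid + matrix.data.mean(axis=0, keepdims=True)
    return CohortMatrix(out, matrix.mask_index, matrix.tissue, list(matrix.subjects),
                        matrix.grid_shape, matrix.affine)
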