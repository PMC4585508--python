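"""Synthetic cohorts with the statistical structure the analyses assume.

Generates, per subject, smooth modulated-style GM and WM template-space maps
plus a behavioral table, emulating a study of adult autistic males with or
without a history of language delay alongside a neurotypical comparison
group.  Structure that can be embedded:

* a global total-GM offset for the language-delay subgroup (multiplicative),
* localized group-difference "blobs" (Gaussian-profile volume effects),
* a per-subject latent language factor that both drives the behavioral
  scores (VIQ, F-A-S word generativity, non-word repetition, ADI-R/ADOS
  subscores) and is expressed spatially in the brain maps,
* additive scan-center offsets and a linear age trend,
* spatially smooth residual noise (white noise convolved with a Gaussian
  kernel of configurable FWHM; FWHM = 2.3548 σ), mirroring 4-mm FWHM
  smoothing of real modulated maps.

A fixed seed fixes every output byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .volumes import VolumeGrid, total_tissue_volume

__all__ = [
    "EffectBlob",
    "CohortSpec",
    "SubjectRecord",
    "classify_delay",
    "generate_cohort",
    "write_cohort",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))  # σ = FWHM / 2.3548

#: Behavioral measures: name -> (population mean, population SD).
#: Scales follow published adult high-functioning cohorts (VIQ ≈ 108 ± 14,
#: F-A-S total words ≈ 38 ± 11, NWR correct ≈ 21 ± 4, ADI-R social ≈ 19 ± 5).
DEFAULT_MEASURE_SCALES: dict[str, tuple[float, float]] = {
    "VIQ": (108.0, 14.0),
    "FAS": (37.8, 11.2),
    "NWR": (21.5, 4.2),
    "ADIR-S": (18.8, 5.2),
}

#: Default standardized loadings of each measure on the latent language factor.
DEFAULT_LATENT_LOADINGS: dict[str, float] = {"VIQ": 0.6, "FAS": 0.6, "NWR": 0.6, "ADIR-S": 0.0}


@dataclass
class EffectBlob:
    """A localized Gaussian-profile volume effect.

    ``amplitude`` (signed) is the peak additive change in map units at the
    blob center; the profile is exp(-d² / (2 radius²)) with d in mm.
    """

    center_mm: tuple[float, float, float]
    radius_mm: float
    amplitude: float
    groups: tuple[str, ...] = ()
    tissue: str = "GM"


@dataclass
class CohortSpec:
    """Generating conditions for a synthetic cohort.

    Group labels follow the study design: ``ASC_delay`` (first words after
    24 months or first phrases after 33 months), ``ASC_nodelay``, ``NT``.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"ASC_delay": 38, "ASC_nodelay": 42, "NT": 57})
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    smoothing_fwhm: float = 4.0
    global_gm_offset: float = 0.05
    effect_blobs: list[EffectBlob] = field(default_factory=list)
    latent_loadings: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LATENT_LOADINGS))
    latent_spatial_pattern: list[EffectBlob] = field(default_factory=list)
    noise_sd: float = 0.05
    age_range: tuple[float, float] = (18.0, 41.0)
    centers: dict[str, float] = field(
        default_factory=lambda: {"KCL": 0.0, "Cambridge": 0.01, "Oxford": -0.01})
    measure_scales: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MEASURE_SCALES))
    seed: int = 0

    def validate(self) -> None:
        if any(s < 8 for s in self.grid_shape):
            raise ValueError("degenerate grid: every axis needs >= 8 voxels to smooth")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel dimensions must be positive")
        if self.smoothing_fwhm < 0:
            raise ValueError("FWHM must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not all(np.isfinite(list(self.latent_loadings.values()))):
            raise ValueError("latent loadings must be finite")
        if any(n <= 0 for n in self.n_per_group.values()):
            raise ValueError("group sizes must be positive")
        for blob in list(self.effect_blobs) + list(self.latent_spatial_pattern):
            self._check_blob_in_grid(blob)

    def _check_blob_in_grid(self, blob: EffectBlob) -> None:
        affine = self.affine()
        inv = np.linalg.inv(affine)
        vox = np.append(np.asarray(blob.center_mm, dtype=float), 1.0) @ inv.T
        if np.any(vox[:3] < 0) or np.any(vox[:3] > np.asarray(self.grid_shape) - 1):
            raise ValueError(f"blob center {blob.center_mm} mm falls outside the grid")

    def affine(self) -> np.ndarray:
        """Diagonal affine centering the grid on MNI (0, 0, 0)."""
        aff = np.eye(4)
        for k in range(3):
            aff[k, k] = self.voxel_size[k]
            aff[k, 3] = -(self.grid_shape[k] - 1) / 2.0 * self.voxel_size[k]
        return aff


@dataclass
class SubjectRecord:
    id: str
    diagnosis: str                       # ASC or NT
    delay_status: str                    # delay / no_delay / n/a
    age: float
    center: str
    scores: dict[str, float]
    total_volumes: dict[str, float]      # GM/WM/CSF, cm³
    latent_factor: float = 0.0
    first_words_months: float | None = None
    first_phrases_months: float | None = None


def classify_delay(first_words_months: float | None,
                   first_phrases_months: float | None) -> str:
    """Binary language-delay status from developmental milestones.

    ``delay`` iff first single words came later than 24 months, or first
    phrases later than 33 months, or both (strict inequalities: exactly 24
    and 33 months is ``no_delay``).  One milestone may be missing; with both
    missing the status is ``undetermined``.
    """
    words_missing = first_words_months is None or (
        isinstance(first_words_months, float) and math.isnan(first_words_months))
    phrases_missing = first_phrases_months is None or (
        isinstance(first_phrases_months, float) and math.isnan(first_phrases_months))
    if words_missing and phrases_missing:
        return "undetermined"
    for v, name in ((first_words_months, "first_words"), (first_phrases_months, "first_phrases")):
        if v is not None and not (isinstance(v, float) and math.isnan(v)) and v < 0:
            raise ValueError(f"{name} must be >= 0 months")
    if not words_missing and first_words_months > 24:
        return "delay"
    if not phrases_missing and first_phrases_months > 33:
        return "delay"
    return "no_delay"


def _mm_coordinate_grids(spec: CohortSpec) -> list[np.ndarray]:
    aff = spec.affine()
    axes = [np.arange(n) * spec.voxel_size[k] + aff[k, 3]
            for k, n in enumerate(spec.grid_shape)]
    return list(np.meshgrid(*axes, indexing="ij"))

def _blob_field(blob: EffectBlob, coords: list[np.ndarray]) -> np.ndarray:
    d2 = sum((c - m) ** 2 for c, m in zip(coords, blob.center_mm))
    return blob.amplitude * np.exp(-d2 / (2.0 * blob.radius_mm ** 2))


def _base_template(spec: CohortSpec, tissue: str) -> np.ndarray:
    """A smooth brain-like envelope: a centered super-Gaussian density."""
    coords = _mm_coordinate_grids(spec)
    half_extent = np.asarray(spec.grid_shape) * np.asarray(spec.voxel_size) / 2.0
    scale = 0.72 if tissue == "GM" else 0.55     # WM sits deeper, smaller support
    r = np.sqrt(sum((c / (scale * h)) ** 2 for c, h in zip(coords, half_extent)))
    peak = 0.7 if tissue == "GM" else 0.6
    return peak * np.exp(-(r ** 4))


def _smooth_noise(rng: np.random.Generator, spec: CohortSpec) -> np.ndarray:
    """Unit-variance smooth noise field (periodic convolution keeps it stationary)."""
    white = rng.standard_normal(spec.grid_shape)
    if spec.smoothing_fwhm == 0:
        return white
    sigma_vox = [spec.smoothing_fwhm * FWHM_TO_SIGMA / v for v in spec.voxel_size]
    sm = gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def generate_cohort(spec: CohortSpec) -> tuple[list[SubjectRecord], dict[str, dict[str, VolumeGrid]]]:
    """Draw a cohort: subject records plus per-subject GM and WM maps.

    Returns ``(records, maps)`` with ``maps["GM"][subject_id]`` a
    :class:`VolumeGrid`.  The language-delay subgroup's GM maps carry a
    multiplicative ``1 + global_gm_offset`` scale (larger absolute total GM
    without changing regional proportions except where blobs act).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    affine = spec.affine()
    coords = _mm_coordinate_grids(spec)

    base = {t: _base_template(spec, t) for t in ("GM", "WM")}
    group_fields: dict[tuple[str, str], np.ndarray] = {}
    for tissue in ("GM", "WM"):
        for g in spec.n_per_group:
            f = np.zeros(spec.grid_shape)
            for blob in spec.effect_blobs:
                if blob.tissue == tissue and (not blob.groups or g in blob.groups):
                    f += _blob_field(blob, coords)
            group_fields[(tissue, g)] = f
    latent_fields = {t: sum((_blob_field(b, coords) for b in spec.latent_spatial_pattern
                             if b.tissue == t), np.zeros(spec.grid_shape))
                     for t in ("GM", "WM")}

    center_names = list(spec.centers)
    records: list[SubjectRecord] = []
    maps: dict[str, dict[str, VolumeGrid]] = {"GM": {}, "WM": {}}
    i = 0
    for group, n in spec.n_per_group.items():
        for _ in range(n):
            sid = f"sub-{i:03d}"
            center = center_names[i % len(center_names)]
            age = rng.uniform(*spec.age_range)
            factor = rng.standard_normal()

            if group == "NT":
                diagnosis, delay_status = "NT", "n/a"
                words = float(rng.uniform(8, 20))
                phrases = float(rng.uniform(14, 30))
            else:
                diagnosis = "ASC"
                if group == "ASC_delay":
                    words = float(25 + rng.exponential(8))
                    phrases = float(words + rng.uniform(6, 18))
                else:
                    words = float(rng.uniform(8, 24))
                    phrases = float(rng.uniform(words + 2, 33))
                delay_status = classify_delay(words, phrases)

            scores: dict[str, float] = {}
            for m, (mu, sd) in spec.measure_scales.items():
                lam = float(np.clip(spec.latent_loadings.get(m, 0.0), -1.0, 1.0))
                eps = rng.standard_normal()
                scores[m] = mu + sd * (lam * factor + math.sqrt(1.0 - lam ** 2) * eps)

            total_volumes: dict[str, float] = {}
            for tissue in ("GM", "WM"):
                vals = base[tissue] + group_fields[(tissue, group)]
                vals = vals + factor * latent_fields[tissue]
                vals = vals + spec.centers[center]
                if spec.noise_sd > 0:
                    vals = vals + spec.noise_sd * _smooth_noise(rng, spec)
                if tissue == "GM" and group == "ASC_delay":
                    vals = vals * (1.0 + spec.global_gm_offset)
                vals = np.clip(vals, 0.0, None)
                grid = VolumeGrid(vals, affine)
                maps[tissue][sid] = grid
                total_volumes[tissue] = total_tissue_volume(grid)
            total_volumes["CSF"] = float(np.clip(rng.normal(270.0, 75.0), 50.0, None))

            records.append(SubjectRecord(
                id=sid, diagnosis=diagnosis, delay_status=delay_status, age=age,
                center=center, scores=scores, total_volumes=total_volumes,
                latent_factor=factor, first_words_months=words,
                first_phrases_months=phrases))
            i += 1
    return records, maps


def records_to_table(records: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "id": r.id, "diagnosis": r.diagnosis, "delay_status": r.delay_status,
            "age": r.age, "center": r.center,
            "first_words_months": r.first_words_months,
            "first_phrases_months": r.first_phrases_months,
            "latent_factor": r.latent_factor,
        }
        row.update({m: v for m, v in r.scores.items()})
        row.update({f"total_{t}_cm3": v for t, v in r.total_volumes.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(records: list[SubjectRecord], maps: dict[str, dict[str, VolumeGrid]],
                 outdir: str | Path, spec: CohortSpec | None = None) -> None:
    """Write per-subject NIfTI maps, a subject CSV, and the generating spec as YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for tissue, per_subject in maps.items():
        for sid, grid in per_subject.items():
            grid.to_nifti(outdir / f"{sid}_{tissue}.nii.gz")
    records_to_table(records).to_csv(outdir / "subjects.csv", index=False)
    if spec is not None:
        d = asdict(spec)
        d["effect_blobs"] = [asdict(b) for b in spec.effect_blobs]
        d["latent_spatial_pattern"] = [asdict(b) for b in spec.latent_spatial_pattern]
        (outdir / "cohort_spec.yaml").write_text(yaml.safe_dump(d, sort_keys=False))
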