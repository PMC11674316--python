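"""Synthetic multimodal cohorts with a recoverable age signal.

This module emulates the *preprocessed* outputs of a typical multimodal
aging-cohort pipeline — gray-matter probability volumes (sMRI), scalar
diffusion maps (FA/MD/AD-style), and per-region MEG power spectral
densities — not raw scanner data. Each modality carries a simple,
provably recoverable age signal:

* structural volumes drift linearly in mean intensity with age, with a
  configurable number of focal "atrophy" spheres whose intensity decays
  at twice the global rate;
* the diffusion map carries an independent linear trend;
* the PSD has a 1/f background plus a Gaussian alpha-band peak whose
  center frequency drifts linearly with age.

On top of iid voxel/bin noise, every modality receives a subject-level
intensity offset (``between_subject_sd``) representing inter-subject
biological and scanner variability. That offset is what limits the
accuracy attainable from any single modality and makes multimodal fusion
genuinely informative; with iid voxel noise alone, the spatial mean
would recover age essentially noiselessly from one volume.

Everything is deterministic given the seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "AgeSignalParams", "VolumeMap", "PSDMatrix", "SyntheticSubject",
    "MANIFEST_COLUMNS", "generate_subject", "generate_cohort", "write_cohort",
]

MANIFEST_COLUMNS = ["subject_id", "age", "smri_path", "dti_path", "psd_path", "split"]

#: frequency resolution of the synthetic PSD grid, Hz per bin
FREQ_STEP_HZ = 1.0


@dataclass(frozen=True)
class AgeSignalParams:
    """Parameters of the injected age signal.

    Intensities are unitless (probability-map scale); ages in years;
    spectral quantities in Hz.
    """

    baseline_intensity: float = 0.5      # mean sMRI voxel value at reference age
    slope_per_year: float = -0.002       # sMRI intensity change per year
    noise_sd: float = 0.05               # iid voxel / spectral noise
    between_subject_sd: float = 0.01     # per-subject, per-modality intensity offset
    atrophy_focus_count: int = 3         # spheres decaying at double slope
    psd_peak_shift_per_year: float = -0.03  # alpha-peak drift, Hz per year
    psd_peak_jitter_hz: float = 0.15     # subject-level alpha-peak jitter, Hz
    reference_age: float = 53.0          # age at which intensity == baseline
    dti_baseline_intensity: float = 0.45
    dti_slope_per_year: float = -0.0015
    alpha_center_hz: float = 10.0        # alpha-peak center at reference age
    alpha_width_hz: float = 1.5
    alpha_amplitude: float = 1.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.between_subject_sd < 0:
            raise ValueError("between_subject_sd must be >= 0")
        if self.psd_peak_jitter_hz < 0:
            raise ValueError("psd_peak_jitter_hz must be >= 0")
        if self.atrophy_focus_count < 0:
            raise ValueError("atrophy_focus_count must be >= 0")


@dataclass
class VolumeMap:
    """One subject's preprocessed 3D brain map for one modality."""

    data: np.ndarray          # float32, shape = grid_shape
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D map, got {self.data.ndim}D")


@dataclass
class PSDMatrix:
    """One subject's MEG power spectral density, regions x frequency bins."""

    values: np.ndarray        # float32, shape (regions, bins)
    freqs_hz: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            raise ValueError("PSD must be 2D (regions, bins)")
        if self.freqs_hz is None:
            self.freqs_hz = (np.arange(self.values.shape[1], dtype=np.float32)
                             + 1.0) * FREQ_STEP_HZ


@dataclass
class SyntheticSubject:
    subject_id: str
    age: float
    smri_map: VolumeMap
    dti_map: VolumeMap
    psd: PSDMatrix


def _atrophy_mask(grid_shape: tuple, count: int) -> np.ndarray:
    """Boolean mask of spherical foci, fixed for a given grid and count so
    the focal geometry is shared across the cohort."""
    mask = np.zeros(grid_shape, dtype=bool)
    if count == 0:
        return mask
    rng = np.random.default_rng(np.random.SeedSequence([count, *grid_shape]))
    radius = max(2, min(grid_shape) // 10)
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in grid_shape), indexing="ij")
    for _ in range(count):
        center = [rng.integers(radius, s - radius) for s in grid_shape]
        dist2 = ((zz - center[0]) ** 2 + (yy - center[1]) ** 2
                 + (xx - center[2]) ** 2)
        mask |= dist2 <= radius ** 2
    return mask


def generate_subject(age: float, params: AgeSignalParams,
                     grid_shape: tuple = (32, 32, 32),
                     psd_shape: tuple = (68, 64),
                     rng_seed: int = 0,
                     subject_id: str = "sub-0000") -> SyntheticSubject:
    """Generate one subject's multimodal data with an age-dependent signal.

    The sMRI voxel mean is ``baseline + slope*(age - reference_age)`` up to
    noise and the (small) contribution of the atrophy foci; the diffusion
    map follows its own linear trend; the PSD alpha peak sits at
    ``alpha_center + psd_peak_shift_per_year*(age - reference_age)`` Hz.
    """
    if age <= 0:
        raise ValueError(f"age must be positive, got {age}")
    if any(s < 8 for s in grid_shape) or len(grid_shape) != 3:
        raise ValueError(f"grid_shape must be 3D with all dims >= 8, got {grid_shape}")
    regions, bins = psd_shape
    if regions < 2 or bins < 4:
        raise ValueError(f"psd_shape needs regions >= 2 and bins >= 4, got {psd_shape}")
    if not (params.reference_age > 0):
        raise ValueError("reference_age must be positive")

    rng = np.random.default_rng(rng_seed)
    delta = age - params.reference_age

    # --- structural MRI ------------------------------------------------------
    smri_offset = rng.normal(0.0, params.between_subject_sd)
    smri = np.full(grid_shape,
                   params.baseline_intensity + params.slope_per_year * delta
                   + smri_offset, dtype=np.float64)
    foci = _atrophy_mask(grid_shape, params.atrophy_focus_count)
    smri[foci] += params.slope_per_year * delta  # double slope inside foci
    if params.noise_sd > 0:
        smri += rng.normal(0.0, params.noise_sd, size=grid_shape)

    # --- diffusion map (independent trend, independent subject offset) -------
    dti_offset = rng.normal(0.0, params.between_subject_sd)
    dti = np.full(grid_shape,
                  params.dti_baseline_intensity
                  + params.dti_slope_per_year * delta + dti_offset,
                  dtype=np.float64)
    if params.noise_sd > 0:
        dti += rng.normal(0.0, params.noise_sd, size=grid_shape)

    # --- MEG power spectral density ------------------------------------------
    freqs = (np.arange(bins) + 1.0) * FREQ_STEP_HZ
    # subject-level jitter of the alpha peak plays the between-subject role;
    # the default 0.15 Hz matches the structural modalities' age-equivalent
    # noise (0.15 / 0.03 Hz-per-year = 5 years, like 0.01 / 0.002 per year)
    peak_jitter = rng.normal(0.0, params.psd_peak_jitter_hz)
    center = (params.alpha_center_hz + params.psd_peak_shift_per_year * delta
              + peak_jitter)
    background = 1.0 / freqs
    peak = params.alpha_amplitude * np.exp(
        -0.5 * ((freqs - center) / params.alpha_width_hz) ** 2)
    region_gain = 1.0 + 0.1 * rng.standard_normal(regions)
    psd = region_gain[:, None] * (background + peak)[None, :]
    if params.noise_sd > 0:
        psd = psd * (1.0 + rng.normal(0.0, params.noise_sd, size=(regions, bins)))
    psd = np.clip(psd, 1e-8, None)

    affine = np.diag([2.0, 2.0, 2.0, 1.0])  # nominal 2 mm isotropic grid
    return SyntheticSubject(
        subject_id=subject_id,
        age=float(age),
        smri_map=VolumeMap(smri.astype(np.float32), affine),
        dti_map=VolumeMap(dti.astype(np.float32), affine.copy()),
        psd=PSDMatrix(psd.astype(np.float32), freqs.astype(np.float32)),
    )


def generate_cohort(n: int, age_range: tuple = (18.0, 88.0),
                    params: AgeSignalParams = AgeSignalParams(),
                    grid_shape: tuple = (32, 32, 32),
                    psd_shape: tuple = (68, 64),
                    seed: int = 0):
    """Generate ``n`` subjects with ages uniform over ``age_range``.

    Returns ``(subjects, manifest)`` where the manifest is a DataFrame with
    columns :data:`MANIFEST_COLUMNS` (paths empty until :func:`write_cohort`).
    Split labels follow the 80/10/10 rule of the training protocol.
    """
    from .model import split_dataset  # local import to avoid a cycle

    if n < 3:
        raise ValueError(f"need at least 3 subjects to form train/val/test, got {n}")
    lo, hi = age_range
    if not (0 < lo < hi):
        raise ValueError(f"invalid age range {age_range}")
    if not (lo <= params.reference_age <= hi):
        raise ValueError(
            f"reference_age {params.reference_age} outside cohort range {age_range}")

    ss = np.random.SeedSequence(seed)
    age_seed, *subject_seeds = ss.spawn(n + 1)
    ages = np.random.default_rng(age_seed).uniform(lo, hi, size=n)

    split = split_dataset(n, seed)
    labels = np.empty(n, dtype=object)
    labels[split.train] = "train"
    labels[split.val] = "val"
    labels[split.test] = "test"

    subjects = []
    rows = []
    for i in range(n):
        sid = f"sub-{i:04d}"
        subj = generate_subject(ages[i], params, grid_shape, psd_shape,
                                rng_seed=subject_seeds[i], subject_id=sid)
        subjects.append(subj)
        rows.append({"subject_id": sid, "age": float(ages[i]),
                     "smri_path": "", "dti_path": "", "psd_path": "",
                     "split": labels[i]})
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return subjects, manifest


def write_cohort(subjects, manifest: pd.DataFrame, out_dir) -> pd.DataFrame:
    """Persist a cohort: gzipped NIfTI volumes, one HDF5 PSD store, a TSV
    manifest. Returns the manifest with paths (relative to ``out_dir``) filled
    in; the same frame is written to ``out_dir/manifest.tsv``."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "volumes").mkdir(exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    if len(subjects) != len(manifest):
        raise ValueError("manifest row count does not match subject count")

    manifest = manifest.copy()
    psd_rel = "psd.h5"
    with h5py.File(out_dir / psd_rel, "w") as store:
        for i, subj in enumerate(subjects):
            smri_rel = f"volumes/{subj.subject_id}_smri.nii.gz"
            dti_rel = f"volumes/{subj.subject_id}_dti.nii.gz"
            nib.save(nib.Nifti1Image(subj.smri_map.data, subj.smri_map.affine),
                     str(out_dir / smri_rel))
            nib.save(nib.Nifti1Image(subj.dti_map.data, subj.dti_map.affine),
                     str(out_dir / dti_rel))
            ds = store.create_dataset(subj.subject_id, data=subj.psd.values)
            ds.attrs["freqs_hz"] = subj.psd.freqs_hz
            manifest.loc[manifest.index[i], ["smri_path", "dti_path", "psd_path"]] = \
                [smri_rel, dti_rel, psd_rel]
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    with open(out_dir / "cohort_info.json", "w") as fh:
        json.dump({"n_subjects": len(subjects),
                   "grid_shape": list(subjects[0].smri_map.data.shape),
                   "psd_shape": list(subjects[0].psd.values.shape)}, fh, indent=2)
    return manifest
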