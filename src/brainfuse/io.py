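"""Readers/writers for the on-disk cohort layout and run configuration.

A cohort on disk is: a TSV manifest (``subject_id, age, smri_path,
dti_path, psd_path, split``; paths relative to the manifest), gzipped or
plain NIfTI-1 volumes, and a single HDF5 store with one PSD dataset per
subject. Run configuration round-trips through YAML with strict keys.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .extractors import MEGEncoderConfig, SFCNConfig
from .model import TrainConfig, SplitAssignment
from .synthetic import MANIFEST_COLUMNS, PSDMatrix, VolumeMap

__all__ = [
    "read_volume", "read_psd", "read_manifest", "load_cohort_arrays",
    "RunConfig",
]


def read_volume(path) -> VolumeMap:
    """Load a 3D NIfTI-1 map (plain or gzipped); dtype coerced to float32."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise ValueError(f"cannot parse {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D map, got {data.ndim}D with shape {data.shape}")
    return VolumeMap(data.astype(np.float32), np.asarray(img.affine))


def read_psd(path, subject_id: str) -> PSDMatrix:
    """Load one subject's PSD from an HDF5 store or a per-subject TSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PSD store not found: {path}")
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as store:
            if subject_id not in store:
                raise KeyError(f"subject {subject_id!r} not in PSD store {path}")
            values = store[subject_id][()]
            freqs = store[subject_id].attrs.get("freqs_hz")
    else:
        values = pd.read_csv(path, sep="\t", header=None).to_numpy()
        freqs = None
    values = np.asarray(values, dtype=np.float32)
    if values.ndim != 2:
        raise ValueError(f"PSD for {subject_id!r} must be 2D, got {values.shape}")
    if not np.all(np.isfinite(values)):
        raise ValueError(f"PSD for {subject_id!r} contains non-finite values")
    return PSDMatrix(values, None if freqs is None
                     else np.asarray(freqs, dtype=np.float32))


def read_manifest(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    manifest = pd.read_csv(path, sep="\t")
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns {sorted(missing)}")
    if manifest["subject_id"].duplicated().any():
        raise ValueError(f"manifest {path} has duplicate subject ids")
    return manifest


def load_cohort_arrays(manifest_path):
    """Load a whole cohort into stacked arrays.

    Returns ``(data, ages, subject_ids, split)`` where ``data`` maps
    modality -> array and ``split`` is a :class:`SplitAssignment` built from
    the manifest's split column (or None if any label is missing).
    """
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    base = manifest_path.parent
    smri, dti, psd = [], [], []
    shapes = set()
    psd_shapes = set()
    for _, row in manifest.iterrows():
        vol_s = read_volume(base / row["smri_path"])
        vol_d = read_volume(base / row["dti_path"])
        spec = read_psd(base / row["psd_path"], row["subject_id"])
        shapes.update([vol_s.data.shape, vol_d.data.shape])
        psd_shapes.add(spec.values.shape)
        smri.append(vol_s.data)
        dti.append(vol_d.data)
        psd.append(spec.values)
    if len(shapes) > 1:
        raise ValueError(f"inconsistent volume grids across cohort: {shapes}")
    if len(psd_shapes) > 1:
        raise ValueError(f"inconsistent PSD shapes across cohort: {psd_shapes}")
    data = {"smri": np.stack(smri), "dti": np.stack(dti), "meg": np.stack(psd)}
    ages = manifest["age"].to_numpy(dtype=np.float64)
    ids = manifest["subject_id"].tolist()
    split = None
    if set(manifest["split"]) <= {"train", "val", "test"}:
        idx = {s: np.flatnonzero((manifest["split"] == s).to_numpy())
               for s in ("train", "val", "test")}
        split = SplitAssignment(train=idx["train"], val=idx["val"],
                                test=idx["test"])
    return data, ages, ids, split


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

def _strict_kwargs(cls, mapping: dict, context: str) -> dict:
    allowed = {f.name for f in fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {context}: {sorted(unknown)}")
    return {k: tuple(v) if isinstance(v, list) else v
            for k, v in mapping.items()}


@dataclass
class RunConfig:
    """Full provenance for one run: paths + all model/protocol settings."""

    manifest: str = ""
    out_dir: str = "."
    seed: int = 0
    train: TrainConfig = field(default_factory=TrainConfig)
    sfcn: SFCNConfig = field(default_factory=SFCNConfig)
    meg: MEGEncoderConfig = field(default_factory=MEGEncoderConfig)
    report_uncorrected: bool = False

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw or {})
        kwargs = {}
        for key in ("train", "sfcn", "meg"):
            sub = raw.pop(key, {})
            sub_cls = {"train": TrainConfig, "sfcn": SFCNConfig,
                       "meg": MEGEncoderConfig}[key]
            kwargs[key] = sub_cls(**_strict_kwargs(sub_cls, sub, key))
        top = _strict_kwargs(cls, raw, "run config")
        kwargs.update(top)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj

        return clean(asdict(self))

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
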