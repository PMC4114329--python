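"""NIfTI / CSV / YAML readers and writers, plus run metadata.

Volumes, masks and ReHo maps travel as NIfTI-1 (.nii.gz) with the sampling
interval stored in the 4th pixdim; demographics travel as UTF-8 CSV with the
header ``subject_id,study,sex,age``.  Every CLI run drops a JSON metadata
record next to its outputs with enough information (tool version, config
snapshot, master seed, per-stage parameters) to reproduce them bit-for-bit.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .masking import SubjectMask
from .preprocess import Volume4D
from .reho import ReHoMap

__all__ = [
    "read_volume", "write_volume", "read_mask", "write_mask",
    "read_reho_map", "write_reho_map",
    "read_demographics", "write_demographics",
    "RunMetadata", "write_run_metadata", "load_yaml",
]

DEMOGRAPHICS_COLUMNS = ["subject_id", "study", "sex", "age"]
VALID_SEX = {"female", "male"}


def _affine() -> np.ndarray:
    return np.eye(4)


def write_volume(volume: Volume4D, path) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float64), _affine())
    img.header.set_zooms((1.0, 1.0, 1.0, volume.sampling_interval))
    nib.save(img, str(path))


def read_volume(path) -> Volume4D:
    img = _load_nifti(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D volume, got shape {data.shape}")
    tr = float(img.header.get_zooms()[3]) or 1.0
    return Volume4D(data, tr)


def write_mask(mask: SubjectMask, path) -> None:
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), _affine()), str(path))


def read_mask(path, source: str = "whole_brain") -> SubjectMask:
    data = np.asarray(_load_nifti(path).dataobj)
    vals = np.unique(data)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{path}: mask is not binary; values found: {vals[:10]}")
    return SubjectMask(data=data.astype(np.uint8), source=source)


def write_reho_map(rmap: ReHoMap, path) -> None:
    nib.save(nib.Nifti1Image(rmap.data.astype(np.float64), _affine()), str(path))


def read_reho_map(path) -> ReHoMap:
    data = np.asarray(_load_nifti(path).dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D map, got shape {data.shape}")
    if data.min() < 0 or data.max() > 1:
        raise ValueError(f"{path}: ReHo values outside [0, 1]")
    return ReHoMap(data=data)


def _load_nifti(path):
    try:
        return nib.load(str(path))
    except Exception as err:
        raise ValueError(f"{path}: not a readable NIfTI file ({err})") from err


def read_demographics(path, exclude_studies: list[str] | None = None) -> pd.DataFrame:
    """Validated subject-level demographics table.

    Requires the ``subject_id,study,sex,age`` header; rejects duplicate ids
    and unknown sex codes; drops the studies in ``exclude_studies`` if given.
    """
    df = pd.read_csv(path)
    missing = set(DEMOGRAPHICS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"{path}: duplicate subject ids {dup[:5]}")
    bad = set(df["sex"].astype(str)) - VALID_SEX
    if bad:
        raise ValueError(f"{path}: unknown sex codes {sorted(bad)}; expected {sorted(VALID_SEX)}")
    if exclude_studies:
        df = df[~df["study"].isin(exclude_studies)].reset_index(drop=True)
    return df


def write_demographics(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=DEMOGRAPHICS_COLUMNS)


@dataclass
class RunMetadata:
    """Reproducibility record written next to every CLI output."""

    command: str
    version: str
    master_seed: int | None
    config: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")


def write_run_metadata(meta: RunMetadata, out_dir) -> Path:
    out = Path(out_dir) / f"run_metadata_{meta.command.replace(' ', '_')}.json"
    out.write_text(json.dumps(asdict(meta), indent=2, default=str) + "\n")
    return out


def load_yaml(path) -> dict:
    with open(path) as fh:
        loaded = yaml.safe_load(fh)
    if not isinstance(loaded, dict):
        raise ValueError(f"{path}: expected a mapping at the top level")
    return loaded
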