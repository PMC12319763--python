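"""NIfTI and tabular I/O carriers for the pipeline."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from somatopipe.synthetic_data import VolumeGrid


class FormatError(ValueError):
    """Input file is not in the expected format."""


def write_image(path, data: np.ndarray, grid: VolumeGrid | None = None,
                affine: np.ndarray | None = None) -> Path:
    """Write a 3-D or 4-D volume as NIfTI-1 (float32)."""
    path = Path(path)
    if affine is None:
        affine = grid.affine() if grid is not None else np.eye(4)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))
    return path


def read_image(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI-1 volume; returns (data, affine)."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"{path} is not a readable NIfTI image: {exc}") from exc
    if not isinstance(img, (nib.Nifti1Image, nib.Nifti2Image)):
        raise FormatError(f"{path} is not a NIfTI image")
    return np.asarray(img.dataobj, dtype=np.float32), img.affine


def grid_from_affine(affine: np.ndarray, shape) -> VolumeGrid:
    diag = np.diag(affine)[:3]
    if not np.allclose(affine[:3, :3], np.diag(diag)):
        raise FormatError("only axis-aligned affines are supported")
    return VolumeGrid(shape=tuple(int(s) for s in shape[:3]),
                      voxel_size_mm=tuple(float(abs(v)) for v in diag),
                      origin_mm=tuple(float(v) for v in affine[:3, 3]))


def write_events_tsv(path, schedule) -> Path:
    path = Path(path)
    schedule.to_events().to_csv(path, sep="\t", index=False)
    return path


def read_events_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"onset", "duration", "trial_type"} - set(df.columns)
    if missing:
        raise FormatError(f"events file lacks columns: {sorted(missing)}")
    return df


def write_physio_tsv(path, times: np.ndarray, values: np.ndarray,
                     value_name: str = "value") -> Path:
    path = Path(path)
    pd.DataFrame({"time": times, value_name: values}).to_csv(
        path, sep="\t", index=False)
    return path


def write_design_tsv(path, design) -> Path:
    path = Path(path)
    design.to_frame().to_csv(path, sep="\t", index=False)
    return path


def write_nuisance_tsv(path, nuisance) -> Path:
    path = Path(path)
    nuisance.to_frame().to_csv(path, sep="\t", index=False)
    return path
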