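"""Volumetric image and atlas I/O.

All spatial data are NIfTI-1; the scan and its atlas must live on the same
voxel grid (no resampling is performed anywhere in the package). Tabular
reader-call data travel as plain CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

CEREBELLUM = "cerebellum"
BACKGROUND = "background"

#: The six cortical regions scored bilaterally in step 1 of the visual read.
CORTICAL_REGIONS = (
    "lateral_anterior_temporal",
    "lateral_posterior_temporal",
    "occipital",
    "parietal",
    "precuneus",
    "frontal",
)

#: The twelve region-sides (region x hemisphere) used for step-1 scoring.
CORTICAL_REGION_SIDES = tuple(
    f"{region}_{side}" for region in CORTICAL_REGIONS for side in ("L", "R")
)

#: Full region-name vocabulary accepted in atlas label tables.
REGION_VOCABULARY = (CEREBELLUM, BACKGROUND) + CORTICAL_REGION_SIDES


@dataclass
class VoxelGrid3D:
    """A 3-D intensity volume with voxel geometry.

    Parameters
    ----------
    values
        3-D array of finite intensities (tracer counts or SUVr; the
        stratification method is invariant to a global scale).
    affine
        4x4 voxel-to-world transform.
    """

    values: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"expected 3-D volume, got {self.values.ndim}-D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        n_bad = int(np.size(self.values) - np.isfinite(self.values).sum())
        if n_bad:
            raise ValueError(f"volume contains {n_bad} non-finite voxel(s)")
        if not np.all(self.voxel_size_mm > 0):
            raise ValueError("voxel sizes derived from affine must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.values.shape)  # type: ignore[return-value]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Voxel edge lengths in mm, from the affine column norms."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def scaled(self, factor: float) -> "VoxelGrid3D":
        """Return a copy with every intensity multiplied by ``factor``."""
        return VoxelGrid3D(self.values * float(factor), self.affine.copy())


@dataclass
class RegionAtlas:
    """Co-registered integer label grid naming cerebellum + cortical region-sides.

    ``label_table`` maps integer labels to names from :data:`REGION_VOCABULARY`;
    label 0 is implicit background and need not appear in the table.
    """

    labels: np.ndarray
    label_table: Mapping[int, str]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be a 3-D grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        self.label_table = dict(self.label_table)
        names = list(self.label_table.values())
        if len(names) != len(set(names)):
            raise ValueError("region names must be unique in label_table")
        unknown = set(names) - set(REGION_VOCABULARY)
        if unknown:
            raise ValueError(f"unknown region name(s): {sorted(unknown)}")
        if CEREBELLUM not in names:
            raise ValueError("label_table must include the cerebellum")
        present = set(np.unique(self.labels).tolist())
        allowed = set(self.label_table) | {0}
        stray = present - allowed
        if stray:
            raise ValueError(f"labels grid contains undeclared label(s): {sorted(stray)}")
        if not np.any(self.labels == self.label_for(CEREBELLUM)):
            raise ValueError("cerebellum label maps to no voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)  # type: ignore[return-value]

    def label_for(self, name: str) -> int:
        for lab, nm in self.label_table.items():
            if nm == name:
                return lab
        raise KeyError(f"unknown region name: {name}")

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of a single named region."""
        return self.labels == self.label_for(name)

    def union_mask(self, names) -> np.ndarray:
        """Boolean mask of the union of several named regions."""
        m = np.zeros(self.shape, dtype=bool)
        for name in names:
            m |= self.mask(name)
        return m

    @property
    def region_names(self) -> list[str]:
        return [nm for nm in self.label_table.values() if nm != BACKGROUND]


def read_volume(path) -> VoxelGrid3D:
    """Load a NIfTI-1 volume.

    The format's stored slope/intercept is applied; nothing else is rescaled.
    Raises on missing files, non-3-D images, and non-finite voxels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"expected 3-D volume, got {len(img.shape)}-D in {path.name}")
    data = np.asarray(img.get_fdata(dtype=np.float64))
    n_bad = int(data.size - np.isfinite(data).sum())
    if n_bad:
        raise ValueError(f"{path.name}: {n_bad} non-finite voxel(s) after load")
    return VoxelGrid3D(values=data, affine=np.asarray(img.affine))


def write_volume(grid: VoxelGrid3D, path) -> None:
    """Write a :class:`VoxelGrid3D` as NIfTI-1, preserving the value dtype."""
    path = Path(path)
    img = nib.Nifti1Image(grid.values, grid.affine)
    img.set_data_dtype(grid.values.dtype)
    nib.save(img, str(path))


def _labels_sidecar(path: Path) -> Path:
    base = path.name
    for suffix in (".nii.gz", ".nii"):
        if base.endswith(suffix):
            base = base[: -len(suffix)]
            break
    return path.with_name(base + ".labels.json")


def write_atlas(atlas: RegionAtlas, path) -> None:
    """Write atlas labels as integer NIfTI plus a JSON label-table sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.affine)
    img.set_data_dtype(np.int16)
    nib.save(img, str(path))
    sidecar = _labels_sidecar(path)
    sidecar.write_text(
        json.dumps({str(k): v for k, v in atlas.label_table.items()}, indent=2, sort_keys=True)
    )


def read_atlas(path, label_table: Mapping[int, str] | None = None) -> RegionAtlas:
    """Load an atlas written by :func:`write_atlas` (or any integer NIfTI).

    If ``label_table`` is not given, the ``.labels.json`` sidecar next to the
    NIfTI file is required.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError("expected 3-D atlas")
    labels = np.asarray(img.dataobj).astype(np.int64)
    if label_table is None:
        sidecar = _labels_sidecar(path)
        if not sidecar.exists():
            raise FileNotFoundError(f"label table sidecar not found: {sidecar}")
        label_table = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    return RegionAtlas(labels=labels, label_table=label_table, affine=np.asarray(img.affine))


def validate_grid_match(grid: VoxelGrid3D, atlas: RegionAtlas, atol: float = 1e-4) -> None:
    """Raise unless scan and atlas share shape and affine (within ``atol``)."""
    if grid.shape != atlas.shape:
        raise ValueError(f"shape mismatch: scan {grid.shape} vs atlas {atlas.shape}")
    diff = np.abs(grid.affine - atlas.affine)
    if np.any(diff > atol):
        idx = np.argwhere(diff > atol)
        comps = ", ".join(
            f"[{i},{j}]: {grid.affine[i, j]:g} vs {atlas.affine[i, j]:g}" for i, j in idx[:4]
        )
        raise ValueError(f"affine mismatch beyond {atol}: {comps}")


# --- tabular reader-call data -------------------------------------------------

CALL_POSITIVE = "high_tau"
CALL_NEGATIVE = "non_high_tau"


def load_reads_csv(path):
    """Load a reads CSV into a :class:`tauread.agreement_stats.ReadMatrix`.

    Expected columns: ``scan_id``, ``reader_id``, ``call`` in
    {high_tau, non_high_tau}, optional ``truth`` with the same coding.
    """
    from .agreement_stats import ReadMatrix  # local import avoids cycle at import time

    df = pd.read_csv(path, dtype=str)
    required = {"scan_id", "reader_id", "call"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"reads CSV missing column(s): {sorted(missing)}")
    bad = set(df["call"]) - {CALL_POSITIVE, CALL_NEGATIVE}
    if bad:
        raise ValueError(f"unrecognised call value(s): {sorted(bad)}")
    return ReadMatrix.from_long(df)


def save_reads_csv(matrix, path) -> None:
    """Write a :class:`ReadMatrix` in the long CSV schema of :func:`load_reads_csv`."""
    matrix.to_long().to_csv(path, index=False)
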