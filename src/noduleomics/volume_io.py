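"""Volume, mask and feature-table I/O.

Internal conventions
--------------------
* Volumes are 3-D arrays in ``(x, y, z)`` axis order with per-axis voxel
  spacing in millimetres.  World coordinate of voxel ``(i, j, k)`` is
  ``origin + index * spacing`` (voxel centres, 0-based indices).
* On-disk formats are NRRD and NIfTI (read and written through SimpleITK);
  SimpleITK's native array order ``(z, y, x)`` is transposed on the way in
  and out so callers never see it.
* Feature tables are CSV files with a header row and the fixed leading
  columns ``case_id, label, split`` followed by numeric feature columns.
  Labels are ``LC`` (primary lung cancer, the positive class) or ``LM``
  (solitary lung metastasis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import SimpleITK as sitk

logger = logging.getLogger("noduleomics")

VALID_LABELS = ("LC", "LM")
POSITIVE_LABEL = "LC"
META_COLUMNS = ("case_id", "label", "split")


def configure_logging(level: str = "INFO") -> None:
    """Configure the package logger (idempotent)."""
    root = logging.getLogger("noduleomics")
    root.setLevel(getattr(logging, level.upper()))
    if not root.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        root.addHandler(handler)


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class ImageVolume:
    """A 3-D scalar intensity grid in Hounsfield units.

    Attributes
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Intensities in HU.
    spacing_mm : tuple of 3 floats
        Per-axis voxel spacing in millimetres; all strictly positive.
    origin_mm : tuple of 3 floats
        World coordinate of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"volume must be 3-D, got shape {self.voxels.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite voxel values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]


@dataclass
class RoiMask:
    """A binary voxel mask congruent with its paired :class:`ImageVolume`.

    ``role`` tags whether the mask delineates the nodule itself (``intra``)
    or the perinodular ring around it (``peri``).
    """

    voxels: np.ndarray
    role: str = "intra"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {self.voxels.shape}")
        if self.role not in ("intra", "peri"):
            raise ValueError(f"role must be 'intra' or 'peri', got {self.role!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def count(self) -> int:
        return int(self.voxels.sum())


@dataclass
class FeatureTable:
    """Per-case feature values plus class label and split tag.

    Wraps a DataFrame whose leading columns are ``case_id, label, split``;
    every remaining column is a numeric feature.  Construction validates
    the contract (unique ids, known labels, numeric finite features).
    """

    data: pd.DataFrame
    feature_columns: list[str] = field(init=False)

    def __post_init__(self) -> None:
        df = self.data
        missing_meta = [c for c in META_COLUMNS if c not in df.columns]
        if missing_meta:
            raise ValueError(f"feature table missing columns {missing_meta}")
        if df["case_id"].duplicated().any():
            dupes = df.loc[df["case_id"].duplicated(), "case_id"].tolist()
            raise ValueError(f"duplicated case ids: {dupes}")
        bad_labels = sorted(set(df["label"]) - set(VALID_LABELS))
        if bad_labels:
            raise ValueError(
                f"unknown labels {bad_labels}; expected one of {VALID_LABELS}"
            )
        self.feature_columns = [c for c in df.columns if c not in META_COLUMNS]
        cells = []
        for col in self.feature_columns:
            numeric = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[numeric.isna()]
            cells.extend((int(r), col) for r in bad)
            df[col] = numeric
        if cells:
            raise ValueError(f"non-numeric or missing feature cells (row, column): {cells}")
        self.data = df.reset_index(drop=True)

    # -- convenience accessors ------------------------------------------------

    @property
    def labels(self) -> np.ndarray:
        return self.data["label"].to_numpy()

    @property
    def case_ids(self) -> np.ndarray:
        return self.data["case_id"].to_numpy()

    def features(self, columns: Iterable[str] | None = None) -> np.ndarray:
        cols = list(columns) if columns is not None else self.feature_columns
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise KeyError(f"features not in table: {missing}")
        return self.data[cols].to_numpy(dtype=float)

    def binary_labels(self) -> np.ndarray:
        """0/1 labels with LC (primary lung cancer) as the positive class."""
        return (self.labels == POSITIVE_LABEL).astype(int)

    def subset(self, mask: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.data.loc[np.asarray(mask)].reset_index(drop=True).copy())

    def split(self, tag: str) -> "FeatureTable":
        return self.subset(self.data["split"].to_numpy() == tag)

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# Volume / mask I/O
# ---------------------------------------------------------------------------

_SUPPORTED_SUFFIXES = (".nrrd", ".nhdr", ".nii", ".nii.gz")


def _check_path(path: str | Path) -> Path:
    path = Path(path)
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise ValueError(f"unsupported volume format: {path} (want NRRD or NIfTI)")
    return path


def read_volume(path: str | Path) -> ImageVolume:
    """Read an NRRD or NIfTI volume into the internal (x, y, z) convention.

    A trailing singleton 4th dimension (common in NIfTI exports) is
    squeezed; any other 4-D shape is an error.
    """
    path = _check_path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = sitk.ReadImage(str(path))
    if img.GetDimension() == 4:
        arr4 = sitk.GetArrayFromImage(img)  # (t, z, y, x)
        if arr4.shape[0] != 1:
            raise ValueError(f"cannot interpret 4-D volume of shape {arr4.shape}")
        spacing = img.GetSpacing()[:3]
        origin = img.GetOrigin()[:3]
        arr = arr4[0]
    elif img.GetDimension() == 3:
        arr = sitk.GetArrayFromImage(img)  # (z, y, x)
        spacing = img.GetSpacing()
        origin = img.GetOrigin()
    else:
        raise ValueError(f"expected a 3-D volume, got dimension {img.GetDimension()}")
    voxels = np.ascontiguousarray(arr.transpose(2, 1, 0))
    return ImageVolume(voxels=voxels, spacing_mm=tuple(spacing), origin_mm=tuple(origin))


def write_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write a volume as NRRD or NIfTI (chosen by file extension)."""
    path = _check_path(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.voxels.transpose(2, 1, 0)))
    img.SetSpacing(volume.spacing_mm)
    img.SetOrigin(volume.origin_mm)
    sitk.WriteImage(img, str(path))


def read_mask(path: str | Path, role: str = "intra") -> RoiMask:
    """Read a binary mask; {0, 255} encodings are normalised to {0, 1}."""
    vol = read_volume(path)
    values = np.unique(vol.voxels)
    if set(values.tolist()) <= {0, 1}:
        voxels = vol.voxels.astype(bool)
    elif set(values.tolist()) <= {0, 255}:
        logger.warning("mask %s uses {0, 255}; normalising to {0, 1}", path)
        voxels = vol.voxels > 0
    else:
        raise ValueError(f"mask {path} is not binary (values {values[:10]})")
    return RoiMask(voxels=voxels, role=role)


def write_mask(mask: RoiMask, volume: ImageVolume, path: str | Path) -> None:
    """Write a mask as uint8 with the geometry of its paired volume."""
    if mask.shape != volume.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {volume.shape}")
    out = ImageVolume(
        voxels=mask.voxels.astype(np.uint8),
        spacing_mm=volume.spacing_mm,
        origin_mm=volume.origin_mm,
    )
    write_volume(out, path)


# ---------------------------------------------------------------------------
# Feature-table I/O
# ---------------------------------------------------------------------------

def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a feature CSV; validates labels, ids and numeric completeness."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"case_id": str, "label": str, "split": str})
    missing = df.isna()
    if missing.any().any():
        cells = [
            (int(r), c) for c in df.columns for r in df.index[missing[c]]
        ]
        raise ValueError(f"missing values at (row, column): {cells}")
    return FeatureTable(df)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    table.data.to_csv(Path(path), index=False, float_format="%.17g")
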