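"""Reading and writing the pipeline's on-disk artifacts.

The native interchange formats are deliberately desk-simple: multi-frame TIFF
for image stacks (with a JSON side-car for acquisition metadata), single-page
0/255 TIFF for pixel masks, and plain CSV for time series and model catalogs.
Proprietary microscope formats can be adapted behind :func:`read_stack` by
converting to these.

Coordinate convention used throughout the package: 0-based ``(row, col)``
with row 0 at the top of the image and pixel-center addressing.
"""

from __future__ import annotations

import json
import numbers
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .exceptions import FormatError, StackIOError, ValidationError

__all__ = [
    "ImageStack",
    "PixelMask",
    "read_stack",
    "write_stack",
    "read_metadata",
    "read_roi_mask",
    "read_nucleus_mask",
    "write_mask",
    "write_model_catalog",
    "read_model_catalog",
    "CATALOG_COLUMNS",
]

#: Metadata fields required to interpret a raw stack.
METADATA_FIELDS = (
    "pixel_size_nm",
    "frame_interval_s",
    "n_pre_damage_frames",
    "damage_frame_index",
)


@dataclass
class ImageStack:
    """A time-lapse fluorescence stack of a single nucleus.

    Parameters
    ----------
    frames
        ``(time, rows, cols)`` array of non-negative intensities.
    pixel_size_nm
        Detector resolution in nanometres per pixel (e.g. 86.77).
    frame_interval_s
        Time between consecutive frames in seconds.
    n_pre_damage_frames
        Number of frames acquired before irradiation; these are the
        reference set for photobleach correction and normalization.
    damage_frame_index
        Index of the first post-irradiation frame.
    valid
        Optional ``(time, rows, cols)`` boolean array flagging pixels that
        carry real data.  Drift correction fills vacated edge pixels with 0
        and marks them invalid so they can be excluded from nuclear sums.
    """

    frames: np.ndarray
    pixel_size_nm: float
    frame_interval_s: float
    n_pre_damage_frames: int
    damage_frame_index: int
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValidationError(
                f"stack must be 3D (time, rows, cols); got ndim={self.frames.ndim}"
            )
        if self.frames.shape[0] < 2:
            raise ValidationError("stack must contain at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValidationError("stack intensities must be finite")
        if np.any(self.frames < 0):
            raise ValidationError("stack intensities must be non-negative")
        if self.pixel_size_nm <= 0:
            raise ValidationError("pixel_size_nm must be > 0")
        if self.frame_interval_s <= 0:
            raise ValidationError("frame_interval_s must be > 0")
        if self.n_pre_damage_frames < 1:
            raise ValidationError("n_pre_damage_frames must be >= 1")
        if not (
            self.n_pre_damage_frames
            <= self.damage_frame_index
            <= self.frames.shape[0]
        ):
            raise ValidationError(
                "require n_pre_damage_frames <= damage_frame_index <= n_frames; got "
                f"{self.n_pre_damage_frames} <= {self.damage_frame_index} "
                f"<= {self.frames.shape[0]}"
            )
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.frames.shape:
                raise ValidationError("valid mask must match frame dimensions")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]  # type: ignore[return-value]

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    def times_from_damage(self) -> np.ndarray:
        """Frame times in seconds, measured from damage onset."""
        return (
            np.arange(self.n_frames, dtype=float) - self.damage_frame_index
        ) * self.frame_interval_s

    def valid_at(self, t: int) -> np.ndarray:
        """Boolean validity grid for frame ``t`` (all-true if untracked)."""
        if self.valid is None:
            return np.ones(self.frame_shape, dtype=bool)
        return self.valid[t]


@dataclass
class PixelMask:
    """Boolean pixel grid on the camera frame (nucleus outline or damage ROI)."""

    grid: np.ndarray
    role: str = "roi"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValidationError("mask grid must be 2D")
        if self.role not in ("nucleus", "roi"):
            raise ValidationError(f"mask role must be 'nucleus' or 'roi', got {self.role!r}")

    @property
    def area(self) -> int:
        return int(np.count_nonzero(self.grid))


def _require_metadata(metadata: Mapping[str, object]) -> dict:
    missing = [k for k in METADATA_FIELDS if k not in metadata]
    if missing:
        raise ValidationError(f"metadata missing required fields: {missing}")
    out = {k: metadata[k] for k in METADATA_FIELDS}
    for key in ("pixel_size_nm", "frame_interval_s"):
        if not isinstance(out[key], numbers.Real) or float(out[key]) <= 0:  # type: ignore[arg-type]
            raise ValidationError(f"metadata field {key} must be a positive number")
    return out


def read_metadata(path: str | Path) -> dict:
    """Load a JSON metadata side-car written by :func:`write_stack`."""
    path = Path(path)
    try:
        with open(path) as fh:
            return json.load(fh)
    except OSError as exc:
        raise StackIOError(f"cannot read metadata file {path}: {exc}") from exc


def read_stack(path: str | Path, metadata: Mapping[str, object]) -> ImageStack:
    """Read a multi-frame TIFF stack.

    ``metadata`` supplies the acquisition parameters (see
    :data:`METADATA_FIELDS`); pass the dict returned by :func:`read_metadata`
    when a side-car file exists.
    """
    path = Path(path)
    meta = _require_metadata(metadata)
    try:
        with tifffile.TiffFile(path) as tif:
            shapes = {page.shape for page in tif.pages}
            if len(shapes) > 1:
                raise FormatError(
                    f"{path}: frames have inconsistent shapes {sorted(shapes)}"
                )
            frames = tif.asarray()
    except (OSError, tifffile.TiffFileError) as exc:
        raise StackIOError(f"cannot read stack {path}: {exc}") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:
        raise ValidationError(f"{path}: a stack needs at least 2 frames")
    if frames.ndim != 3:
        raise FormatError(f"{path}: expected a 2D multi-frame stack, got ndim={frames.ndim}")
    return ImageStack(
        frames=frames.astype(float),
        pixel_size_nm=float(meta["pixel_size_nm"]),
        frame_interval_s=float(meta["frame_interval_s"]),
        n_pre_damage_frames=int(meta["n_pre_damage_frames"]),  # type: ignore[call-overload]
        damage_frame_index=int(meta["damage_frame_index"]),  # type: ignore[call-overload]
    )


def write_stack(stack: ImageStack, path: str | Path, sidecar: bool = True) -> None:
    """Write a stack as multi-frame TIFF (float32) with a JSON metadata side-car."""
    path = Path(path)
    try:
        tifffile.imwrite(path, stack.frames.astype(np.float32), photometric="minisblack")
    except OSError as exc:
        raise StackIOError(f"cannot write stack {path}: {exc}") from exc
    if sidecar:
        meta = {
            "pixel_size_nm": stack.pixel_size_nm,
            "frame_interval_s": stack.frame_interval_s,
            "n_pre_damage_frames": stack.n_pre_damage_frames,
            "damage_frame_index": stack.damage_frame_index,
        }
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(meta, fh, indent=2)


def _read_single_image(path: Path) -> np.ndarray:
    try:
        img = tifffile.imread(path)
    except (OSError, tifffile.TiffFileError) as exc:
        raise StackIOError(f"cannot read mask {path}: {exc}") from exc
    img = np.asarray(img)
    if img.ndim == 3 and img.shape[0] == 1:
        img = img[0]
    if img.ndim != 2:
        raise FormatError(f"{path}: mask file must hold a single 2D image")
    return img


def read_roi_mask(path: str | Path, stack_shape: tuple[int, int]) -> PixelMask:
    """Read a single-image ROI trace; nonzero pixels mark the irradiated region."""
    path = Path(path)
    img = _read_single_image(path)
    if img.shape != tuple(stack_shape):
        raise ValidationError(
            f"{path}: ROI shape {img.shape} does not match stack frames {tuple(stack_shape)}"
        )
    grid = img > 0
    if not grid.any():
        raise ValidationError(f"{path}: empty ROI (no nonzero pixels)")
    return PixelMask(grid=grid, role="roi")


def read_nucleus_mask(path: str | Path, stack_shape: tuple[int, int]) -> PixelMask:
    """Read a previously saved nuclear-envelope mask."""
    mask = read_roi_mask(path, stack_shape)
    return PixelMask(grid=mask.grid, role="nucleus")


def write_mask(mask: PixelMask, path: str | Path) -> None:
    """Write a mask as an 8-bit 0/255 single-page TIFF."""
    try:
        tifffile.imwrite(Path(path), (mask.grid.astype(np.uint8) * 255))
    except OSError as exc:
        raise StackIOError(f"cannot write mask {path}: {exc}") from exc


#: Column order of the all-models catalog (``all_models.csv``).
CATALOG_COLUMNS = (
    "rank",
    "delta_x_px",
    "D_eff_um2_s",
    "F_ppt",
    "r2",
    "rmsd",
    "rmsd_replicate_min",
    "rmsd_replicate_max",
)


def write_model_catalog(result, path: str | Path) -> None:
    """Write a ranked catalog of every sampled ``(D_eff, F)`` model.

    Rows are ordered best-fit first (ascending representative RMSD).  D_eff is
    printed to 4 significant figures; r² and RMSD to 4 decimal places.
    """
    table = result.to_frame()
    if table.empty:
        raise ValidationError("cannot write an empty model catalog")
    out = pd.DataFrame(
        {
            "rank": np.arange(1, len(table) + 1),
            "delta_x_px": table["delta_x"].astype(int),
            "D_eff_um2_s": [f"{v:.4g}" for v in table["D_eff_um2_s"]],
            "F_ppt": table["F_ppt"].astype(int),
            "r2": [f"{v:.4f}" for v in table["r2"]],
            "rmsd": [f"{v:.4f}" for v in table["rmsd"]],
            "rmsd_replicate_min": [f"{v:.4f}" for v in table["rmsd_replicate_min"]],
            "rmsd_replicate_max": [f"{v:.4f}" for v in table["rmsd_replicate_max"]],
        }
    )
    try:
        out.to_csv(Path(path), index=False)
    except OSError as exc:
        raise StackIOError(f"cannot write model catalog {path}: {exc}") from exc


def read_model_catalog(path: str | Path) -> pd.DataFrame:
    """Parse an ``all_models.csv`` back into a DataFrame (ranking preserved)."""
    try:
        df = pd.read_csv(Path(path))
    except OSError as exc:
        raise StackIOError(f"cannot read model catalog {path}: {exc}") from exc
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: catalog missing columns {missing}")
    return df
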