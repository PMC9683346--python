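"""Image preprocessing: segmentation, drift and photobleach correction, and
extraction of the normalized accumulation time series.

The processing chain mirrors what a microirradiation experiment needs before
any model fitting can happen:

1. segment the nucleus from the (pre-damage) protein channel,
2. estimate and remove lateral drift of the nucleus in the camera frame,
3. rescale every frame so the total nuclear intensity is conserved
   (photobleach correction): ``s(t) = I_o / I_net(t)``,
4. sum the corrected intensity inside the damage ROI and normalize by the
   pre-damage average to obtain the fold-increase curve ``I_exp(t)``.

Drift is estimated against the *initial* frame by cross-correlation in
Fourier space and applied as integer-pixel translations; rotations and
nuclear deformation are out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label
from skimage.registration import phase_cross_correlation

from .exceptions import NormalizationError, SegmentationError, ValidationError
from .stack_io import ImageStack, PixelMask

__all__ = [
    "BleachScaling",
    "DriftTrack",
    "AccumulationSeries",
    "segment_nucleus",
    "estimate_drift",
    "apply_drift_correction",
    "bleach_correct",
    "adjust_roi",
    "extract_series",
]

logger = logging.getLogger(__name__)


@dataclass
class BleachScaling:
    """Per-frame photobleach scaling.

    ``I_o`` is the frame-averaged total nuclear intensity over the reference
    (pre-damage) frames; ``I_net[t]`` the total nuclear intensity at frame
    ``t``; ``s[t] = I_o / I_net[t]`` the multiplicative correction applied to
    any intensity measured at frame ``t``.
    """

    I_o: float
    I_net: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        self.I_net = np.asarray(self.I_net, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.I_o <= 0:
            raise ValidationError("reference intensity I_o must be > 0")
        if self.I_net.shape != self.s.shape:
            raise ValidationError("I_net and s must have one entry per frame")

    @classmethod
    def identity(cls, n_frames: int, I_o: float = 1.0) -> "BleachScaling":
        """A no-op scaling (s ≡ 1), useful to bypass bleach correction."""
        return cls(I_o=I_o, I_net=np.full(n_frames, I_o), s=np.ones(n_frames))


@dataclass
class DriftTrack:
    """Integer ``(dy, dx)`` displacement of each frame relative to frame 0."""

    shifts: np.ndarray

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=int)
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 2:
            raise ValidationError("shifts must be an (n_frames, 2) array of (dy, dx)")
        if np.any(self.shifts[0] != 0):
            raise ValidationError("the reference (initial) frame must have shift (0, 0)")

    def __len__(self) -> int:
        return self.shifts.shape[0]


@dataclass
class AccumulationSeries:
    """Bleach-corrected, pre-damage-normalized ROI intensity time series.

    ``times`` are in seconds relative to damage onset (pre-damage frames are
    negative).  ``I_prime`` is the bleach-corrected ROI intensity I'(t);
    ``I_norm`` is I'(t) divided by its pre-damage average — the fold-increase
    curve the diffusion model is fitted to.
    """

    times: np.ndarray
    I_prime: np.ndarray
    I_norm: np.ndarray
    n_pre_damage_frames: int = 1
    raw: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.I_prime = np.asarray(self.I_prime, dtype=float)
        self.I_norm = np.asarray(self.I_norm, dtype=float)
        if not (len(self.times) == len(self.I_prime) == len(self.I_norm)):
            raise ValidationError("times, I_prime and I_norm must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if self.raw is not None:
            self.raw = np.asarray(self.raw, dtype=float)

    @property
    def post_damage(self) -> np.ndarray:
        """Boolean selector for timepoints at or after damage onset."""
        return self.times >= 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "frame": np.arange(len(self.times)),
                "time_s": self.times,
                "bleach_corrected": self.I_prime,
                "normalized": self.I_norm,
            }
        )
        if self.raw is not None:
            df.insert(2, "raw", self.raw)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_pre_damage_frames: int | None = None) -> "AccumulationSeries":
        df = pd.read_csv(path)
        for col in ("time_s", "bleach_corrected", "normalized"):
            if col not in df.columns:
                raise ValidationError(f"{path}: time-series CSV missing column {col!r}")
        if n_pre_damage_frames is None:
            n_pre_damage_frames = int(np.count_nonzero(df["time_s"].to_numpy() < 0))
        return cls(
            times=df["time_s"].to_numpy(),
            I_prime=df["bleach_corrected"].to_numpy(),
            I_norm=df["normalized"].to_numpy(),
            n_pre_damage_frames=max(n_pre_damage_frames, 1),
            raw=df["raw"].to_numpy() if "raw" in df.columns else None,
        )


def segment_nucleus(stack: ImageStack, reference_frames: int | None = None) -> PixelMask:
    """Segment the nuclear outline from the pre-damage frames.

    The reference frames are averaged, Gaussian-smoothed (sigma = 2 px) and
    thresholded with Otsu's method; the largest connected component is kept
    and its holes filled.  Two foreground components of exactly equal size
    are ambiguous and raise instead of guessing.
    """
    if reference_frames is None:
        reference_frames = stack.n_pre_damage_frames
    if reference_frames < 1 or reference_frames > stack.n_pre_damage_frames:
        raise ValidationError(
            "reference_frames must be between 1 and n_pre_damage_frames "
            f"({stack.n_pre_damage_frames}); got {reference_frames}"
        )
    reference = stack.frames[:reference_frames].mean(axis=0)
    if not np.any(reference > 0):
        raise SegmentationError("no foreground found: reference frames are blank")
    smoothed = gaussian(reference, sigma=2, preserve_range=True)
    try:
        thresh = threshold_otsu(smoothed)
    except ValueError as exc:  # constant image
        raise SegmentationError("no foreground found: reference image is constant") from exc
    fg = smoothed > thresh
    if not fg.any():
        raise SegmentationError("no foreground found above Otsu threshold")
    labels, n_components = label(fg, return_num=True)
    sizes = np.bincount(labels.ravel())[1:]
    order = np.argsort(sizes)[::-1]
    if n_components > 1 and sizes[order[0]] == sizes[order[1]]:
        raise SegmentationError(
            "ambiguous segmentation: two equal-size foreground components; "
            "select the nucleus manually"
        )
    grid = labels == (order[0] + 1)
    grid = ndimage.binary_fill_holes(grid)
    if grid.sum() == 0 or grid.sum() >= grid.size:
        raise SegmentationError("segmented nucleus must cover part, not all, of the frame")
    return PixelMask(grid=grid, role="nucleus")


def estimate_drift(stack: ImageStack) -> DriftTrack:
    """Estimate per-frame lateral drift against the initial frame.

    Translations are found from the peak of the cross-correlation between
    frame 0 and each subsequent frame, computed in Fourier space, at
    integer-pixel resolution.  ``shifts[k]`` is the (dy, dx) displacement of
    frame k's content relative to frame 0.
    """
    shifts = np.zeros((stack.n_frames, 2), dtype=int)
    reference = stack.frames[0]
    for k in range(1, stack.n_frames):
        # phase_cross_correlation returns the shift that registers the moving
        # frame onto the reference, i.e. minus the content displacement.
        registration, _, _ = phase_cross_correlation(
            reference, stack.frames[k], upsample_factor=1, normalization=None
        )
        shifts[k] = -np.round(registration).astype(int)
    return DriftTrack(shifts=shifts)


def _translate(frame: np.ndarray, dy: int, dx: int) -> tuple[np.ndarray, np.ndarray]:
    """Shift frame content by (-dy, -dx), zero-filling vacated pixels.

    Returns the translated frame and a boolean grid of pixels that carry
    real (non-fill) data.
    """
    rows, cols = frame.shape
    out = np.zeros_like(frame)
    valid = np.zeros(frame.shape, dtype=bool)
    src_r = slice(max(dy, 0), rows + min(dy, 0))
    src_c = slice(max(dx, 0), cols + min(dx, 0))
    # destination index = source index - (dy, dx)
    dst_r = slice(src_r.start - dy, src_r.stop - dy)
    dst_c = slice(src_c.start - dx, src_c.stop - dx)
    out[dst_r, dst_c] = frame[src_r, src_c]
    valid[dst_r, dst_c] = True
    return out, valid


def apply_drift_correction(stack: ImageStack, track: DriftTrack) -> ImageStack:
    """Translate each frame by the negative of its estimated shift.

    The nucleus becomes stationary in the camera frame so the fixed damage
    ROI stays registered with the physically damaged chromatin.  Edge pixels
    vacated by the translation are zero-filled and flagged invalid in the
    returned stack so downstream nuclear sums can exclude them.
    """
    if len(track) != stack.n_frames:
        raise ValidationError(
            f"drift track length {len(track)} != frame count {stack.n_frames}"
        )
    rows, cols = stack.frame_shape
    if np.any(np.abs(track.shifts[:, 0]) >= rows) or np.any(
        np.abs(track.shifts[:, 1]) >= cols
    ):
        raise ValidationError("drift shifts exceed the frame dimensions")
    frames = np.empty_like(stack.frames)
    valid = np.empty(stack.frames.shape, dtype=bool)
    for k in range(stack.n_frames):
        dy, dx = track.shifts[k]
        frames[k], valid[k] = _translate(stack.frames[k], int(dy), int(dx))
    return ImageStack(
        frames=frames,
        pixel_size_nm=stack.pixel_size_nm,
        frame_interval_s=stack.frame_interval_s,
        n_pre_damage_frames=stack.n_pre_damage_frames,
        damage_frame_index=stack.damage_frame_index,
        valid=valid,
    )


def bleach_correct(
    stack: ImageStack, nucleus: PixelMask, reference_frames: int | None = None
) -> BleachScaling:
    """Compute the per-frame photobleach scaling factors.

    Assumes the total number of fluorescent molecules in the nucleus is
    constant over the experiment, so any decline of the summed nuclear
    intensity ``I_net(t)`` is bleaching to be divided out:
    ``s(t) = I_o / I_net(t)`` with ``I_o`` the reference-frame average.
    Pixels invalidated by drift correction are excluded from the sums.
    """
    if reference_frames is None:
        reference_frames = stack.n_pre_damage_frames
    if reference_frames < 1:
        raise ValidationError("reference_frames must be >= 1")
    if nucleus.area == 0:
        raise ValidationError("nucleus mask is empty")
    n = stack.n_frames
    I_net = np.empty(n)
    for t in range(n):
        sel = nucleus.grid & stack.valid_at(t)
        clipped = nucleus.area - int(np.count_nonzero(sel))
        if clipped > 0.01 * nucleus.area:
            logger.warning(
                "frame %d: %.1f%% of nuclear pixels translated out of frame",
                t,
                100.0 * clipped / nucleus.area,
            )
        I_net[t] = stack.frames[t][sel].sum()
        if I_net[t] == 0:
            raise ValidationError(f"empty nuclear signal at frame {t}")
    I_o = float(I_net[:reference_frames].mean())
    return BleachScaling(I_o=I_o, I_net=I_net, s=I_o / I_net)


def adjust_roi(roi: PixelMask, x_adjust: int = 0, y_adjust: int = 0) -> PixelMask:
    """Grow (positive) or shrink (negative) the ROI along each axis.

    Each ROI edge along X is moved outward by ``x_adjust`` pixels (inward if
    negative), and likewise along Y — e.g. ``y_adjust=+10`` turns a 10-px
    stripe into a 30-px stripe.  Used to absorb edge effects of the
    irradiated region.  The result is clipped to the image bounds.
    """
    grid = roi.grid
    for adjust, axis in ((y_adjust, 0), (x_adjust, 1)):
        if adjust == 0:
            continue
        size = 2 * abs(int(adjust)) + 1
        structure = np.ones((size, 1) if axis == 0 else (1, size), dtype=bool)
        if adjust > 0:
            grid = ndimage.binary_dilation(grid, structure=structure)
        else:
            grid = ndimage.binary_erosion(grid, structure=structure)
    if not grid.any():
        raise ValidationError(
            f"ROI adjustment (x={x_adjust}, y={y_adjust}) left no pixels"
        )
    return PixelMask(grid=grid, role=roi.role)


def extract_series(
    stack: ImageStack,
    nucleus: PixelMask,
    roi: PixelMask,
    scaling: BleachScaling,
) -> AccumulationSeries:
    """Extract the normalized fold-increase curve from the damage region.

    The raw ROI intensity ``I(t)`` is summed over ``roi ∩ nucleus`` (valid
    pixels only), bleach-corrected to ``I'(t) = s(t)·I(t)``, and divided by
    the pre-damage average of I' so the pre-damage level is 1 by
    construction.
    """
    if roi.grid.shape != nucleus.grid.shape:
        raise ValidationError("ROI and nucleus masks must share dimensions")
    region = roi.grid & nucleus.grid
    if not region.any():
        raise ValidationError("ROI does not intersect the nucleus")
    if len(scaling.s) != stack.n_frames:
        raise ValidationError("bleach scaling must have one factor per frame")
    n = stack.n_frames
    raw = np.empty(n)
    for t in range(n):
        raw[t] = stack.frames[t][region & stack.valid_at(t)].sum()
    I_prime = scaling.s * raw
    n_pre = stack.n_pre_damage_frames
    pre_mean = I_prime[:n_pre].mean()
    if pre_mean == 0:
        raise NormalizationError("pre-damage ROI intensity averages to zero")
    return AccumulationSeries(
        times=stack.times_from_damage(),
        I_prime=I_prime,
        I_norm=I_prime / pre_mean,
        n_pre_damage_frames=n_pre,
        raw=raw,
    )
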