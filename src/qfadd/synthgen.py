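"""Synthetic microirradiation fixtures with known ground truth.

Generates image stacks (and fast, render-free accumulation series) whose
dynamics come from the package's own diffusion forward model, so every stage
of the pipeline — segmentation, drift and bleach correction, series
extraction, grid-search fitting — can be validated against known
``(D_eff, F)`` truth without any microscope data.

A generated stack is a bright nucleus-shaped particle cloud on a dark
background: pre-damage frames show the initial uniform particle positions;
from the damage frame onward particles evolve under the absorbing-trap
random walk.  Each frame renders particles as single-pixel intensity
deposits blurred by a Gaussian PSF (sigma = 1 px), then applies a cumulative
photobleach factor, a cumulative lateral drift translation, and optional
Poisson photon noise plus Gaussian read noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .diffusion import SimParams, init_particles, simulate, step_particles
from .exceptions import ValidationError
from .preprocess import AccumulationSeries
from .stack_io import ImageStack, PixelMask, write_mask, write_stack

__all__ = ["SynthSpec", "make_masks", "generate_series", "generate_stack", "write_fixture"]


@dataclass
class SynthSpec:
    """Ground-truth recipe for one synthetic nucleus.

    Defaults mirror a typical striping experiment: 6 pre-damage frames,
    86.77 nm pixels, a full-width stripe ROI across the nucleus, and a
    0.2 s Monte Carlo timestep.
    """

    image_shape: tuple[int, int] = (121, 161)
    nucleus_shape: str = "ellipse"
    nucleus_center: tuple[int, int] = (60, 80)
    nucleus_radii: tuple[int, int] = (48, 68)
    roi_geometry: str = "stripe"  # or "speckle"
    roi_stripe_height: int = 12
    roi_speckle_radius: int = 8
    roi_center: tuple[int, int] | None = None
    true_delta_x: int = 8
    true_F_ppt: int = 300
    delta_t: float = 0.2
    frame_interval_s: float = 2.0
    n_pre_frames: int = 6
    n_post_frames: int = 30
    pixel_size_nm: float = 86.77
    drift_per_frame: tuple[float, float] = (0.0, 0.0)
    bleach_rate: float = 0.0  # fractional intensity loss per frame
    poisson_noise: bool = False
    read_noise_sigma: float = 0.0
    particle_brightness: float = 100.0
    n_particles: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nucleus_shape != "ellipse":
            raise ValidationError("only elliptical nuclei are implemented")
        if self.roi_geometry not in ("stripe", "speckle"):
            raise ValidationError("roi_geometry must be 'stripe' or 'speckle'")
        if not 0 <= self.bleach_rate < 1:
            raise ValidationError("bleach_rate must lie in [0, 1)")
        if self.n_pre_frames < 1 or self.n_post_frames < 2:
            raise ValidationError("need >=1 pre-damage and >=2 post-damage frames")

    @property
    def n_frames(self) -> int:
        return self.n_pre_frames + self.n_post_frames

    @property
    def damage_frame_index(self) -> int:
        return self.n_pre_frames

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    def post_times(self) -> np.ndarray:
        """Post-damage frame times in s (0 at damage onset)."""
        return np.arange(self.n_post_frames, dtype=float) * self.frame_interval_s

    def frame_times(self) -> np.ndarray:
        return (
            np.arange(self.n_frames, dtype=float) - self.damage_frame_index
        ) * self.frame_interval_s


def make_masks(spec: SynthSpec) -> tuple[PixelMask, PixelMask]:
    """Ground-truth nucleus and ROI masks for a spec."""
    rows, cols = spec.image_shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    cy, cx = spec.nucleus_center
    ry, rx = spec.nucleus_radii
    nucleus = ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0
    roi_center = spec.roi_center if spec.roi_center is not None else spec.nucleus_center
    if spec.roi_geometry == "stripe":
        half = spec.roi_stripe_height / 2.0
        roi = (rr >= roi_center[0] - half) & (rr < roi_center[0] + half)
    else:
        roi = (rr - roi_center[0]) ** 2 + (cc - roi_center[1]) ** 2 <= spec.roi_speckle_radius**2
    return PixelMask(grid=nucleus, role="nucleus"), PixelMask(grid=roi, role="roi")


def _sim_params(spec: SynthSpec, n_iterations: int) -> SimParams:
    return SimParams(
        delta_x=spec.true_delta_x,
        F_ppt=spec.true_F_ppt,
        delta_t=spec.delta_t,
        pixel_size_um=spec.pixel_size_um,
        n_particles=spec.n_particles,
        n_iterations=n_iterations,
        seed=spec.seed,
    )


def generate_series(
    spec: SynthSpec, noise_sigma: float = 0.0, noise_seed: int | None = None
) -> tuple[AccumulationSeries, dict]:
    """Render-free accumulation series straight from the diffusion model.

    The normalized trap-count trajectory at the true parameters is sampled
    at the post-damage frame times; pre-damage points are exactly 1.
    ``noise_sigma`` adds Gaussian noise (in normalized-intensity units) to
    the post-damage points only, emulating measurement scatter on the
    fold-increase curve.  Returns the series and a ground-truth record.
    """
    duration = spec.post_times().max()
    n_iter = max(1, int(math.ceil(duration / spec.delta_t)))
    traj = simulate(*make_masks(spec), _sim_params(spec, n_iter))
    post = np.interp(spec.post_times(), traj.iteration_times, traj.normalized)
    clean = np.concatenate([np.ones(spec.n_pre_frames), post])
    values = clean.copy()
    if noise_sigma > 0:
        rng = np.random.default_rng(spec.seed + 1 if noise_seed is None else noise_seed)
        values[spec.n_pre_frames :] += rng.normal(0.0, noise_sigma, spec.n_post_frames)
    series = AccumulationSeries(
        times=spec.frame_times(),
        I_prime=values,
        I_norm=values,
        n_pre_damage_frames=spec.n_pre_frames,
    )
    truth = {
        "true_delta_x": spec.true_delta_x,
        "true_F_ppt": spec.true_F_ppt,
        "initial_roi_count": traj.initial_roi_count,
        "clean_normalized": clean,
        "trajectory": traj,
    }
    return series, truth


def _render(
    positions: np.ndarray, spec: SynthSpec, frame_idx: int, shift: tuple[int, int]
) -> np.ndarray:
    rows, cols = spec.image_shape
    img = np.zeros((rows, cols))
    np.add.at(img, (positions[:, 0], positions[:, 1]), spec.particle_brightness)
    img = ndimage.gaussian_filter(img, sigma=1.0)
    img *= (1.0 - spec.bleach_rate) ** frame_idx
    dy, dx = shift
    if dy or dx:
        shifted = np.zeros_like(img)
        src_r = slice(max(-dy, 0), rows - max(dy, 0))
        src_c = slice(max(-dx, 0), cols - max(dx, 0))
        shifted[
            slice(src_r.start + dy, src_r.stop + dy),
            slice(src_c.start + dx, src_c.stop + dx),
        ] = img[src_r, src_c]
        img = shifted
    return img


def _cumulative_shift(spec: SynthSpec, frame_idx: int) -> tuple[int, int]:
    dy = spec.drift_per_frame[0] * frame_idx
    dx = spec.drift_per_frame[1] * frame_idx
    rnd = lambda v: int(math.floor(v + 0.5)) if v >= 0 else -int(math.floor(-v + 0.5))
    return rnd(dy), rnd(dx)


def generate_stack(spec: SynthSpec) -> tuple[ImageStack, PixelMask, dict]:
    """Render a full synthetic image stack.

    Returns ``(stack, roi_mask, truth)`` where ``truth`` records the true
    nucleus mask, per-frame noise-free trap counts, per-frame cumulative
    integer drift shifts, and the generating spec.
    """
    nucleus, roi = make_masks(spec)
    # the drifted nucleus must stay inside the field of view
    coords = np.argwhere(nucleus.grid)
    final = np.array(_cumulative_shift(spec, spec.n_frames - 1))
    lo = coords.min(axis=0) + np.minimum(final, 0)
    hi = coords.max(axis=0) + np.maximum(final, 0)
    if (lo < 0).any() or (hi >= np.array(spec.image_shape)).any():
        raise ValidationError("drift pushes the nucleus outside the image frame")

    rng = np.random.default_rng(spec.seed)
    steps_per_frame = max(1, int(round(spec.frame_interval_s / spec.delta_t)))
    n_iter_total = steps_per_frame * (spec.n_post_frames - 1)
    state = init_particles(nucleus, roi, _sim_params(spec, max(1, n_iter_total)), rng)
    trap = PixelMask(grid=nucleus.grid & roi.grid, role="roi")

    frames = np.empty((spec.n_frames, *spec.image_shape))
    trap_counts = np.empty(spec.n_frames, dtype=int)
    shifts = np.zeros((spec.n_frames, 2), dtype=int)
    noise_rng = np.random.default_rng(spec.seed + 7919)
    for k in range(spec.n_frames):
        if k > spec.damage_frame_index:
            for _ in range(steps_per_frame):
                state = step_particles(state, nucleus, trap, spec.true_delta_x, rng)
        shifts[k] = _cumulative_shift(spec, k)
        img = _render(state.positions, spec, k, tuple(shifts[k]))
        if spec.poisson_noise:
            img = noise_rng.poisson(np.clip(img, 0, None)).astype(float)
        if spec.read_noise_sigma > 0:
            img = img + noise_rng.normal(0.0, spec.read_noise_sigma, img.shape)
        frames[k] = np.clip(img, 0.0, None)
        trap_counts[k] = int(np.count_nonzero(state.trapped))
    stack = ImageStack(
        frames=frames,
        pixel_size_nm=spec.pixel_size_nm,
        frame_interval_s=spec.frame_interval_s,
        n_pre_damage_frames=spec.n_pre_frames,
        damage_frame_index=spec.damage_frame_index,
    )
    truth = {
        "spec": spec,
        "nucleus": nucleus,
        "trap_counts": trap_counts,
        "initial_roi_count": int(trap_counts[spec.damage_frame_index]),
        "shifts": shifts,
    }
    return stack, roi, truth


def write_fixture(spec: SynthSpec, outdir: str | Path) -> dict[str, Path]:
    """Write a stack + ROI + ground-truth CSV fixture set to disk."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stack, roi, truth = generate_stack(spec)
    paths = {
        "stack": outdir / "stack.tif",
        "roi": outdir / "roi.tif",
        "truth": outdir / "ground_truth.csv",
        "nucleus": outdir / "true_nucleus.tif",
    }
    write_stack(stack, paths["stack"])
    write_mask(roi, paths["roi"])
    write_mask(truth["nucleus"], paths["nucleus"])
    pd.DataFrame(
        {
            "frame": np.arange(spec.n_frames),
            "time_s": spec.frame_times(),
            "trap_count": truth["trap_counts"],
            "shift_dy": truth["shifts"][:, 0],
            "shift_dx": truth["shifts"][:, 1],
            "true_delta_x": spec.true_delta_x,
            "true_F_ppt": spec.true_F_ppt,
        }
    ).to_csv(paths["truth"], index=False)
    return paths
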