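"""Monte Carlo free-diffusion model on the nuclear pixel grid.

The recruitment of a tagged protein to the damage region is modeled as free
diffusion of point particles on the pixel lattice of the nuclear mask.  A
population of ``n_particles`` molecules starts uniformly distributed over the
nucleus; only the mobile fraction ``F`` (in parts per thousand) moves.  Each
iteration every mobile, untrapped particle makes a composite hop of
``(±Δx, ±Δx)`` pixels with independent equiprobable signs; a hop whose
destination falls outside the nuclear envelope is rejected outright
(reflecting-by-rejection boundary), and a particle landing inside the damage
region ``roi ∩ nucleus`` is trapped there permanently (absorbing trap).  The
model describes accumulation only — dissipation after repair is outside it.

Because both axes step every iteration with fixed magnitude ``Δx``, the
per-iteration mean squared displacement is ``2·Δx²`` pixels², giving the
effective diffusion coefficient

    D_eff = (Δx · p)² / (2 · Δt)

with ``p`` the pixel size (μm) and ``Δt`` the iteration timestep (s).
``D_eff`` is "effective" because experimentally observed motion convolves
true diffusion with fast binding/unbinding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .stack_io import PixelMask

__all__ = [
    "SimParams",
    "ParticleState",
    "Trajectory",
    "deff_from_step",
    "step_from_deff",
    "init_particles",
    "step_particles",
    "simulate",
]


def deff_from_step(delta_x: float, pixel_size_um: float, delta_t: float) -> float:
    """Effective diffusion coefficient (μm²/s) for a grid step size.

    ``D_eff = (Δx·p)²/(2Δt)``; a step size of 0 yields 0 (no motion).
    """
    if pixel_size_um <= 0:
        raise ValidationError("pixel_size_um must be > 0")
    if delta_t <= 0:
        raise ValidationError("delta_t must be > 0")
    if delta_x < 0:
        raise ValidationError("delta_x must be >= 0")
    return (delta_x * pixel_size_um) ** 2 / (2.0 * delta_t)


def step_from_deff(deff: float, pixel_size_um: float, delta_t: float) -> int:
    """Inverse of :func:`deff_from_step`, rounded to the nearest integer step."""
    if pixel_size_um <= 0:
        raise ValidationError("pixel_size_um must be > 0")
    if delta_t <= 0:
        raise ValidationError("delta_t must be > 0")
    if deff < 0:
        raise ValidationError("deff must be >= 0")
    return int(round(math.sqrt(2.0 * deff * delta_t) / pixel_size_um))


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class SimParams:
    """Parameters of one diffusion simulation.

    ``delta_x`` in pixels/iteration, ``F_ppt`` the mobile fraction in parts
    per thousand (0–1000), ``delta_t`` the iteration timestep in seconds,
    ``pixel_size_um`` the camera resolution.  ``n_particles`` defaults to
    10,000 — enough for reproducible occupancy curves (fewer than ~1,000 is
    not; more mainly reduces residual noise).
    """

    delta_x: int
    F_ppt: int
    delta_t: float
    pixel_size_um: float
    n_particles: int = 10_000
    n_iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta_x < 0:
            raise ValidationError("delta_x must be >= 0")
        if not 0 <= self.F_ppt <= 1000:
            raise ValidationError("F_ppt must lie in [0, 1000]")
        if self.delta_t <= 0 or self.pixel_size_um <= 0:
            raise ValidationError("delta_t and pixel_size_um must be > 0")
        if self.n_particles < 1 or self.n_iterations < 1:
            raise ValidationError("n_particles and n_iterations must be >= 1")

    @property
    def deff_um2_s(self) -> float:
        return deff_from_step(self.delta_x, self.pixel_size_um, self.delta_t)

    @property
    def n_mobile(self) -> int:
        return _round_half_away(self.n_particles * self.F_ppt / 1000.0)


@dataclass
class ParticleState:
    """Positions and status flags of the simulated molecules."""

    positions: np.ndarray  # (n, 2) int (row, col)
    mobile: np.ndarray  # (n,) bool
    trapped: np.ndarray  # (n,) bool

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.mobile = np.asarray(self.mobile, dtype=bool)
        self.trapped = np.asarray(self.trapped, dtype=bool)
        n = self.positions.shape[0]
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValidationError("positions must be an (n, 2) array")
        if self.mobile.shape != (n,) or self.trapped.shape != (n,):
            raise ValidationError("mobile/trapped flags must be (n,) arrays")

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]


@dataclass
class Trajectory:
    """Per-iteration occupancy of the damage region.

    ``normalized`` is ``roi_counts / initial_roi_count`` — the simulated
    analogue of the experimental fold-increase curve (both series count
    relative to the pre-motion level).
    """

    iteration_times: np.ndarray
    roi_counts: np.ndarray
    initial_roi_count: int
    normalized: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(len(self.iteration_times)),
                "time_s": self.iteration_times,
                "count": self.roi_counts,
                "normalized": self.normalized,
            }
        )


def init_particles(
    nucleus: PixelMask,
    roi: PixelMask,
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> ParticleState:
    """Place particles uniformly at random over the nuclear grid.

    Exactly ``round(n·F/1000)`` particles (round-half-away-from-zero) are
    flagged mobile, chosen uniformly.  Any particle starting inside
    ``roi ∩ nucleus`` is trapped from iteration 0 — the damage region is
    absorbing for the entire simulation.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if nucleus.area == 0:
        raise ValidationError("nucleus mask is empty")
    trap = nucleus.grid & roi.grid
    if not trap.any():
        raise ValidationError("roi ∩ nucleus is empty: nothing can be trapped")
    coords = np.argwhere(nucleus.grid)
    idx = rng.integers(0, len(coords), size=params.n_particles)
    positions = coords[idx]
    mobile = np.zeros(params.n_particles, dtype=bool)
    if params.n_mobile > 0:
        mobile[rng.choice(params.n_particles, size=params.n_mobile, replace=False)] = True
    trapped = trap[positions[:, 0], positions[:, 1]]
    return ParticleState(positions=positions, mobile=mobile, trapped=trapped.copy())


def step_particles(
    state: ParticleState,
    nucleus: PixelMask,
    trap: PixelMask,
    delta_x: int,
    rng: np.random.Generator,
) -> ParticleState:
    """Advance every mobile, untrapped particle by one Monte Carlo iteration.

    Each such particle proposes a composite move of ``(±Δx, ±Δx)`` with the
    two signs drawn independently; if the destination pixel lies outside the
    nuclear mask the entire move is rejected and the particle stays put.
    Only the landing pixel is inspected — intermediate pixels are never
    checked, so a large step can jump across a thin trap.  Particles landing
    in the trap are trapped permanently.
    """
    positions = state.positions.copy()
    trapped = state.trapped.copy()
    active = state.mobile & ~trapped
    n_active = int(np.count_nonzero(active))
    if n_active and delta_x > 0:
        signs = rng.integers(0, 2, size=(n_active, 2)) * 2 - 1
        proposal = positions[active] + delta_x * signs
        rows, cols = nucleus.grid.shape
        inside = (
            (proposal[:, 0] >= 0)
            & (proposal[:, 0] < rows)
            & (proposal[:, 1] >= 0)
            & (proposal[:, 1] < cols)
        )
        dest = positions[active].copy()
        ok = np.zeros(n_active, dtype=bool)
        ok[inside] = nucleus.grid[proposal[inside, 0], proposal[inside, 1]]
        dest[ok] = proposal[ok]
        positions[active] = dest
        landed = trap.grid[dest[:, 0], dest[:, 1]]
        trapped_active = trapped[active]
        trapped_active |= landed
        trapped[active] = trapped_active
    return ParticleState(positions=positions, mobile=state.mobile, trapped=trapped)


def simulate(nucleus: PixelMask, roi: PixelMask, params: SimParams) -> Trajectory:
    """Run one seeded diffusion simulation and record trap occupancy.

    Returns a :class:`Trajectory` with ``n_iterations + 1`` samples (the
    initial configuration is iteration 0 at t = 0, coinciding with damage
    onset).  The occupancy count includes trapped mobile particles and
    immobile particles resident in the region; it is non-decreasing because
    the trap is absorbing and immobile particles never move.  Bit-identical
    given identical inputs and seed.
    """
    rng = np.random.default_rng(params.seed)
    trap_grid = nucleus.grid & roi.grid
    if not trap_grid.any():
        raise ValidationError("roi ∩ nucleus is empty")
    trap = PixelMask(grid=trap_grid, role="roi")
    state = init_particles(nucleus, roi, params, rng)
    # the trapped flag covers every particle in the region (mobile or not)
    initial = int(np.count_nonzero(state.trapped))
    if initial == 0:
        raise ValidationError(
            "no particles initialized inside roi ∩ nucleus; "
            "increase n_particles or enlarge the ROI"
        )

    # fast path: only mobile, untrapped particles evolve
    rows, cols = nucleus.grid.shape
    active_pos = state.positions[state.mobile & ~state.trapped]
    n_trapped = initial
    counts = np.empty(params.n_iterations + 1, dtype=np.int64)
    counts[0] = n_trapped
    dx = params.delta_x
    for it in range(1, params.n_iterations + 1):
        m = active_pos.shape[0]
        if m and dx > 0:
            signs = rng.integers(0, 2, size=(m, 2)) * 2 - 1
            proposal = active_pos + dx * signs
            inside = (
                (proposal[:, 0] >= 0)
                & (proposal[:, 0] < rows)
                & (proposal[:, 1] >= 0)
                & (proposal[:, 1] < cols)
            )
            ok = np.zeros(m, dtype=bool)
            ok[inside] = nucleus.grid[proposal[inside, 0], proposal[inside, 1]]
            active_pos = np.where(ok[:, None], proposal, active_pos)
            landed = trap_grid[active_pos[:, 0], active_pos[:, 1]]
            n_trapped += int(np.count_nonzero(landed))
            active_pos = active_pos[~landed]
        counts[it] = n_trapped
    times = np.arange(params.n_iterations + 1, dtype=float) * params.delta_t
    return Trajectory(
        iteration_times=times,
        roi_counts=counts,
        initial_roi_count=initial,
        normalized=counts / float(initial),
    )
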