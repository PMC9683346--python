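# Methods

## The measurement being modeled

In a laser-microirradiation experiment a focused ~405 nm laser damages a
defined region of chromatin (the ROI) inside the nucleus of a live cell
expressing a fluorescently tagged DNA-repair protein. The tagged protein
accumulates at the damage site, and the time course of the ROI fluorescence —
normalized to its pre-damage level — is the experimental readout, the
fold-increase curve `I_exp(t)`.

Rather than summarizing `I_exp(t)` with a half-time or exponential fit, the
package fits it with an explicit free-diffusion simulation on the *measured
nuclear geometry*, which makes the resulting parameters comparable across
nuclei of different shapes and with orthogonal diffusion measurements
(FRAP, FCS). Two parameters describe each nucleus:

- **D_eff** (μm²/s): the effective diffusion coefficient. "Effective"
  because the observed motion convolves true diffusion with fast
  binding/unbinding; no attempt is made to separate the two.
- **F** (parts per thousand): the mobile fraction — the proportion of the
  tagged population free to reach the damage site. The remainder is
  stationary (e.g. tightly chromatin-bound, or simply in excess of the
  available damage).

## Preprocessing

1. **Segmentation** — the pre-damage frames are averaged, smoothed
   (Gaussian, σ = 2 px), thresholded with Otsu's method; the largest
   connected component is kept and holes filled. The protein channel
   itself provides a quasi-uniform nuclear outline when the protein is
   overexpressed and nuclear-localized. Two equal-size foreground
   components raise an error rather than guessing — nucleus selection is
   ultimately the experimenter's responsibility.
2. **Drift correction** — lateral motion of the nucleus mimics dissipation
   from the fixed camera ROI. Per-frame translations are estimated from the
   peak of the cross-correlation (computed in Fourier space) between the
   initial frame and each later frame, at integer-pixel resolution, and
   removed by integer translation with zero fill. Integer resolution keeps
   the stack aligned with the pixel masks exactly; rotations and nuclear
   deformation are not corrected and such nuclei should be excluded.
   Vacated edge pixels are flagged invalid and excluded from nuclear sums
   (a warning is logged if they exceed 1% of the nucleus), so the
   translation itself cannot masquerade as bleaching.
3. **Photobleach correction** — assuming the total number of fluorophores
   in the nucleus is constant, each frame is rescaled by
   `s(t) = I_o / I_net(t)`, where `I_net(t)` is the summed nuclear
   intensity at frame `t` and `I_o` its average over the pre-damage
   reference frames (default 6).
4. **ROI adjustment** — the damage ROI can be grown or shrunk per edge and
   per axis (defaults −10 px in X, +10 px in Y) to absorb edge effects of
   the irradiated stripe.
5. **Series extraction** — `I(t)` is the corrected intensity summed over
   `roi ∩ nucleus`; dividing by the pre-damage mean gives `I_exp(t)` with a
   pre-damage level of exactly 1. Times are reported relative to damage
   onset, defined as the first post-irradiation frame.

## The diffusion model

`n_particles` point molecules (default 10,000) start uniformly distributed
over the nuclear pixel grid; `round(n·F/1000)` of them are mobile. Each
iteration (timestep Δt, default 0.2 s) every mobile, untrapped particle
hops `(±Δx, ±Δx)` pixels with independent equiprobable signs. A hop whose
destination lies outside the nuclear mask is rejected wholesale (the
particle waits); a particle landing in `roi ∩ nucleus` is trapped there
permanently. Occupancy of the trap region, divided by the pre-motion
occupancy, is the simulated analogue of `I_exp`.

Because both axes move every iteration, the per-iteration mean squared
displacement is `2Δx²` px², so

    D_eff = (Δx · p)² / (2 · Δt)

with `p` the pixel size in μm. At `p = 0.08677` μm and `Δt = 0.2` s the
step range 1–15 px/iteration spans D_eff ≈ 0.019–4.24 μm²/s.

Deliberate simplifications, inherited from the model's scope:

- **No dissipation**: the trap is absorbing, so only the accumulation phase
  is modeled; proteins that detectably leave the damage site within the
  acquisition window should not be fit with this model.
- **Landing-pixel rule**: only the destination pixel is checked against
  mask and trap; a large Δx can step across a thin trap stripe without
  being captured. An alternative per-axis rejection rule is available in
  `step_particles`-style stepping for sensitivity checks but the composite
  move is the default and the calibrated one.
- **Parity**: the composite `(±Δx, ±Δx)` move preserves the parity of
  `row+col` (and of each axis separately for even Δx), so a single
  particle samples only one sublattice. Full-width stripe ROIs contain
  both parities and are unaffected; very small speckle ROIs (a few pixels)
  should be grown via the ROI adjustment so both sublattices are
  represented.
- 2D only; uniform initial distribution.

## Grid search and scoring

The user defines grids of Δx (default 1–15 px/iteration) and F (default
100–1000 ppt in steps of 100). Each grid point is simulated
`n_replicates = 11` times with deterministic seeds `base_seed + i`;
grid points are fully independent tasks, so serial and parallel schedules
give bit-identical catalogs. Each trajectory is linearly interpolated to
the experimental timepoints and compared with `I_exp` by

    RMSD = sqrt( (1/N) Σ (I_qFADD(tᵢ) − I_exp(tᵢ))² )

and by the coefficient of determination r². Both metrics are computed over
post-damage timepoints only: the pre-damage points equal 1 by construction
and would inflate the apparent fit quality (this windowing is switchable).
The representative model of a grid point is the replicate with the median
RMSD (lower median for even counts, so the representative is always an
actual replicate curve); a pointwise-average readout is available and
agrees with the median readout on rankings for ≥10 replicates.

RMSD is the primary ranking key: on the same representative curves r² is an
exactly monotone (decreasing) transform of RMSD — `r² = 1 − N·RMSD²/SS_tot`
— so the two rankings always agree, but RMSD, being in normalized-intensity
units, separates near-perfect models far better than r² values crowding 1.
Ties are broken by higher r², then smaller Δx, then smaller F, making the
catalog order a deterministic total order. A failing grid point (e.g. an
ROI too small to receive any initialized particle) is recorded and skipped.
The r² choice of "coefficient of determination" (not squared Pearson
correlation) is a package decision; it penalizes scale offsets, which is
what distinguishes wrong-plateau models.

## Cohorts

Each nucleus contributes its best-ranked (D_eff, F). A cohort is summarized
by mean ± SEM (SEM with n−1 degrees of freedom, undefined for n = 1). Two
cohorts are compared with Welch's unequal-variance t-test by default —
chosen because cohort sizes are small and variances visibly unequal —
with Mann–Whitney U as a distribution-free alternative. Violin plots show
the per-nucleus values with mean ± SEM annotations; a single-nucleus group
is drawn as a point (no density from one value).

## Synthetic data generator

The generator exists so the entire pipeline is testable with known ground
truth and no microscope. It emulates:

- an elliptical nucleus rendered from the particle cloud itself (single-
  pixel deposits blurred by a σ = 1 px Gaussian PSF) — segmentation sees a
  realistic quasi-uniform outline;
- a full-width stripe ROI (striping mode) or a disk (speckle mode);
- particle dynamics taken *directly from the package's diffusion model*,
  so recovery tests close the loop generator → pipeline → estimates;
- optional lateral drift (float px/frame, applied as cumulative rounded
  integer translations), exponential photobleaching (fractional loss per
  frame), Poisson photon noise and Gaussian read noise.

Default conditions mirror a typical striping acquisition: 6 pre-damage
frames, 86.77 nm pixels, Δt = 0.2 s, 2 s frame interval, 30 post-damage
frames (≈1 min of accumulation), 10,000 particles, a 121×161 px field with
an ellipse of semi-axes 48×68 px and a 12 px damage stripe through its
center. What it does **not** emulate: chromatin texture, nuclear blebs,
rotation or deformation, camera-specific noise calibration, 3D PSFs —
passing tests therefore demonstrate correctness of the algorithms, not
robustness to every real-microscope pathology.

`generate_series` bypasses rendering and returns the exact normalized
trap-count curve at the frame times (optionally plus additive Gaussian
noise on the post-damage points), which is what the fast grid-search tests
use; `generate_stack` renders full frames for the preprocessing tests.

## Numerical and design choices

- Coordinates are 0-based `(row, col)`, row 0 at the top, everywhere.
- Mobile-count rounding is round-half-away-from-zero of `n·F/1000`.
- Mobile particles initialized inside the trap are trapped from iteration
  0; immobile particles inside the ROI count toward occupancy throughout.
- Replicate seeds are `base_seed + replicate_index`; a simulation is
  bit-reproducible from (inputs, seed).
- The simulated time origin coincides with the damage frame; a run covers
  `ceil(t_max / Δt)` iterations so interpolation never extrapolates.
- Catalog formatting: D_eff to 4 significant figures, r² and RMSD to 4
  decimal places.
- Verification problem sizes: the recovery studies simulate the full
  15×10 grid with 11 replicates of 2,000 particles against truth curves
  generated at 10,000 particles; the Markov-chain cross-check uses 200
  seeds of 2,000 fully mobile particles on an 11×11 grid, compared with
  exact absorbing-chain propagation of the single-particle distribution.
  At 2,000 particles per replicate the replicate-to-replicate scatter is
  noticeably wider than at the 10,000-particle default; the grid-search
  median readout is what keeps the recovered optimum stable at the reduced
  count.

## Known limitations

- Integer-pixel drift correction cannot remove sub-pixel drift; residual
  sub-pixel motion appears as slight blurring of the accumulation edge.
- The bleach correction assumes conservation of total nuclear fluorophores;
  import/export across the nuclear envelope during acquisition violates it.
- Replicate RMSD spread scales like `plateau / sqrt(n_particles · a/A)`
  (`a/A` the ROI fraction of the nucleus): narrow-ROI speckle experiments
  need more particles for the same fit stability as striping experiments.
- The grid search is exhaustive, not adaptive; the mobile fraction should
  be refined by re-running a focused grid (e.g. 10–25 ppt resolution)
  around the coarse optimum rather than by fitting at 1 ppt globally,
  which overfits typical data.
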