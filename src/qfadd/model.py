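"""statsmodels-style model surface over the diffusion grid search.

``RecruitmentModel`` bundles an experimental accumulation series with the
nuclear and damage-region geometry; ``fit()`` runs the replicate grid search
and returns a ``RecruitmentResults`` carrying the ranked model catalog,
best-fit estimates, diagnostics and export/plot helpers.

Example
-------
>>> model = RecruitmentModel(series, nucleus, roi, pixel_size_um=0.08677)
>>> res = model.fit(delta_x_values=range(1, 16),
...                 F_values_ppt=range(100, 1001, 100))
>>> print(res.summary())
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import stack_io
from .exceptions import ValidationError
from .gridsearch import FitResult, GridResult, GridSpec, run_grid
from .preprocess import AccumulationSeries
from .stack_io import PixelMask

__all__ = ["RecruitmentModel", "RecruitmentResults"]


class RecruitmentModel:
    """Free-diffusion recruitment model for one nucleus.

    Parameters
    ----------
    series
        Bleach-corrected, normalized accumulation curve from preprocessing.
    nucleus, roi
        Pixel masks of the nuclear envelope and the damage region (camera
        frame, shared shape).
    pixel_size_um
        Camera resolution in μm/pixel.
    delta_t
        Monte Carlo timestep in seconds (default 0.2 s — about an order of
        magnitude finer than typical frame rates).
    n_particles
        Simulated molecules per replicate (default 10,000).
    """

    def __init__(
        self,
        series: AccumulationSeries,
        nucleus: PixelMask,
        roi: PixelMask,
        pixel_size_um: float,
        delta_t: float = 0.2,
        n_particles: int = 10_000,
    ) -> None:
        if nucleus.grid.shape != roi.grid.shape:
            raise ValidationError("nucleus and ROI masks must share dimensions")
        if not (nucleus.grid & roi.grid).any():
            raise ValidationError("ROI does not intersect the nucleus")
        if pixel_size_um <= 0 or delta_t <= 0:
            raise ValidationError("pixel_size_um and delta_t must be > 0")
        self.series = series
        self.nucleus = nucleus
        self.roi = roi
        self.pixel_size_um = pixel_size_um
        self.delta_t = delta_t
        self.n_particles = n_particles

    @classmethod
    def from_files(
        cls,
        series_csv: str | Path,
        nucleus_tif: str | Path,
        roi_tif: str | Path,
        pixel_size_um: float,
        **kwargs,
    ) -> "RecruitmentModel":
        """Build a model from preprocessing outputs on disk."""
        series = AccumulationSeries.from_csv(series_csv)
        import tifffile

        shape = tifffile.imread(nucleus_tif).shape
        nucleus = stack_io.read_nucleus_mask(nucleus_tif, shape)
        roi = stack_io.read_roi_mask(roi_tif, shape)
        return cls(series, nucleus, roi, pixel_size_um=pixel_size_um, **kwargs)

    def fit(
        self,
        delta_x_values: Iterable[int] = range(1, 16),
        F_values_ppt: Iterable[int] = range(100, 1001, 100),
        n_replicates: int = 11,
        readout: str = "median",
        base_seed: int = 0,
        n_jobs: int = 1,
    ) -> "RecruitmentResults":
        """Grid search over (Δx, F); returns ranked results."""
        spec = GridSpec(
            delta_x_values=list(delta_x_values),
            F_values_ppt=list(F_values_ppt),
            n_replicates=n_replicates,
            readout=readout,
            base_seed=base_seed,
            delta_t=self.delta_t,
            n_particles=self.n_particles,
            pixel_size_um=self.pixel_size_um,
        )
        grid = run_grid(self.series, self.nucleus, self.roi, spec, n_jobs=n_jobs)
        return RecruitmentResults(self, grid)


class RecruitmentResults:
    """Results of a fitted :class:`RecruitmentModel`."""

    def __init__(self, model: RecruitmentModel, grid: GridResult) -> None:
        self.model = model
        self.grid = grid

    # -- estimates -----------------------------------------------------
    @property
    def best(self) -> FitResult:
        return self.grid.best

    @property
    def D_eff_um2_s(self) -> float:
        return self.best.D_eff_um2_s

    @property
    def F_ppt(self) -> int:
        return self.best.F_ppt

    @property
    def r2(self) -> float:
        return self.best.r2

    @property
    def rmsd(self) -> float:
        return self.best.rmsd

    @property
    def catalog(self):
        """Ranked DataFrame of all sampled models (best first)."""
        return self.grid.to_frame()

    def heatmap_r2(self):
        return self.grid.heatmap_r2()

    def residuals(self) -> np.ndarray:
        """Best-model minus experiment at the fitted timepoints."""
        return self.best.representative_curve - self.grid.exp_values

    def summary(self) -> str:
        """Human-readable fit summary."""
        b = self.best
        spread = b.replicate_rmsds
        lines = [
            "Free-diffusion recruitment fit",
            "=" * 46,
            f"grid points sampled      {len(self.grid.results):>12d}",
            f"replicates per point     {self.grid.spec.n_replicates:>12d}",
            f"readout                  {self.grid.spec.readout:>12s}",
            f"fitted timepoints (N)    {b.n_timepoints:>12d}",
            "-" * 46,
            f"best step size (px/iter) {b.delta_x:>12d}",
            f"best D_eff (um^2/s)      {b.D_eff_um2_s:>12.4g}",
            f"best mobile fraction F   {b.F_ppt:>9d} ppt",
            f"r^2                      {b.r2:>12.4f}",
            f"RMSD                     {b.rmsd:>12.4f}",
            f"replicate RMSD range     [{spread.min():.4f}, {spread.max():.4f}]",
            "=" * 46,
        ]
        if self.grid.failures:
            lines.append(f"failed grid points: {len(self.grid.failures)}")
        return "\n".join(lines)

    # -- export --------------------------------------------------------
    def save(self, outdir: str | Path) -> None:
        """Write all_models.csv, best_model.csv and the r² heatmap CSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stack_io.write_model_catalog(self.grid, outdir / "all_models.csv")
        self.catalog.head(1).to_csv(outdir / "best_model.csv", index=False)
        self.heatmap_r2().to_csv(outdir / "heatmap_r2.csv")

    def plot_fit(self, path: str | Path | None = None):
        """Best model vs experiment with residuals underneath."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, (ax0, ax1) = plt.subplots(
            2, 1, sharex=True, height_ratios=[3, 1], figsize=(6, 5)
        )
        t = self.grid.exp_times
        ax0.plot(t, self.grid.exp_values, "k.", label="experiment")
        ax0.plot(t, self.best.representative_curve, "r-", label="best model")
        ax0.set_ylabel("normalized ROI intensity")
        ax0.legend(frameon=False)
        ax1.axhline(0.0, color="0.6", lw=0.8)
        ax1.plot(t, self.residuals(), "b-")
        ax1.set_xlabel("time from damage (s)")
        ax1.set_ylabel("residual")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig

    def plot_heatmap(self, path: str | Path | None = None):
        """r² heatmap over the (Δx, F) grid, Δx axis annotated in μm²/s."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        mat = self.heatmap_r2()
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(mat.to_numpy(), origin="lower", aspect="auto", cmap="viridis")
        ax.set_xticks(range(len(mat.columns)), [str(c) for c in mat.columns])
        deffs = [
            f"{dx}\n({dx_deff:.2g})"
            for dx, dx_deff in zip(
                mat.index,
                [
                    (dx * self.model.pixel_size_um) ** 2 / (2 * self.model.delta_t)
                    for dx in mat.index
                ],
            )
        ]
        ax.set_yticks(range(len(mat.index)), deffs)
        ax.set_xlabel("mobile fraction F (ppt)")
        ax.set_ylabel("step size px/iter (D_eff um$^2$/s)")
        fig.colorbar(im, ax=ax, label="r$^2$")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig
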