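# qfadd

Quantitation of fluorescence accumulation after DNA damage (Q-FADD):
diffusion-model fitting of laser-microirradiation recruitment curves.

## What it does and for whom

Laser microirradiation damages a defined region of chromatin (the ROI)
inside the nucleus of a live cell and tracks the accumulation of a
fluorescently tagged DNA-repair protein at the damage site. Half-times and
exponential fits of those curves ignore nuclear geometry and cannot be
compared with orthogonal diffusion measurements. `qfadd` instead fits the
normalized accumulation curve `I_exp(t)` with a Monte Carlo free-diffusion
simulation run on the segmented nucleus itself, with the damage region as
an absorbing trap, yielding two physically interpretable parameters per
nucleus:

- **D_eff** — the effective diffusion coefficient (μm²/s), related to the
  lattice step size Δx (pixels/iteration) by `D_eff = (Δx·p)²/(2Δt)`,
  where `p` is the pixel size and Δt the simulation timestep;
- **F** — the mobile fraction (parts per thousand) of the tagged population
  free to reach the damage site.

The package is aimed at cell biologists analyzing microirradiation stacks
(striping or speckle mode) and covers the full workflow: image
preprocessing (nuclear segmentation, lateral-drift correction, photobleach
correction, ROI time-series extraction), replicate grid-search fitting of
(D_eff, F) scored by RMSD and r², cohort aggregation with significance
tests across nuclei, and a ground-truth synthetic data generator. See
`docs/methods.md` for the model and its assumptions.

## Worked example

Fit a synthetic nucleus generated at known truth (Δx = 8 px/iteration,
F = 300 ppt; 86.77 nm pixels, 6 pre-damage frames, a 12 px damage stripe):

```python
from qfadd import RecruitmentModel
from qfadd.synthgen import SynthSpec, generate_series, make_masks

spec = SynthSpec(true_delta_x=8, true_F_ppt=300, seed=101)
series, truth = generate_series(spec)
nucleus, roi = make_masks(spec)

model = RecruitmentModel(series, nucleus, roi,
                         pixel_size_um=spec.pixel_size_um, n_particles=2000)
res = model.fit(delta_x_values=range(1, 16),
                F_values_ppt=range(100, 1001, 100),
                n_replicates=11, base_seed=11)
print(res.summary())
```

```
Free-diffusion recruitment fit
==============================================
grid points sampled               150
replicates per point               11
readout                        median
fitted timepoints (N)              30
----------------------------------------------
best step size (px/iter)            8
best D_eff (um^2/s)             1.205
best mobile fraction F         300 ppt
r^2                            0.9839
RMSD                           0.0414
replicate RMSD range     [0.0132, 0.2219]
==============================================
```

The grid search recovers the generating parameters: the best of 150
candidate models steps 8 px per 0.2 s iteration (D_eff = 1.205 μm²/s) with
a 300 ppt mobile fraction, matching the experiment with an average
discrepancy of 0.041 in normalized-intensity units (RMSD; r² = 0.984).
The replicate RMSD range shows why the median of 11 replicates, not a
single run, picks the winner. `res.catalog` holds all 150 ranked models,
`res.save(outdir)` writes `all_models.csv` / `best_model.csv` /
`heatmap_r2.csv`, and `res.plot_fit(...)` / `res.plot_heatmap(...)` draw
the model-vs-experiment comparison and the r² landscape.

The same workflow is available from the shell for real data:

```sh
qfadd preprocess --stack nucleus.tif --roi roi.tif --outdir pre/
qfadd fit --series pre/time_series.csv --pixel-size-um 0.08677 --outdir fit/
qfadd cohort --group PARP1 fits_parp1/ --group PARP2 fits_parp2/ --outdir cohort/
```

`qfadd preprocess` and `qfadd fit` also accept directories for batch
processing of many nuclei, and `qfadd cohort` compares the per-nucleus
(D_eff, F) distributions between conditions (Welch's t-test by default)
with violin-plot exports.

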