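import numpy as np
import pytest

from qfadd.gridsearch import GridSpec, simulate_grid_curves
from qfadd.synthgen import SynthSpec, generate_series, make_masks


@pytest.fixture(scope="session")
def recovery_fixture():
    """Shared striping fixture at truth (Δx=8, F=300 ppt).

    Simulating the full 15x10 grid (11 replicates each) once per session
    keeps the recovery and concordance tests fast; scoring against any
    series sampled at the same timepoints is cheap.
    """
    spec = SynthSpec(n_particles=10_000, seed=101)
    series, truth = generate_series(spec)
    nucleus, roi = make_masks(spec)
    grid_spec = GridSpec(
        delta_x_values=range(1, 16),
        F_values_ppt=range(100, 1001, 100),
        n_replicates=11,
        base_seed=11,
        n_particles=2000,
        pixel_size_um=spec.pixel_size_um,
        delta_t=0.2,
    )
    exp_times = series.times[series.post_damage]
    curves = simulate_grid_curves(nucleus, roi, grid_spec, exp_times)
    return {
        "spec": spec,
        "series": series,
        "truth": truth,
        "nucleus": nucleus,
        "roi": roi,
        "grid_spec": grid_spec,
        "curves": curves,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(42)
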