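"""Cohort aggregation: distributions of (D_eff, F) across many nuclei.

Each analyzed nucleus contributes one best-fit record; a cohort summary is
the mean ± standard error of the mean of D_eff and F over its nuclei.
Two cohorts (e.g. two proteins, or treated vs control) are compared with
Welch's unequal-variance t-test by default — appropriate for small cohorts
with unequal spreads — or the Mann–Whitney U test on request.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError

__all__ = [
    "NucleusResult",
    "CohortSummary",
    "GroupComparison",
    "aggregate",
    "compare_groups",
    "distribution_export",
    "read_results_dir",
]


@dataclass
class NucleusResult:
    """Best-fit model of one nucleus."""

    nucleus_id: str
    D_eff_um2_s: float
    F_ppt: int
    r2: float
    rmsd: float


@dataclass
class CohortSummary:
    """Mean ± SEM of D_eff and F over a cohort of nuclei.

    SEM fields are NaN for a single-nucleus cohort (undefined for n < 2).
    """

    group_label: str
    n: int
    mean_D: float
    sem_D: float
    mean_F: float
    sem_F: float


@dataclass
class GroupComparison:
    """Two-sample location test between cohorts on one metric."""

    metric: str
    test: str
    statistic: float
    df: float
    p_value: float


def _metric_values(results: Sequence[NucleusResult], metric: str) -> np.ndarray:
    if metric == "D_eff":
        return np.array([r.D_eff_um2_s for r in results], dtype=float)
    if metric == "F":
        return np.array([r.F_ppt for r in results], dtype=float)
    raise ValidationError(f"metric must be 'D_eff' or 'F', got {metric!r}")


def aggregate(results: Sequence[NucleusResult], label: str = "") -> CohortSummary:
    """Mean and SEM of D_eff and F across nuclei (SEM uses n−1 dof)."""
    if len(results) < 1:
        raise ValidationError("cannot aggregate an empty cohort")
    D = _metric_values(results, "D_eff")
    F = _metric_values(results, "F")
    n = len(results)

    def sem(x: np.ndarray) -> float:
        if n < 2:
            return float("nan")
        return float(np.std(x, ddof=1) / math.sqrt(n))

    return CohortSummary(
        group_label=label,
        n=n,
        mean_D=float(D.mean()),
        sem_D=sem(D),
        mean_F=float(F.mean()),
        sem_F=sem(F),
    )


def compare_groups(
    a: Sequence[NucleusResult],
    b: Sequence[NucleusResult],
    metric: str = "D_eff",
    test: str = "welch",
) -> GroupComparison:
    """Two-sided two-sample test on D_eff or F between two cohorts.

    ``test='welch'`` (default) uses Welch's unequal-variance t-test with
    Welch–Satterthwaite degrees of freedom; ``test='mannwhitney'`` uses the
    Mann–Whitney U test (df reported as NaN).
    """
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 nuclei to compare")
    xa = _metric_values(a, metric)
    xb = _metric_values(b, metric)
    if test == "welch":
        res = stats.ttest_ind(xa, xb, equal_var=False)
        return GroupComparison(
            metric=metric,
            test="welch",
            statistic=float(res.statistic),
            df=float(res.df),
            p_value=float(res.pvalue),
        )
    if test == "mannwhitney":
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        return GroupComparison(
            metric=metric,
            test="mannwhitney",
            statistic=float(res.statistic),
            df=float("nan"),
            p_value=float(res.pvalue),
        )
    raise ValidationError(f"test must be 'welch' or 'mannwhitney', got {test!r}")


def distribution_export(
    groups: Sequence[tuple[str, Sequence[NucleusResult]]],
    outdir: str | Path | None = None,
    plot: bool = True,
) -> pd.DataFrame:
    """Long-format table of per-nucleus values with cohort annotations.

    Returns a DataFrame with one row per nucleus (group, nucleus_id, D_eff,
    F, r2, rmsd, group mean ± SEM columns).  When ``outdir`` is given, a
    ``cohort_values.csv`` / ``cohort_summary.csv`` pair and a violin plot of
    each metric are written there.  A single-nucleus group appears as a
    plain point in the plot (no density can be estimated from one value).
    """
    if len(groups) < 1:
        raise ValidationError("need at least one group")
    rows = []
    summaries = []
    for label, results in groups:
        summary = aggregate(results, label)
        summaries.append(summary)
        for r in results:
            rows.append(
                {
                    "group": label,
                    "nucleus_id": r.nucleus_id,
                    "D_eff_um2_s": r.D_eff_um2_s,
                    "F_ppt": r.F_ppt,
                    "r2": r.r2,
                    "rmsd": r.rmsd,
                    "group_mean_D": summary.mean_D,
                    "group_sem_D": summary.sem_D,
                    "group_mean_F": summary.mean_F,
                    "group_sem_F": summary.sem_F,
                }
            )
    table = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "cohort_values.csv", index=False)
        pd.DataFrame([s.__dict__ for s in summaries]).to_csv(
            outdir / "cohort_summary.csv", index=False
        )
        if plot:
            _violin_plot(groups, summaries, outdir)
    return table


def _violin_plot(groups, summaries, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    for metric, attr, ylabel, fname in (
        ("D_eff", "D_eff_um2_s", "D$_{eff}$ ($\\mu$m$^2$/s)", "violin_deff.png"),
        ("F", "F_ppt", "mobile fraction (ppt)", "violin_mobile_fraction.png"),
    ):
        fig, ax = plt.subplots(figsize=(1.5 + 1.5 * len(groups), 4))
        data = [[getattr(r, attr) for r in results] for _, results in groups]
        positions = np.arange(1, len(groups) + 1)
        multi = [d for d in data if len(d) > 1]
        if multi:
            pos_multi = [p for p, d in zip(positions, data) if len(d) > 1]
            ax.violinplot(multi, positions=pos_multi, showmedians=True)
        for p, d in zip(positions, data):
            ax.plot(np.full(len(d), p), d, "k.", ms=4, alpha=0.6)
        for p, s in zip(positions, summaries):
            mean = s.mean_D if metric == "D_eff" else s.mean_F
            sem = s.sem_D if metric == "D_eff" else s.sem_F
            note = f"{mean:.3g}" if math.isnan(sem) else f"{mean:.3g}$\\pm${sem:.2g}"
            ax.annotate(
                note, (p, mean), textcoords="offset points", xytext=(8, 0), fontsize=8
            )
        ax.set_xticks(positions, [label for label, _ in groups])
        ax.set_ylabel(ylabel)
        fig.tight_layout()
        fig.savefig(outdir / fname, dpi=150)
        plt.close(fig)


def read_results_dir(path: str | Path, pattern: str = "**/best_model.csv") -> list[NucleusResult]:
    """Collect best-fit records from a directory tree of ``best_model.csv`` files."""
    path = Path(path)
    results = []
    for f in sorted(path.glob(pattern)):
        df = pd.read_csv(f)
        if df.empty:
            continue
        row = df.iloc[0]
        results.append(
            NucleusResult(
                nucleus_id=str(f.parent.name),
                D_eff_um2_s=float(row["D_eff_um2_s"]),
                F_ppt=int(row["F_ppt"]),
                r2=float(row["r2"]),
                rmsd=float(row["rmsd"]),
            )
        )
    if not results:
        raise ValidationError(f"no best_model.csv files found under {path}")
    return results
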