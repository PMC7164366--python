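"""Infinite-sites diagnostics and complete-vs-reduced dataset comparison.

The infinite-sites plot regresses posterior 95% CI width on posterior
mean node age: with unlimited sequence data the points fall on a line
whose slope measures the irreducible, calibration-driven uncertainty
(e.g. a slope of 0.192 means 0.192 Ma of CI width per 1 Ma of divergence).
Comparing a complete gene set with a reduced clocklike subset shows how
much finite-data uncertainty the extra loci remove.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["InfiniteSitesFit", "infinite_sites_fit", "DatasetComparison",
           "compare_datasets"]


@dataclass
class InfiniteSitesFit:
    points: pd.DataFrame          # mean_age, ci_width per node
    slope: float
    intercept: float
    r2: float
    variant: str                  # with_root | without_root

    def __repr__(self):  # pragma: no cover
        return (f"<InfiniteSitesFit {self.variant}: width = "
                f"{self.slope:.3f} * age + {self.intercept:.3f}, "
                f"r2={self.r2:.3f}, n={len(self.points)}>")


def _age_table(summary: pd.DataFrame) -> pd.DataFrame:
    if "mean" not in summary.columns or "ci_width" not in summary.columns:
        raise ValueError("summary must carry 'mean' and 'ci_width'")
    tab = summary[summary.index.astype(str).str.startswith("age_")]
    if tab.empty:
        tab = summary
    return tab[["mean", "ci_width"]].astype(float)


def infinite_sites_fit(summary: pd.DataFrame,
                       include_root: bool = True) -> InfiniteSitesFit:
    """OLS of CI width on posterior mean age over dated internal nodes.

    ``summary`` is a posterior summary table (e.g. from
    ``summarize_posterior``) whose age rows are named ``age_*``.  With
    ``include_root=False`` the oldest node is dropped before fitting.
    """
    tab = _age_table(summary)
    if not include_root:
        tab = tab.drop(tab["mean"].idxmax())
    if len(tab) < 3:
        raise ValueError("need at least 3 nodes for the regression")
    x = tab["mean"].to_numpy()
    y = tab["ci_width"].to_numpy()
    X = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    yhat = X @ coef
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return InfiniteSitesFit(tab, float(coef[0]), float(coef[1]), r2,
                            "with_root" if include_root else
                            "without_root")


@dataclass
class DatasetComparison:
    """Per-node pairing of two posterior summaries over the same tree."""

    pairs: pd.DataFrame            # mean_full, mean_reduced, widths
    mean_width_ratio: float        # mean over nodes of reduced/full
    regression_slope: float        # full means on reduced means
    regression_intercept: float
    slope_full: float              # infinite-sites slopes of each summary
    slope_reduced: float


def compare_datasets(full_summary: pd.DataFrame,
                     reduced_summary: pd.DataFrame) -> DatasetComparison:
    """Compare dating precision between a complete data set and a reduced
    (e.g. clocklike-subset) analysis over the same nodes."""
    f = _age_table(full_summary)
    r = _age_table(reduced_summary)
    if set(f.index) != set(r.index):
        only_f = sorted(set(f.index) - set(r.index))
        only_r = sorted(set(r.index) - set(f.index))
        raise ValueError(f"node sets differ: only in full {only_f}, "
                         f"only in reduced {only_r}")
    r = r.loc[f.index]
    pairs = pd.DataFrame({
        "mean_full": f["mean"], "mean_reduced": r["mean"],
        "width_full": f["ci_width"], "width_reduced": r["ci_width"],
        "width_ratio": r["ci_width"] / f["ci_width"]})
    X = np.column_stack([pairs["mean_reduced"],
                         np.ones(len(pairs))])
    coef, *_ = np.linalg.lstsq(X, pairs["mean_full"].to_numpy(),
                               rcond=None)
    return DatasetComparison(
        pairs, float(pairs["width_ratio"].mean()),
        float(coef[0]), float(coef[1]),
        infinite_sites_fit(full_summary).slope,
        infinite_sites_fit(reduced_summary).slope)


def plot_infinite_sites(fits: Sequence[InfiniteSitesFit], path) -> None:
    """Optional figure: CI width vs mean age with regression lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 4))
    for fit, style in zip(fits, ("-", "--", ":", "-.")):
        x = fit.points["mean"]
        ax.scatter(x, fit.points["ci_width"], s=12, alpha=0.6)
        xs = np.linspace(0, float(x.max()), 50)
        ax.plot(xs, fit.slope * xs + fit.intercept, style,
                label=f"{fit.variant}: {fit.slope:.3f}x+"
                      f"{fit.intercept:.2f} (r2={fit.r2:.2f})")
    ax.set_xlabel("posterior mean age (Ma)")
    ax.set_ylabel("95% CI width (Ma)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
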