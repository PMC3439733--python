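"""Gene-set scale distribution and log-log power-law regression.

The *scale* of a gene set is its number of member symbols. Integrated
gene-set databases tend to show an approximately power-law frequency of
scales: many small sets, few very large ones. This module tabulates the
exact frequency of each distinct scale in a collection and fits ordinary
least squares to (log10 scale, log10 frequency), reporting slope,
intercept and R². No binning is applied — one point per distinct scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd
from scipy import stats

from .genesets import GeneSetCollection

__all__ = ["LogLogFit", "ScaleDistribution", "scale_distribution", "loglog_fit",
           "plot_distribution"]


@dataclass(frozen=True)
class LogLogFit:
    slope: float
    intercept: float
    r_squared: float | None  # None marks a degenerate (zero-variance) fit
    degenerate: bool = False


@dataclass
class ScaleDistribution:
    """Frequency of each distinct scale, plus an optional log-log OLS fit."""

    table: pd.DataFrame  # columns: scale, frequency (only frequency >= 1 rows)
    fit: LogLogFit | None = None

    @property
    def total_sets(self) -> int:
        return int(self.table["frequency"].sum())

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def scale_distribution(collection: GeneSetCollection) -> ScaleDistribution:
    """Count how many sets fall at each distinct scale."""
    if len(collection) == 0:
        raise ValueError("collection is empty")
    counts: dict[int, int] = {}
    for s in collection:
        counts[s.scale] = counts.get(s.scale, 0) + 1
    table = pd.DataFrame(
        sorted(counts.items()), columns=["scale", "frequency"]
    )
    return ScaleDistribution(table=table)


def loglog_fit(dist: ScaleDistribution) -> ScaleDistribution:
    """OLS on (log10 scale, log10 frequency); requires >= 3 distinct scales.

    A zero-variance response (all frequencies equal) makes R² meaningless;
    the fit is then returned with slope 0 and a degenerate marker instead
    of a fabricated 0 or 1.
    """
    import numpy as np

    if len(dist.table) < 3:
        raise ValueError("log-log fit needs at least 3 distinct scales")
    x = np.log10(dist.table["scale"].to_numpy(dtype=float))
    y = np.log10(dist.table["frequency"].to_numpy(dtype=float))
    if np.allclose(y, y[0]):
        fit = LogLogFit(slope=0.0, intercept=float(y[0]), r_squared=None,
                        degenerate=True)
    else:
        res = stats.linregress(x, y)
        fit = LogLogFit(
            slope=float(res.slope),
            intercept=float(res.intercept),
            r_squared=float(res.rvalue**2),
        )
    return replace(dist, fit=fit)


def plot_distribution(dist: ScaleDistribution, path: str | Path) -> None:
    """Log-log scatter of the distribution with the fitted trend line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(dist.table["scale"], dist.table["frequency"], s=12)
    if dist.fit is not None and not dist.fit.degenerate:
        xs = np.logspace(
            np.log10(dist.table["scale"].min()),
            np.log10(dist.table["scale"].max()),
            100,
        )
        ax.plot(xs, 10**dist.fit.intercept * xs**dist.fit.slope, "r-",
                label=(f"slope={dist.fit.slope:.2f}, "
                       f"$R^2$={dist.fit.r_squared:.2f}"))
        ax.legend()
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("gene-set scale")
    ax.set_ylabel("frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
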