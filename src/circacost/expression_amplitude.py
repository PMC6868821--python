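"""Transcription level versus rhythmicity: quintile proportions and the
log-log amplitude regression with variance attribution.

Two summaries of the same phenomenon: (1) how the population of cycling
genes distributes over expression quintiles (all expressed genes are split
into five equally sized bins by mean expression, and each bin's share of
all cycling genes is reported), and (2) an ordinary least-squares fit of
log amplitude on log mean expression over cycling genes, whose R^2 is read
as the fraction of amplitude variance attributable to expression level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

__all__ = [
    "mean_expression",
    "quintile_proportions",
    "amplitude_expression_regression",
    "RegressionReport",
]

_BIN_LABELS = ["bottom_20", "20_40", "40_60", "60_80", "top_20"]


def mean_expression(series) -> float:
    """Arithmetic mean of a complete expression series."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    return float(x.mean())


def quintile_proportions(levels, cycling) -> pd.DataFrame:
    """Share of all cycling genes falling in each expression quintile.

    Genes are ranked by mean expression (ties broken by stable input
    order) and split into five bins as equal as possible (sizes differ by
    at most one). For each bin the gene count, cycling count, the bin's
    proportion of *all* cycling genes, and the within-bin cycling fraction
    are reported; bins run from ``bottom_20`` to ``top_20``.

    With zero cycling genes the proportions are zero and the frame carries
    ``attrs["no_cycling_warning"] = True``.
    """
    levels = np.asarray(levels, dtype=float)
    cycling = np.asarray(cycling, dtype=bool)
    if levels.size != cycling.size:
        raise ValueError("levels and cycling flags differ in length")
    if levels.size < 5:
        raise ValueError("need at least 5 genes to form quintiles")
    order = np.argsort(levels, kind="stable")
    bins = np.array_split(order, 5)
    n_cyc = int(cycling.sum())
    rows = []
    for label, idx in zip(_BIN_LABELS, bins):
        k = int(cycling[idx].sum())
        rows.append({
            "bin": label,
            "gene_count": int(idx.size),
            "cycling_count": k,
            "proportion_of_cycling": k / n_cyc if n_cyc else 0.0,
            "within_bin_fraction": k / idx.size if idx.size else 0.0,
        })
    out = pd.DataFrame(rows)
    out.attrs["no_cycling_warning"] = n_cyc == 0
    return out


@dataclass
class RegressionReport:
    """OLS fit of log amplitude on log mean expression."""

    n: int
    n_zero_amplitude_excluded: int
    pearson_r: float
    r_squared: float
    slope: float
    intercept: float
    p_value: float

    def to_dict(self):
        return dict(self.__dict__)


def amplitude_expression_regression(records: pd.DataFrame,
                                    top_fraction: float | None = None) -> RegressionReport:
    """Regress log amplitude on log mean expression over cycling records.

    ``records`` must carry mean_expression, amplitude and is_cycling
    columns for *all* expressed genes: when ``top_fraction`` is given, the
    top fraction of all expressed genes by mean expression is taken first
    and then intersected with the cycling set (the "top 50% highly
    expressed genes" control). Cycling genes with amplitude exactly 0 are
    excluded (log undefined) and counted in the report. Natural logs are
    used; r, R^2 and slope are invariant to the base and to rescaling the
    expression units.
    """
    df = records
    if top_fraction is not None:
        if not 0 < top_fraction <= 1:
            raise ValueError("top_fraction must lie in (0, 1]")
        k = int(np.ceil(top_fraction * len(df)))
        df = df.nlargest(k, "mean_expression")
    df = df[df["is_cycling"]]
    n_zero = int((df["amplitude"] <= 0).sum())
    df = df[df["amplitude"] > 0]
    if len(df) < 3:
        raise ValueError("fewer than 3 usable cycling records")
    fit = linregress(np.log(df["mean_expression"].to_numpy()),
                     np.log(df["amplitude"].to_numpy()))
    return RegressionReport(
        n=len(df),
        n_zero_amplitude_excluded=n_zero,
        pearson_r=float(fit.rvalue),
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
    )
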