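"""Bland-Altman method-agreement statistics.

Compares algorithmic counts against a reference (manual counts, or the mean
of two observers): bias is the mean of the paired differences (algorithm
minus reference), precision their standard deviation, and the 95% limits of
agreement bias +/- 1.96 * precision.  The two methods are judged
interchangeable when the relative bias is below 10% of the grand mean and
there is no tendency of the difference to grow with the magnitude (two-sided
test of the regression slope of differences on pairwise means, alpha 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class AgreementResult:
    n: int
    bias: float
    precision: float
    loa_low: float
    loa_high: float
    percent_bias: float
    trend_slope: float
    trend_p: float
    interchangeable: bool

    def to_dict(self) -> dict:
        return asdict(self)


def observer_mean(obs1, obs2) -> np.ndarray:
    """Element-wise mean of two observers' count series."""
    a = np.asarray(obs1, dtype=float)
    b = np.asarray(obs2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("observer series must have equal length")
    return (a + b) / 2.0


def bland_altman(algo_counts, ref_counts, alpha: float = 0.05,
                 bias_limit_pct: float = 10.0) -> AgreementResult:
    """Bland-Altman comparison of an algorithmic against a reference series.

    Differences are algorithm minus reference.  With constant differences
    (e.g. identical series) the trend test is vacuous and reported as
    no-trend (slope 0, p = 1).
    """
    algo = np.asarray(algo_counts, dtype=float)
    ref = np.asarray(ref_counts, dtype=float)
    if algo.shape != ref.shape:
        raise ValueError("paired series must have equal length")
    n = algo.size
    if n < 3:
        raise ValueError("need at least 3 pairs for agreement statistics")

    diffs = algo - ref
    means = (algo + ref) / 2.0
    bias = float(diffs.mean())
    precision = float(diffs.std(ddof=1))
    loa_low = bias - 1.96 * precision
    loa_high = bias + 1.96 * precision

    grand_mean = float(means.mean())
    if grand_mean != 0.0:
        percent_bias = 100.0 * bias / grand_mean
    else:
        percent_bias = 0.0 if bias == 0.0 else float("inf")

    if np.ptp(diffs) == 0.0 or np.ptp(means) == 0.0:
        slope, trend_p = 0.0, 1.0
    else:
        fit = stats.linregress(means, diffs)
        slope = float(fit.slope)
        trend_p = float(fit.pvalue) if np.isfinite(fit.pvalue) else 1.0

    interchangeable = abs(percent_bias) < bias_limit_pct and trend_p >= alpha
    return AgreementResult(n=n, bias=bias, precision=precision,
                           loa_low=loa_low, loa_high=loa_high,
                           percent_bias=percent_bias, trend_slope=slope,
                           trend_p=trend_p, interchangeable=interchangeable)


def agreement_by_class(counts: pd.DataFrame) -> dict[str, AgreementResult]:
    """Per-cell-class agreement from a counts table.

    Expects columns ``cell_class``, ``algo_count`` and either ``ref_count``
    or the observer pair ``obs1_count``/``obs2_count`` (averaged into the
    reference series).
    """
    results = {}
    for cls, grp in counts.groupby("cell_class"):
        if "ref_count" in grp:
            ref = grp["ref_count"].to_numpy(dtype=float)
        else:
            ref = observer_mean(grp["obs1_count"], grp["obs2_count"])
        results[str(cls)] = bland_altman(grp["algo_count"].to_numpy(dtype=float), ref)
    return results


def plot_bland_altman(algo_counts, ref_counts, result: AgreementResult | None = None,
                      ax=None, title: str | None = None):
    """Difference-vs-mean scatter with bias and limits of agreement drawn."""
    import matplotlib
    if ax is None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    algo = np.asarray(algo_counts, dtype=float)
    ref = np.asarray(ref_counts, dtype=float)
    result = result or bland_altman(algo, ref)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((algo + ref) / 2, algo - ref, s=18, color="k", alpha=0.7)
    ax.axhline(result.bias, color="tab:blue", label=f"bias {result.bias:.2f}")
    for y in (result.loa_low, result.loa_high):
        ax.axhline(y, color="tab:blue", linestyle="--")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("algorithm - reference")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    return ax
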