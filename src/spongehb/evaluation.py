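"""Prediction-quality metrics and Bland-Altman agreement analysis.

Metrics (with y the actual and y_hat the predicted Hb masses):

    MAE  = (1/n) * sum |y_hat_i - y_i|                       [mg]
    MAPE = (100/n) * sum |(y_hat_i - y_i) / y_i|             [%]
    R^2  = 1 - sum (y_i - y_hat_i)^2 / sum (y_i - ybar)^2

R^2 is the coefficient of determination (not a squared correlation): it
is negative whenever the predictor is worse than the constant mean.

Bland-Altman analysis summarizes agreement through the differences
d_i = y_hat_i - y_i: the bias is mean(d), the limits of agreement (LOA)
are bias +/- z*sd(d) (z = 1.96 for 95% limits, sample SD with divisor
n-1). Two confidence-interval conventions for the LOA are provided:

* ``loa_ci="matched"`` (default): the same half-width z*sd/sqrt(n) for
  the bias and both LOA. Published agreement tables in this problem
  domain print numerically identical CI half-widths for all three lines,
  which only this convention reproduces.
* ``loa_ci="textbook"``: the classical LOA standard error
  sd*sqrt(3/n), giving wider LOA intervals.

A distribution-free mode (``mode="percentile"``) takes the 2.5th/97.5th
percentiles of the differences as LOA and the median as bias, with
order-statistic (binomial) confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetricSet",
    "AgreementReport",
    "mae",
    "mape",
    "r2",
    "compute_metrics",
    "bland_altman",
    "compare_models",
    "bland_altman_plot",
]


@dataclass(frozen=True)
class MetricSet:
    """MAE (mg), MAPE (%), and R^2 for one model on one test set."""

    mae: float
    mape: float
    r2: float


@dataclass(frozen=True)
class AgreementReport:
    """Bland-Altman summary of predicted-minus-actual differences (mg)."""

    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    ci_bias: tuple[float, float]
    ci_loa_lower: tuple[float, float]
    ci_loa_upper: tuple[float, float]
    n: int
    mode: str = "parametric"

    def __post_init__(self) -> None:
        if not self.loa_lower <= self.bias <= self.loa_upper:
            raise ValueError("bias must lie between the limits of agreement")
        for ci, point in (
            (self.ci_bias, self.bias),
            (self.ci_loa_lower, self.loa_lower),
            (self.ci_loa_upper, self.loa_upper),
        ):
            if not ci[0] <= point <= ci[1]:
                raise ValueError(f"CI {ci} does not contain its point estimate {point}")


def _paired(actual, predicted) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(actual, dtype=np.float64).ravel()
    p = np.asarray(predicted, dtype=np.float64).ravel()
    if a.size != p.size:
        raise ValueError(f"length mismatch: {a.size} actual vs {p.size} predicted")
    if a.size == 0:
        raise ValueError("empty input")
    return a, p


def mae(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Mean absolute error in mg."""
    a, p = _paired(actual, predicted)
    return float(np.mean(np.abs(p - a)))


def mape(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Mean absolute percentage error (%); actual values must be nonzero."""
    a, p = _paired(actual, predicted)
    zero = np.flatnonzero(a == 0)
    if zero.size:
        raise ZeroDivisionError(
            f"MAPE undefined: actual value is 0 at index {int(zero[0])}"
        )
    return float(100.0 * np.mean(np.abs((p - a) / a)))


def r2(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    a, p = _paired(actual, predicted)
    if a.size < 2:
        raise ValueError("R^2 requires at least 2 observations")
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined: all actual values are equal (zero variance)")
    return float(1.0 - np.sum((a - p) ** 2) / ss_tot)


def compute_metrics(actual: Sequence[float], predicted: Sequence[float]) -> MetricSet:
    return MetricSet(mae(actual, predicted), mape(actual, predicted), r2(actual, predicted))


def _quantile_ci(sorted_d: np.ndarray, q: float, level: float = 0.95) -> tuple[float, float]:
    """Distribution-free order-statistic CI for the q-quantile."""
    n = sorted_d.size
    lo = int(stats.binom.ppf((1 - level) / 2, n, q))
    hi = int(stats.binom.ppf(1 - (1 - level) / 2, n, q)) + 1
    lo = max(0, min(lo, n - 1))
    hi = max(0, min(hi, n - 1))
    return float(sorted_d[lo]), float(sorted_d[hi])


def bland_altman(
    predicted: Sequence[float],
    actual: Sequence[float],
    *,
    z: float = 1.96,
    mode: str = "parametric",
    loa_ci: str = "matched",
) -> AgreementReport:
    """Bland-Altman agreement between predicted and actual Hb masses.

    Differences are predicted - actual. See the module docstring for the
    ``mode`` and ``loa_ci`` conventions. Requires n >= 3.
    """
    a, p = _paired(actual, predicted)
    n = a.size
    if n < 3:
        raise ValueError(f"Bland-Altman analysis requires n >= 3, got {n}")
    if mode not in ("parametric", "percentile"):
        raise ValueError(f"mode must be 'parametric' or 'percentile', got {mode!r}")
    if loa_ci not in ("matched", "textbook"):
        raise ValueError(f"loa_ci must be 'matched' or 'textbook', got {loa_ci!r}")

    d = p - a
    sd = float(np.std(d, ddof=1))

    if mode == "percentile":
        srt = np.sort(d)
        bias = float(np.median(d))
        loa_lo = float(np.quantile(d, 0.025))
        loa_hi = float(np.quantile(d, 0.975))
        ci_bias = _quantile_ci(srt, 0.5)
        ci_lo = _quantile_ci(srt, 0.025)
        ci_hi = _quantile_ci(srt, 0.975)
        # quantile interpolation can land just outside the order statistics
        ci_bias = (min(ci_bias[0], bias), max(ci_bias[1], bias))
        ci_lo = (min(ci_lo[0], loa_lo), max(ci_lo[1], loa_lo))
        ci_hi = (min(ci_hi[0], loa_hi), max(ci_hi[1], loa_hi))
        return AgreementReport(
            bias=bias, sd_diff=sd, loa_lower=loa_lo, loa_upper=loa_hi,
            ci_bias=ci_bias, ci_loa_lower=ci_lo, ci_loa_upper=ci_hi,
            n=n, mode="percentile",
        )

    bias = float(np.mean(d))
    loa_lo = bias - z * sd
    loa_hi = bias + z * sd
    hw_bias = z * sd / np.sqrt(n)
    hw_loa = hw_bias if loa_ci == "matched" else z * sd * np.sqrt(3.0 / n)
    return AgreementReport(
        bias=bias,
        sd_diff=sd,
        loa_lower=loa_lo,
        loa_upper=loa_hi,
        ci_bias=(bias - hw_bias, bias + hw_bias),
        ci_loa_lower=(loa_lo - hw_loa, loa_lo + hw_loa),
        ci_loa_upper=(loa_hi - hw_loa, loa_hi + hw_loa),
        n=n,
        mode="parametric",
    )


def compare_models(metrics: Mapping[str, MetricSet]) -> pd.DataFrame:
    """Pairwise improvement table over a set of scored models.

    For each ordered pair (baseline, candidate) the improvements are
    baseline.mae - candidate.mae (mg), baseline.mape - candidate.mape
    (percentage points) and candidate.r2 - baseline.r2 — positive numbers
    mean the candidate is better on that axis.
    """
    if len(metrics) < 2:
        raise ValueError("compare_models needs at least 2 models")
    rows = []
    for base, cand in permutations(metrics, 2):
        rows.append(
            {
                "baseline": base,
                "candidate": cand,
                "mae_improvement_mg": metrics[base].mae - metrics[cand].mae,
                "mape_improvement_pct": metrics[base].mape - metrics[cand].mape,
                "r2_improvement": metrics[cand].r2 - metrics[base].r2,
            }
        )
    return pd.DataFrame(rows)


def bland_altman_plot(
    predicted: Sequence[float],
    actual: Sequence[float],
    path,
    *,
    report: AgreementReport | None = None,
):
    """Scatter of differences vs means with bias and LOA lines (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a, p = _paired(actual, predicted)
    rep = report if report is not None else bland_altman(p, a)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter((a + p) / 2, p - a, s=12, alpha=0.6)
    ax.axhline(rep.bias, color="red", ls="--", label=f"bias {rep.bias:.2f} mg")
    ax.axhline(rep.loa_upper, color="blue", ls="--", label=f"LOA {rep.loa_upper:.2f}")
    ax.axhline(rep.loa_lower, color="blue", ls="--", label=f"LOA {rep.loa_lower:.2f}")
    ax.set_xlabel("mean of predicted and actual Hb mass (mg)")
    ax.set_ylabel("predicted - actual (mg)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return rep
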