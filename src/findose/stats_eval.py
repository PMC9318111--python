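"""Predicted-vs-observed evaluation: Pearson correlation, slope, factor-2.

The evaluation mirrors how finite-dose predictions are judged against
measured absorption ratios: a Pearson correlation with a two-sided
t-test (df = n−2), the slope of the predicted–observed relationship, and
the fraction of chemicals whose prediction falls within a factor of two
of the observation (the dashed guide lines on the usual scatter plot).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats

from .datatypes import ComparisonResult

__all__ = [
    "pearson_with_p",
    "factor2_fraction",
    "evaluate_predictions",
    "plot_comparison",
]


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r and its two-sided p-value.

    The p-value comes from ``t = r·sqrt((n−2)/(1−r²))`` against a
    t-distribution with n−2 degrees of freedom; for |r| = 1 the statistic
    degenerates and p is reported as 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired (equal length)")
    if x.size < 3:
        raise ValueError("need at least 3 pairs for a correlation test")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in input")
    res = stats.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    if 1.0 - r * r < 1e-15:  # |r| = 1: t statistic degenerates, p reported as 0
        p = 0.0
    return r, p


def factor2_fraction(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Fraction of pairs within two-fold of each other.

    A pair agrees when ``max(pred/obs, obs/pred) <= 2``.  Both values
    must be strictly positive (ratios on a log scale).
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.size != obs.size:
        raise ValueError("pred and obs must be paired (equal length)")
    if pred.size == 0:
        raise ValueError("need at least one pair")
    if np.any(pred <= 0) or np.any(obs <= 0):
        raise ValueError("factor-2 agreement needs strictly positive values")
    ratio = np.maximum(pred / obs, obs / pred)
    return float(np.mean(ratio <= 2.0))


def _slope(pred: np.ndarray, obs: np.ndarray, through_origin: bool) -> float:
    if through_origin:
        # least squares of obs on pred constrained through the origin:
        # slope 1 means a 1:1 relationship on ratio axes
        return float(np.dot(pred, obs) / np.dot(pred, pred))
    fit = stats.linregress(pred, obs)
    return float(fit.slope)


def evaluate_predictions(
    pairs: Sequence[tuple[str, float, float]] | None = None,
    *,
    pred: Sequence[float] | None = None,
    obs: Sequence[float] | None = None,
    slope_through_origin: bool = True,
) -> ComparisonResult:
    """Bundle all agreement metrics for paired predicted/observed ratios.

    Accepts either ``pairs`` of ``(chemical, predicted, observed)`` or
    separate ``pred``/``obs`` vectors.  The slope is computed from the
    least-squares fit of observed on predicted, constrained through the
    origin by default (slope ≈ 1 then reads as a 1:1 relationship);
    set ``slope_through_origin=False`` for the intercept form.
    """
    if pairs is not None:
        pred = [p for _, p, _ in pairs]
        obs = [o for _, _, o in pairs]
    if pred is None or obs is None:
        raise ValueError("provide either pairs or both pred and obs")
    pred_arr = np.asarray(pred, dtype=float)
    obs_arr = np.asarray(obs, dtype=float)
    r, p_value = pearson_with_p(pred_arr, obs_arr)
    return ComparisonResult(
        n=int(pred_arr.size),
        r=r,
        p_value=p_value,
        slope=_slope(pred_arr, obs_arr, slope_through_origin),
        factor2_fraction=factor2_fraction(pred_arr, obs_arr),
    )


def plot_comparison(
    pred: Sequence[float],
    obs: Sequence[float],
    labels: Sequence[str] | None = None,
    path: str | None = None,
):
    """Scatter of observed vs predicted ratios with identity and factor-2 lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    hi = max(pred.max(), obs.max()) * 1.2
    line = np.array([0.0, hi])
    ax.plot(line, line, "k-", lw=1, label="identity")
    ax.plot(line, 2 * line, "k--", lw=0.8, label="factor 2")
    ax.plot(line, 0.5 * line, "k--", lw=0.8)
    ax.scatter(pred, obs, zorder=3)
    if labels is not None:
        for x, y, s in zip(pred, obs, labels):
            ax.annotate(s, (x, y), fontsize=7, xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("predicted absorption ratio")
    ax.set_ylabel("observed absorption ratio")
    ax.set_xlim(0, hi)
    ax.set_ylim(0, hi)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
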