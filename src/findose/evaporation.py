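"""Complete-evaporation time (T_eva) estimation from weight time series.

The applied solution is weighed at a fixed cadence (0.25 h by default)
until the weight stops changing.  T_eva is defined as the onset of the
sustained plateau: the earliest sampled time from which every subsequent
consecutive weight change stays within a threshold expressed as a
fraction of the initial weight.  The criterion is relative, so scaling
the whole series leaves the estimate unchanged, and loosening the
threshold can only move the estimate earlier.
"""

from __future__ import annotations

import numpy as np

from .datatypes import EvaporationSeries, TevaEstimate

__all__ = ["estimate_teva", "EvaporationIncompleteError"]


class EvaporationIncompleteError(ValueError):
    """No sustained weight plateau within the measured series."""


def estimate_teva(
    series: EvaporationSeries,
    rel_threshold: float = 0.01,
) -> TevaEstimate:
    """Estimate the complete-evaporation time from a weight series.

    Parameters
    ----------
    series:
        Weight (mg) vs time (h); at least 3 points.
    rel_threshold:
        Plateau criterion as a fraction of the initial weight: a
        consecutive change ``|w_i − w_{i−1}|`` counts as "no change" when
        it is at most ``rel_threshold · w_0``.  Default 1 %.

    Returns
    -------
    :class:`TevaEstimate` with ``Teva`` = earliest time from which all
    subsequent consecutive changes satisfy the criterion (sustained to
    the end of the series) and ``plateau_weight`` = mean weight from
    ``Teva`` on.

    Raises
    ------
    EvaporationIncompleteError
        If the weight is still changing at the end of the series.
    """
    if series.times.size < 3:
        raise ValueError("need at least 3 weight measurements")
    if not rel_threshold > 0:
        raise ValueError("rel_threshold must be positive")
    w = series.weights
    t = series.times
    thr = rel_threshold * w[0]
    quiet = np.abs(np.diff(w)) <= thr  # quiet[i]: no change between t[i] and t[i+1]
    # plateau onset: smallest i with quiet[i:] all True; needs >= 1 quiet pair
    not_quiet = np.flatnonzero(~quiet)
    onset = 0 if not_quiet.size == 0 else int(not_quiet[-1]) + 1
    if onset >= quiet.size:  # last pair still changing
        raise EvaporationIncompleteError(
            "evaporation incomplete: weight still changing at the end of the series"
        )
    return TevaEstimate(
        Teva=float(t[onset]),
        plateau_weight=float(np.mean(w[onset:])),
        criterion=f"consecutive change <= {rel_threshold:g} * initial weight, sustained",
    )
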