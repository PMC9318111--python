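"""Permeation-parameter estimation from infinite-dose Franz-cell profiles.

The cumulative amount permeated through a membrane under an infinite dose
approaches a straight line ``Q = Flux·(t − Tlag)`` once diffusion reaches
steady state.  The slope gives the steady-state flux, the x-intercept the
lag time, and the classical lag-time relations then yield the three
transport parameters:

    Kp = Flux / Cv          (permeability coefficient, cm/h)
    D  = L² / (6·Tlag)      (diffusion coefficient in the membrane, cm²/h)
    K  = 6·Tlag·Kp / L      (membrane/vehicle partition coefficient, −)

so that ``Kp = K·D/L`` identically.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy import stats

from .datatypes import (
    PermeationParameters,
    PermeationProfile,
    SamplingScheme,
)

__all__ = [
    "correct_cumulative_for_sampling",
    "steady_state_window",
    "fit_steady_state",
    "compute_kp",
    "compute_D",
    "compute_K",
    "estimate_parameters",
    "aggregate_replicates",
    "SteadyStateFitError",
]


class SteadyStateFitError(ValueError):
    """The profile admits no positive steady-state flux."""


def correct_cumulative_for_sampling(
    concentrations: Sequence[float],
    scheme: SamplingScheme = SamplingScheme(),
    area: float = 1.0,
) -> np.ndarray:
    """Convert receiver concentrations to cumulative permeated amounts.

    At each sampling an aliquot is withdrawn and replaced with fresh
    solvent, so mass removed in earlier aliquots must be added back.
    Mass balance for the n-th timepoint::

        Q_n = (C_n · V_receiver + Σ_{i<n} C_i · V_aliquot) / A

    Parameters
    ----------
    concentrations:
        Receiver concentrations (µg/mL), ordered by sampling time.
    scheme:
        Receiver and aliquot volumes (mL).
    area:
        Effective diffusion area (cm²).

    Returns
    -------
    Cumulative amounts permeated per unit area (µg/cm²).
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise ValueError("receiver concentrations must be non-negative")
    if not area > 0:
        raise ValueError(f"area must be positive, got {area}")
    removed = np.concatenate(([0.0], np.cumsum(conc[:-1]) * scheme.aliquot_volume))
    return (conc * scheme.receiver_volume + removed) / area


def steady_state_window(profile: PermeationProfile, t_min: float | None = None) -> np.ndarray:
    """Default indices of the steady-state fitting window.

    Skin-like membranes are linear from the first (2 h) sample, whereas
    Strat-M shows a visibly curved 2 h point, so its default window starts
    at 4 h.  Pass ``t_min`` to override.
    """
    if t_min is None:
        t_min = 4.0 if profile.membrane.name.startswith("strat") else 2.0
    idx = np.flatnonzero(profile.times >= t_min - 1e-12)
    return idx


def fit_steady_state(
    profile: PermeationProfile,
    window: Sequence[int] | None = None,
) -> tuple[float, float, float]:
    """Fit the steady-state tangent ``Q = a·t + b`` over a window of points.

    Returns ``(Flux, Tlag, r²)`` with ``Flux = a`` and ``Tlag = −b/a``.
    A negative lag time (possible on noisy data) is retained and flagged
    with a warning rather than clamped, so downstream parameters expose
    the anomaly.

    Raises
    ------
    SteadyStateFitError
        If the fitted slope is not strictly positive.
    """
    if window is None:
        idx = steady_state_window(profile)
    else:
        idx = np.asarray(window, dtype=int)
    if idx.size < 2:
        raise ValueError("steady-state window must select at least 2 points")
    t = profile.times[idx]
    q = profile.cumulative[idx]
    fit = stats.linregress(t, q)
    slope, intercept = float(fit.slope), float(fit.intercept)
    if not slope > 0:
        raise SteadyStateFitError(
            f"no positive steady-state flux (fitted slope {slope:.4g})"
        )
    tlag = -intercept / slope
    if tlag < 0:
        warnings.warn(
            f"negative lag time ({tlag:.4g} h) from steady-state fit; "
            "check window/linearity",
            stacklevel=2,
        )
    # r² is 1 by construction for a 2-point window
    r2 = 1.0 if idx.size == 2 else float(fit.rvalue) ** 2
    return slope, tlag, r2


def compute_kp(flux: float, Cv: float) -> float:
    """Permeability coefficient ``Kp = Flux / Cv`` (cm/h)."""
    if not Cv > 0:
        raise ValueError(f"donor concentration Cv must be positive, got {Cv}")
    return flux / Cv


def compute_D(L: float, tlag: float) -> float:
    """Membrane diffusion coefficient ``D = L² / (6·Tlag)`` (cm²/h)."""
    if not L > 0:
        raise ValueError(f"membrane thickness L must be positive, got {L}")
    if not tlag > 0:
        raise ValueError("lag time non-positive; D undefined")
    return L * L / (6.0 * tlag)


def compute_K(tlag: float, kp: float, L: float) -> float:
    """Membrane/vehicle partition coefficient ``K = 6·Tlag·Kp / L`` (−)."""
    if not L > 0:
        raise ValueError(f"membrane thickness L must be positive, got {L}")
    return 6.0 * tlag * kp / L


def estimate_parameters(
    profile: PermeationProfile,
    window: Sequence[int] | None = None,
) -> PermeationParameters:
    """Estimate the full parameter bundle {Flux, Tlag, Kp, D, K} from a profile.

    Composes the steady-state fit with the lag-time relations.  When the
    fitted lag time is non-positive, D is undefined and reported as NaN
    (with a recorded warning); K is still computed (0 at Tlag = 0).
    """
    flux, tlag, r2 = fit_steady_state(profile, window)
    kp = compute_kp(flux, profile.Cv)
    notes: list[str] = []
    if tlag > 0:
        D = compute_D(profile.membrane.L, tlag)
    else:
        D = float("nan")
        notes.append(f"lag time non-positive ({tlag:.4g} h); D undefined")
    K = compute_K(tlag, kp, profile.membrane.L)
    n = len(window) if window is not None else steady_state_window(profile).size
    return PermeationParameters(
        flux=flux, tlag=tlag, kp=kp, D=D, K=K,
        fit_r2=r2, n_points=n, warnings=tuple(notes),
    )


def aggregate_replicates(
    replicates: Sequence[PermeationParameters],
) -> dict[str, tuple[float, float]]:
    """Mean ± standard error of each parameter across replicate cells.

    Returns a mapping ``{"kp": (mean, se), "K": (mean, se), ...}``;
    SE is the sample standard deviation divided by √n (0 for n = 1).
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    out: dict[str, tuple[float, float]] = {}
    for attr in ("flux", "tlag", "kp", "D", "K"):
        vals = np.array([getattr(p, attr) for p in replicates], dtype=float)
        mean = float(np.mean(vals))
        se = float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        out[attr] = (mean, se)
    return out
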