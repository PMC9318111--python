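"""Synthetic Franz-cell study generator with known ground truth.

Every other module is testable without laboratory data because this one
emulates the three measurements of a finite-dose study:

* infinite-dose cumulative-permeation profiles, generated from the exact
  slab-diffusion series solution (whose large-time tangent has slope
  ``Kp·Cv`` and x-intercept ``Tlag = L²/(6D)``), so lag-time parameter
  estimation is exercised on the real transient, not just the asymptote;
* applied-solution weight decay curves (near-linear decline to a small
  residual plateau) for T_eva estimation;
* noisy "observed" finite-dose absorption ratios, built from the
  numerical ODE oracle so they stay independent of the closed-form
  prediction they are later compared against.

Noise is multiplicative Gaussian (amounts are positive and replicate
scatter scales roughly with the mean); all randomness flows through a
seed, so a fixed seed gives byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .absorption_model import ode_oracle
from .datatypes import (
    EvaporationSeries,
    FiniteDoseConfig,
    MembraneSpec,
    NoiseModel,
    PermeationProfile,
    STRAT_M,
)

__all__ = [
    "slab_diffusion_cumulative",
    "generate_infinite_profile",
    "generate_evaporation_series",
    "generate_observed_absorption",
    "SyntheticStudySpec",
    "simulate_study",
]

_SERIES_TOL = 1e-12
_SERIES_MAX_TERMS = 200


def slab_diffusion_cumulative(
    times: np.ndarray, kp: float, K: float, L: float, cv: float
) -> np.ndarray:
    """Exact cumulative amount permeated through a slab membrane, µg/cm².

    Series solution of diffusion through a slab initially at zero
    concentration with constant donor concentration::

        Q(t) = K·L·Cv · ( D·t/L² − 1/6 − (2/π²) Σ_{n≥1} (−1)ⁿ/n² · exp(−D·n²π²·t/L²) )

    with ``D = Kp·L/K``.  The series is truncated when a term drops below
    1e-12 (cap 200 terms).  The large-t tangent is ``Kp·Cv·(t − L²/6D)``.
    """
    if not (kp > 0 and L > 0 and cv > 0):
        raise ValueError("need kp, L, cv > 0")
    if not K > 0:
        raise ValueError("K must be positive (D = Kp·L/K undefined at K = 0)")
    t = np.asarray(times, dtype=float)
    D = kp * L / K
    tau = D * t / (L * L)  # dimensionless time
    acc = np.zeros_like(tau)
    for n in range(1, _SERIES_MAX_TERMS + 1):
        term = ((-1.0) ** n / (n * n)) * np.exp(-(n * n) * np.pi**2 * tau)
        acc += term
        if np.max(np.abs(term)) < _SERIES_TOL:
            break
    q = K * L * cv * (tau - 1.0 / 6.0 - (2.0 / np.pi**2) * acc)
    return np.clip(q, 0.0, None)  # exact Q >= 0; clip truncation dust at tiny t


def generate_infinite_profile(
    kp: float,
    K: float,
    L: float,
    cv: float,
    times: Sequence[float] = (2.0, 4.0, 6.0, 8.0),
    noise: NoiseModel = NoiseModel(),
    seed: int | None = None,
    chemical: str = "synthetic",
    membrane: MembraneSpec | None = None,
) -> PermeationProfile:
    """Generate an infinite-dose permeation profile with known (Kp, K, D).

    The noiseless profile fed back to
    :func:`findose.params_estimation.estimate_parameters` recovers the
    generating parameters (round-trip property), provided the sampling
    window lies in the near-steady-state regime.
    """
    t = np.asarray(times, dtype=float)
    q = slab_diffusion_cumulative(t, kp, K, L, cv)
    rng = np.random.default_rng(seed)
    q = noise.apply(q, rng)
    if membrane is None:
        membrane = MembraneSpec("synthetic_membrane", L=L, A=1.0)
    elif membrane.L != L:
        raise ValueError("membrane.L must equal the generating thickness L")
    return PermeationProfile(
        chemical=chemical, times=t, cumulative=q, Cv=cv, membrane=membrane
    )


def generate_evaporation_series(
    w0: float,
    teva_true: float,
    interval: float = 0.25,
    noise: NoiseModel = NoiseModel(),
    seed: int | None = None,
    duration: float | None = None,
    residual_frac: float = 0.01,
) -> EvaporationSeries:
    """Generate an applied-solution weight curve: linear decline, then plateau.

    Weight falls linearly from ``w0`` (mg, at t = 0) to a residual plateau
    of ``residual_frac · w0`` reached exactly at ``teva_true`` (which must
    be a multiple of the sampling ``interval``), then stays flat until
    ``duration`` (default ``teva_true + 1 h``).
    """
    if not w0 > 0:
        raise ValueError("w0 must be positive")
    n_decline = teva_true / interval
    if abs(n_decline - round(n_decline)) > 1e-9:
        raise ValueError("teva_true must be a multiple of the sampling interval")
    if duration is None:
        duration = teva_true + 1.0
    times = np.arange(0.0, duration + interval / 2, interval)
    residual = residual_frac * w0
    weights = np.where(
        times < teva_true,
        w0 - (w0 - residual) * times / teva_true,
        residual,
    )
    rng = np.random.default_rng(seed)
    weights = noise.apply(weights, rng)
    return EvaporationSeries(times=times, weights=weights)


def generate_observed_absorption(
    kp: float,
    K: float,
    cv: float,
    cfg: FiniteDoseConfig = FiniteDoseConfig(),
    noise: NoiseModel = NoiseModel(),
    seed: int | None = None,
) -> float:
    """A noisy "observed" finite-dose absorption ratio with known truth.

    The ground truth is the ODE-oracle ratio (independent of the closed
    forms); noise perturbs it multiplicatively and the result is clipped
    to [0, 1].
    """
    truth = ode_oracle(kp, K, cv, cfg).ratio
    rng = np.random.default_rng(seed)
    observed = float(noise.apply(np.array([truth]), rng)[0])
    return float(np.clip(observed, 0.0, 1.0))


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Design of a full synthetic study: chemicals, membrane, sampling, noise.

    ``chemicals`` is a sequence of ``(name, Kp, K, Cv)`` ground truths.
    A fixed ``seed`` makes the whole bundle byte-identical across runs.
    """

    chemicals: tuple[tuple[str, float, float, float], ...]
    membrane: MembraneSpec = STRAT_M
    sampling_times: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0)
    noise: NoiseModel = NoiseModel()
    seed: int = 0
    n_replicates: int = 3
    cfg: FiniteDoseConfig = field(default_factory=FiniteDoseConfig)
    w0_mg: float = 10.0
    teva_true: float = 1.5


def simulate_study(spec: SyntheticStudySpec, outdir: str | Path | None = None) -> dict:
    """Generate a full study bundle (profiles, evaporation curve, observations).

    Returns a dict with per-chemical replicate profiles, the evaporation
    series, observed finite-dose ratios, and the ground truth.  When
    ``outdir`` is given, writes one profile CSV per chemical/replicate,
    the evaporation CSV and a ground-truth JSON alongside.
    """
    root = np.random.default_rng(spec.seed)
    bundle: dict = {"profiles": {}, "observed": {}, "truth": {}}
    for name, kp, K, cv in spec.chemicals:
        reps = []
        for _ in range(spec.n_replicates):
            sub = int(root.integers(0, 2**31 - 1))
            reps.append(
                generate_infinite_profile(
                    kp, K, spec.membrane.L, cv,
                    times=spec.sampling_times, noise=spec.noise, seed=sub,
                    chemical=name, membrane=spec.membrane,
                )
            )
        bundle["profiles"][name] = reps
        obs_seed = int(root.integers(0, 2**31 - 1))
        bundle["observed"][name] = generate_observed_absorption(
            kp, K, cv, spec.cfg, noise=spec.noise, seed=obs_seed
        )
        bundle["truth"][name] = {"kp": kp, "K": K, "cv": cv}
    eva_seed = int(root.integers(0, 2**31 - 1))
    bundle["evaporation"] = generate_evaporation_series(
        spec.w0_mg, spec.teva_true, noise=spec.noise, seed=eva_seed
    )
    if outdir is not None:
        _write_bundle(bundle, spec, Path(outdir))
    return bundle


def _write_bundle(bundle: dict, spec: SyntheticStudySpec, outdir: Path) -> None:
    import pandas as pd

    outdir.mkdir(parents=True, exist_ok=True)
    for name, reps in bundle["profiles"].items():
        for i, prof in enumerate(reps, start=1):
            df = pd.DataFrame(
                {"time_h": prof.times, "cumulative_ug_per_cm2": prof.cumulative}
            )
            df.to_csv(outdir / f"profile_{name}_rep{i}.csv", index=False)
    eva = bundle["evaporation"]
    pd.DataFrame({"time_h": eva.times, "weight_mg": eva.weights}).to_csv(
        outdir / "evaporation.csv", index=False
    )
    truth = {
        "seed": spec.seed,
        "membrane": {"name": spec.membrane.name, "L_cm": spec.membrane.L},
        "chemicals": bundle["truth"],
        "observed_ratios": bundle["observed"],
        "teva_true_h": spec.teva_true,
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
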