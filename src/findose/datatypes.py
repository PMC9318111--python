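"""Core domain types for finite-dose percutaneous absorption modelling.

Units are fixed throughout the package: time in hours, length in cm,
mass in µg, volume in mL (1 mL ≡ 1 cm³).  Concentrations are µg/mL,
cumulative permeated amounts µg/cm², fluxes µg/cm²/h, permeability
coefficients cm/h and diffusion coefficients cm²/h.  Callers convert
on ingest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MembraneSpec",
    "SamplingScheme",
    "PermeationProfile",
    "PermeationParameters",
    "ChemicalSpec",
    "FiniteDoseConfig",
    "AbsorptionPrediction",
    "EvaporationSeries",
    "TevaEstimate",
    "NoiseModel",
    "ComparisonResult",
    "PORCINE_SKIN",
    "STRAT_M",
]


@dataclass(frozen=True)
class MembraneSpec:
    """A diffusion membrane mounted in a Franz cell.

    Parameters
    ----------
    name:
        Label, e.g. ``"porcine_skin"`` or ``"strat_m"``.
    L:
        Membrane thickness in cm.
    A:
        Effective diffusion area in cm².
    """

    name: str
    L: float
    A: float = 1.0

    def __post_init__(self) -> None:
        if not self.L > 0:
            raise ValueError(f"membrane thickness L must be positive, got {self.L}")
        if not self.A > 0:
            raise ValueError(f"diffusion area A must be positive, got {self.A}")


#: Excised porcine ear skin, 0.10 cm thick, 1.0 cm² Franz-cell area.
PORCINE_SKIN = MembraneSpec("porcine_skin", L=0.10, A=1.0)

#: Strat-M synthetic membrane, 0.03 cm thick, 1.0 cm² Franz-cell area.
STRAT_M = MembraneSpec("strat_m", L=0.03, A=1.0)


@dataclass(frozen=True)
class SamplingScheme:
    """Receiver-compartment sampling protocol.

    An aliquot is withdrawn at each timepoint and replaced with fresh
    solvent, so measured receiver concentrations under-report the
    cumulative permeated amount; see
    :func:`findose.params_estimation.correct_cumulative_for_sampling`.
    """

    receiver_volume: float = 8.0  # mL
    aliquot_volume: float = 0.5  # mL

    def __post_init__(self) -> None:
        if not 0 < self.aliquot_volume <= self.receiver_volume:
            raise ValueError(
                "need 0 < aliquot_volume <= receiver_volume, got "
                f"{self.aliquot_volume} / {self.receiver_volume}"
            )


@dataclass(frozen=True)
class PermeationProfile:
    """One infinite-dose cumulative-permeation time course (one Franz cell).

    ``cumulative`` is the amount permeated per unit area (µg/cm²) at each
    sampling time; ``Cv`` the (effectively constant) donor concentration.
    """

    chemical: str
    times: np.ndarray  # h, strictly increasing
    cumulative: np.ndarray  # µg/cm²
    Cv: float  # µg/mL
    membrane: MembraneSpec

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        cumulative = np.asarray(self.cumulative, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "cumulative", cumulative)
        if times.ndim != 1 or times.size < 2:
            raise ValueError("need at least 2 sampling times")
        if times.size != cumulative.size:
            raise ValueError("times and cumulative must have the same length")
        if not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(times > 0):
            raise ValueError("all sampling times must be positive")
        if np.any(cumulative < 0):
            raise ValueError("cumulative amounts must be non-negative")
        if not self.Cv > 0:
            raise ValueError(f"donor concentration Cv must be positive, got {self.Cv}")


@dataclass(frozen=True)
class PermeationParameters:
    """Steady-state permeation parameters derived from one profile.

    ``Flux = Kp·Cv`` (steady-state flux), ``Tlag`` the x-intercept of the
    steady-state tangent, ``Kp = Flux/Cv``, ``D = L²/(6·Tlag)`` and
    ``K = 6·Tlag·Kp/L``.  ``D`` is NaN when ``Tlag <= 0`` (undefined);
    ``warnings`` records such anomalies instead of hiding them.
    """

    flux: float  # µg/cm²/h
    tlag: float  # h
    kp: float  # cm/h
    D: float  # cm²/h
    K: float  # dimensionless
    fit_r2: float
    n_points: int
    warnings: tuple[str, ...] = field(default=())


@dataclass(frozen=True)
class ChemicalSpec:
    """A test chemical and its applied aqueous solution."""

    name: str
    MW: float  # g/mol
    logKow: float
    Cv: float  # µg/mL
    solvent: str = "water"

    def __post_init__(self) -> None:
        if not self.Cv > 0:
            raise ValueError(f"Cv must be positive, got {self.Cv}")


@dataclass(frozen=True)
class FiniteDoseConfig:
    """Geometry and dosing constants for the finite-dose prediction.

    Defaults are the in-use experimental conditions: 10 µL of aqueous
    solution (``dose_volume`` = 0.01 cm³) on 1.0 cm², stratum-corneum
    volume 0.002 cm³, complete solvent evaporation at ``Teva`` = 1.5 h,
    observation until ``t_end`` = 24 h.
    """

    A: float = 1.0  # cm²
    V: float = 0.01  # cm³ applied solvent volume
    Vsc: float = 0.002  # cm³ stratum-corneum volume
    Teva: float = 1.5  # h
    t_end: float = 24.0  # h
    dose_volume: float = 0.01  # cm³

    def __post_init__(self) -> None:
        for attr in ("A", "V", "Vsc", "dose_volume"):
            if not getattr(self, attr) > 0:
                raise ValueError(f"{attr} must be positive, got {getattr(self, attr)}")
        if not 0 <= self.Teva <= self.t_end:
            raise ValueError(
                f"need 0 <= Teva <= t_end, got Teva={self.Teva}, t_end={self.t_end}"
            )


@dataclass(frozen=True)
class AbsorptionPrediction:
    """Mass budget of a finite-dose application at ``t_end``.

    ``M1`` is the amount cleared through the stratum corneum while solvent
    remains (phase 1, 0..Teva), ``M2`` the amount cleared from the SC depot
    afterwards (phase 2, Teva..t_end); ``total = M1 + M2`` is the
    percutaneous absorption and ``ratio = total / M0`` the absorption
    ratio.  ``surface_residue`` is the mass stranded on the skin surface
    when the solvent evaporates; it never penetrates.
    """

    M0: float  # µg applied
    M1: float  # µg
    M2: float  # µg
    total: float  # µg
    ratio: float
    Msc_at_teva: float  # µg in the SC when the solvent is gone
    Msc_at_end: float  # µg left in the SC at t_end
    surface_residue: float  # µg stranded on the surface

    def mass_balance_error(self) -> float:
        """Relative mass-balance defect |M1+M2+Msc(t_end)+residue − M0| / M0."""
        if self.M0 == 0:
            return 0.0
        acc = self.M1 + self.M2 + self.Msc_at_end + self.surface_residue
        return abs(acc - self.M0) / self.M0


@dataclass(frozen=True)
class EvaporationSeries:
    """Applied-solution weight (mg) vs time (h), sampled uniformly."""

    times: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "weights", weights)
        if times.size != weights.size:
            raise ValueError("times and weights must have the same length")
        if not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(weights < 0):
            raise ValueError("weights must be non-negative")


@dataclass(frozen=True)
class TevaEstimate:
    """Complete-evaporation time estimated from a weight series."""

    Teva: float  # h
    plateau_weight: float  # mg
    criterion: str


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise model for synthetic data.

    ``gaussian_relative`` applies multiplicative Gaussian noise
    ``x·(1 + σ·z)``; amounts stay non-negative by clipping.
    """

    kind: str = "none"  # {"none", "gaussian_relative"}
    sigma_rel: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian_relative"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma_rel < 0:
            raise ValueError("sigma_rel must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.kind == "none" or self.sigma_rel == 0.0:
            return values.copy()
        perturbed = values * (1.0 + self.sigma_rel * rng.standard_normal(values.shape))
        return np.clip(perturbed, 0.0, None)


@dataclass(frozen=True)
class ComparisonResult:
    """Predicted-vs-observed agreement metrics."""

    n: int
    r: float
    p_value: float
    slope: float
    factor2_fraction: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0 + 1e-15:
            raise ValueError(f"Pearson r out of range: {self.r}")
        if not 0.0 <= self.factor2_fraction <= 1.0:
            raise ValueError(f"factor-2 fraction out of range: {self.factor2_fraction}")


def partition_fraction(K: float, V: float, Vsc: float) -> float:
    """Fraction of the surface+SC compartment residing in the SC at equilibrium.

    ``Vsc·K / (V + Vsc·K)``; tends to 1 as K → ∞ (everything partitions
    into the SC) and to 0 as K → 0.
    """
    if K < 0:
        raise ValueError(f"partition coefficient K must be >= 0, got {K}")
    if math.isinf(K):
        return 1.0
    denom = V + Vsc * K
    if denom == 0:
        return 0.0
    return Vsc * K / denom
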