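"""Run configuration: experiment constants with validated defaults.

The defaults are the standard study conditions: membrane thicknesses
0.10 cm (skin) and 0.03 cm (Strat-M), 1.0 cm² area, 10 µL applied dose,
stratum-corneum volume 0.002 cm³, complete evaporation at 1.5 h,
24 h observation.  Config files are flat YAML ``key: value`` mappings;
omitted keys keep their defaults and unknown keys are rejected.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .datatypes import FiniteDoseConfig

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    L_skin: float = 0.10  # cm
    L_stratm: float = 0.03  # cm
    A: float = 1.0  # cm²
    V: float = 0.01  # cm³
    Vsc: float = 0.002  # cm³
    dose_volume: float = 0.01  # cm³
    Teva: float = 1.5  # h
    t_end: float = 24.0  # h
    skin_window_t_min: float = 2.0  # h
    stratm_window_t_min: float = 4.0  # h
    seed: int = 0
    output_dir: str = "findose_output"
    input_paths: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        for attr in (
            "L_skin", "L_stratm", "A", "V", "Vsc", "dose_volume", "t_end",
            "skin_window_t_min", "stratm_window_t_min",
        ):
            if not getattr(self, attr) > 0:
                raise ValueError(f"{attr} must be positive, got {getattr(self, attr)}")
        if not 0 <= self.Teva <= self.t_end:
            raise ValueError(f"need 0 <= Teva <= t_end, got {self.Teva}/{self.t_end}")

    def finite_dose_config(self) -> FiniteDoseConfig:
        return FiniteDoseConfig(
            A=self.A, V=self.V, Vsc=self.Vsc,
            Teva=self.Teva, t_end=self.t_end, dose_volume=self.dose_volume,
        )


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a RunConfig from a flat YAML key-value file.

    ``None`` or an empty file yields the full default configuration.
    Unknown keys raise a descriptive error.
    """
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a flat key: value mapping")
    known = set(asdict(RunConfig()))
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config key(s): {', '.join(sorted(unknown))}")
    if "input_paths" in raw:
        raw["input_paths"] = tuple(raw["input_paths"])
    return RunConfig(**raw)
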