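"""CSV readers/writers for permeation profiles and evaporation series.

Profile CSVs carry a ``time_h`` column plus either
``cumulative_ug_per_cm2`` (already-corrected cumulative amounts) or
``receiver_conc_ug_per_ml`` (raw receiver concentrations, converted via
the withdrawal mass-balance correction).  Metadata may be supplied as a
``# key: value`` header block or as keyword arguments; keyword arguments
win.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd

from .datatypes import (
    EvaporationSeries,
    MembraneSpec,
    PermeationProfile,
    SamplingScheme,
)
from .params_estimation import correct_cumulative_for_sampling

__all__ = ["read_profile_csv", "read_evaporation_csv", "write_profile_csv"]

_META_KEYS = {"chemical", "cv", "membrane", "l", "a", "receiver_volume", "aliquot_volume"}


def _parse_header_block(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                key = key.strip().lower()
                if key in _META_KEYS:
                    meta[key] = value.strip()
    return meta


def read_profile_csv(
    path: str | Path,
    chemical: str | None = None,
    Cv: float | None = None,
    membrane: MembraneSpec | None = None,
    scheme: SamplingScheme | None = None,
    apply_withdrawal_correction: bool = True,
) -> PermeationProfile:
    """Read one replicate's permeation profile from CSV.

    When the file holds receiver concentrations, the withdrawal
    correction is applied (toggle with ``apply_withdrawal_correction``;
    disabling it treats ``C·V_receiver/A`` as the cumulative amount).
    """
    path = Path(path)
    meta = _parse_header_block(path)
    df = pd.read_csv(path, comment="#")
    if "time_h" not in df.columns:
        raise ValueError(f"{path}: missing required column 'time_h'")
    chemical = chemical or meta.get("chemical", path.stem)
    if Cv is None:
        if "cv" not in meta:
            raise ValueError(f"{path}: donor concentration Cv not given")
        Cv = float(meta["cv"])
    if membrane is None:
        name = meta.get("membrane", "membrane")
        L = float(meta.get("l", 0.0))
        A = float(meta.get("a", 1.0))
        if L <= 0:
            raise ValueError(f"{path}: membrane thickness L not given")
        membrane = MembraneSpec(name, L=L, A=A)
    if "cumulative_ug_per_cm2" in df.columns:
        cumulative = df["cumulative_ug_per_cm2"].to_numpy(dtype=float)
    elif "receiver_conc_ug_per_ml" in df.columns:
        if scheme is None:
            scheme = SamplingScheme(
                receiver_volume=float(meta.get("receiver_volume", 8.0)),
                aliquot_volume=float(meta.get("aliquot_volume", 0.5)),
            )
        conc = df["receiver_conc_ug_per_ml"].to_numpy(dtype=float)
        if apply_withdrawal_correction:
            cumulative = correct_cumulative_for_sampling(conc, scheme, membrane.A)
        else:
            cumulative = conc * scheme.receiver_volume / membrane.A
    else:
        raise ValueError(
            f"{path}: need column 'cumulative_ug_per_cm2' or 'receiver_conc_ug_per_ml'"
        )
    return PermeationProfile(
        chemical=chemical,
        times=df["time_h"].to_numpy(dtype=float),
        cumulative=cumulative,
        Cv=Cv,
        membrane=membrane,
    )


def write_profile_csv(profile: PermeationProfile, path: str | Path) -> None:
    """Write a profile as CSV with a metadata header block."""
    buf = _io.StringIO()
    buf.write(f"# chemical: {profile.chemical}\n")
    buf.write(f"# cv: {profile.Cv}\n")
    buf.write(f"# membrane: {profile.membrane.name}\n")
    buf.write(f"# L: {profile.membrane.L}\n")
    buf.write(f"# A: {profile.membrane.A}\n")
    pd.DataFrame(
        {"time_h": profile.times, "cumulative_ug_per_cm2": profile.cumulative}
    ).to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def read_evaporation_csv(path: str | Path) -> EvaporationSeries:
    """Read an applied-solution weight series (columns time_h, weight_mg)."""
    df = pd.read_csv(path, comment="#")
    for col in ("time_h", "weight_mg"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    return EvaporationSeries(
        times=df["time_h"].to_numpy(dtype=float),
        weights=df["weight_mg"].to_numpy(dtype=float),
    )
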