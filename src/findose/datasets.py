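"""Packaged reference tables: chemical properties and permeation parameters.

The package ships the seven-chemical reference dataset (kojic acid,
caffeine, isosorbide 5-mononitrate, lidocaine, sodium benzoate at two
pH values, methylparaben) with their applied concentrations, and the
infinite-dose permeation parameters (Kp, K as mean ± SE) measured on
porcine skin and on Strat-M.  Note the chemical table records sodium
benzoate with MW 122.12 at pH 3.0 and 121.12 at pH 7.0, reproducing the
source table as published.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .datatypes import ChemicalSpec

__all__ = [
    "load_chemicals",
    "load_permeation_parameters",
    "chemical_specs",
    "STRAT_M_IN_DOMAIN",
    "LOGKOW_DOMAIN",
]

#: Applicability domain of Strat-M-derived parameters (Log Kow bounds).
LOGKOW_DOMAIN = (-0.2, 2.0)

#: Chemicals whose Strat-M permeation matches skin (within the Log Kow domain).
STRAT_M_IN_DOMAIN = ("CAF", "ISMN", "BA (pH 3.0)", "MP")


def _read(name: str) -> pd.DataFrame:
    with resources.files("findose.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_chemicals() -> pd.DataFrame:
    """Chemical properties table: name, abbreviation, MW, Log Kow, Cv, solvent."""
    return _read("table1_chemicals.csv")


def load_permeation_parameters(membrane: str | None = None) -> pd.DataFrame:
    """Permeation parameters (Kp, K, mean ± SE) per chemical and membrane.

    ``membrane`` filters to ``"porcine_skin"`` or ``"strat_m"``.
    """
    df = _read("table2_permeation_parameters.csv")
    if membrane is not None:
        if membrane not in set(df["membrane"]):
            raise ValueError(f"unknown membrane {membrane!r}")
        df = df[df["membrane"] == membrane].reset_index(drop=True)
    return df


def chemical_specs() -> dict[str, ChemicalSpec]:
    """The reference chemicals as :class:`ChemicalSpec`, keyed by abbreviation."""
    return {
        row.abbreviation: ChemicalSpec(
            name=row.abbreviation,
            MW=row.mw,
            logKow=row.log_kow,
            Cv=row.cv_ug_per_ml,
            solvent=row.solvent,
        )
        for row in load_chemicals().itertuples()
    }
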