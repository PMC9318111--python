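"""End-to-end study reproduction from the packaged reference tables.

``reproduce_study`` predicts the finite-dose percutaneous absorption
ratio for every reference chemical from the porcine-skin permeation
parameters, and for the four chemicals inside the Strat-M applicability
domain (Log Kow between −0.2 and 2.0: CAF, ISMN, BA (pH 3.0), MP) from
the Strat-M parameters.  Every closed-form prediction is cross-checked
against the numerical ODE oracle, and predictions from Strat-M
parameters for chemicals outside the Log Kow domain are emitted with an
out-of-domain warning rather than silently dropped.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import pandas as pd

from . import __version__
from .absorption_model import ode_oracle, predict_absorption
from .config import RunConfig
from .datasets import (
    LOGKOW_DOMAIN,
    STRAT_M_IN_DOMAIN,
    chemical_specs,
    load_permeation_parameters,
)

__all__ = ["reproduce_study", "predict_from_table"]


def _fixture_checksums() -> dict[str, str]:
    out = {}
    for name in ("table1_chemicals.csv", "table2_permeation_parameters.csv"):
        data = resources.files("findose.data").joinpath(name).read_bytes()
        out[name] = hashlib.sha256(data).hexdigest()
    return out


def predict_from_table(
    params_table: pd.DataFrame,
    chemicals: dict,
    cfg,
    check_domain: bool = False,
) -> pd.DataFrame:
    """Predict absorption for each (chemical, Kp, K) row of a parameter table.

    ``params_table`` needs columns abbreviation, membrane, kp_cm_per_h, k.
    Each row gains the closed-form mass budget, the ODE-oracle ratio and
    their relative difference; with ``check_domain``, chemicals whose
    Log Kow falls outside the Strat-M applicability domain are flagged.
    """
    rows = []
    for row in params_table.itertuples():
        chem = chemicals[row.abbreviation]
        pred = predict_absorption((row.kp_cm_per_h, row.k), chem, cfg)
        oracle = ode_oracle(row.kp_cm_per_h, row.k, chem.Cv, cfg)
        denom = oracle.ratio if oracle.ratio != 0 else 1.0
        rec = {
            "chemical": row.abbreviation,
            "membrane": row.membrane,
            "kp_cm_per_h": row.kp_cm_per_h,
            "K": row.k,
            "M0_ug": pred.M0,
            "M1_ug": pred.M1,
            "M2_ug": pred.M2,
            "total_ug": pred.total,
            "ratio": pred.ratio,
            "Msc_end_ug": pred.Msc_at_end,
            "surface_residue_ug": pred.surface_residue,
            "oracle_ratio": oracle.ratio,
            "oracle_rel_diff": abs(pred.ratio - oracle.ratio) / denom,
        }
        if check_domain:
            lo, hi = LOGKOW_DOMAIN
            rec["logKow"] = chem.logKow
            rec["in_domain"] = bool(lo <= chem.logKow <= hi)
        rows.append(rec)
    return pd.DataFrame(rows)


def reproduce_study(
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
    include_timestamp: bool = False,
) -> dict:
    """Run the full prediction workflow on the packaged parameter tables.

    Returns a report dict with the per-chemical prediction table
    (7 porcine-skin rows + 4 in-domain Strat-M rows), the constants used,
    fixture checksums and any applicability warnings.  When ``outdir``
    is given, writes ``predictions.csv`` and ``report.json``.  Output is
    deterministic; timestamps are off by default so repeated runs are
    byte-identical.
    """
    config = config or RunConfig()
    cfg = config.finite_dose_config()
    chems = chemical_specs()

    porcine = load_permeation_parameters("porcine_skin")
    porcine_pred = predict_from_table(porcine, chems, cfg)

    stratm = load_permeation_parameters("strat_m")
    stratm_all = predict_from_table(stratm, chems, cfg, check_domain=True)
    in_domain = stratm_all[stratm_all["chemical"].isin(STRAT_M_IN_DOMAIN)]
    warnings = [
        f"{c}: Log Kow {k:g} outside Strat-M applicability domain "
        f"[{LOGKOW_DOMAIN[0]}, {LOGKOW_DOMAIN[1]}]; prediction excluded from "
        "the reproduction table"
        for c, k in zip(stratm_all["chemical"], stratm_all["logKow"])
        if c not in STRAT_M_IN_DOMAIN
    ]

    predictions = pd.concat(
        [porcine_pred, in_domain.drop(columns=["logKow", "in_domain"])],
        ignore_index=True,
    )
    report = {
        "version": __version__,
        "constants": {
            "A_cm2": cfg.A, "V_cm3": cfg.V, "Vsc_cm3": cfg.Vsc,
            "Teva_h": cfg.Teva, "t_end_h": cfg.t_end,
            "dose_volume_cm3": cfg.dose_volume,
            "L_skin_cm": config.L_skin, "L_stratm_cm": config.L_stratm,
        },
        "fixture_sha256": _fixture_checksums(),
        "n_porcine": int(len(porcine_pred)),
        "n_stratm": int(len(in_domain)),
        "max_oracle_rel_diff": float(predictions["oracle_rel_diff"].max()),
        "applicability_warnings": warnings,
        "predictions": predictions.to_dict(orient="records"),
    }
    if include_timestamp:
        import datetime

        report["timestamp"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        predictions.to_csv(outdir / "predictions.csv", index=False)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
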