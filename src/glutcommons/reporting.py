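"""Tabular reporting: equilibrium, therapy and gambit sweeps as DataFrames.

Each builder returns a pandas DataFrame with raw float columns; with
``rounding="paper_integer"`` the strategy/payoff columns are rounded to the
nearest integer, half away from zero, matching the printed precision of the
reference tables.  Raw values are always recoverable by re-running with
``rounding="raw"``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .equilibrium import sweep_N
from .glut1 import EnzymeKinetics, estimate_glut1
from .model import ModelParams, ScalingAssumption
from .therapy import TherapyScenario, gambit_sweep

__all__ = [
    "ess_table",
    "therapy_table",
    "gambit_table",
    "glut1_report",
    "write_table",
]

Rounding = Literal["paper_integer", "raw"]

_ROUNDED_COLS = {
    "ess_transporters_per_cell",
    "ess_transporters_total",
    "ess_payoff",
    "team_transporters_per_cell",
    "team_payoff",
    "competitiveness",
    "treated_ess_transporters_per_cell",
    "treated_ess_payoff",
    "untreated_ess_transporters_per_cell",
    "untreated_ess_payoff",
    "resident_strategy",
    "gambit_payoff",
    "treated_ess_payoff",
}


def _round_half_away(x: float) -> float:
    return float(np.sign(x) * np.floor(np.abs(x) + 0.5))


def _apply_rounding(df: pd.DataFrame, rounding: Rounding) -> pd.DataFrame:
    if rounding == "raw":
        return df
    if rounding != "paper_integer":
        raise ValueError(f"rounding must be 'paper_integer' or 'raw'; got {rounding!r}")
    out = df.copy()
    for col in out.columns:
        if col in _ROUNDED_COLS:
            out[col] = out[col].map(_round_half_away).astype("int64")
    return out


def ess_table(
    params: ModelParams,
    N_values: Iterable[int],
    scaling: ScalingAssumption | str = ScalingAssumption.DEPLETION_ZONE,
    rounding: Rounding = "paper_integer",
) -> pd.DataFrame:
    """ESS vs team-optimum sweep over neighborhood sizes."""
    rows = []
    for ess, team in sweep_N(params, N_values, scaling):
        rows.append(
            {
                "N": ess.N,
                "ess_transporters_per_cell": ess.v_star,
                "ess_transporters_total": ess.v_star_total,
                "ess_payoff": ess.payoff,
                "team_transporters_per_cell": team.v_star,
                "team_payoff": team.payoff,
                "competitiveness": ess.v_star - team.v_star,
            }
        )
    return _apply_rounding(pd.DataFrame(rows), rounding)


def therapy_table(
    scenario: TherapyScenario,
    N_values: Iterable[int],
    scaling: ScalingAssumption | str = ScalingAssumption.DEPLETION_ZONE,
    rounding: Rounding = "paper_integer",
) -> pd.DataFrame:
    """Treated ESS sweep with untreated-comparison columns."""
    rows = []
    treated_pairs = sweep_N(scenario.treated, N_values, scaling)
    untreated_pairs = sweep_N(scenario.baseline, [p[0].N for p in treated_pairs], scaling)
    for (t_ess, _), (u_ess, _) in zip(treated_pairs, untreated_pairs):
        rows.append(
            {
                "N": t_ess.N,
                "treated_ess_transporters_per_cell": t_ess.v_star,
                "treated_ess_payoff": t_ess.payoff,
                "untreated_ess_transporters_per_cell": u_ess.v_star,
                "untreated_ess_payoff": u_ess.payoff,
            }
        )
    return _apply_rounding(pd.DataFrame(rows), rounding)


def gambit_table(
    scenario: TherapyScenario,
    N_values: Iterable[int],
    scaling: ScalingAssumption | str = ScalingAssumption.DEPLETION_ZONE,
    rounding: Rounding = "paper_integer",
) -> pd.DataFrame:
    """Sucker's-gambit sweep: inherited strategy, its mismatched payoff, and
    the treated-ESS payoff the cells would reach by re-equilibrating."""
    if scenario.hypothesis == "plastic":
        # Plastic cells re-equilibrate instantly: the gambit collapses onto
        # the plain treated-ESS table.
        return therapy_table(scenario, N_values, scaling, rounding)
    rows = []
    for res in gambit_sweep(scenario, N_values, scaling):
        rows.append(
            {
                "N": res.N,
                "resident_strategy": res.v_resident,
                "gambit_payoff": res.payoff,
                "treated_ess_payoff": res.reference_ess.payoff,
            }
        )
    return _apply_rounding(pd.DataFrame(rows), rounding)


def glut1_report(
    kin: EnzymeKinetics,
    variance: float = 0.5,
    mode: str = "paper_exact",
) -> dict:
    """Kinetics-derived transporter estimate as a plain dict (JSON-friendly)."""
    est = estimate_glut1(kin, variance=variance, mode=mode)  # type: ignore[arg-type]
    return {
        "mode": est.mode,
        "concentration_nmol_per_gram": est.concentration_per_gram,
        "transporters_per_cell": est.count_per_cell,
        "range_low": est.range_low,
        "range_high": est.range_high,
        "variance_fraction": variance,
    }


def write_table(df: pd.DataFrame, path: str | Path, fmt: Literal["csv", "json"] = "csv") -> None:
    """Write a result table to disk; CSV is comma-separated UTF-8 with header."""
    path = Path(path)
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=2) + "\n")
    else:
        raise ValueError(f"format must be 'csv' or 'json'; got {fmt!r}")
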