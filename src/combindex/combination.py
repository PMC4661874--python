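"""Chou-Talalay combination-index analysis for drug pairs.

The mutually non-exclusive combination index at a fixed effect level F
(here the IC50, F = 0.5) is

    CI = dA/DA + dB/DB + (dA * dB) / (DA * DB)

where DA and DB are the single-agent doses producing F and dA, dB the
doses of each agent in the combination that together produce F. The
cross-product term is what distinguishes the non-exclusive form used for
drugs with independent mechanisms; it makes CI strictly larger than the
two-term exclusive index.

Classification uses the study convention CI < 0.8 synergism, CI > 1.2
antagonism, 0.8 <= CI <= 1.2 additive (boundaries inclusive for the
additive call). A CI whose single-agent reference dose is out of the
tested range is *undefined* -- a first-class value, never an exception.

For combinations where CI cannot be formed at all (a partner with no
finite IC50), :func:`plot_based_call` compares the observed combination
inhibition against the Bliss-independence expectation across the shared
dose grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dose_response import DoseEffectCurve
from .errors import DataError, DomainError, UnitMismatchError

__all__ = [
    "CIInput",
    "CIResult",
    "combination_index",
    "classify_ci",
    "ci_grid",
    "bliss_expected_inhibition",
    "plot_based_call",
    "SYNERGY_THRESHOLD",
    "ANTAGONISM_THRESHOLD",
]

SYNERGY_THRESHOLD = 0.8
ANTAGONISM_THRESHOLD = 1.2


@dataclass(frozen=True)
class CIInput:
    """The dose quadruple behind one combination index.

    ``d_a_alone`` / ``d_b_alone`` are the single-agent doses giving the
    effect level F; ``d_a_combo`` / ``d_b_combo`` the doses of each agent
    in the combination giving the same F. ``None`` for an *alone* dose
    means that agent never reached F in the tested range, which makes the
    CI undefined. All four quantities must be measured under the same
    fixed-dose background, if any.
    """

    d_a_alone: Optional[float]
    d_b_alone: Optional[float]
    d_a_combo: float
    d_b_combo: float
    effect_level: float = 0.5
    background: tuple = ()

    def __post_init__(self):
        for name in ("d_a_combo", "d_b_combo"):
            v = getattr(self, name)
            if v is None or v <= 0:
                raise DomainError(f"{name} must be a positive concentration, got {v}")
        for name in ("d_a_alone", "d_b_alone"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise DomainError(f"{name} must be positive when defined, got {v}")
        if not 0.0 < self.effect_level < 1.0:
            raise DomainError(f"effect level must be in (0, 1), got {self.effect_level}")


@dataclass
class CIResult:
    ci: Optional[float]
    category: str  # synergism | additive | antagonism | undefined
    inputs: Optional[CIInput] = None
    meta: dict = None  # free-form cell labels for grid/report use

    def __post_init__(self):
        if self.meta is None:
            self.meta = {}


def combination_index(inp: CIInput) -> CIResult:
    """Evaluate the non-exclusive CI; undefined when a single-agent dose
    at the effect level does not exist (out of tested range)."""
    if inp.d_a_alone is None or inp.d_b_alone is None:
        return CIResult(ci=None, category="undefined", inputs=inp)
    ra = inp.d_a_combo / inp.d_a_alone
    rb = inp.d_b_combo / inp.d_b_alone
    ci = ra + rb + ra * rb
    return CIResult(ci=float(ci), category=classify_ci(ci), inputs=inp)


def classify_ci(ci: Optional[float]) -> str:
    """Map a CI to synergism (< 0.8), additive ([0.8, 1.2]) or antagonism
    (> 1.2); ``None`` (undefined, the table's "countless") passes through."""
    if ci is None:
        return "undefined"
    if ci <= 0 or not np.isfinite(ci):
        raise DomainError(f"combination index must be a positive number, got {ci}")
    if ci < SYNERGY_THRESHOLD:
        return "synergism"
    if ci > ANTAGONISM_THRESHOLD:
        return "antagonism"
    return "additive"


_GRID_COLUMNS = [
    "varied_agent",
    "partner_agent",
    "partner_dose",
    "partner_dose_unit",
    "background_dose",
    "ic50",
    "ic50_unit",
]


def ci_grid(ic50_table: pd.DataFrame) -> list[CIResult]:
    """Compute one CI per (partner agent, partner dose, background level)
    cell of a long-format IC50 table.

    The table holds one row per measured IC50 with columns
    ``varied_agent, partner_agent, partner_dose, partner_dose_unit,
    background_dose, ic50, ic50_unit``. Rows with a null ``partner_agent``
    are single-agent references: the varied agent alone (DA) under each
    background level, and each partner titrated alone (DB, a row whose
    ``varied_agent`` equals the partner) under the same background. A null
    ``ic50`` marks a single-agent IC50 out of the tested range and yields
    *undefined* cells rather than failures. The fixed background agent is
    identified by ``background_dose`` level alone; its own single-agent
    IC50 may be unknown without blocking the pairwise CI.
    """
    missing = [c for c in _GRID_COLUMNS if c not in ic50_table.columns]
    if missing:
        raise DataError(f"ic50 table missing column(s): {missing}")
    t = ic50_table.copy()
    t["partner_agent"] = t["partner_agent"].where(pd.notna(t["partner_agent"]), None)

    def _single_agent(agent: str, background_dose) -> tuple[Optional[float], Optional[str]]:
        rows = t[
            (t["varied_agent"] == agent)
            & (t["partner_agent"].isna())
            & (t["background_dose"] == background_dose)
        ]
        if rows.empty:
            return None, None
        r = rows.iloc[0]
        ic50 = r["ic50"]
        return (None if pd.isna(ic50) else float(ic50)), r["ic50_unit"]

    results = []
    combo_rows = t[t["partner_agent"].notna()]
    for _, row in combo_rows.iterrows():
        meta = {
            "varied_agent": row["varied_agent"],
            "partner_agent": row["partner_agent"],
            "partner_dose": float(row["partner_dose"]),
            "background_dose": row["background_dose"],
        }
        da_alone, da_unit = _single_agent(row["varied_agent"], row["background_dose"])
        db_alone, db_unit = _single_agent(row["partner_agent"], row["background_dose"])
        da_combo = None if pd.isna(row["ic50"]) else float(row["ic50"])
        if da_unit is not None and row["ic50_unit"] != da_unit:
            raise UnitMismatchError(
                f"{row['varied_agent']}: combo IC50 in {row['ic50_unit']}, "
                f"single-agent IC50 in {da_unit}"
            )
        if db_alone is not None and row["partner_dose_unit"] != db_unit:
            raise UnitMismatchError(
                f"{row['partner_agent']}: fixed dose in {row['partner_dose_unit']}, "
                f"single-agent IC50 in {db_unit}"
            )
        if da_combo is None or da_alone is None or db_alone is None:
            res = CIResult(ci=None, category="undefined")
        else:
            res = combination_index(
                CIInput(
                    d_a_alone=da_alone,
                    d_b_alone=db_alone,
                    d_a_combo=da_combo,
                    d_b_combo=float(row["partner_dose"]),
                )
            )
        res.meta.update(meta)
        results.append(res)
    return results


def bliss_expected_inhibition(fa_a: float, fa_b: float) -> float:
    """Expected combined inhibition if the agents act independently:
    1 - (1 - fa_a)(1 - fa_b)."""
    for name, v in (("fa_a", fa_a), ("fa_b", fa_b)):
        if not 0.0 <= v <= 1.0:
            raise DomainError(f"{name} must be a fraction in [0, 1], got {v}")
    return 1.0 - (1.0 - fa_a) * (1.0 - fa_b)


def plot_based_call(
    curve_combo: DoseEffectCurve,
    curve_a: DoseEffectCurve,
    fa_b: float,
    tolerance: float = 0.05,
) -> str:
    """Classify a combination by its mean excess inhibition over the Bliss
    expectation across a shared dose grid.

    ``fa_b`` is the fixed partner's single-agent fraction affected at its
    plate dose. Mean signed excess above ``tolerance`` is synergism, below
    ``-tolerance`` antagonism, otherwise additive. The default tolerance
    (0.05 fraction affected) absorbs triplicate noise at CV ~0.10.
    """
    if len(curve_combo.doses) != len(curve_a.doses) or not np.allclose(
        curve_combo.doses, curve_a.doses, rtol=1e-9
    ):
        raise DataError("combination and single-agent curves must share a dose grid")
    expected = np.array(
        [bliss_expected_inhibition(float(np.clip(fa, 0.0, 1.0)), fa_b) for fa in curve_a.fa]
    )
    excess = float(np.mean(curve_combo.fa - expected))
    if excess > tolerance:
        return "synergism"
    if excess < -tolerance:
        return "antagonism"
    return "additive"


def ci_results_to_frame(results: Sequence[CIResult]) -> pd.DataFrame:
    """Tidy DataFrame view of grid results (one row per cell)."""
    rows = []
    for r in results:
        row = dict(r.meta)
        row["ci"] = r.ci
        row["category"] = r.category
        rows.append(row)
    return pd.DataFrame(rows)
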