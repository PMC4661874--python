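"""End-to-end orchestration: simulate -> IC50 -> CI -> in vivo -> report.

These functions are the library behind the CLI subcommands. Each stage
consumes and produces the public containers of the analysis modules so
results stay inspectable between steps.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from . import synthetic
from .combination import CIResult, ci_grid
from .dose_response import (
    IC50Estimate,
    WellRecord,
    aggregate_experiments,
    build_curve,
    ic50_4pl,
    ic50_interpolate,
)
from .errors import ConfigurationError
from .invivo import GroupDaySummary, TumorObservation, summarize_study

__all__ = [
    "simulate_study",
    "estimate_ic50s",
    "ic50_grid_table",
    "analyze_combinations",
    "analyze_invivo",
]

_ESTIMATORS = {
    "interp": ic50_interpolate,
    "interpolation": ic50_interpolate,
    "4pl": ic50_4pl,
    "four_parameter_logistic": ic50_4pl,
}

# Default fixed partner doses for the simulated combination plates
# (cytostatic held constant while imatinib is titrated).
DEFAULT_PARTNER_DOSES = {"DTX": (1.0,)}


def simulate_study(
    seed: int, noise_cv: float = 0.10
) -> tuple[list[WellRecord], list[TumorObservation]]:
    """Generate the default study: single-agent and combination plates
    (imatinib titrated alone, over the vitamin-D-analog background, and
    over cytostatic + background), plus the six-group xenograft study."""
    truths = synthetic.study_ground_truths()
    by_id = {t.agent_id: t for t in truths}
    wells: list[WellRecord] = []
    bg_levels = (None, *synthetic.PRI2191_BACKGROUND_NM)
    k = 0
    for bg in bg_levels:
        bg_part = (("PRI-2191", bg),) if bg is not None else ()
        # imatinib alone under this background level
        wells += synthetic.simulate_plate(
            truths,
            synthetic.PlateDesign(
                "GV", synthetic.GV_DOSES_NG_ML, background=bg_part,
                seed=seed + k, noise_cv=noise_cv,
            ),
        )
        k += 1
        for partner, doses in DEFAULT_PARTNER_DOSES.items():
            # the cytostatic titrated alone under this background (D_B)
            wells += synthetic.simulate_plate(
                truths,
                synthetic.PlateDesign(
                    partner, synthetic.DTX_ID_DOSES_NG_ML, background=bg_part,
                    seed=seed + k, noise_cv=noise_cv,
                ),
            )
            k += 1
            for dose in doses:
                # imatinib titrated over cytostatic + background
                wells += synthetic.simulate_plate(
                    truths,
                    synthetic.PlateDesign(
                        "GV",
                        synthetic.GV_DOSES_NG_ML,
                        background=bg_part + ((partner, dose),),
                        seed=seed + k,
                        noise_cv=noise_cv,
                    ),
                )
                k += 1
    observations = synthetic.simulate_tumor_study(
        synthetic.study_tumor_groups(seed=seed + 100, noise_cv=noise_cv),
        synthetic.STUDY_MEASUREMENT_DAYS,
    )
    return wells, observations


def estimate_ic50s(
    wells: Sequence[WellRecord], method: str = "interp"
) -> list[IC50Estimate]:
    """Per-condition IC50s: one per-experiment estimate each, aggregated
    as mean +/- sample SD across experiments."""
    try:
        estimator = _ESTIMATORS[method]
    except KeyError:
        raise ConfigurationError(f"unknown IC50 method {method!r}") from None
    conditions = sorted({w.condition for w in wells}, key=repr)
    aggregated = []
    for cond in conditions:
        cond_wells = [w for w in wells if w.condition == cond]
        experiments = sorted({w.experiment_id for w in cond_wells})
        per_exp = []
        for exp in experiments:
            curve = build_curve(
                [w for w in cond_wells if w.experiment_id == exp], cond
            )
            per_exp.append(estimator(curve))
        aggregated.append(aggregate_experiments(per_exp))
    return aggregated


def ic50_grid_table(
    estimates: Sequence[IC50Estimate], background_agent: str = "PRI-2191"
) -> pd.DataFrame:
    """Reshape aggregated IC50s into the long-format table ci_grid reads.

    The named background agent sets the ``background_dose`` level (0 when
    absent); any other fixed-dose agent in a condition is the combination
    partner. Out-of-range estimates carry a null ic50.
    """
    rows = []
    for e in estimates:
        partners = [b for b in e.condition.background if b.agent != background_agent]
        if len(partners) > 1:
            raise ConfigurationError(
                f"condition {e.condition} has multiple partner agents: {partners}"
            )
        bg = next(
            (b.dose for b in e.condition.background if b.agent == background_agent), 0.0
        )
        partner = partners[0] if partners else None
        rows.append(
            {
                "varied_agent": e.condition.varied_agent,
                "partner_agent": partner.agent if partner else None,
                "partner_dose": partner.dose if partner else None,
                "partner_dose_unit": partner.unit if partner else None,
                "background_dose": bg,
                "ic50": e.mean if e.status == "ok" else None,
                "ic50_unit": e.condition.dose_unit,
                "ic50_sd": e.sd,
                "n_experiments": e.n_used,
            }
        )
    return pd.DataFrame(rows)


def analyze_combinations(
    estimates: Sequence[IC50Estimate], background_agent: str = "PRI-2191"
) -> list[CIResult]:
    """CI grid over the aggregated IC50s, annotated with the combination
    IC50 mean/SD for reporting."""
    table = ic50_grid_table(estimates, background_agent)
    results = ci_grid(table[[c for c in table.columns if c not in ("ic50_sd", "n_experiments")]])
    by_cell = {
        (r["varied_agent"], r["partner_agent"], r["partner_dose"], r["background_dose"]): r
        for r in table.to_dict("records")
        if r["partner_agent"] is not None
    }
    for res in results:
        key = (
            res.meta["varied_agent"],
            res.meta["partner_agent"],
            res.meta["partner_dose"],
            res.meta["background_dose"],
        )
        src = by_cell.get(key)
        if src is not None:
            res.meta["ic50_mean"] = src["ic50"]
            res.meta["ic50_sd"] = src["ic50_sd"]
    return results


def analyze_invivo(
    observations: Sequence[TumorObservation],
    control_group: str = "control",
    baseline_day: Optional[int] = None,
) -> list[GroupDaySummary]:
    return summarize_study(observations, control_group, baseline_day=baseline_day)
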