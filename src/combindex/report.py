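"""Report assembly: CSV + JSON mirrors of the two study-table shapes.

The in vitro table pivots the CI grid wide (rows: cytostatic x fixed
dose; per background level: varied-agent IC50 mean, SD, CI, category),
rendering undefined CIs as ``countless/NA``. The in vivo table lists
median volume, TGI% and HTGI% per group and day. Every number is computed
upstream by a dose_response / combination / invivo operation; rendering
only formats. Methodological flags (estimator used, TGI sign convention,
the independence reading of hypothetical TGI, any warnings raised during
analysis) go to the report footer, never silently dropped.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .combination import CIResult
from .dose_response import IC50Estimate
from .invivo import GroupDaySummary, round_half_away, summaries_to_frame

__all__ = ["render_report", "pivot_ci_table", "pivot_invivo_table"]

UNDEFINED_CI = "countless/NA"

FOOTER_NOTES = [
    "TGI% = 100*(1 - VT/VC): positive values denote inhibition (the sign "
    "convention of the reported tables; the ratio form (VT/VC)*100-100 has "
    "the opposite sign).",
    "HTGI is the hypothetical TGI under independence: "
    "100*(1 - (VT_a/VC)*(VT_b/VC)) from the paired single-agent medians.",
    "CI thresholds: <0.8 synergism, 0.8-1.2 additive (inclusive), >1.2 "
    "antagonism; 'countless/NA' marks CIs undefined because a single-agent "
    "IC50 lies outside the tested range.",
    "Rounding of reported TGI/HTGI: nearest integer, halves away from zero.",
]


def _fmt(v, nd=3) -> str:
    return "" if v is None else f"{v:.{nd}g}"


def pivot_ci_table(
    ci_results: Sequence[CIResult],
    ic50_estimates: Optional[Sequence[IC50Estimate]] = None,
) -> pd.DataFrame:
    """Wide table: one row per (partner agent, partner dose), one column
    block per background level with the varied agent's combination IC50
    (mean +/- SD when aggregated) and the CI with its category."""
    rows = {}
    for r in ci_results:
        key = (r.meta.get("partner_agent"), r.meta.get("partner_dose"))
        bg = r.meta.get("background_dose")
        cell = rows.setdefault(key, {})
        cell[f"bg{bg}_ci"] = UNDEFINED_CI if r.ci is None else round(r.ci, 3)
        cell[f"bg{bg}_category"] = r.category
        if "ic50_mean" in r.meta:
            cell[f"bg{bg}_ic50_mean"] = r.meta["ic50_mean"]
            cell[f"bg{bg}_ic50_sd"] = r.meta.get("ic50_sd")
    out = []
    for (agent, dose), cell in sorted(rows.items(), key=lambda kv: (kv[0][0], -kv[0][1])):
        row = {"partner_agent": agent, "partner_dose": dose}
        row.update(cell)
        out.append(row)
    return pd.DataFrame(out)


def pivot_invivo_table(summaries: Sequence[GroupDaySummary], days=None) -> pd.DataFrame:
    """Study-table layout: one row per group, per-day column blocks of
    median volume, rounded TGI% and rounded HTGI% ('countless' for groups
    where no independence expectation applies)."""
    if days is None:
        days = sorted({s.day for s in summaries})
    rows = {}
    for s in summaries:
        if s.day not in days:
            continue
        row = rows.setdefault(s.group, {"group": s.group})
        row[f"day{s.day}_median_mm3"] = round(s.median_volume, 1)
        row[f"day{s.day}_tgi_pct"] = (
            "countless" if s.tgi is None else round_half_away(s.tgi)
        )
        row[f"day{s.day}_htgi_pct"] = (
            "countless" if s.htgi is None else round_half_away(s.htgi)
        )
    return pd.DataFrame(list(rows.values()))


def _ic50_frame(estimates: Sequence[IC50Estimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        bg = ";".join(f"{b.agent}={b.dose:g} {b.unit}" for b in e.condition.background)
        rows.append(
            {
                "varied_agent": e.condition.varied_agent,
                "dose_unit": e.condition.dose_unit,
                "background": bg,
                "method": e.method,
                "status": e.status,
                "ic50": e.value,
                "ic50_mean": e.mean,
                "ic50_sd": e.sd,
                "n_experiments_used": e.n_used,
                "n_experiments_excluded": e.n_excluded,
                "flags": ";".join(e.flags),
            }
        )
    return pd.DataFrame(rows)


def render_report(
    results: dict,
    out_dir,
    warnings: Optional[Sequence[str]] = None,
) -> dict:
    """Write CSV and JSON mirrors of whichever analysis sections are
    present in ``results`` (keys: ``ic50`` -> list[IC50Estimate], ``ci``
    -> list[CIResult], ``invivo`` -> list[GroupDaySummary]); empty
    sections are omitted. Returns {section: [paths written]}."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, list[str]] = {}
    report_json: dict = {"sections": {}, "notes": list(FOOTER_NOTES)}
    if warnings:
        report_json["warnings"] = list(warnings)

    if results.get("ic50"):
        frame = _ic50_frame(results["ic50"])
        p = out_dir / "ic50_table.csv"
        frame.to_csv(p, index=False)
        written["ic50"] = [str(p)]
        report_json["sections"]["ic50"] = json.loads(frame.to_json(orient="records"))

    if results.get("ci"):
        ci_results = results["ci"]
        frame = pivot_ci_table(ci_results)
        p = out_dir / "ci_table.csv"
        frame.to_csv(p, index=False)
        written["ci"] = [str(p)]
        report_json["sections"]["ci"] = [
            {
                **r.meta,
                "ci": r.ci,
                "category": r.category,
            }
            for r in ci_results
        ]

    if results.get("invivo"):
        summaries = results["invivo"]
        wide = pivot_invivo_table(summaries)
        p1 = out_dir / "invivo_table.csv"
        wide.to_csv(p1, index=False)
        tidy = summaries_to_frame(summaries)
        p2 = out_dir / "invivo_summaries.csv"
        tidy.to_csv(p2, index=False)
        written["invivo"] = [str(p1), str(p2)]
        report_json["sections"]["invivo"] = json.loads(tidy.to_json(orient="records"))

    p = out_dir / "report.json"
    with open(p, "w", encoding="utf-8") as fh:
        json.dump(report_json, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written["report"] = [str(p)]
    return written
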