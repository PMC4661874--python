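"""Xenograft tumor-growth-inhibition analysis.

Caliper volumes use the standard formula V = (a^2 * b) / 2 with a the
shorter and b the longer diameter in mm. Efficacy is summarized per group
and day by the median volume; tumor growth inhibition is

    TGI% = 100 * (1 - VT / VC)

with VT the treated-group and VC the concurrent-control median (positive
values mean inhibition). For a combination group, the *hypothetical* TGI
is the inhibition expected if the two single agents acted independently
(Bliss independence on the volume ratios):

    HTGI% = 100 * (1 - (VT_a / VC) * (VT_b / VC))

A combination beating its HTGI indicates in vivo synergy. Rounding to
integers (half away from zero) happens only at reporting; internal values
keep full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DomainError, InsufficientDataError

__all__ = [
    "TumorObservation",
    "GroupDaySummary",
    "tumor_volume",
    "group_median",
    "tgi",
    "htgi",
    "body_weight_change",
    "compare_groups",
    "summarize_study",
    "round_half_away",
]


@dataclass(frozen=True)
class TumorObservation:
    """One mouse on one measurement day: caliper diameters (mm) and,
    optionally, body weight (g). Diameters are canonicalized so that
    ``diam_short <= diam_long``."""

    mouse_id: str
    group: str
    day: int
    diam_short: float
    diam_long: float
    body_weight: Optional[float] = None

    def __post_init__(self):
        if self.diam_short <= 0 or self.diam_long <= 0:
            raise DataError(
                f"non-positive diameter for mouse {self.mouse_id} day {self.day}"
            )
        if self.day < 0:
            raise DataError("day must be >= 0 (days post-inoculation)")
        if self.diam_short > self.diam_long:
            a, b = self.diam_long, self.diam_short
            object.__setattr__(self, "diam_short", a)
            object.__setattr__(self, "diam_long", b)

    @property
    def volume(self) -> float:
        return tumor_volume(self.diam_short, self.diam_long)


@dataclass
class GroupDaySummary:
    """Per-group, per-day medians with TGI (treated groups), HTGI
    (combination groups) and body-weight change from baseline."""

    group: str
    day: int
    median_volume: float
    n_mice: int
    tgi: Optional[float] = None
    htgi: Optional[float] = None
    body_weight_change: Optional[float] = None
    flags: list = field(default_factory=list)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (reporting rule)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def tumor_volume(a: float, b: float) -> float:
    """(shorter^2 * longer) / 2 in mm^3; argument order is irrelevant."""
    if a <= 0 or b <= 0:
        raise DataError(f"diameters must be positive, got ({a}, {b})")
    lo, hi = min(a, b), max(a, b)
    return (lo * lo * hi) / 2.0


def group_median(
    observations: Sequence[TumorObservation], group: str, day: int
) -> Optional[float]:
    """Median tumor volume for (group, day); ``None`` when no mouse was
    measured (missing data, not an error). Mice lost to follow-up are
    simply absent on later days."""
    vols = [o.volume for o in observations if o.group == group and o.day == day]
    if not vols:
        return None
    return float(np.median(vols))


def tgi(vt: float, vc: float) -> float:
    """Tumor growth inhibition percent, 100 * (1 - VT/VC); positive values
    denote inhibition, negative values a treated median above control."""
    if vc <= 0:
        raise DomainError(f"control median volume must be positive, got {vc}")
    return 100.0 * (1.0 - vt / vc)


def htgi(vt_a: float, vt_b: float, vc: float) -> float:
    """Hypothetical TGI under independence: the combination inhibition
    expected if the single agents' volume ratios multiplied,
    100 * (1 - (VT_a/VC) * (VT_b/VC)). Symmetric in the two agents and
    algebraically equal to tgi(vt_a * vt_b / vc, vc)."""
    if vc <= 0:
        raise DomainError(f"control median volume must be positive, got {vc}")
    return 100.0 * (1.0 - (vt_a / vc) * (vt_b / vc))


def body_weight_change(
    observations: Sequence[TumorObservation],
    group: str,
    day: int,
    baseline_day: int,
) -> Optional[float]:
    """Percent change of mean body weight from baseline day to target day,
    over mice weighed on both days; ``None`` when no mouse overlaps."""
    base = {
        o.mouse_id: o.body_weight
        for o in observations
        if o.group == group and o.day == baseline_day and o.body_weight is not None
    }
    now = {
        o.mouse_id: o.body_weight
        for o in observations
        if o.group == group and o.day == day and o.body_weight is not None
    }
    shared = sorted(set(base) & set(now))
    if not shared:
        return None
    w0 = float(np.mean([base[m] for m in shared]))
    w1 = float(np.mean([now[m] for m in shared]))
    if w0 <= 0:
        raise DataError(f"non-positive baseline weight mean for group {group}")
    return 100.0 * (w1 - w0) / w0


def compare_groups(
    observations: Sequence[TumorObservation],
    group_a: str,
    group_b: str,
    day: int,
    test: str = "mannwhitney",
) -> Optional[float]:
    """Two-tailed nonparametric p-value comparing tumor volumes of two
    groups on one day (Mann-Whitney U by default, Kruskal-Wallis as an
    alternative). ``None`` when either group has fewer than two mice."""
    xa = [o.volume for o in observations if o.group == group_a and o.day == day]
    xb = [o.volume for o in observations if o.group == group_b and o.day == day]
    if len(xa) < 2 or len(xb) < 2:
        return None
    if test == "mannwhitney":
        return float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
    if test == "kruskal":
        return float(stats.kruskal(xa, xb).pvalue)
    raise ValueError(f"unknown test {test!r}")


def _combination_parts(group: str, groups: set, sep: str = " + ") -> Optional[tuple]:
    """Split a combination label 'A + B' into its single-agent groups,
    provided both exist in the study; no other pairing is supported."""
    if sep not in group:
        return None
    a, b = group.split(sep, 1)
    a, b = a.strip(), b.strip()
    if a in groups and b in groups:
        return a, b
    return None


def summarize_study(
    observations: Sequence[TumorObservation],
    control_group: str,
    baseline_day: Optional[int] = None,
    combination_sep: str = " + ",
) -> list[GroupDaySummary]:
    """Full per-group/day study summary: median volumes, TGI against the
    concurrent control, HTGI for combination groups whose label splits
    into two present single-agent groups, and body-weight change from the
    baseline (default: earliest) day. TGI is computed only for days on
    which the control was also measured; there is no interpolation across
    days."""
    if not observations:
        raise InsufficientDataError("no observations")
    groups = sorted({o.group for o in observations})
    if control_group not in groups:
        raise DataError(f"control group {control_group!r} not present in data")
    days = sorted({o.day for o in observations})
    if baseline_day is None:
        baseline_day = days[0]
    group_set = set(groups)

    summaries = []
    for day in days:
        vc = group_median(observations, control_group, day)
        for group in groups:
            med = group_median(observations, group, day)
            if med is None:
                continue
            n = len({o.mouse_id for o in observations if o.group == group and o.day == day})
            s = GroupDaySummary(group=group, day=day, median_volume=med, n_mice=n)
            if group != control_group and vc is not None:
                s.tgi = tgi(med, vc)
                parts = _combination_parts(group, group_set - {group}, combination_sep)
                if parts is not None:
                    va = group_median(observations, parts[0], day)
                    vb = group_median(observations, parts[1], day)
                    if va is not None and vb is not None:
                        s.htgi = htgi(va, vb, vc)
                        s.flags.append("htgi_independence_expectation")
            s.body_weight_change = body_weight_change(
                observations, group, day, baseline_day
            )
            summaries.append(s)
    return summaries


def summaries_to_frame(summaries: Sequence[GroupDaySummary]) -> pd.DataFrame:
    """Tidy DataFrame of summaries, with reporting-rounded TGI/HTGI columns
    alongside the full-precision ones."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "group": s.group,
                "day": s.day,
                "median_volume_mm3": s.median_volume,
                "n_mice": s.n_mice,
                "tgi_pct": s.tgi,
                "tgi_pct_rounded": None if s.tgi is None else round_half_away(s.tgi),
                "htgi_pct": s.htgi,
                "htgi_pct_rounded": None if s.htgi is None else round_half_away(s.htgi),
                "body_weight_change_pct": s.body_weight_change,
            }
        )
    return pd.DataFrame(rows)
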