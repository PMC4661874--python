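"""Plate normalization, dose-effect curves and IC50 estimation.

The IC50 is the concentration inhibiting proliferation by 50% relative to
vehicle control. Two estimators are provided and every report names the
one used:

* ``interpolation`` -- log-linear interpolation between the two doses
  bracketing 50% inhibition, the common manual practice for SRB
  (sulforhodamine B) viability plates;
* ``four_parameter_logistic`` -- a least-squares 4PL fit
  ``fa(d) = bottom + (top - bottom) / (1 + (ic50 / d)**slope)``.

IC50s are estimated per experiment and then aggregated as mean +/- sample
SD across experiments, the convention of multi-experiment SRB studies.
Doses carry their native unit (ng/mL, ug/mL, nM); nothing converts units
implicitly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import DataError, InsufficientDataError, UnitMismatchError

__all__ = [
    "BackgroundDose",
    "Condition",
    "WellRecord",
    "DoseEffectCurve",
    "IC50Estimate",
    "normalize_viability",
    "build_curve",
    "ic50_interpolate",
    "ic50_4pl",
    "aggregate_experiments",
]


class BackgroundDose(NamedTuple):
    """A fixed-dose background agent present in every well of a condition."""

    agent: str
    dose: float
    unit: str


class Condition(NamedTuple):
    """Identifies a dose-response condition: the varied agent (with its
    dose unit) and the fixed-dose background it was titrated over."""

    varied_agent: str
    dose_unit: str
    background: tuple  # tuple[BackgroundDose, ...], sorted by agent


def make_condition(
    varied_agent: str, dose_unit: str, background: Sequence[BackgroundDose] = ()
) -> Condition:
    bg = tuple(sorted((BackgroundDose(*b) for b in background), key=lambda b: b.agent))
    return Condition(varied_agent, dose_unit, bg)


@dataclass(frozen=True)
class WellRecord:
    """One plate well: a dose assignment plus its viability reading.

    ``viability`` is the fraction of the vehicle-control signal (1.0 means
    no inhibition). Raw absorbances travel in the same field until
    :func:`normalize_viability` divides by the in-experiment control mean.
    """

    experiment_id: str
    varied_agent: str
    dose: float
    dose_unit: str
    replicate: int
    viability: float
    background: tuple = ()  # tuple[BackgroundDose, ...]

    def __post_init__(self):
        if self.dose < 0:
            raise DataError(f"negative dose {self.dose} for {self.varied_agent}")
        if self.viability < 0:
            raise DataError(f"negative viability reading {self.viability}")
        if not self.dose_unit:
            raise DataError("every dose must record its unit")

    @property
    def condition(self) -> Condition:
        return make_condition(self.varied_agent, self.dose_unit, self.background)


@dataclass
class DoseEffectCurve:
    """Per-condition dose grid with mean fraction-affected values.

    ``fa`` is 1 - mean viability at each dose. Small negative values
    (wells reading above control) are retained and flagged; values below
    -0.5 are rejected as data errors.
    """

    condition: Condition
    doses: np.ndarray
    fa: np.ndarray
    n_replicates: np.ndarray
    flags: list = field(default_factory=list)

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        self.fa = np.asarray(self.fa, dtype=float)
        self.n_replicates = np.asarray(self.n_replicates, dtype=int)
        if len(self.doses) < 2:
            raise InsufficientDataError("a dose-effect curve needs >= 2 distinct doses")
        if np.any(np.diff(self.doses) <= 0):
            raise DataError("doses must be strictly increasing")
        if np.any(self.fa < -0.5) or np.any(self.fa > 1.0 + 1e-9):
            raise DataError("fraction affected outside [-0.5, 1]")
        if np.any(self.fa < 0) and "negative_fa" not in self.flags:
            self.flags.append("negative_fa")


@dataclass
class IC50Estimate:
    """An IC50 with its provenance: method, in-range status, and (after
    aggregation) the per-experiment values behind the mean +/- SD."""

    condition: Condition
    value: Optional[float]
    method: str  # "interpolation" | "four_parameter_logistic"
    status: str  # "ok" | "above_range" | "below_range"
    per_experiment_values: list = field(default_factory=list)
    mean: Optional[float] = None
    sd: Optional[float] = None
    n_used: int = 0
    n_excluded: int = 0
    flags: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)


def normalize_viability(
    raw_wells: Sequence[WellRecord], control_wells: Sequence[WellRecord]
) -> list[WellRecord]:
    """Divide raw readings by the mean vehicle-control reading of the same
    experiment.

    Requires at least one control well per experiment represented in
    ``raw_wells``; a non-positive control mean is a data error.
    """
    control_sums: dict[str, list[float]] = {}
    for w in control_wells:
        control_sums.setdefault(w.experiment_id, []).append(w.viability)
    out = []
    for w in raw_wells:
        readings = control_sums.get(w.experiment_id)
        if not readings:
            raise DataError(f"no control wells for experiment {w.experiment_id!r}")
        ctrl = float(np.mean(readings))
        if ctrl <= 0:
            raise DataError(
                f"non-positive control mean {ctrl} in experiment {w.experiment_id!r}"
            )
        out.append(replace(w, viability=w.viability / ctrl))
    return out


def build_curve(wells: Sequence[WellRecord], condition: Condition) -> DoseEffectCurve:
    """Average replicate viabilities per dose and return fa = 1 - mean.

    Doses come out sorted ascending regardless of input order; replicate
    counts are preserved per dose.
    """
    by_dose: dict[float, list[float]] = {}
    for w in wells:
        if w.condition != condition:
            continue
        by_dose.setdefault(w.dose, []).append(w.viability)
    if len(by_dose) < 2:
        raise InsufficientDataError(
            f"condition {condition} has {len(by_dose)} distinct dose(s); need >= 2"
        )
    doses = np.array(sorted(by_dose))
    fa = np.array([1.0 - np.mean(by_dose[d]) for d in doses])
    n = np.array([len(by_dose[d]) for d in doses])
    return DoseEffectCurve(condition=condition, doses=doses, fa=fa, n_replicates=n)


def _crossings(fa_clipped: np.ndarray) -> list[int]:
    """Indices i such that fa[i] < 0.5 <= fa[i+1], scanning ascending doses."""
    lo = fa_clipped[:-1] < 0.5
    hi = fa_clipped[1:] >= 0.5
    return list(np.flatnonzero(lo & hi))


def ic50_interpolate(curve: DoseEffectCurve) -> IC50Estimate:
    """Log-linear interpolation of the dose at 50% inhibition.

    Negative fa values are clipped to 0 for the bracketing search only.
    If the curve never reaches 0.5 the status is ``above_range`` with no
    value; if it starts above 0.5 the status is ``below_range`` with the
    minimum dose recorded as an upper bound. Multiple crossings use the
    first one (ascending doses) and are flagged.
    """
    fa = np.clip(curve.fa, 0.0, None)
    flags = list(curve.flags)
    if fa.max() < 0.5:
        return IC50Estimate(curve.condition, None, "interpolation", "above_range", flags=flags)
    if fa[0] > 0.5:
        flags.append("ic50_below_tested_range")
        return IC50Estimate(
            curve.condition, float(curve.doses[0]), "interpolation", "below_range", flags=flags
        )
    if fa[0] == 0.5:
        return IC50Estimate(
            curve.condition, float(curve.doses[0]), "interpolation", "ok", flags=flags
        )
    idx = _crossings(fa)
    if len(idx) > 1:
        flags.append("multiple_crossings")
    i = idx[0]
    d_lo, d_hi = curve.doses[i], curve.doses[i + 1]
    fa_lo, fa_hi = fa[i], fa[i + 1]
    log_ic50 = np.log10(d_lo) + (0.5 - fa_lo) * (np.log10(d_hi) - np.log10(d_lo)) / (
        fa_hi - fa_lo
    )
    return IC50Estimate(
        curve.condition, float(10.0**log_ic50), "interpolation", "ok", flags=flags
    )


def _four_pl(d, bottom, top, ic50, slope):
    return bottom + (top - bottom) / (1.0 + (ic50 / d) ** slope)


def ic50_4pl(curve: DoseEffectCurve) -> IC50Estimate:
    """Four-parameter logistic fit of fraction affected versus dose.

    Requires >= 4 distinct doses. The fit is variance-weighted for the
    multiplicative reading noise of viability plates: the standard error
    of a mean fa is proportional to the surviving fraction, so weights
    are 1/sigma^2 with sigma = max(1 - fa, 0.05)/sqrt(n_replicates),
    refined once from the fitted curve (one reweighting pass removes the
    correlation between noisy readings and their own weights). On
    non-convergence (including degenerate flat curves) falls back to
    interpolation with a warning flag.
    """
    if len(curve.doses) < 4:
        raise InsufficientDataError("4PL fit needs >= 4 distinct doses")

    def _fallback(reason: str) -> IC50Estimate:
        est = ic50_interpolate(curve)
        est.flags.append(f"4pl_nonconvergence:{reason}")
        return est

    fa = curve.fa
    if np.ptp(fa) < 1e-6:
        return _fallback("constant_fa")
    interp = ic50_interpolate(curve)
    guess_ic50 = interp.value if interp.value else float(np.sqrt(curve.doses[0] * curve.doses[-1]))
    p0 = [max(fa.min(), 0.0), min(max(fa.max(), 0.1), 1.0), guess_ic50, 1.0]
    bounds = ([-0.5, 0.0, curve.doses[0] / 1e3, 0.05], [0.5, 1.5, curve.doses[-1] * 1e3, 10.0])

    def _sigma(fa_like: np.ndarray) -> np.ndarray:
        return np.maximum(1.0 - fa_like, 0.05) / np.sqrt(curve.n_replicates)

    try:
        popt, pcov = curve_fit(
            _four_pl, curve.doses, fa, p0=p0, bounds=bounds,
            sigma=_sigma(fa), maxfev=10000,
        )
        popt, pcov = curve_fit(
            _four_pl, curve.doses, fa, p0=popt, bounds=bounds,
            sigma=_sigma(_four_pl(curve.doses, *popt)), maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        return _fallback(type(exc).__name__)
    bottom, top, ic50, slope = (float(v) for v in popt)
    if not np.isfinite(ic50) or ic50 <= 0:
        return _fallback("invalid_ic50")
    if ic50 > curve.doses[-1]:
        status = "above_range"
    elif ic50 < curve.doses[0]:
        status = "below_range"
    else:
        status = "ok"
    diag = {
        "bottom": bottom,
        "top": top,
        "slope": slope,
        "rss": float(np.sum((_four_pl(curve.doses, *popt) - fa) ** 2)),
    }
    return IC50Estimate(
        curve.condition,
        ic50,
        "four_parameter_logistic",
        status,
        flags=list(curve.flags),
        diagnostics=diag,
    )


def aggregate_experiments(per_experiment: Sequence[IC50Estimate]) -> IC50Estimate:
    """Mean and sample (n-1) SD of the in-range per-experiment IC50s.

    Out-of-range experiments are excluded from the mean and counted in
    ``n_excluded``. If no experiment yields an in-range IC50 the majority
    out-of-range status is propagated.
    """
    if not per_experiment:
        raise InsufficientDataError("nothing to aggregate")
    conditions = {e.condition for e in per_experiment}
    if len(conditions) > 1:
        raise DataError(f"estimates span multiple conditions: {conditions}")
    units = {e.condition.dose_unit for e in per_experiment}
    if len(units) > 1:  # unreachable with equal conditions, kept as a guard
        raise UnitMismatchError(f"mixed units {units}")
    cond = per_experiment[0].condition
    ok = [e for e in per_experiment if e.status == "ok"]
    excluded = len(per_experiment) - len(ok)
    methods = sorted({e.method for e in per_experiment})
    method = methods[0] if len(methods) == 1 else "+".join(methods)
    flags = sorted({f for e in per_experiment for f in e.flags})
    if not ok:
        status = Counter(e.status for e in per_experiment).most_common(1)[0][0]
        return IC50Estimate(
            cond, None, method, status, per_experiment_values=[],
            n_used=0, n_excluded=excluded, flags=flags,
        )
    values = [float(e.value) for e in ok]
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) >= 2 else None
    return IC50Estimate(
        cond,
        mean,
        method,
        "ok",
        per_experiment_values=values,
        mean=mean,
        sd=sd,
        n_used=len(values),
        n_excluded=excluded,
        flags=flags,
    )
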