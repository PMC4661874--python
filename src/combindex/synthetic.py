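"""Synthetic plate and xenograft data with the statistical structure the
analysis modules assume.

The plate generator draws 96-well-style SRB viability readings from Hill
curves: a varied agent titrated over an optional fixed-dose background,
with the expected well survival given by the Bliss product of the
single-agent survivals and multiplicative lognormal reading noise
(plate-reader readings are strictly positive). Readings are emitted as
already-normalizable percent-of-control fractions and clipped to [0, 1.5]
to mimic raw-absorbance artifacts.

The tumor generator grows per-mouse volumes exponentially,
``v(t) = v0 * exp(r * (1 - effect) * t)`` with t in days since treatment
start, perturbs them with lognormal noise, and decomposes each volume into
caliper diameters such that (a^2 * b)/2 recovers it. Body weights follow
an exponential per-day trend.

All randomness flows from explicit integer seeds through named
``numpy.random.Generator`` instances; identical configuration gives
byte-identical tables. Default design constants reproduce the study
layout this pipeline targets: four-point dose grids per agent, triplicate
wells, 3 experiments, reading noise CV 0.10; tumor groups of 7-9 mice
measured on days 7-31 post-inoculation with treatment from day 7.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dose_response import BackgroundDose, WellRecord
from .errors import ConfigurationError
from .invivo import TumorObservation

__all__ = [
    "HillGroundTruth",
    "PlateDesign",
    "GrowthGroundTruth",
    "simulate_plate",
    "simulate_tumor_study",
    "study_plate_designs",
    "study_ground_truths",
    "study_tumor_groups",
    "STUDY_MEASUREMENT_DAYS",
]


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of
    variation ``cv``; degenerate (all ones) at cv = 0."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


@dataclass(frozen=True)
class HillGroundTruth:
    """Ground-truth single-agent dose-response: a Hill curve with midpoint
    ``ic50`` (agent-native units), slope ``hill_slope`` and asymptotic
    ``max_inhibition``. For a full curve (max_inhibition = 1) the
    inhibition at the IC50 is exactly 0.5."""

    agent_id: str
    ic50: float
    hill_slope: float = 1.0
    max_inhibition: float = 1.0
    unit: str = "ng/mL"

    def __post_init__(self):
        if self.ic50 <= 0:
            raise ConfigurationError(f"{self.agent_id}: ic50 must be > 0")
        if self.hill_slope <= 0:
            raise ConfigurationError(f"{self.agent_id}: hill_slope must be > 0")
        if not 0.0 < self.max_inhibition <= 1.0:
            raise ConfigurationError(f"{self.agent_id}: max_inhibition must be in (0, 1]")

    def inhibition(self, dose) -> np.ndarray:
        """Fraction affected at dose (monotone nondecreasing in dose)."""
        dose = np.asarray(dose, dtype=float)
        with np.errstate(divide="ignore"):
            ratio = np.where(dose > 0, (self.ic50 / np.maximum(dose, 1e-300)) ** self.hill_slope, np.inf)
        return np.where(dose > 0, self.max_inhibition / (1.0 + ratio), 0.0)


@dataclass(frozen=True)
class PlateDesign:
    """Layout of one simulated dose-response assay: a varied agent over a
    strictly increasing dose grid, an optional fixed-dose background, with
    triplicate-style replication within and across experiments."""

    varied_agent: str
    varied_doses: tuple
    background: tuple = ()  # ((agent, dose), ...) in each agent's native unit
    replicates_per_dose: int = 3
    n_experiments: int = 3
    noise_cv: float = 0.10
    seed: int = 0

    def __post_init__(self):
        doses = np.asarray(self.varied_doses, dtype=float)
        if doses.size < 1 or np.any(doses <= 0) or np.any(np.diff(doses) <= 0):
            raise ConfigurationError("varied_doses must be strictly increasing and positive")
        if self.replicates_per_dose < 1:
            raise ConfigurationError("replicates_per_dose must be >= 1")
        if self.n_experiments < 1:
            raise ConfigurationError("n_experiments must be >= 1")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")


@dataclass(frozen=True)
class GrowthGroundTruth:
    """Ground truth for one treatment group's tumor trajectories.

    ``v0`` is the median volume at treatment start; ``treatment_effect``
    the fractional reduction of the exponential growth rate in [0, 1);
    ``weight_trend`` a per-day fractional body-weight change (negative for
    toxicity-driven loss). ``eccentricity`` >= 1 sets the long/short
    caliper diameter ratio used when decomposing volumes (1 gives
    a = b = cbrt(2V); the decomposition is otherwise underdetermined)."""

    group_label: str
    v0: float
    growth_rate: float
    treatment_effect: float = 0.0
    weight_trend: float = 0.0
    n_mice: int = 8
    noise_cv: float = 0.10
    seed: int = 0
    baseline_weight_g: float = 20.0
    weight_noise_cv: float = 0.02
    eccentricity: float = 1.0

    def __post_init__(self):
        if self.v0 <= 0:
            raise ConfigurationError(f"{self.group_label}: v0 must be > 0")
        if self.growth_rate <= 0:
            raise ConfigurationError(f"{self.group_label}: growth_rate must be > 0")
        if not 0.0 <= self.treatment_effect < 1.0:
            raise ConfigurationError(f"{self.group_label}: treatment_effect must be in [0, 1)")
        if self.n_mice < 1:
            raise ConfigurationError(f"{self.group_label}: n_mice must be >= 1")
        if self.eccentricity < 1.0:
            raise ConfigurationError(f"{self.group_label}: eccentricity must be >= 1")


def simulate_plate(
    truths: Sequence[HillGroundTruth], design: PlateDesign
) -> list[WellRecord]:
    """Simulate one assay: one well per (experiment, dose, replicate).

    Expected viability at dose d of the varied agent over background B is
    the Bliss-combined survival prod_i (1 - inhibition_i); readings get
    multiplicative lognormal noise with CV ``design.noise_cv`` and are
    clipped to [0, 1.5]."""
    by_id = {t.agent_id: t for t in truths}
    if design.varied_agent not in by_id:
        raise ConfigurationError(f"no ground truth for varied agent {design.varied_agent!r}")
    for agent, _dose in design.background:
        if agent not in by_id:
            raise ConfigurationError(f"no ground truth for background agent {agent!r}")

    varied = by_id[design.varied_agent]
    doses = np.asarray(design.varied_doses, dtype=float)
    bg_survival = 1.0
    bg_tuple = []
    for agent, dose in design.background:
        t = by_id[agent]
        bg_survival *= 1.0 - float(t.inhibition(dose))
        bg_tuple.append(BackgroundDose(agent, float(dose), t.unit))
    bg_tuple = tuple(sorted(bg_tuple, key=lambda b: b.agent))

    expected = (1.0 - varied.inhibition(doses)) * bg_survival
    rng = np.random.default_rng(design.seed)
    records = []
    for e in range(1, design.n_experiments + 1):
        noise = _lognormal_factors(
            rng, design.noise_cv, (doses.size, design.replicates_per_dose)
        )
        readings = np.clip(expected[:, None] * noise, 0.0, 1.5)
        for i, d in enumerate(doses):
            for r in range(design.replicates_per_dose):
                records.append(
                    WellRecord(
                        experiment_id=f"E{e}",
                        varied_agent=design.varied_agent,
                        dose=float(d),
                        dose_unit=varied.unit,
                        replicate=r + 1,
                        viability=float(readings[i, r]),
                        background=bg_tuple,
                    )
                )
    return records


def _diameters(volume: float, eccentricity: float) -> tuple[float, float]:
    """Split V into (a, b), a <= b, with b = eccentricity * a and
    (a^2 * b)/2 = V."""
    a = (2.0 * volume / eccentricity) ** (1.0 / 3.0)
    return a, eccentricity * a


def simulate_tumor_study(
    truths: Sequence[GrowthGroundTruth],
    days: Sequence[int],
    treatment_start: Optional[int] = None,
) -> list[TumorObservation]:
    """Simulate caliper measurements for every group on every listed day.

    Days are post-inoculation and must be sorted ascending; growth time t
    is measured from ``treatment_start`` (default: the first listed day).
    Per mouse, volume is v0 * exp(rate * (1 - effect) * t) with lognormal
    noise; emitted diameters reproduce the noisy volume exactly. Body
    weight follows baseline * exp(weight_trend * t) with its own (small)
    lognormal noise."""
    if not truths:
        raise ConfigurationError("at least one group is required")
    days = list(days)
    if not days or any(b <= a for a, b in zip(days, days[1:])):
        raise ConfigurationError("days must be a non-empty ascending sequence")
    if treatment_start is None:
        treatment_start = days[0]
    t = np.array([d - treatment_start for d in days], dtype=float)
    if np.any(t < 0):
        raise ConfigurationError("all measurement days must be >= treatment_start")

    observations = []
    for g in truths:
        rng = np.random.default_rng(g.seed)
        rate = g.growth_rate * (1.0 - g.treatment_effect)
        mean_vol = g.v0 * np.exp(rate * t)  # (n_days,)
        mean_wt = g.baseline_weight_g * np.exp(g.weight_trend * t)
        vol_noise = _lognormal_factors(rng, g.noise_cv, (g.n_mice, t.size))
        wt_noise = _lognormal_factors(rng, g.weight_noise_cv, (g.n_mice, t.size))
        for m in range(g.n_mice):
            mouse_id = f"{g.group_label}:{m + 1}"
            for j, day in enumerate(days):
                v = float(mean_vol[j] * vol_noise[m, j])
                a, b = _diameters(v, g.eccentricity)
                observations.append(
                    TumorObservation(
                        mouse_id=mouse_id,
                        group=g.group_label,
                        day=int(day),
                        diam_short=a,
                        diam_long=b,
                        body_weight=float(mean_wt[j] * wt_noise[m, j]),
                    )
                )
    return observations


# --- Default study conditions -------------------------------------------------
#
# Dose grids mirror the targeted assay design: imatinib (GV) titrated
# 10-10,000 ng/mL, docetaxel/idarubicin 0.1-100 ng/mL, cisplatin
# 1-1,000 ng/mL, with the vitamin-D analog PRI-2191 as a 10/100 nM
# fixed-dose background. Ground-truth potencies are plausible for A549
# cells and deliberately place the analog's IC50 far above its background
# doses (its single-agent IC50 is out of tested range, so pairwise CIs
# against it are undefined and plot-based calls apply).

GV_DOSES_NG_ML = (10.0, 100.0, 1000.0, 10000.0)
DTX_ID_DOSES_NG_ML = (0.1, 1.0, 10.0, 100.0)
CIS_DOSES_NG_ML = (1.0, 10.0, 100.0, 1000.0)
PRI2191_BACKGROUND_NM = (10.0, 100.0)
STUDY_MEASUREMENT_DAYS = (7, 10, 12, 14, 17, 19, 21, 24, 26, 28, 31)


def study_ground_truths() -> list[HillGroundTruth]:
    """Default single-agent ground truths for the study's five agents."""
    return [
        HillGroundTruth("GV", ic50=2000.0, hill_slope=1.2, unit="ng/mL"),
        HillGroundTruth("DTX", ic50=5.0, hill_slope=1.0, unit="ng/mL"),
        HillGroundTruth("ID", ic50=3.0, hill_slope=1.1, unit="ng/mL"),
        HillGroundTruth("CIS", ic50=300.0, hill_slope=1.0, unit="ng/mL"),
        # Analog alone barely inhibits at its plate doses (IC50 >> 100 nM).
        HillGroundTruth("PRI-2191", ic50=5000.0, hill_slope=1.0, unit="nM"),
    ]


def study_plate_designs(seed: int = 0, noise_cv: float = 0.10) -> list[PlateDesign]:
    """One design per Table-1-style condition: each agent alone and
    imatinib over each PRI-2191 background level."""
    designs = [
        PlateDesign("GV", GV_DOSES_NG_ML, seed=seed, noise_cv=noise_cv),
        PlateDesign("DTX", DTX_ID_DOSES_NG_ML, seed=seed + 1, noise_cv=noise_cv),
        PlateDesign("ID", DTX_ID_DOSES_NG_ML, seed=seed + 2, noise_cv=noise_cv),
        PlateDesign("CIS", CIS_DOSES_NG_ML, seed=seed + 3, noise_cv=noise_cv),
    ]
    for k, bg in enumerate(PRI2191_BACKGROUND_NM):
        designs.append(
            PlateDesign(
                "GV",
                GV_DOSES_NG_ML,
                background=(("PRI-2191", bg),),
                seed=seed + 10 + k,
                noise_cv=noise_cv,
            )
        )
    return designs


def study_tumor_groups(seed: int = 0, noise_cv: float = 0.10) -> list[GrowthGroundTruth]:
    """Default xenograft groups: vehicle control (8 mice), imatinib alone
    (7, essentially inactive), the analog s.c./oral (9 each) and the two
    combinations (9 each) with added body-weight loss. Control kinetics
    (v0 52 mm^3 at day 7, rate 0.156/day) back-solve the targeted control
    medians of ~154 mm^3 at day 14 and ~460 mm^3 at day 21."""
    r, v0 = 0.156, 52.0
    common = dict(v0=v0, growth_rate=r, noise_cv=noise_cv)
    return [
        GrowthGroundTruth("control", n_mice=8, seed=seed, **common),
        GrowthGroundTruth(
            "GV", n_mice=7, treatment_effect=0.02, weight_trend=-0.002,
            seed=seed + 1, **common,
        ),
        GrowthGroundTruth(
            "PRI-2191 s.c.", n_mice=9, treatment_effect=0.30, weight_trend=-0.003,
            seed=seed + 2, **common,
        ),
        GrowthGroundTruth(
            "PRI-2191 oral", n_mice=9, treatment_effect=0.35, weight_trend=-0.004,
            seed=seed + 3, **common,
        ),
        GrowthGroundTruth(
            "GV + PRI-2191 s.c.", n_mice=9, treatment_effect=0.45, weight_trend=-0.006,
            seed=seed + 4, **common,
        ),
        GrowthGroundTruth(
            "GV + PRI-2191 oral", n_mice=9, treatment_effect=0.40, weight_trend=-0.006,
            seed=seed + 5, **common,
        ),
    ]
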