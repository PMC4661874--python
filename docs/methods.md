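# Methods

## Scope

`combindex` analyzes preclinical drug-combination efficacy data of the
kind produced by an imatinib + vitamin-D-analog study in the A549
non-small-cell lung cancer model: SRB (sulforhodamine B) viability plates
in vitro and caliper-measured subcutaneous xenografts in vivo. It covers
four computations — IC50 estimation, the Chou–Talalay combination index,
tumor growth inhibition (TGI), and the independence benchmark for
combination TGI — plus a seeded generator that emulates both assay types.

## Dose–response and IC50

Plate readings are normalized per experiment by the mean vehicle-control
reading; fraction affected is fa = 1 − mean viability per dose. Two IC50
estimators are exposed and named in every output:

* **Log-linear interpolation** (default): the dose at fa = 0.5 obtained by
  interpolating log10(dose) between the two bracketing grid points. This
  mirrors common manual SRB practice. Negative fa values (wells above
  control) are kept for fitting but clipped to 0 for the bracketing
  search, which keeps the crossing well defined without discarding
  information. If the curve never reaches 0.5 the estimate is
  `above_range` with no value; if it starts above 0.5 it is `below_range`
  with the lowest dose recorded as an upper bound. Non-monotone curves use
  the first crossing scanning doses ascending and are flagged.
* **Four-parameter logistic (4PL)**:
  fa(d) = bottom + (top − bottom)/(1 + (IC50/d)^slope), least squares via
  `scipy.optimize.curve_fit`, requiring ≥ 4 distinct doses. The fit is
  variance-weighted for the multiplicative reading noise of viability
  plates — the standard error of a mean fa is proportional to the
  surviving fraction, so σ_i = max(1 − fa_i, 0.05)/√n_i — and the weights
  are refined once from the fitted curve so that noisy readings do not
  set their own weights. On non-convergence (including flat curves) the
  estimator falls back to interpolation and flags the fallback.

Per-experiment IC50s are aggregated as mean ± sample (n−1) SD over
experiments whose estimate is in range; out-of-range experiments are
excluded and counted. Every dose carries its native unit (ng/mL, µg/mL,
nM); no unit is ever converted implicitly, and mixing units in one
computation is an error.

## Combination index

The mutually non-exclusive Chou–Talalay index at the IC50 effect level is

    CI = dA/DA + dB/DB + (dA·dB)/(DA·DB)

with DA, DB the single-agent doses giving 50% inhibition and dA, dB the
doses in the combination that reach the same effect. Calls follow the
study convention: CI < 0.8 synergism, CI > 1.2 antagonism, 0.8–1.2
additive with inclusive boundaries. Note that because of the cross term,
a Loewe-additive half/half split of one agent reads CI = 1.25.

Triple-combination semantics: the fixed-dose background agent (the
vitamin-D analog) defines the measurement context. Within each background
level, DA is the varied agent's single-agent IC50 *measured under that
background* and DB the cytostatic's single-agent IC50 under the same
background; dB equals the cytostatic's fixed plate dose, because the
design titrates only the varied agent. Within-column consistency is the
only reading that keeps the effect level fixed when the varied agent's
IC50 shifts with the background. A single-agent IC50 outside the tested
range makes the cell's CI *undefined* ("countless" in study tables) — a
first-class value, never an exception — and the background agent's own
IC50 is never required.

For combinations whose CI is undefined, `plot_based_call` classifies by
the mean signed excess of observed combination inhibition over the Bliss
expectation 1 − (1 − fa_A)(1 − fa_B) across the shared dose grid. The
default tolerance of 0.05 fraction affected was chosen to absorb
triplicate noise at reading CV 0.10 and is configurable.

## In vivo efficacy

Tumor volume is V = (a²·b)/2 with a ≤ b the caliper diameters in mm
(inputs are canonicalized, so argument order never matters). Groups are
summarized by the median volume per day; mice lost to follow-up drop out
per day. Tumor growth inhibition against the concurrent control is

    TGI% = 100 · (1 − VT/VC)

with positive values denoting inhibition — the sign convention of the
reported tables (the equivalent ratio form (VT/VC)·100 − 100 has the
opposite sign; the report footer records this). TGI is computed only on
days where both groups were measured; no interpolation across days.

The **hypothetical TGI** of a combination is the inhibition expected if
the two single agents acted independently, i.e. Bliss independence
applied to the volume ratios:

    HTGI% = 100 · (1 − (VT_a/VC)·(VT_b/VC))

It is symmetric in the two agents and algebraically equal to
tgi(VT_a·VT_b/VC, VC). A combination whose observed TGI exceeds its HTGI
indicates in vivo synergy. HTGI is flagged in all outputs as an
independence *expectation*, and single-agent partners are paired with a
combination group strictly by its "A + B" label.

Body-weight toxicity is the percent change of mean weight from the
baseline day over mice weighed on both days. Group comparisons delegate
to `scipy.stats` (Mann–Whitney U two-sided by default, Kruskal–Wallis as
an option), with 0.05 as the conventional significance level.

Rounding of reported TGI/HTGI is to the nearest integer, halves away from
zero, applied only at reporting; all internal values keep full precision.

## Synthetic data generator

The generator defines the package's study conditions and makes the whole
pipeline testable without raw data.

**Plates.** Each single agent follows a Hill curve
inh(d) = E_max·d^h/(d^h + IC50^h); a full curve (E_max = 1) inhibits
exactly 50% at its IC50. Expected well survival for a varied agent over a
fixed-dose background is the Bliss product of single-agent survivals.
Readings get multiplicative lognormal noise with configurable CV
(default 0.10, a typical plate-reader figure) and are clipped to [0, 1.5]
to mimic raw-absorbance artifacts; they are emitted as
already-normalizable percent-of-control fractions, since the blank/
control plate layout of the original assay is not modeled. Default
designs use the study's grids — imatinib 10–10,000 ng/mL, docetaxel/
idarubicin 0.1–100 ng/mL, cisplatin 1–1,000 ng/mL, the analog PRI-2191 at
10/100 nM as background — triplicate wells and 3 experiments. Ground-truth
potencies are invented but plausible for A549 cells, and the analog's
IC50 (5,000 nM) is deliberately far above its background doses so its
single-agent IC50 is out of range, exercising the undefined-CI path.

**Xenografts.** Per-mouse volumes grow exponentially,
v(t) = v0·exp(r·(1 − e)·t) with t in days since treatment start, with
lognormal noise (CV default 0.10). Diameters are emitted so that (a²·b)/2
reproduces the noisy volume exactly; by default a = b = (2V)^(1/3)
because the decomposition is underdetermined by V alone, with an
eccentricity parameter for elongated tumors. Body weight follows
baseline·exp(trend·t) with small measurement noise (CV 0.02; baseline
20 g, typical of NOD/SCID mice). Default groups mirror the targeted
design — control 8 mice, imatinib 7 (nearly inert, effect 0.02), analog
s.c./oral and both combinations 9 each — measured on days 7–31 with
treatment from day 7. Control kinetics (v0 = 52 mm³ at day 7,
r = 0.156/day) back-solve the study's control medians (~154 mm³ at day
14, ~460 mm³ at day 21).

All randomness flows from explicit integer seeds through named
`numpy.random.Generator` instances; identical configuration yields
byte-identical tables.

**What the generator does not emulate:** raw optical densities and plate
layout, pharmacokinetics, inter-mouse correlation over time (noise is
independent per measurement), dropout/censoring mechanisms, and any
mechanistic (VEGF/p53) biology. Passing tests therefore demonstrate the
correctness and statistical calibration of the computations under the
stated noise model, not the biological conclusions of any particular
study.

## Numerical choices and degenerate inputs

* 4PL bounds: bottom ∈ [−0.5, 0.5], top ∈ [0, 1.5], IC50 within three
  decades of the grid ends, slope ∈ [0.05, 10]; initial IC50 guess from
  interpolation. Flat curves short-circuit to the interpolation fallback.
* Interpolation with multiple 0.5-crossings takes the first and flags it.
* CI with one combination dose tending to zero tends to the single-drug
  value 1, continuously.
* Even group sizes take the mean of the two central volumes for the
  median (NumPy convention).
* Empty group/day cells and absent weights are missing-data signals
  (`None`), not exceptions; malformed CSV rows are collected with line
  numbers instead of aborting the read.

## Problem sizes used by the checks

The recovery check simulates plates with four doses per decade over three
decades around the true IC50 (13 doses), triplicate wells, four
experiments, reading CV 0.10, and 200 independent seeds; the aggregate
4PL estimate lands within 10% of truth in ≥ 90% of runs and within 1% on
noise-free data. The algebraic CI properties are verified over 10⁴ random
positive dose quadruples. In vivo checks are closed-form and instant.

## Known limitations

* The interpolation IC50 is grid-dependent; agreement with 4PL within 2%
  holds at ≥ 4 doses per decade but degrades on coarse grids with steep
  slopes.
* HTGI assumes the two single-agent groups share the control; it is an
  expectation under independence, not a statistical test, and carries no
  uncertainty interval.
* The CI is computed at a single effect level (the IC50); no median-effect
  regression (Dm, m) or isobolograms, and no CI confidence intervals.
* Unit handling is by exact string match; a conversion table is the
  caller's responsibility.
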