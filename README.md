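# combindex

Analysis pipeline for preclinical drug-combination efficacy studies:
in vitro dose–response (IC50) estimation with Chou–Talalay
combination-index classification — including triple combinations measured
over a fixed-dose background agent — and in vivo xenograft tumor-growth
inhibition with an independence benchmark for combination groups. Written
for pharmacology groups running SRB viability plates and caliper-measured
mouse xenografts, e.g. tyrosine-kinase inhibitor + vitamin-D-analog
combinations in non-small-cell lung cancer models.

## The quantities it computes

**IC50** — the concentration inhibiting proliferation by 50% of vehicle
control, per experiment, by log-linear interpolation of the bracketing
doses or by a four-parameter logistic fit
fa(d) = bottom + (top − bottom)/(1 + (IC50/d)^slope), aggregated as
mean ± SD over experiments.

**Combination index** (mutually non-exclusive, at the IC50 effect level):

    CI = dA/DA + dB/DB + (dA·dB)/(DA·DB)

with DA, DB the single-agent doses reaching 50% inhibition and dA, dB the
doses in the combination reaching the same effect. CI < 0.8 is called
synergism, CI > 1.2 antagonism, 0.8–1.2 additive. When a single-agent
IC50 lies outside the tested range the CI is *undefined* and reported as
"countless/NA"; such combinations can instead be judged against the Bliss
expectation 1 − (1 − fa_A)(1 − fa_B) across the dose grid
(`plot_based_call`).

**Tumor growth inhibition** — from caliper diameters, V = (a²·b)/2 (a ≤ b,
mm), per-group/day median volumes, and

    TGI% = 100·(1 − VT/VC)      HTGI% = 100·(1 − (VT_a/VC)·(VT_b/VC))

where HTGI is the *hypothetical* TGI a combination would show if its two
single agents acted independently — the in vivo synergy benchmark — plus
body-weight toxicity series and nonparametric group comparisons.

A seeded synthetic-data generator (Hill-curve plates with multiplicative
reading noise; exponential tumor growth with treatment-specific rate
reductions) emulates both assay types so the full pipeline runs and is
tested without external data. See `docs/methods.md` for the model
details and design choices.

## Worked example

```python
from combindex import tgi, htgi, round_half_away, combination_index, CIInput

# Day-14 median tumor volumes (mm^3): control 154, analog s.c. 98,
# imatinib 134, combination 76.
print(round_half_away(tgi(76, 154)))        # 51  -> observed combination TGI%
print(round_half_away(htgi(98, 134, 154)))  # 45  -> TGI% expected under independence

# observed 51% > expected 45%: the combination beats the independence
# benchmark, i.e. in vivo synergy.

res = combination_index(CIInput(d_a_alone=20.0, d_b_alone=0.004,
                                d_a_combo=7.0, d_b_combo=0.001))
print(round(res.ci, 4), res.category)       # 0.6875 synergism
```

The command-line pipeline runs end to end on synthetic data:

```
combindex full --seed 3 --out results/demo
```

writes `plate.csv` / `animals.csv` (the simulated raw data), per-condition
IC50 tables, a combination-index grid (undefined cells rendered as
`countless/NA`), the per-group/day in vivo table with TGI%/HTGI%, and a
`report.json` whose footer records the estimator used, the TGI sign
convention and the independence reading of HTGI. With a fixed seed the
outputs are byte-identical across runs. The staged subcommands
`simulate`, `ic50`, `ci` and `invivo` run the same steps on your own CSV
files (plate dialect: `experiment_id,varied_agent,dose,dose_unit,
background,replicate,viability`; animal dialect: `mouse_id,group,day,
diam_a_mm,diam_b_mm,weight_g`).

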