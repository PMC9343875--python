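# Methods

## Scope and assumptions

The simulator models hepatocyte triglyceride handling on the timescale that
clinical liver-fat endpoints are measured (weeks to months). Accordingly:

1. every flux is a 24-hour average — there are no meal, diurnal, or
   receptor-cycling dynamics;
2. all inputs (NEFA delivery from adipose, DNL substrate supply, dietary
   chylomicron appearance) are constant unless an intervention scales them;
3. β-oxidation is set by hepatic energy demand, not by substrate
   concentration, except at near-depletion (see below);
4. plasma triglyceride is one lumped pool for all lipoprotein classes.

States are whole-compartment amounts in µmol (FA or TG equivalents), which
avoids volume bookkeeping inside the hepatocyte. Triglyceride counts 3
fatty-acid equivalents; the glycerol backbone's mass is ignored and TG mass
uses MW 885 g/mol.

## Equations

With intervention scalings `u = (u_nefa, u_dnl, u_est, u_vldl, u_chylo)`
(all 1 at baseline):

```
v_uptake   = j_nefa  · u_nefa · (fa_cyt_0 / fa_cyt)^γ_up
v_dnl      = j_dnl   · u_dnl
v_ox       = k_ox · max(u_dnl, 0.05)^(−γ_ox) · (1+κ)·fa_cyt/(κ·fa_cyt_0 + fa_cyt)
v_est_cyt  = k_est_cyt · fa_cyt · u_est        v_lip_cyt = k_lip_cyt · tg_cyt
v_trans    = k_trans · fa_cyt
v_est_er   = k_est_er · fa_er · u_est          v_lip_er  = k_lip_er · tg_er
v_vldl     = vmax_vldl · u_vldl · tg_er / (km_vldl + tg_er)
v_chylo    = j_chylo · u_chylo
v_clear    = k_clear · tg_pl                   v_reuptake = k_reuptake · tg_pl

d fa_cyt/dt = v_uptake + v_dnl + 3·v_lip_cyt + 3·v_reuptake − v_ox − 3·v_est_cyt − v_trans
d tg_cyt/dt = v_est_cyt − v_lip_cyt
d fa_er/dt  = v_trans + 3·v_lip_er − 3·v_est_er
d tg_er/dt  = v_est_er − v_lip_er − v_vldl
d tg_pl/dt  = v_vldl + v_chylo − v_clear − v_reuptake
```

Summing with the 3:1 stoichiometry, internal cycles cancel and
`3·(dtg_cyt + dtg_er + dtg_pl) + dfa_cyt + dfa_er` equals boundary influx
(`v_uptake + v_dnl + 3·v_chylo`) minus boundary outflux
(`v_ox + 3·v_clear`) identically — the conservation property the test suite
asserts at arbitrary states.

### Oxidation is demand-driven

`k_ox` is a flux (µmol FA/day), not a rate constant: hepatocyte mitochondria
oxidize fat at a rate fixed by the liver's basal metabolic requirement.
This is a deliberate structural choice with a large qualitative consequence.
If oxidation were first-order in `fa_cyt`, then at steady state the
cytosolic esterification/lipolysis cycle cancels out of the fatty-acid
balance, `fa_cyt` becomes invariant to esterification inhibition, and liver
fat responds to `u_est` with elasticity exactly 1 — making esterification
inhibition structurally the strongest possible intervention. With
demand-driven oxidation, a reduction in fatty-acid influx cannot be absorbed
by oxidation and falls entirely on the export pathway, so upstream flux
inhibition (NEFA uptake, DNL) becomes the most potent lever — which is the
behaviour the sensitivity analysis of this class of model reports and the
reason limiting adipose→liver NEFA flux is the leading anti-steatotic
strategy.

Pure zeroth-order oxidation would drive `fa_cyt` negative under extreme
influx inhibition, so demand is attenuated by the substrate factor
`(1+κ)·fa/(κ·fa_cyt_0 + fa)` with κ = 0.05 (a fixed structural constant,
stored in the registry's constants block, not one of the 22 parameters).
It equals 1 at baseline, is negligible above ~20 % of basal `fa_cyt`, and
shuts oxidation off linearly below ~5 %. Likewise the DNL feedback term
`u_dnl^(−γ_ox)` floors `u_dnl` at 0.05 so that full DNL inhibition stays
finite (the sweep maximum is 95 % inhibition anyway).

### Feedbacks

Both feedbacks are power laws normalised to 1 at baseline, so they drop out
of calibration. High cytosolic FA suppresses uptake (SREBP1c-like
homeostasis, gain `γ_up ≥ 0`); DNL activity suppresses oxidation
(malonyl-CoA/CPT-1 inhibition, gain `γ_ox ≥ 0`, driven by the DNL
intervention scaling). The oxidation feedback responds to the *commanded*
DNL level rather than a state variable, consistent with the model's
constant-input philosophy.

## Calibration and the 22-parameter registry

The registry holds 5 basal pools, 3 input fluxes, 10 kinetic constants, 2
physiology constants and the 2 gains. Rate constants are derived, not
guessed: given basal pools and basal flux anchors, the five steady-state
constraints yield

```
k_ox      = j_nefa + j_dnl + 3·(v_reuptake_0 − v_vldl_0)      (FA balance)
k_est_cyt = v_lip_cyt_0 / fa_cyt_0                            (tg_cyt)
k_trans   = 3·v_vldl_0 / fa_cyt_0                             (fa_er)
k_est_er  = (v_lip_er_0 + v_vldl_0) / fa_er_0                 (tg_er)
k_clear   = (v_vldl_0 + j_chylo − v_reuptake_0) / tg_pl_0     (tg_pl)
```

with `k_lip_cyt`, `k_lip_er`, `k_reuptake`, `vmax_vldl` inverting their
anchors directly (`vmax_vldl = v_vldl_0·(km_vldl + tg_er_0)/tg_er_0`).
Anchors implying a non-positive oxidation or clearance are rejected as
inconsistent. The basal state is therefore an exact steady state by
construction, which the suite verifies by 365-day integration (drift
< 1e−6).

### Default anchors

The defaults describe a healthy-skewed reference subject and are all
overridable through the registry/config:

| quantity | default | rationale |
|----------|---------|-----------|
| liver mass | 1,800 g | adult liver |
| plasma volume | 30 dL | ~3 L plasma |
| basal liver fat | 3 % | healthy median; total liver TG ≈ 61,000 µmol |
| ER TG pool | 1,500 µmol | small VLDL-assembly transit pool (~2 h turnover) |
| cytosolic FA | 10,000 µmol | ~2.6 g free FA |
| ER FA | 500 µmol | transit pool |
| basal plasma TG | 100 mg/dL | healthy fasting value |
| NEFA delivery | 90,000 µmol FA/day | ~60 % of the 150,000 µmol FA/day hepatic influx |
| DNL | 26,250 µmol FA/day | ~17.5 % of influx |
| plasma-TG reuptake | 11,250 µmol TG/day | remainder (~22.5 % of influx as FA equivalents) |
| VLDL-TG export | 16,949 µmol TG/day | 15 g/day |
| chylomicron input | 79,096 µmol TG/day | 70 g dietary fat/day |
| cytosolic lipolysis | 30,000 µmol TG/day | droplet turnover ~2 days |
| ER lipolysis | 5,000 µmol TG/day | minor futile cycle |
| km_vldl | 1,500 µmol | export half-saturated at basal |

The influx split (NEFA dominant, DNL a minority, TG reuptake the balance)
follows stable-isotope source-attribution studies of liver triglyceride.
Implied basal oxidation is 99,153 µmol FA/day (~28 g/day), consistent with
hepatic energy expenditure; implied plasma clearance gives a circulating TG
residence time of about an hour.

### The two free gains

`γ_up` and `γ_ox` are the model's free dynamical parameters — they do not
affect the basal steady state, only adaptation to perturbations. They were
fixed once by scanning steady-state cohort-mean responses to matched 50 %
single-mechanism perturbations on large prior-drawn NAFLD cohorts and
choosing values for which the mechanism ordering (NEFA uptake > DNL ≥
esterification > VLDL activation) is reproduced with several percentage
points of margin and is stable across sampling seeds: `γ_up = 0.2`,
`γ_ox = 0.35`. Both are weak-to-moderate homeostatic gains (a doubling of
cytosolic FA suppresses uptake by ~13 %; halving DNL raises oxidation by
~27 %). The cohort-mean NEFA response is governed almost entirely by
`γ_up` and the DNL response by `γ_ox`, while the esterification response is
structurally pinned near the inhibition fraction itself, so this
calibration is well-conditioned.

## Prior and plausible patients

The prior is a diagonal log-normal over the 17 calibration inputs (pools,
input fluxes, anchor fluxes, `km_vldl`, physiology, gains). Each log-SD is
`ln(fold)/Φ⁻¹(0.95)` so that 90 % of draws lie within the fold range: fold 4
by default, narrowed to 1.5 for liver mass and plasma volume, whose
physiological ranges are far tighter than a generic 16-fold band. Sampling
calibration inputs and re-deriving the dependent rate constants per draw
keeps every patient on the steady-state manifold — all 22 registry
parameters vary across the population, but never inconsistently. Draws
whose anchors imply a non-positive oxidation or clearance are infeasible
and are treated as rejections.

The Metropolis-Hastings chain walks log-parameter space with per-parameter
Gaussian steps of 0.25·log-SD, targeting prior × box-indicator, with
burn-in 1,000 and thinning 10 (all configurable); one integer seed expands
to independent per-chain substreams. The plausibility box defaults to liver
fat 0.5–50 % and plasma TG 30–600 mg/dL — wide enough to span healthy
through NAFLD-with-hyperlipidemia phenotypes. Because a plausible patient's
steady state is its own calibrated basal state, no ODE solve is needed per
draw; the steady-state residual is still checked (< 1e−6 relative to the
NEFA influx scale). If the proposal acceptance rate falls below 0.1 % over
a diagnostic window the sampler aborts with advice to widen the box or
shrink the step. With the box disabled the chain samples the prior exactly,
up to the feasibility truncation above, which involves only the flux
parameters.

## Target and selection

The selection target is a joint log-normal over (liver fat %, plasma TG),
either fitted by maximum likelihood to a user cohort table (log-transform,
1/n mean and covariance) or taken from the built-in synthetic fixture:
median liver fat 4.5 %, median TG 110 mg/dL, log-SDs 0.75/0.45, correlation
0.45 — documented fixture values chosen so roughly 44 % of the implied
population exceeds the 5 % NAFLD threshold; they stand in for an
unavailable clinical scatter and are flagged as synthetic in every artifact.

Acceptance-rejection uses weights `w = f_target/f̂_plausible` evaluated in
log-observable space; the plausible density is a Gaussian KDE with
Silverman bandwidth — exact for populations up to 20,000, and a 512²-bin
histogram-smoothed evaluation above that (agreeing with the exact KDE to a
few percent where the density is non-negligible, and several orders of
magnitude faster at half a million points). Weights are normalised by the
empirical maximum (recorded in provenance); every plausible row is retained
with its weight and accepted flag for audit. An `expected_size` option
rescales the capped acceptance probabilities (by bisection) to tune the
expected accepted count, used when emulating selections of a fixed size.
The NAFLD cohort is the strict sub-selection liver fat > 5 %.

## Interventions and sensitivity

Interventions are instantaneous, sustained multiplicative steps on fluxes.
The pioglitazone-like scenario is a single −28 % step on NEFA delivery for
24 weeks (168 days), representing adipose insulin sensitization as the sole
pharmacodynamic effect; the diet-like scenario combines −20 % chylomicron
input, −55 % DNL and −11 % NEFA delivery for 26 weeks (182 days). These
effect sizes are constants of the scenario definitions. The endpoint is per
patient `100·(LF_end − LF_0)/LF_0`, aggregated as cohort mean and
population SD (invariant under duplicating the cohort; 0 for a cohort of
one).

Sensitivity sweeps perturb one mechanism at a time on the NAFLD cohort for
26 weeks: inhibitions of NEFA uptake, DNL, or esterification over 0–95 %
(the esterification scaling acts on both the cytosolic and ER steps), and
VLDL-synthesis activation over 1–20×. Ranking compares mean liver-fat
reduction at a matched perturbation, mapping activation folds through the
inverse convention `fold = 1/(1 − inhibition)`; ties are broken
alphabetically and flagged.

## Numerics

- Integration: LSODA, rtol 1e−8, atol 1e−10 scaled per pool by its basal
  size (pools span 500–80,000 µmol). The system is mildly stiff (fast
  FA/plasma pools ~hours, slow droplet pool ~days).
- Steady states: root-finding on log-pools (positivity by construction)
  seeded from the basal state, long-integration fallback plus polish;
  residual tolerance 1e−9 relative to the dominant flux.
- Determinism: all randomness flows through `numpy` Generators seeded from
  explicit integers; seeds expand to named substreams via `SeedSequence`.
- Degenerate inputs: non-positive states, empty cohorts, inconsistent
  anchors, degenerate covariance targets and starved MH chains raise
  informative errors rather than propagating NaNs.

## Problem sizes used in the shipped checks

The test suite exercises the full chain at desk scale, chosen for stable
cohort statistics: 2,000 plausible patients (→ ~630 selected, ~260 NAFLD)
for intervention and ranking properties; 100 prior draws for the
steady-state/integration equivalence; 200,000 Monte-Carlo draws for the
prior fold-range mass; and a 500,000-patient observable-only synthetic
cloud, tuned to accept ≈1,900, for the run-to-run selection-size spread
(10 seeds). The same quantities are recomputed from scratch by
`scripts/acceptance.py`.

## What the synthetic data does and does not show

The fixture cohort and toy clouds are draws from the very distribution
family the selection machinery assumes (joint log-normal), so passing
selection tests demonstrates correctness of the samplers and estimators,
not that real cohorts are log-normal. Likewise the virtual population
inherits the model's structural idealizations: no meal dynamics, a single
lumped plasma TG pool, interventions with perfect adherence and constant
effect, and cohort SDs that reflect parameter heterogeneity only — not
assay noise or within-trial variability. Clinical-scale conclusions (e.g.,
the NEFA-first sensitivity ordering) hold for the documented default
anchors; materially different basal flux shares can reorder the middle of
the ranking, which is why the anchors live in one overridable block.

## Known limitations

- The flux topology and feedback forms are a reconstruction of this model
  class from its textual description; the original's exact equations are
  not reproduced line by line.
- Liver fat includes both cytosolic and ER triglyceride over a fixed liver
  mass denominator; at very high steatosis (> ~15 %) the fixed denominator
  slightly overstates fat fraction.
- The plausible-patient steady state coincides with the drawn basal pools
  by construction; pathologies reachable only through non-steady dynamics
  are not represented.
- No pharmacokinetics: therapy steps are idealized constant inhibitions.
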