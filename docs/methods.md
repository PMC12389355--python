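# Methods

This note documents the models implemented in `cypind`, the assumptions and
parameter choices behind the packaged fixtures, the synthetic-data
generators, and the numerical settings. It is the package's own account;
nothing here asserts a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. In vitro induction analysis

**Data model.** One dataset is a compound × enzyme × donor × readout table
of nominal inducer concentrations (µM) with replicate fold-change values
(mRNA or marker activity, normalized to the vehicle control, so baseline is
1 and all values are positive). Quadruplicates are the design norm; at least
four distinct non-zero concentrations are required for fitting.

**No-call rule.** If the maximum over concentrations of the *mean* fold
change is strictly below 2, the dataset is a no-call (NC): the induction
signal is below the conventional quantifiability threshold and no parameters
are estimated. The threshold is strict (`max = 2.0` is a call). NC is kept
distinct from "no induction" everywhere downstream — a no-call enzyme has an
*undefined* static ratio, not R3 = 1.

**Sigmoid forms.** The default form is a three-parameter logistic in
log10 concentration anchored at the vehicle baseline,

    Y = 1 + (Emax − 1) / (1 + exp(−(x − log10 EC50)/s)),   x = log10 C,

which reports EC50 on the linear µM scale; a hyperbolic/Hill alternative
`Y = 1 + (Emax − 1)·C^h/(EC50^h + C^h)` is available via `form="hill"`.
The baseline anchor is a modeling decision: fold change at zero
concentration must equal 1, and log-concentration sigmoids are the standard
dose–response practice for this assay class.

**Estimation.** Replicate means are fitted by bounded nonlinear least
squares. The default weighting is *relative* (σ ∝ response), matching the
multiplicative error structure of fold-change data; weighting by the
replicate SD is available but discouraged — with n = 4 the sample SD is so
noisy that SD weights materially degrade EC50 recovery. Initialisation:
Emax₀ = max mean fold, EC50₀ = tested concentration nearest the
half-maximal response, slope₀ = 1. Bounds: slope ∈ [0.3, 5], Emax ∈
[1, 2 × max observed mean fold] (the fit-sanity constraint: a fitted plateau
should never be far above anything observed), log10 EC50 within ±3 decades
of the tested range. A fitted EC50 outside [min conc/10, max conc×10] is
reported as non-converged rather than trusted. `fix_slope=1.0` pins the
slope for hyperbolic recovery experiments. Duplicate concentrations are
averaged before fitting.

**Recovery characteristics** (quantified by the test suite): noiseless
round-trips recover EC50/Emax to better than 1e-4 relative error for any
truth inside the tested range. With 10% CV quadruplicates over an
8-concentration design, the near-efficient estimator achieves a median
absolute EC50 error of ~6% with ≥99% of estimates within ±30% — the
information content of a 32-well experiment bounds the achievable precision;
sub-5% median error would need a larger design.

**Stability metrics.** Dosing-interval depletion is summarised by the linear
trapezoidal AUC over the incubation window (default 96 h), the average
concentration AUC/window, and the extent of loss 1 − avg/nominal (clipped at
zero).

## 2. Mechanistic static model

Per enzyme, the basic induction ratio follows the regulatory basic model

    R3 = 1 / (1 + d · (Emax − 1) · I / (EC50 + I)),

with scaling factor d = 1 and exposure input I = multiplier × Imax,u
(maximal unbound perpetrator plasma concentration). The 10× correction
factor is applied to every enzyme by default — the CYP2C enzymes share PXR/
CAR regulation with CYP3A4, and a uniform treatment keeps the model
symmetric — with a per-enzyme override for users who want the correction on
CYP3A4 only. Because the fitted Emax here is *total* fold (baseline 1), the
induction amplitude entering R3 is Emax − 1; `emax_convention="fold"`
exposes the convention that uses Emax itself.

Victim exposure combines pathways through the fraction metabolized:

    AUCR = 1 / (Σᵢ fmᵢ·FCᵢ + (1 − Σᵢ fmᵢ)),   FCᵢ = 1/R3ᵢ,

with the residual clearance fraction untouched. `msm_table` evaluates this
per donor and reports the across-donor mean and range. Donor-level NC
enzymes are treated as uninduced in that donor's net ratio; a victim whose
every fm pathway is NC in every donor is reported as a no-call row.

## 3. Dynamic enzyme-turnover model

**Perpetrator.** Linear one-compartment kinetics with first-order oral
absorption, solved in closed form by superposition (a zero-order infusion
route exists for steady-exposure analyses). This is exact for linear PK and
makes the superposition and absorption-mass-balance invariants identities
rather than solver approximations. Rifampicin autoinduction of its own
clearance is not modeled; instead the fixture clearance is the *steady-state*
literature value, which is the regime all packaged designs probe.

**Induction driver.** The hepatic driver is the unbound hepatic-inlet
concentration `fu·(C_plasma + ka·A_gut/Q_h)` — the standard correction that
credits the liver with portal absorption flux — optionally scaled by a
hepatocellular unbound partition Kp,uu for compounds with active hepatic
uptake. For rifampicin (an OATP1B1 substrate with well-documented hepatic
accumulation) the fixture uses Kp,uu = 4, inside the range reported by
uptake and imaging studies. A systemic-unbound driver is a settings switch.

**Enzyme turnover.** Each enzyme pool follows zero-order synthesis /
first-order degradation with hyperbolic stimulation of synthesis:

    dE/dt = kdeg·[1 + (Emax − 1)·C(t)/(EC50 + C(t))] − kdeg·E,   E(0) = 1.

The Hill slope from the in vitro fit is deliberately *not* propagated
(static regulatory models and standard induction PBPK practice are slope-1);
this is configurable in principle by pre-transforming parameters. Default
degradation rate constants (editable config, `data/enzyme_settings.json`):

| pool | kdeg (1/h) | t½ |
|---|---|---|
| hepatic CYP3A4 | 0.0193 | 36 h |
| enterocyte CYP3A4 | 0.030 | 23 h |
| CYP2C8 | 0.030 | 23 h |
| CYP2C9 | 0.0067 | 103 h |
| CYP2C19 | 0.026 | 27 h |
| CYP2B6 | 0.022 | 32 h |

The slow CYP2C9 turnover is why the packaged tolbutamide design runs the
perpetrator for 14 days: at 5 days CYP2C9 is only ~55% of the way to its
induced steady state.

**Gut CYP3A4.** Victims with baseline gut availability Fg₀ < 1 get an
enterocyte CYP3A4 pool with its own (faster) kdeg, driven by the absorption
surrogate concentration `ka·A_gut/Q_gut`. Gut availability responds as
`Fg(E) = Fg₀ / (Fg₀ + (1 − Fg₀)·E)`, the flow-vs-metabolism competition
form that reduces to Fg₀ at baseline. This pool is what carries >85%
midazolam AUC reductions; hepatic induction alone cannot reach them.

**Victim disposition.** Semi-physiological one-compartment oral model:
absorbed drug passes sequentially through the gut wall (Fg) and liver (Fh,
well-stirred) before reaching the central compartment, and is eliminated by
the time-varying well-stirred hepatic clearance plus a fixed renal term.
The fm partition enters the intrinsic clearance,
`CL_int(t) = CL_int,0·(Σ fmᵢ·Eᵢ(t) + 1 − Σ fm)`, with CL_int,0
back-calculated from the fixture's systemic clearance. In the static limit
this reproduces `AUC_po = Fa·Fg·D/(fu·CL_int)`, so for a low-extraction oral
victim under constant perpetrator exposure the dynamic AUCR converges to the
static fm-weighted ratio (verified to <2% in the test suite). Blood:plasma
partitioning is fixed at 1 (plasma-flow convention).

**AUC.** Both arms are integrated to 10 baseline half-lives past the victim
dose (≥72 h), sampled on a 0.05 h grid, AUC by trapezoid plus C_last/k_el
extrapolation from the terminal log-linear slope. A non-estimable terminal
slope demotes the result to AUC_last with a warning; extrapolated fractions
≥20% warn. Percent reduction is defined as 100·(1 − AUCR) exactly.

**Numerics.** LSODA with rtol 1e-8 / atol 1e-10, integration segmented at
every dose event, max step 1–2 h so daily absorption pulses are never
stepped over. Halving the tolerances moves reported AUCRs by ≪0.5%
(tested). The full nine-design sweep runs in a few seconds on one CPU.

## 4. Fixtures and calibration

Induction parameters are the vendored per-donor tables; the dynamic engine
defaults to the **geometric mean across non-NC donors** of the mRNA readout
(EC50 and Emax are log-scale quantities; mRNA has full donor coverage
whereas the activity readout is NC-heavy). Per-donor runs are available for
range estimates.

Base PK fixtures are literature reconstructions (citations in
`data/compounds.json`); none of the source study's proprietary compound
files are available, so exact agreement with simulator-specific outcome
values is not expected — the comparisons carry tolerances for that reason.
Calibration protocol: the rifampicin fixture was set so that its simulated
steady-state exposure falls within 0.8–1.25-fold of clinical steady-state
AUC (tested), and the hepatic-uptake and gut parameters were checked against
the rifampicin–midazolam positive control; the fixtures were then frozen and
the remaining victims are predictions. fm maps printed as inequalities carry
explicit numeric fixtures (midazolam 0.94, alfentanil 0.93, atorvastatin
0.90 — the dosing-table value where sources disagree); residual fm
(tolbutamide 0.15 "other CYPs", bupropion 0.61) is treated as uninduced
clearance.

Victim dose timings: "after the perpetrator on day N" is implemented as 1 h
after that day's dose; "12.5 h after the final dose" is literal; bupropion
is dosed the morning of day 8 of evening perpetrator dosing (12 h offset).
Warfarin is registered (fm and PK) but marked experimental: enantioselective
kinetics are out of scope and no outcome row exists for it.

## 5. Synthetic data

`gen_concentration_response` emulates the quadruplicate induction assay:
truth curve (hyperbolic by default) times mean-one log-normal noise
(σ² = ln(1+CV²), default CV 10% — the source experiments do not report
replicate CVs, so this is an assumed, exposed parameter). It does **not**
emulate plate effects, concentration-dependent error, cytotoxic dropouts, or
upstream qPCR/LC-MS mechanics; passing recovery tests therefore demonstrate
estimator correctness under well-behaved noise, not robustness to assay
artifacts. `gen_pk_observations` samples the closed-form PK profile with
mean-one log-normal residual error; it inherits the one-compartment
assumption and does not emulate absorption variability or BLQ censoring.
Both are pure functions of (spec, seed).

## 6. Known limitations

* CYP-only clearance: OATP1B1 uptake (rate-determining for repaglinide,
  substantial for glyburide and atorvastatin acid) and its inhibition are
  not modeled; fm-faithful predictions for such victims overpredict
  induction DDIs, visibly so in the packaged outcome table.
* Printed fm maps are point estimates; for several CYP2C victims the
  effective in vivo fm implied by clinical outcomes is smaller than the
  literature values vendored here, and the static and dynamic models share
  that input.
* Single representative subject; no inter-individual variability or virtual
  population.
* One-compartment PK backbones; no enterohepatic recirculation, active
  metabolites (pioglitazone, bupropion), or nonlinearities.
* Perpetrator autoinduction is folded into steady-state clearance fixtures,
  so the first one or two days of a perpetrator course are approximate.
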