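# Methods

## Scientific setting

The package analyses a differential cytotoxicity screen on glioblastoma
stem-like cells (GSCs) measured in two states: proliferating, and a
reversible quiescent (G0) state induced *in vitro* by withholding medium
renewal. Compound effects are read out as ATP-dependent luminescence 24 h
after treatment; a well's luminescence is a proxy for the number of
metabolically active cells. The analysis chain is: plate quality control and
normalization, single-point hit calling at 50 μM, duplicate confirmation at
50 and 5 μM, dose-response fitting, selectivity classification, and two
auxiliary analyses (prodrug hydrolysis kinetics and qPCR expression).

## Plate QC and normalization

Each 96-well plate carries 12 negative-control wells (1 % DMSO vehicle) and
4 positive-control wells (ophiobolin A 50 μM, cytotoxic to both cell
states). Assay quality is the Z′ factor

    Z′ = 1 − 3(σ_pos + σ_neg) / |μ_pos − μ_neg|,

which is ≤ 1 by construction and undefined when the control means coincide
(reported as NaN, plate failed). A plate passes only when Z′ > 0.5 —
strictly: Z′ = 0.5 exactly fails. Control SDs use the sample convention
(n−1), treating the 12/4 control wells as samples of plate noise; the
convention is configurable (`ddof`) because the one used to produce
published screen medians is not stated. Z′ is invariant under affine
rescaling of the luminescence channel, which the tests verify.

Relative ATP is `100 · L_w / μ_neg` of the same plate. Controls are
normalized too so QC plots can be regenerated; a plate's negative-control
mean relative ATP is exactly 100. Wells on failed plates are carried through
flagged "untested" rather than deleted — a failed plate is missing evidence,
not evidence of inactivity.

## Hit calling

Primary (single well per compound, 50 μM): a well is a hit when relative
ATP < 5 % **or** luminescence < μ_neg − 5 σ_neg. Both inequalities are
strict; boundary equality is a non-hit. The two branches answer different
questions — near-complete kill versus statistically resolvable kill — and
either suffices. Secondary (duplicates at 50 and 5 μM): duplicate wells are
averaged on the relative-ATP scale before thresholding (averaging, not
two-out-of-two voting, was chosen as the less noisy default; both duplicates
are usually on the same plate — when they are not, the per-plate SD
threshold expressed on the relative scale is averaged across their plates).
Quiescent-condition plates keep the 5-SD multiplier; proliferating plates
use 3 SD to compensate for their higher variability. A compound is
*confirmed* for a condition iff it is a primary hit and a secondary hit at
50 μM in that condition.

ATP-increase candidates are called with a symmetric convention (relative
ATP > 200 % or L > μ + kσ, k = 5 by default). This rule is an artifact of
this package — increasers were tracked upstream without a stated criterion —
and is clearly separated in the API (`direction="increase"`).

## Dose-response model

The four-parameter logistic on the linear response scale:

    y(x) = [S_max + S_min (x/EC50)^n] / [1 + (x/EC50)^n]
         =  S_min + (S_max − S_min)/(1 + (x/EC50)^n),

decreasing for cytotoxicity data (S_max ≥ S_min); the two algebraic forms
agree to machine precision (property-tested on 10 000 random draws).
Fitting is trust-region least squares on the untransformed response with a
fully deterministic initialisation: S_max from the mean response at the two
lowest doses, S_min at the two highest, EC50 at the geometric mean of the
tested range, n = 1. EC50 is parameterised as log10(EC50) for conditioning,
bounded within a decade of the tested range, and n ∈ [0.3, 10]; these
bounds prevent pathological fits on flat data. Replicates enter as
individual uniformly weighted points. Standard errors come from the
Gauss-Newton covariance (JᵀJ)⁻¹·RSS/dof, with the delta method for EC50.

A point estimate requires ≥ 4 distinct concentrations spanning ≥ 2 decades.
When the fitted midpoint falls above the highest tested concentration, or
the curve is flat, the potency is reported as the censored bound
`"> max"` — a censored EC50 is a one-sided statement, never a number.
Monotone-increasing fits are flagged `wrong_direction` for a cytotoxicity
readout.

## Selectivity classification

With ratio = EC50_P / EC50_Q: group 3 (quiescent-selective) requires
ratio ≥ 2 ("at least two-fold"), group 2 (proliferating-selective) is the
mirrored strict rule (ratio < 0.5), group 1 the open interval (0.5, 2). The
wording leaves ratio = 0.5 exactly unassigned; it is placed in group 2 so
the classifiable compounds are always partitioned (exchange symmetry maps
group 2 ↔ group 3 and fixes group 1, which the tests verify on random
inputs). Censored EC50s propagate as interval arithmetic on the ratio
(e.g. "> 100" over 1.07 gives ratio > 93); a group is assigned only when the
whole interval satisfies its rule, otherwise "unclassified".

Ratios recomputed from *rounded* published potencies can sit on the
two-fold boundary even when the original unrounded classification did not.
Ratios (or interval endpoints) inside [1.9, 2.1] or [0.476, 0.526] are
therefore flagged `boundary_flag` rather than forced to match a published
grouping. On the bundled 20-compound reference table this flags exactly
sertraline (rounded ratio 2.05 in the quiescent/proliferating direction)
and ethacrynic acid (1.98); every other compound lands in its published
group, so the published 12/4/4 group sizes are reproduced up to those two
flagged compounds — the stated limit of exact reproduction from printed
values.

Specificity profiles express potency as 1/EC50 (μM⁻¹) per compound × cell
context; censored entries are potency 0 with a separate boolean mask, a
distinct "inactive in tested range" category rather than a measured zero.

## Hydrolysis kinetics

Bisacodyl (diester, HPLC retention 1.78 min) hydrolyses sequentially to its
monoester (1.56 min) and then DDPM (1.35 min). With first-order rates k1,
k2 (h⁻¹):

    A(t) = a0 e^(−k1 t)
    B(t) = a0 k1/(k2−k1) (e^(−k1 t) − e^(−k2 t)),  k1 ≠ k2
         = a0 k1 t e^(−k1 t),                       k1 = k2 (removable singularity,
                                                     explicit branch at |k1−k2|/k1 < 1e−9)
    C(t) = a0 − A − B.

Mass balance holds for all t and the intermediate is transient with a single
interior maximum at t* = ln(k1/k2)/(k1−k2) — both property-tested. Peak
areas are modelled as response_factor × amount; factors default to 1
(calibrated areas) with optional estimation (the parent factor then fixes
the scale). The fit is joint least squares over all observed species with
parameters log-transformed for positivity and initialised from a log-linear
regression of the parent decay — deterministic given the data. A
multiplicative-noise option (log-scale residuals) is available. If only the
parent is observed, only k1 is identifiable; the model warns and fits a
single exponential. Half-lives are t½ = ln2/k with delta-method standard
errors. Both the joint A/B/C fit and the parent-only single-exponential
route are provided because published half-lives rarely state the estimation
method.

## qPCR (ΔΔCt)

Replicate Cts are averaged arithmetically within an experiment (standard
Livak convention, amplification efficiency fixed at 2).
ΔCt = Ct_gene − Ct_18S per sample; ΔΔCt = ΔCt_sample − ΔCt_calibrator;
fold = 2^(−ΔΔCt). Across independent experiments the *folds* are averaged,
not the ΔΔCts: the mean of per-experiment folds is what worked examples in
this field print (e.g. mean fold 6.32 for mean ΔΔCt −2.66; and a mean fold
of 2.32 can coexist with 2^1.22 ≈ 2.33), and fold-averaging is therefore
the default, with the mean ΔΔCt also reported. The array detection filter
keeps genes with min-over-conditions ΔCt ≤ 21 cycles (inclusive: 21.0 is
retained); larger ΔCt marks low expression with poor signal-to-noise.

## Synthetic-data generators

The generators emulate the *measurement model* the analysis assumes — not
cell biology. A screen plate is baseline × viability × lognormal(1, CV)
noise per well (luminescent assays have signal-proportional error;
additive-offset behaviour is deliberately not modelled, and the tests check
that normalization is scale- but not offset-invariant). Defaults are the
study conditions: 1120 compounds at 50 μM, 80 per plate (14 plates per
condition), 12 negative / 4 positive control wells, positive-control kill
fraction 0.9. Per-condition baselines (750 000 / 1 000 000 RLU for
proliferating / quiescent) reflect the different seeding densities
(30 000 vs 40 000 cells/well); their absolute scale is arbitrary since every
statistic downstream is scale-invariant. Well CV defaults to 0.07, which
places simulated per-plate Z′ near the published screen medians
(0.615/0.68) — a calibration of the simulator to the documented assay
window, not a claim about the true per-well CV, which is unpublished.
Control-well positions are not published; the simulator fixes them (column
1 plus A12–D12 negative, E12–H12 positive) and an optional row/column
gradient can inject edge effects to stress-test QC, but no spatial
correction is applied anywhere (none was used upstream).

Dose-response data use a 10-point 3-fold dilution from 100 μM in triplicate
at 10 % CV by default (the grid behind the "> 100" censoring convention;
the exact grid used upstream is unpublished and configurable). Kinetics
series sample the five stability timepoints 2 min, 2, 4, 6, 24 h at 5 % CV.
Ct tables are built as Ct_gene = Ct_18S + ΔCt_calibrator − log2(fold) +
noise with a constant housekeeping gene.

What passing on synthetic data does *not* show: robustness to spatial
artefacts, carry-over, compound fluorescence/luminescence interference,
heteroscedasticity beyond the multiplicative model, or any biology of the
quiescent state itself.

## Problem sizes and numerical choices

Monte-Carlo summaries in the acceptance script use 200 replicates per
quantity (medians of EC50 and half-life recovery), the package's standard
reporting size; tests use 50–100 replicates for the same checks. Property
tests are derandomised/seeded. Optimiser tolerances are 1e−12/1e−13
(xtol/ftol/gtol) so fits are reproducible to well below reporting
precision. All simulation randomness flows through
`numpy.random.SeedSequence` spawning, so every result is a pure function of
the user-facing seed.

## Known limitations

* Screen-level published counts (57/69/40 primary hits, median Z′
  0.615/0.68) depend on unpublished raw plate data and are not reproducible
  from printed information; the package reproduces the *rules*, verified on
  synthetic truth.
* Single-criterion secondary voting (both-duplicates-must-pass) is
  implemented only via configuration, not studied.
* No 5PL/asymmetric dose-response models, no robust/weighted fits, no
  multiple-testing correction, no B-score/spatial normalization — mirroring
  the upstream analysis, which used none.
* Kinetics assumes first-order (non-enzymatic) hydrolysis; Michaelis–Menten
  behaviour in conditioned medium would bias half-life estimates.
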