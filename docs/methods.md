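# Methods

## Scope

`tundraflux` implements the full measurement-to-inference chain used in
chamber-based studies of tundra CO₂ exchange: deriving net ecosystem
exchange (NEE), ecosystem respiration (ER) and gross primary production
(GPP) from closed dynamic chamber traces; estimating green fractional cover
(GFC) from nadir collar photographs; fitting univariate and
multi-regression driver models of ER and GPP with AIC-based selection,
randomization pruning and driver-weight attribution; and assessing all
significance statements by permutation rather than asymptotic theory.  A
synthetic campaign generator with exact ground truth makes every stage
testable end to end.

## Flux derivation

The closed chamber accumulates CO₂ over ~3 minutes.  The concentration
tendency is estimated by ordinary least squares on the trace (a trace with
zero concentration variance is assigned slope 0 and, by convention, r² = 0)
and converted with the ideal-gas chamber equation

    flux = slope · Pr·V / (R · T_K · A)          [µmol m⁻² s⁻¹]

with V the effective headspace volume (collar area × chamber height plus a
configurable extra headspace), A the collar area, and ambient Pr, T taken
as constant over the deployment.  GPP = NEE − ER from the
transparent/darkened pair at the same collar; the conventions ER ≥ 0,
GPP ≤ 0 are enforced as warnings, never as silent edits.  Quality control
flags (default r² < 0.70) mark estimates rather than dropping them.  The
analyser is assumed to report dry mole fraction; no water-vapour dilution
or cell-pressure correction is applied.  Raw variables are screened for
outliers with the generalized extreme studentized deviate (Rosner)
procedure, implemented directly since no installed library provides it.

## Green fractional cover

GFC is the fraction of collar area covered by green photosynthetic
vegetation.  Images are low-pass filtered with an adaptive local Wiener
filter (implemented with reflective boundary handling so that a constant
image is a fixed point; window default 5×5), reduced to the excess-green
index g = 2G − B − R, and segmented inside a circular collar ROI.  The
default threshold is the index's natural background boundary g > 0; Otsu's
method on the within-ROI g histogram is available as an alternative
interpretation.  GFC = green pixels / ROI pixels, hence bounded in [0, 1];
canopy layering is deliberately not modelled, and reddish vegetation
(g < 0) is excluded by construction.

## Flux models

Classical responses:

    ER  = a·exp(b·Ta),                 Q10 = exp(10·b)
    GPP = Fmax·α·rs / (Fmax + α·rs),   Fmax, α < 0 so GPP ≤ 0

The multi-regression family perturbs the classical parameters linearly in
additional drivers (candidates: GFC, VWC, Ts, RH, Pr, hour, DOY):

    ER  = (a0 + a1·x1 + …)·exp(b0·Ta)
    GPP = K·(A0 + A1·y1 + …) + K²·(B0 + B1·y1 + …),   K = F·α0·rs/(F + α0·rs)

### Identifiability and gauge convention

The GPP family is exactly invariant under (F, α0, A, B) → (cF, cα0, A/c,
B/c²) for any c ≠ 0, so ordinary least squares has a flat direction and any
particular (F, α0, A) triple is one representative of an orbit.  Internally
the package fits the identifiable parametrisation ρ = F/α0 (W/m²),
P_i = F·A_i (µmol m⁻² s⁻¹), Q_j = F²·B_j, in which the model is linear
given ρ.  Reported (F, α0, A_i) use the convention that the A-block
averages to 1 over the sample — F is then the light-saturated flux at the
campaign-mean cover and moisture.  Consequences worth knowing:

* the reported A_i are normalised block *shapes*; scaling the whole
  response block leaves them nearly unchanged.  Between-group comparisons
  of the GPP response therefore use R_i = P_i·rs_ref/(ρ + rs_ref), the
  driver response at a fixed reference irradiance rs_ref = 400 W/m² —
  ρ and P_i individually trade off along a nearly flat direction on noisy
  or heterogeneous data, while their combination at mid-range irradiance is
  stable;
* parameter-recovery results are stated for the identifiable set
  (a0, a1, a2, b0; ρ, P0, P1, P2).

### Fitting

Variable projection: for fixed b0 (ER) or ρ (GPP) the model is linear and
solved exactly; the single nonlinear parameter is profiled on a grid
(b0 ∈ [−0.3, 0.6]; log ρ ∈ [0, log 2·10⁴]) and polished with bounded Brent
to ~10⁻¹¹.  This is the same unweighted least-squares estimator a generic
NLS routine would target, without initialisation failures, and it makes
permutation refits cheap.  Permutation nulls for coefficient tests use the
same profile fit executed for all shuffles at once, with a parabolic
3-point refinement of the profiled parameter.  Constant or collinear
driver columns raise a rank-deficiency error naming the offending terms.
Heteroscedastic residuals are reported (Bartlett), not reweighted.

### Selection statistics

Explained variance σ²_expl = (σ²_flux − σ²_res)/σ²_flux.  Model comparison
uses the regression Akaike criterion in the form AIC = N·log(Σε²) − 2k
(natural log), with k counting the named model parameters plus the
residual variance; for GPP the named count is kept although one
combination is a gauge.  Candidates are ranked by AIC ascending, ties
broken by fewer parameters then lexicographic driver names.  A
partial-correlation screen (each driver pair conditioned on the remaining
candidates; covariates numerically identical to a member of the pair are
dropped) forbids significantly inter-correlated drivers from co-occurring.
After ranking, the front runner is pruned: extra drivers whose permutation
p-value exceeds α are removed iteratively, worst first, never touching the
classical kernel; only the AIC-best candidate is pruned, which cannot
change the selected model (the pruned model is a sub-spec of the winner)
and keeps the randomization budget affordable.  Driver weights are
Δσ²_expl of (classical + one driver) over classical.  Residual diagnostics:
Lilliefors for normality; Bartlett across (default 4) equal-size groups
ordered by fitted value.

## Randomization inference

Three double-tailed shuffle tests share the add-one estimator
p = (1 + #{|draw| ≥ |observed|})/(n_shuffles + 1), which never returns 0:
group-size-preserving reassignment for mean differences (switching to
exact enumeration whenever the number of assignments is ≤ 10,000),
driver-column permutation for coefficient significance, and cross-series
mixing with double refits for between-group parameter differences.  The
default n_shuffles is 10,000 for standalone use; the pipeline default is
999.  With 199 shuffles the achievable p-grid makes the α = 0.05 type-I
error exactly 10/200 for continuous statistics, which the calibration
checks confirm empirically.  No multiple-testing correction is applied to
the pairwise species matrices; the p-values are reported raw.

## Synthetic campaigns

The generator emulates a High-Arctic summer campaign: a smooth single-peak
diurnal cycle for Ta (8.2–17.5 °C) and rs (37.12–651 W/m², the floor
strictly positive — polar day), pressure near 1023 hPa, soil temperature
damped toward air temperature; 177 points over 10 days sampled between
07:00 and 19:00; vegetation classes V/NV/MIX/BS at 35/30/33/2% with
class-specific beta-distributed GFC (V right-shifted, NV concentrated near
0.05, so the pooled distribution sits mostly below 0.20); VWC uniform on
5–45% and independent of GFC; species labels CX/DR/SL/SX/SI on vascular
points.  True fluxes come from the multi-regression models above with
default generative parameters (a0, a1, a2, b0) = (0.17, 2.63, 0.0035,
0.074) and (F, α0, A0, A1, A2) = (−2.16, −0.031, 0.021, 7.31, 0.0024);
observed fluxes add Gaussian noise with sd = s·|flux|^q, q = 0.5.

Two noise regimes are provided:

* **default** — s chosen once, in closed form, from the asymptotic
  sandwich covariance of the unweighted LS estimator on the default design
  so that the worst-identified parameter has a 5% relative standard error
  (s_ER = 0.047, s_GPP = 0.0076).  This is the regime for estimator
  validation: the smallest coefficients (above all the GPP block intercept
  F·A0 ≈ −0.045 µmol m⁻² s⁻¹, ~30× below a typical GPP) are recoverable
  only from very quiet data, and demanding recovery fixes the noise scale;
* **`CampaignConfig.field_realistic()`** — s chosen so that refitting the
  generating models yields explained variances near 0.64 (ER) and 0.76
  (GPP), the residual level typical of field chamber campaigns.  At this
  level only the dominant parameters (a1, b0, P1) are well constrained —
  an identifiability property of the model family worth keeping visible —
  and this regime drives the heteroscedasticity checks and pipeline
  demonstrations.

What the generator does *not* emulate: spatial autocorrelation and point
placement, multi-day weather systems, plant morphology in images (the
green patch is a compact pixel blob), instrument drift.  Passing tests
therefore demonstrate correctness of the estimators and calibration of the
tests under the stated statistical structure, not robustness to every
field artefact.

Chamber traces are synthesised by inverting the ideal-gas equation
(ambient 415 ppm, 3 min at 5 s sampling, optional analyzer noise), making
flux → trace → flux an identity at zero noise.  Collar images place an
exactly counted contiguous green patch (2G − B − R > 0) inside the collar
ROI on a soil background (2G − B − R < 0), with luminance-only pixel noise
that leaves the index invariant.

## Problem sizes in the distributed checks

The test-suite and acceptance-script simulation sizes are the package's
chosen defaults: 200 seeds for recovery and selection rates, 2000 null
simulations at 199 shuffles for test calibration, 100 images at 512×512
for cover recovery, campaign size n = 177 throughout (60 for the null
coefficient simulations).  Unit tests use smaller replicas of the same
constructions.

## Known limitations

* The GPP gauge means printed (F, α0, A) triples from other software are
  comparable to ours only through the identifiable combinations.
* The B-block (kernel-squared) terms are implemented and testable but
  empty in the reproduced final model specifications.
* Unweighted least squares under the heteroscedastic noise the data
  exhibit is inefficient (though unbiased); weighting is deliberately not
  applied to keep the estimator the standard one for this analysis chain.
* ρ = F/α0 is weakly identified when irradiance spans only the saturating
  part of the light response; the reference-irradiance responses R_i are
  the stable summaries.
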