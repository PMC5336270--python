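# Methods

## Design space and coding

The experiment varies three diet ingredients inside a fixed mixture share:
yeast (A) ∈ [3, 6]%, corn flour (B) ∈ [5.3, 8.3]%, corncob fractions (C) ∈
[19, 22]% of the whole diet, with A + B + C = 30.3%.  The remaining 69.7%
(sugar 8.2, sodium benzoate 0.4, methylparaben 0.1, citric acid 0.44, guar
gum 0.1, water 60.46) is constant and never modelled.  All proportions in
the package are percent of the whole diet.

Because every component has a positive lower bound, models are fitted on
**L-pseudocomponents** `z_i = (x_i − L_i)/(T − ΣL)` with `T = 30.3` and
`ΣL = 27.3`.  Under this coding the extreme blends (6/5.3/19, 3/8.3/19,
3/5.3/22) map to the unit vectors, so linear Scheffé coefficients equal the
predicted responses at those vertices — the property that makes the
confidence interval of term A a natural acceptance limit (the standard
mass-rearing blend *is* the A vertex).  An alternative ±1 "coded factor"
convention exists for mixture bounds; we use the vertex convention because
it is the one under which the published vertex predictions and the derived
optimization limits are mutually consistent.

The default design reproduces the study layout: 19 distinct blends, 40 runs,
cohorts of 25 larvae.  The exact replicate allocation was published only
graphically, so the plan is configurable; the default (three vertices ×4,
twelve blends ×2, four interior singletons — mixtures 7, 8, 12 and 13) was
chosen to satisfy every printed degree of freedom: 21 pure-error df
(40 − 19), linear-model ANOVA on (2, 37) df, lack of fit on (16, 21), and —
because singleton runs exist — dropping one outlying run leaves 39 runs on
18 blends, preserving 21 pure-error df and giving the 8-term reduced special
quartic its (10, 21) lack-of-fit df.

## Scheffé models and selection

Model ladder (three components): mean (1 term), linear (3), quadratic (6,
adds AB, AC, BC), special cubic (7, adds ABC), cubic (10, adds the
difference terms AB(A−B) etc.), special quartic (9, adds A²BC, AB²C, ABC²),
quartic (15, adds AB(A−B)² etc.).  Scheffé models have no intercept; ANOVA
uses the mean-corrected total SS with df_model = p − 1, the convention that
reproduces the published F dimensions.

Fitting is ordinary least squares (via `statsmodels.OLS`) on the pseudo
design matrix.  Adult emergence is arcsine-square-root transformed before
fitting (heteroscedastic proportion data); predictions and CI endpoints are
back-transformed with sin² after clamping to [0, π/2].  Back-transforming
*individual coefficients* of a multi-term model is not meaningful (the
transform does not commute with the model sum), so transformed fits are
compared and optimized on the transformed scale and only predictions are
back-transformed.

Sequential selection walks the ladder with incremental Type I F tests, each
increment tested against the current order's residual mean square.  The
selection criteria — no aliased terms, significant sequential terms,
non-significant lack of fit, favourable PRESS/R² family — are encoded as:
reject aliased orders; among orders with sequential p < 0.05 prefer those
without significant lack of fit and take the highest, breaking exact ties by
predicted R²; fall back to linear when nothing qualifies.  A gap
R²_adj − R²_pred > 0.2 is reported as a reliability warning.

Backward elimination removes, one at a time, the removable term with the
largest partial-F p ≥ 0.05, refitting after each removal.  Linear terms are
never removed, and the mixture hierarchy is enforced: a term is removable
only if no retained higher-order term contains it (componentwise exponent
dominance), which is why non-significant two-way terms survive under a
significant A²BC.

Summary statistics follow the standard response-surface definitions:
lack-of-fit F from pure error pooled within identical blends (blend equality
at 4 decimals); PRESS via the hat-matrix identity Σ(e_i/(1−h_ii))², which
the tests verify against explicit leave-one-out refits; R²_pred = 1 −
PRESS/SS_total; adequate precision (max ŷ − min ŷ)/√(p σ̂²/n) with > 4
deemed adequate for prediction.

## Diagnostics and exclusion

Externally studentized (outlier-t) residuals, Cook's distance, DFFITS and
DFBETAS are computed from the closed-form leave-one-out identities and are
tested to equal brute-force refits to 1e-8.  Numerically exact fits (σ̂ at
machine zero) report all influence statistics as zero rather than 0/0 noise.

The source workflow does not state its flagging thresholds; the defaults
here are the conventional |t| > 3, D > 1, |DFFITS| > 2√(p/n),
|DFBETAS| > 2/√n, all configurable.  A run becomes an exclusion candidate
only when the outlier rule fires *together with* at least one influence rule
(outlying **and** influential), and at most one run is excluded per response
by default — matching a workflow that removed exactly one run for larval
duration and one for pupal weight.  Box-Cox profiles (grid −3…3, step 0.1,
geometric-mean scaling, 95% profile-likelihood CI) apply to untransformed
positive responses; "no transform" is recommended when λ = 1 is inside the CI.

## Cost model

Only the three variable ingredients are costed: for blend `x` (percent) and
prices `p` ($/kg), cost per ton of finished diet = `1000·Σ (x_i/100)·p_i`.
Cost is exactly affine in the blend, hence linear on the pseudo simplex.
When per-kg prices are unavailable they are recovered from three published
anchors — the standard blend's annual cost ($791,716), the all-corn-flour
vertex's annual cost ($596,525) and the corncob vertex's savings (21.29%) at
1,730.29 t/yr — by solving the 3×3 linear system; the recovered prices
($4.204, $0.4437, $0.9569 per kg) reproduce all three anchors to rounding
precision.  The implied corncob price exceeding the corn-flour price is a
property of the printed anchors, not an assumption.

## Optimization

Acceptance criteria are one-sided bounds on each response at the standard
blend's 95% prediction CI: lower endpoints for pupation (0.70), pupal weight
(16.39 mg) and emergence, upper endpoint for larval duration (9.46 d).  The
packaged reference criteria carry emergence ≥ 0.80 as a stated constant
because the published back-transformed CI for the emergence A term is
degenerate and cannot supply it.  The published emergence coefficients are
likewise shipped on the proportion scale as printed; within the operability
region the emergence surface sits far above its limit, so this reporting
approximation does not move any reported bound.

The overlay is an exhaustive lattice search: yeast and corn flour on a
0.01-percentage-point grid (≈ 45k points, sub-second), corncob implied by
the mixture total.  The feasible set is the conjunction of all criteria;
component ranges are rounded half-up to 2 decimals; the savings argmax is
tie-broken by lowest yeast then highest corn flour.  A criterion is reported
*binding* when relaxing it alone would enlarge the region, and the criterion
with the smallest individual feasible mask is reported as most restrictive
(larval duration, with the study inputs).  With the packaged inputs the
computed region is 5.27 ≤ A ≤ 6.00, 5.30 ≤ B ≤ 6.03, 19.00 ≤ C ≤ 19.71: the
duration-pinned corner (A 5.27, B 6.03) and the corncob ceiling (19.71)
match the published region, while the published interior bounds A ≤ 5.88 and
B ≥ 5.42 do not follow from the four stated criteria (the standard blend
itself satisfies them all); the package reports its computed bounds and the
binding constraints rather than asserting those two figures.

## Synthetic data

The generator emulates the real experiment's structure for testing without
raw data: truth surfaces default to the packaged reference coefficients;
pupation is Binomial(25, p(z))/25 and emergence Binomial(n_pupae, q(z))
per recovered pupa (biologically natural dish-level noise, even though the
analysis itself uses least squares on proportions); larval duration and
pupal weight get Gaussian noise with sd 0.45 d and 1.6 mg — residual scales
were not published, so these were chosen once to put simulated R² in the
moderate 0.3–0.8 band typical of such assays.  Consequences for testing:
noise-free simulation recovers coefficients exactly; normal-error responses
give exactly nominal CI coverage (verified at 200 replicates); but binomial
proportion data violate the homoscedastic OLS model slightly, and the
generator does not simulate larval density effects, dish-to-dish temperature
gradients, or any real S1-table idiosyncrasies — passing tests demonstrate
the correctness of the statistical machinery, not biological claims.

## Numerical choices and limitations

* Blend sums are validated to 1e-9; replicate grouping keys round to 4
  decimals to survive CSV round-trips; pseudo-coding round-trips to 1e-12.
* Rank deficiency (aliased term sets) raises rather than silently pruning.
* Lattice coordinates are rounded to the step's decimal precision so grid
  membership tests are exact.
* Degenerate guards: zero pure error reports LOF as 0 or +inf; leverage-1
  points make PRESS undefined (error); constant fitted surfaces give
  adequate precision 0, exact fits +inf.
* Reports serialize with 6 significant digits; the pipeline is a pure
  function of (config, data, seed).
* Raw run-level and price-level supplements of the reference study are not
  redistributed; data-dependent published statistics (response means, R²
  values) can be checked only when a user supplies that data via the CSV
  loader, while every design-determined quantity (df structure) and every
  coefficient-level published figure is reproduced by the packaged constants.
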