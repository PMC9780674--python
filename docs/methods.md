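# Methods

This note records the statistical conventions, numerical choices and open
design decisions behind the package, in the spirit of a model-description
appendix.

## Designs and coding

Factor settings are handled on two scales related by the affine map
coded = (actual − center)/step. `FactorDef` stores center and half-range
(`step`); the −1/+1 actual levels are derived, and the triple is
self-consistent by construction. Coded design entries are stored as exact
integers −1/0/+1; actual concentrations only materialize through
`decode`, so round-trips are exact at the design points.

Plackett–Burman matrices are built from the standard cyclic first rows
(n = 8, 12, 16, 20): the first row is cycled n−2 times and an all-minus
row appended. Published matrices are typically row/column permutations of
the standard construction, so every fitting function accepts an explicit
user-supplied matrix; generation exists for planning new studies, and run
order is never randomized implicitly (a separate `shuffle_runs` takes an
explicit seed). The first `n_factors` columns are assigned to factors in
declared order; the remaining columns are retained as labelled dummy
columns, reportable but excluded from fits.

The three-factor Box–Behnken design comprises the 12 edge midpoints of
the cube — all four ±1 sign pairs for each factor pair, third factor at
0 — plus `n_center` replicated center runs (5 gives the classical 17-run
design; the center replicates alone carry the pure-error information).

## Screening stage

The first-order model is fitted by unweighted OLS on per-run **mean**
responses. Replicate SEs are carried through containers for display but do
not weight the fit: with equal replication per run, weighting would not
change the estimates, and published tables are reproduced by the means.

Per-factor ANOVA uses single-df Type III sums of squares,
SSᵢ = βᵢ²/[(XᵀX)⁻¹]ᵢᵢ, which on an orthogonal two-level design reduces to
n·βᵢ². F is taken against the regression residual mean square (df =
n − k − 1; for 6 factors in 12 runs, df = 5) and p is the upper tail of
F(1, df). The contribution rate is defined as 100·SSᵢ/SS_total with the
residual share included in the denominator, so all shares sum to 100 %;
this convention is stated here because software packages differ on it.

Significance tiers mirror table notation: `**` for p < 0.01, `*` for
p < 0.05. Factor selection returns every factor with p < α together with
the direction implied by the coefficient sign (increase for +, decrease
for −) and marks the rest "fix at current level".

Degenerate inputs: when the residual sum of squares is numerically zero
(noiseless data), a term with zero SS gets F = 0 and p = 1, a term with
positive SS gets F = ∞ and p = 0. "Numerically zero" means below
10⁻¹² × the total SS, so the rule is scale-free.

## Steepest ascent

Two path modes are provided. The coefficient-sign mode is the textbook
procedure: step k sets each moving factor to base + (k−1)·sign(β)·step.
The explicit-grid mode takes a user table verbatim; it exists because
published paths are sometimes constructed by unstated rules (the packaged
study's path increases all three factors even though two fitted
coefficients are negative), and faithful reproduction requires accepting
the grid as given. The winning step is the maximal observed mean response,
first occurrence on ties; its settings become the next stage's center,
with per-factor steps defaulting to the path increments.

## Response-surface stage

The full 10-term quadratic is fitted by unweighted OLS. Pure error comes
from the center replicates only (df = n_center − 1); lack of fit is the
remainder of the residual, tested as MS_LoF/MS_PE against
F(df_LoF, df_PE). With fewer than two center runs the lack-of-fit rows
are omitted and a warning flag set rather than reporting zeros.

Term sums of squares are again Type III (β²/c_jj, equivalently the
increase in residual SS when the term is dropped — the equivalence is
asserted against a drop-one refit oracle in the tests). The quadratic
columns of a Box–Behnken design are not mutually orthogonal, so these
term SS do not sum to the model SS; the Model row is therefore
SS_total − SS_residual, which is what standard RSM software prints.
R² = SS_model/SS_total, adjusted R² uses the df-corrected ratio, and
CV % = 100·√MS_residual/ȳ. A consequence of the design's structure worth
noting: the fitted intercept equals the mean of the center-run responses.

Effect ranking orders linear and interaction terms by descending F;
exact ties keep factor declaration order (sort keys are rounded at 10
significant digits relative to the largest term SS so that float noise
cannot reorder genuinely tied terms).

Coefficients are kept at full precision internally; a separate report
layer (`format_anova`, `format_equation`) rounds SS/MS to 4 dp, F to 2 dp
and p to 4 dp, matching how such tables are conventionally printed.

## Optimum stage

The stationary point solves Hx = −b with H the Hessian (Hᵢᵢ = 2βᵢᵢ,
Hᵢⱼ = βᵢⱼ) and is classified by eigenvalue signs; a Hessian with an
eigenvalue below 10⁻¹⁰ (relative) is treated as singular and the ridge
direction reported in the error.

The constrained maximum over the coded box (default [−1, 1]³) uses a
dense grid scan at 0.01 coded units followed by a bounded L-BFGS-B polish
from the best node; the polish result is never allowed to fall below its
starting node. Grid + polish was chosen over closed-form KKT enumeration
because screening-stage surfaces are frequently saddles (the packaged
study's is), where boundary maxima make the algebraic route fragile for
no performance gain in three dimensions. Grid evaluation broadcasts the
polynomial over 1-D axis arrays rather than expanding a basis matrix per
node, so the 0.01-step scan of the cube costs about 8×10⁶ additions.
Extrapolation beyond the design cube requires explicitly wider bounds.

For the packaged study the two headline numbers deliberately differ: the
model prediction at the study's reported optimum settings, coded
(−1, −1, 0), is 2.11 %, while the model's own constrained maximum over
the cube is ≈2.16 % at ≈(−0.13, −1, 0.18). The study does not state how
its software arrived at the reported point, so the package reports both
side by side and asserts nothing about their agreement.

## Synthetic data

`simulate_responses` draws, per run, `n_reps` replicates of
polynomial(coded point) + N(0, σ) and returns the replicate mean and SE.
Defaults are σ = 0.03 percentage points (mid-range of the replicate SEs
seen in triplicate protein determinations, 0.01–0.13) and 3 replicates,
i.i.d. Gaussian: the generator emulates replicate noise around a smooth
true surface and nothing else — no heteroscedasticity, no batch or time
effects, no model misspecification (the truth is exactly quadratic).
Passing tests on synthetic data therefore demonstrate correctness of the
estimators and the pipeline plumbing under the model's own assumptions,
not robustness to real-world violations of them. All randomness flows
through `numpy.random.default_rng` (PCG64) with explicit seeds, so
datasets are bit-reproducible across platforms.

`scenario_study` packages the study's designs with its fitted equations
as ground truth. The screening truth keeps only the three dominant main
effects and zeroes the minor ones: with a noiseless draw the regression
residual is exactly zero, so any nonzero true coefficient — however
small — would be flagged significant; zeroing the negligible effects
makes the noiseless scenario select exactly the factors that truly
matter, which is the property the end-to-end test exercises.

`recovery_study` repeats simulate→fit and reports per-coefficient bias,
RMSE, Monte-Carlo SE and 95 % t-interval coverage; with σ = 0.03 and 1000
replicates on the 17-run design, coverage is within 2 percentage points
of nominal (asserted in the acceptance suite).

## Problem sizes in the test-suite

Property tests use the designs at their natural sizes (12- and 17-run);
sum-of-squares conservation runs over 1000 random datasets, interval
coverage over 1000 simulated surface experiments, and the optimizer is
checked against an exhaustive-equivalent 0.001-step grid oracle on the
packaged fit plus 100 random quadratic surfaces. The oracle enumerates
the (x₁, x₂) grid and maximizes each x₃ line in closed form (a parabola's
grid maximum is at an endpoint or a vertex-bracketing grid point), which
is mathematically identical to enumerating all 2001³ nodes.

## Known limitations

- Designs beyond two-level Plackett–Burman and the 3-factor Box–Behnken
  (central composite, fractional factorial, mixture, D-optimal, 4–7
  factor BBD) are out of scope.
- No stepwise term elimination, Box–Cox transformation, or studentized
  residual diagnostics; no fold-over designs or Lenth's method for
  unreplicated screens.
- Single-response optimization only (no desirability functions); surface
  grids are exported as data, rendering is left to the user.
- Replicate SEs are display-only; fitting raw replicates rather than
  means is supported simply by supplying them as additional runs is *not*
  implemented — the containers summarize to per-run means.
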