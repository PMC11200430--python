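# Methods

## Design construction and coding

`build_bbd` generates the standard Box–Behnken design for 3–5 three-level
factors: for each of the C(k,2) factor pairs, the four (±1, ±1) corner
combinations with every other factor at its center, followed by the center
replicates. Runs are ordered pair-major with centers last; designs read from
CSV keep their own order, and design comparison is by coded-pattern multiset,
not row position. At least three center replicates are recommended (and
checked by `validate_design(lack_of_fit=True)`) so the pure-error estimate
for the lack-of-fit test has two degrees of freedom.

Two codings of the actual factor levels are implemented.

* `ordinal`: level index → −1/0/+1. The design's center level always codes
  to 0 regardless of spacing; off-level values are rejected.
* `affine` (default): v → (v − (low+high)/2) / ((high−low)/2). Low and high
  map to ∓1; a center level off the arithmetic midpoint codes to an interior
  value — for the 26/35/40 kHz frequency factor, 35 kHz codes to +2/7.

For equally spaced factors the two schemes coincide. For the frequency
factor they do not, and the interaction and curvature columns differ, so the
fitted surfaces genuinely disagree. The package default is `affine` because
refitting the packaged study under affine coding reproduces its published
predicted-response columns to within print rounding (max |Δ| ≈ 0.012 across
all 108 predictions) whereas ordinal coding misses by up to ≈ 1.35;
affine coding also reproduces the published adequate-precision range
11.04–13.04 exactly. This is the convention of mainstream DOE software,
which codes by the linear map between the physical extremes.

## Response-surface fitting and ANOVA

The full 15-term quadratic is fitted by `numpy.linalg.lstsq` on the coded
model matrix; no term selection is performed (the published predictions are
consistent with the full model, and reduced-model selection is explicitly
out of scope). Requirements: n ≥ p+1 runs and a full-rank design.

ANOVA uses partial (Type-III) sums of squares — SS(term) = SSE(model
without the term) − SSE(full model) — each tested with 1 df against the
full-model residual mean square. With ≥ 2 center replicates the residual is
partitioned into lack-of-fit and pure error and F(LOF) = MS_LOF/MS_PE is
reported; without replicates the rows are omitted. Significance defaults to
α = 0.05.

Adequacy statistics: R² = 1 − SSE/SST, adjusted R², CV% = 100·√MSE/ȳ, and
adequate precision (max ŷ − min ŷ over the design points)/√(p·MSE/n) with
p = 15 model terms. A residual SS below 10⁻¹⁶·SST is treated as an exact
interpolation and adequate precision reported as +∞ rather than a
rounding-noise artifact. Confidence intervals for coefficients are the
standard OLS β̂ ± t₁₋α/₂,df·SE with SE² from MSE·(XᵀX)⁻¹.

On the packaged study the four fits give R² = 0.911–0.939, lack-of-fit
p = 0.063–0.450, and adequate precision 11.04 (DPPH) to 13.04 (TPC); for
TPC the ethanol, time and temperature main effects are significant at 0.05
and the frequency main effect is not.

## Neural surrogate

Architecture: k coded inputs → H tanh hidden units → m linear outputs
(default 4–H–4); an optional cascade flag adds direct input→output skip
connections. Inputs are the coded factors (already order-1); outputs are
min-max scaled to [−1, 1] per response over the full dataset, and the
scaling is stored with the weights so the round trip is exact.

Splitting is largest-remainder apportionment of the 0.65/0.20/0.15
train/test/validation fractions (27 runs → 18/5/4) with seeded random
membership. Training minimizes MSE on the training partition only:

* `lm` (default): `scipy.optimize.least_squares` on the per-sample residual
  vector with the analytic network Jacobian. The trust-region-reflective
  variant is used because the training problem is typically under-determined
  (e.g. 72 residuals vs 94 weights at H = 10), which the textbook
  Levenberg–Marquardt update rejects; it shares the damped Gauss–Newton
  character that makes the family effective on small networks.
* `bfgs`: `scipy.optimize.minimize(method="BFGS")` on the scalar MSE with
  the analytic gradient.

Weights initialize uniform in [−0.5, 0.5] from `(seed, restart)`, so a fixed
(data, seed, config) triple is bit-reproducible. `n_restarts` re-trains from
fresh seeded initializations keeping the lowest validation MSE — the
"try again until it trains well" practice made deterministic. Defaults
max_iter = 500 and tol = 10⁻⁸ on the solver's convergence criteria. If a
pathological solver run ends with a worse training MSE than it started,
the initialization is kept instead, preserving the contract that training
never degrades the start point.

`sweep_hidden_neurons` trains one surrogate per H (default 1–20) on the same
split and selects the lowest validation MSE, ties to the smaller network.
With only 18 training runs, large H overfits freely (training MSE collapses
while validation MSE is noisy), so the selected H depends on the split seed;
the published study's choice of H = 10 arose from its own unrecorded split
and initialization and is not a reproduction target. One 4-output network
is trained by default, matching the published 4–10–4 topology description;
a per-response option falls out of passing a single-column response frame.

## Genetic-algorithm optimization

Candidates live in the coded box [−1, 1]^k and are decoded to actual units
for every surrogate evaluation; under ordinal coding the frequency decodes
by nearest level, so the optimizer only ever reports physically available
frequencies. Fitness is the weighted mean of min-max-normalized predicted
responses, the normalization bounds being the observed response ranges —
the simplest faithful reading of "maximize all responses", with weights
exposed for other trade-offs.

GA defaults: population 50, 100 generations, tournament size 3, blend
(BLX-0.5) crossover with probability 0.8, Gaussian mutation (rate 0.1,
σ = 0.2 coded units), elitism 2. The design's 27 coded points can be
injected into the initial population (`seed_points`), which guarantees the
optimum never falls below the best design point. `grid_search_oracle`
evaluates the full lattice (default 21 per axis, capped at 2·10⁶ points) as
an independent check; on the packaged study's quadratic surfaces the GA and
the oracle agree to < 10⁻³ normalized fitness.

## Prediction-ability metrics

AAD% = (100/n)·Σ|ŷᵢ−yᵢ|/yᵢ (relative to each observation; undefined at
yᵢ = 0), RMSE = √(Σ(ŷ−y)²/n), SEP% = 100·RMSE/ȳ, and R² = 1 − SSE/SST
(negative for predictors worse than the mean). AAD and SEP have competing
variants in the literature; these definitions are fixed here and used
consistently. On the published prediction columns the neural surrogate beats
the quadratic on all four metrics for all four responses, matching the
study's conclusion. A surrogate this package retrains need not reproduce
that — the published ANN column came from an unrecorded split/initialization
— and the non-divergence guard only requires the selected network's
validation MSE to stay within a factor 2 of the scaled-target variance.

## Assay calibrations

The packaged standard curves are TPC y = 0.0526x + 0.0020, TFC
y = 0.0336x + 0.0021, DPPH y = 0.0555x + 0.0123 and ABTS
y = 0.0369x + 0.0133 (absorbance y, analyte x). The ABTS source printed the
line with the "x" typographically dropped and TFC with a stray space in the
slope; both are implemented as ordinary linear calibrations as above.
Readings below the blank intercept convert to negative concentrations and
are flagged, not clipped; percent inhibition outside [0, 100] is clipped
with a flag.

## Synthetic studies

`generate_study` evaluates a known 15-term coded surface at the BBD points
and adds i.i.d. N(0, σ²) noise per response, seeded. The "study-like" preset
uses the fixture's fitted TPC surface as truth with σ chosen so the surface
variance over the design points is 10× the noise variance; at that level the
fitted R² lands in (0.8, 1.0) essentially always (median ≈ 0.96 over 200
replicates), bracketing the packaged study's 0.91–0.94 regime. What the
generator does not emulate: replicate-level assay noise structure (the
fixture's ± SDs are carried but unused, as the study fitted run means),
non-quadratic lack of fit, run-order drift, or any correlation between the
four responses. Passing synthetic tests therefore validate the estimation
machinery, not the chemistry.

## Problem sizes and numerical choices

All computations run on the 27-run study scale: fits are 27×15 least
squares, the CI-coverage and R²-regime simulations use 200 replicates, the
GA evaluates ≤ 50·101 candidates per run and the verification lattice is
21⁴. The fixture's printed 2-decimal values are compared with |Δ| ≤ 0.05
(print rounding). Ties in the neuron sweep go to the smaller network; ties
in the GA keep the earlier best-ever individual.

## Known limitations

* The published ANN-predicted column and the appendix-only ANOVA/metric
  tables are not recoverable and are not targets.
* The ordinal coding scheme is retained as an option but does not reproduce
  the published predictions; conclusions drawn under it differ in the
  interaction terms involving frequency.
* The GA treats frequency as continuous in coded space; only the decoded
  report is guaranteed physically realizable under ordinal coding.
* Multi-response optimization is scalarized; no Pareto front is computed.
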