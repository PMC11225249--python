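# Methods

## Triangular fuzzy numbers

All fuzzy quantities are triangular fuzzy numbers (TFNs): triples
(a₁, a₂, a₃) with a₁ ≤ a₂ ≤ a₃, membership rising linearly to 1 at the
vertex a₂ and falling to 0 at the support endpoints. We deliberately allow
degenerate triples a₁ = a₂ = a₃ so crisp numbers (thresholds, un-fuzzified
predictors) live in the same algebra; strict inequality buys nothing and
would exclude the crisp embedding.

Arithmetic follows α-cut interval rules. Addition and subtraction are
exact (componentwise sum; (a₁−b₃, a₂−b₂, a₃−b₁) for the difference). The
product of two TFNs is not triangular; `multiply` keeps the exact vertex
a₂b₂ and the exact α=0 support (min/max of the four endpoint products) and
re-reads the result as a TFN. The approximation error is confined to
intermediate membership levels; support and vertex — the only features the
model consumes — are exact, and the tests verify them against brute-force
grids over the support intervals.

Two scalar summaries are used. The *expected value* E(Ā) = (a₁+2a₂+a₃)/4
is the midpoint of the interval-valued fuzzy mean; the cited construction
defines an interval, and we adopt its midpoint as the single number the
classifier thresholds (the α-cut integral ∫₀¹ mid(Ā_α) dα gives the same
value, which the tests check by quadrature). The *centre of gravity*
(a₁+a₂+a₃)/3 is used only for interpreting coefficients, where equal
weighting of the three defining points is the convention.

The TFN discrepancy behind the fit's error measures averages |aᵢ−bᵢ| (or
squared differences) over the three defining points. A vertex-only variant
exists as a switch; the three-point form is the default because it is the
simplest metric that sees fuzziness at all.

## Fuzzification

Responses: F(y) = (y − m·ℓ·u, y, y + m·r·u), one independent
u ~ Uniform(I_L, I_U) per value. Defaults m = 1, r = ℓ = 1 (symmetric),
(I_L, I_U) = (0.001, 0.1). With these limits the spread never exceeds 0.1,
so clamping of the support to [−1, 1] is off by default (available as
`clamp_response` for aggressive m). The vertex is always the observed
label — fuzzification adds uncertainty around the data, never moves it.

Predictors: the construction is genuinely open in the source framework, so
it is a documented choice here. Columns are standardised to zero mean and
unit variance (this is what makes a single bounded coefficient range
meaningful across predictors), then each value receives a symmetric spread
m·u with its own uniform draw; a `degenerate` mode keeps predictors crisp.
Per-value (rather than row-shared) draws are the simplest reading of the
definition and are the default.

## Coefficient search

Candidates are drawn exactly as the framework prescribes: 3(k+1) uniforms
on [0, 1] (read from the dimension "three points per coefficient,
intercept included"), grouped into consecutive triples, each triple
sorted, then mapped affinely onto Ī_β = [I⁻, I⁺]. Default range [−2, 2]:
published crisp estimates from twelve clinical fits cluster inside
[−1.6, 1.9] on the standardised scale, and a symmetric ±2 box covers them
with margin. Defaults of 500 candidates × 20 repetitions.

Each candidate's predicted response TFNs (the fuzzy probabilities P̄, via
the logistic map applied pointwise to the fuzzy linear predictor) are
scored against the fuzzified observed responses Ȳ by MAE, MSE and RMSE.
"Lowest variation" across repetitions is measured by the coefficient of
variation of each measure's per-repetition best value — a scale-free
criterion; raw variance would trivially favour squared measures whenever
errors are below 1. The winning measure's overall best candidate is the
fit; argmin ties break to the lowest candidate index so fits are
reproducible. The logistic map is strictly increasing, so fuzzy
probabilities are always valid ordered triples in (0, 1) — the inversion
of the fuzzy logit needs no further machinery.

Classification: E(P̄) < t₂ gives label 0, otherwise 1 (equality counts as
1). The prediction TFN spreads the label by w(𝔻) = (d₃−d₁)/2, half the
support width of 𝔻 = P̄ ⊖ τ̄, so the output TFN's total support equals the
difference's support; a full-width variant would double-count the spread
on each side. Default τ̄ = (0.4, 0.5, 0.6); the framework leaves the
threshold to the analyst, and a symmetric threshold about ½ is the neutral
choice.

With m = 0 and crisp coefficients the whole pipeline collapses to
classical logistic probabilities exactly (tested to 1e−12), which anchors
the fuzzy model to its crisp limit.

## Separation diagnostics

Classical logistic regression is fitted by hand-rolled IRLS so the
per-iteration coefficient path is available — the path *is* the
diagnostic, and library fits expose only the endpoint. Under complete (or
quasi-) separation the likelihood has no finite maximiser: deviance slides
toward 0 while some |βⱼ| grows without bound. The detector flags predictor
j if its final standardised |estimate| exceeds 10, or if it grew strictly
in each of the last 5 iterations without convergence (max_iter = 100,
tol = 1e−8 on the max coefficient step). The numeric thresholds replace a
visual judgement of "estimates deviating to infinity"; 10 on the
standardised scale corresponds to an odds ratio above e¹⁰ per standard
deviation, well past anything interpretable. Converged fits are verified
against statsmodels GLM in the tests.

## Evaluation

Metrics come from the confusion matrix with class 1 positive. Cells with a
zero denominator (e.g. precision when nothing is predicted positive)
return 0 with a warning, matching the convention that lets all-negative
classifiers be scored; MCC with a zero factor under the root returns 0.

Cross-validation is 10 repeated stratified random 70/30 splits — "k folds
with a 70–30 split" cannot be a classic partition, since 10 equal folds
would force 90/10 — with SMOTE (when enabled) applied to the training part
only. SMOTE is implemented directly from its definition (convex
combinations of minority points with their minority nearest neighbours,
oversampling to exact balance).

Model comparison over several datasets uses the Friedman statistic
Q = 12N/(k(k+1))·[ΣR̄ⱼ² − k(k+1)²/4], its Iman–Davenport refinement
F_f = (N−1)Q/(N(k−1)−Q), and the Nemenyi critical difference
CD = q_α √(k(k+1)/6N). q_α is computed from the studentized-range
distribution (ppf at 1−α, k groups, ∞ df, divided by √2) rather than a
typed table, which reproduces the tabulated values (q = 1.960 at k = 2,
α = 0.05) and works for any k.

## Synthetic data generator

The generator emulates the two-predictor clinical motif used throughout:
X1 is strongly associated but non-separating (large relative mean gap,
E(X1|0) = −5.8·E(X1|1), with the minority class *more* dispersed,
Var(X1|1) = 1.6·Var(X1|0)), while X2 is an age-like, all-positive
separator (E(X2|1) = 2.33·E(X2|0) and a much more homogeneous minority,
Var(X2|1) = 0.3·Var(X2|0)). Presets: Dataset I (n = 100, 85% class 0) and
Dataset II (n = 50, 80% class 0, smaller mean gap — the "new data" with
weaker separation). Base variances are not pinned by the design ratios, so
they are package defaults: Var(X1|0) = 9 keeps X1's class distributions
overlapping in typical draws, and Var(X2|0) = 100 makes the X2 class
supports essentially disjoint; X2 is redrawn at 0 to stay positive. Class
counts are allocated deterministically from the imbalance proportion
(exactly round(n·p₀) zeros), then rows are shuffled under the seed.

What the generator does *not* emulate: correlated predictors, non-normal
tails, measurement error, more than two predictors, or label noise.
Passing tests therefore demonstrate behaviour under the idealised
imbalance/separation mechanism, not performance on real clinical tables.

One caveat the replicate studies surfaced: with these defaults the X1
design itself produces chance complete or near-quasi separation on X1 in
roughly 10% of n = 100 draws (15 minority cases leave room for the class
supports to miss each other). Detector flags on X1-only fits at about that
rate are correct detections of a property of the finite sample, not false
positives.

## Study sizes and determinism

The replicate studies run 50 seeded replicates; fits inside them use 200
candidates × 10 repetitions, sizes at which the compared quantity (a
median gap between two models) is already stable — the verdict is
unchanged at the full 500 × 20 search. All randomness flows from explicit
seeds: estimators derive independent fuzzification and search streams from
`random_state` via `SeedSequence`, so a seeded fit serialises to a
byte-identical JSON document on repeat runs.

## Known limitations

* The random search explores a box; with many predictors (large k) its
  coverage degrades and more candidates are needed.
* TFN multiplication is support/vertex-exact but linearises intermediate
  membership; downstream quantities use only support and vertex.
* Only TFNs are supported (no trapezoidal or Gaussian shapes), and
  coefficient uncertainty carries no significance tests.
* SMOTE here is the plain variant; borderline/adaptive refinements are out
  of scope.
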