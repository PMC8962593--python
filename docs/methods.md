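# Methods

`pathwayopt` implements the analytics of a biosensor-driven
Design-Build-Test-Learn cycle for combinatorial pathway balancing: a
multi-gene biosynthetic pathway (the default configuration models the
four-step naringenin pathway TAL → 4CL → CHS → CHI in *E. coli*) is
assembled combinatorially from a promoter library and isozyme variants, a
colony screen read out by a transcription-factor biosensor selects strains
for characterization, and three predictive models trained on the
characterized subset rank every genotype in the search space.

## Genotype space

A library is an ordered list of operons; each operon draws one promoter,
one coding sequence, and (formally) one RBS and one terminator from its
part sets. The space size is the product over operons of the per-operon
part counts, which reduces to the familiar power form when operons are
identical; the per-operon product form is used because post-filtering
spaces are heterogeneous. Enumeration order is fixed — operons in pathway
order, promoters before coding sequences, parts in declaration order — so
that ranking ties and top-k lists are reproducible. RBS and terminator
counts default to 1: the workflow varies neither, but the counts
participate in the size arithmetic.

## Promoter scale

Promoter strength is a transcription initiation frequency (TIF) in
arbitrary fluorescence-derived units spanning orders of magnitude. All
modelling happens on the linlog scale

    x = (log P − (log P_max + log P_min)/2) / ((log P_max − log P_min)/2)

which maps the weakest library promoter to −1, the strongest to +1, and
the geometric midpoint to 0. The transform is log-base invariant and
strictly increasing. TIFs outside the calibration range are transformed
with a warning rather than rejected, since the formula extends naturally
to future, wider libraries.

## Synthetic screening data

The generator exists so every downstream stage is testable without any
external dataset. It emulates, in order:

1. **Ground-truth landscape** — expected titer is a quadratic response
   surface on the linlog scale (linear, quadratic and pairwise interaction
   terms) plus additive per-isozyme offsets, minus a burden penalty applied
   when TAL and CHS expression simultaneously exceed a linlog threshold.
   This mirrors the model family used for fitting and the joint
   overexpression burden observed in validation strains; it is a
   statistical stand-in, not a mechanistic claim. Titers are floored at 0
   and carry multiplicative lognormal noise (CV 10% by default).
2. **Biosensor** — a Hill transfer function `a + (M−a)·c^n/(K^n+c^n)`
   converts titer to normalized fluorescence; multiplicative Gaussian
   readout noise (CV 10% default) models plate-reader scatter. The
   packaged Hill parameters (a=120, M=1800, n=1.3, K=25 mg/L) are
   synthetic but place half-saturation inside the screened titer range so
   producers are resolved without saturating.
3. **Colony screen** — colonies are i.i.d. uniform draws from the library
   (a sequence-independent assembly does not favor parts); OD is drawn
   normally and the blank-corrected FL/OD ratio is recomputed from the raw
   signals.
4. **Range-covering selection** — the characterization subset is chosen at
   evenly spaced fluorescence **values** between the extremes (nearest
   unpicked colony per target, both extremes always included). Spacing on
   values rather than ranks is deliberate: poor-variant colonies pile up
   near basal fluorescence, a value-spaced pick visits that cluster only a
   few times, and the weak isozymes end up underrepresented in the subset —
   the behaviour a production-ranked selection shows in practice. A
   rank-quantile rule is available as `method="rank"`; it preserves pool
   composition instead.

Default numbers (190 colonies, 35 selected, titer span ≈1–25 mg/L,
strong TAL-variant effect FjTAL ≫ RgTAL, weak At4CL/PhCHS variants, burden
penalty 8 mg/L above linlog 0.75 on TAL and CHS jointly) were fixed once to
match the screen the workflow is designed around. What the generator does
**not** model: plasmid copy-number variation, σ-factor competition,
biosensor operational-range saturation artifacts, batch effects between
plates, or measurement error in the promoter TIFs themselves. Tests passing
on this generator therefore certify the statistical machinery, not the
biology of any particular screen.

The packaged promoter TIF values are a geometric series over 1–400 a.u.;
they are synthetic placeholders with a realistic dynamic range, and any
measured TIF table can be substituted through the YAML library format.

## Filtering and design matrix

Records with missing genotypes (failed sequencing) are dropped first.
Then any isozyme level observed fewer than `min_level_count = 4` times is
dropped together with the records carrying it: in an unbiased assembly,
near-absence from a production-ranked selection indicates poor performance,
and a level supported by 1–3 observations would only inflate model
variance. The default of 4 is a judgment threshold, not an algorithmic
necessity; an explicit drop list overrides it. Every removal is recorded
with its reason, and filtering is idempotent.

The design matrix contains: linlog promoter terms for all steps; a 0/1
dummy for each step retaining ≥ 2 isozyme levels (reference level = first
declared, coded 0); promoter squares; matching promoter-by-isozyme
products; and all pairwise promoter-by-promoter products. Cross-step
isozyme interactions and non-matching promoter-isozyme products are
excluded as biologically subordinate. With two-level TAL and CHI and
single-level 4CL and CHS this yields 18 regressors (4+2+4+2+6).

## Exploration statistics

Pearson correlations are computed pairwise over complete cases; the Holm
step-down adjustment controls the familywise error over the off-diagonal
pairs. One-way ANOVA per categorical feature uses the classic F test with
optional Tukey HSD post-hoc comparison; a sample with zero spread returns
F = 0, p = 1 rather than NaN. The outlier test is Grubbs' two-sided,
single-outlier form: G = max|x−mean|/sd against the t-based critical value
at level α/(2n); it is deliberately non-iterative (one labeled outlier is
the use case) and undefined for zero-variance samples.

## OLS with backward elimination

The titer is regressed on the design matrix plus intercept. Backward
elimination repeatedly removes the least significant removal-eligible term,
where eligibility respects marginality: a main effect cannot leave while
any surviving square or interaction contains its feature. Ties on p-value
remove the later column in construction order. The procedure stops when
every eligible term is significant at `p_ceiling = 0.15`, or when the next
removal would push model R² to or below `r2_floor = 0.9`; an initial model
already at or below the floor is returned unpruned with a warning. The
full removal trace (term, p at removal, R² and model p after) is recorded
so alternative stopping conventions can be audited.

Two caveats are inherent to this rule and documented rather than hidden:
the stop-at-significance criterion can retain a few noise terms whose
p-values are small by chance (their coefficients are negligible), and
p-values in a sequentially reduced model are post-selection quantities.
Leave-one-out refitting (explicit, per fold) supplies the honest
predictive R²; predictions over the space are reported raw — the
polynomial family permits negative values — with clipping available as a
view.

## PLS

Single-response PLS is implemented as classical NIPALS deflation: weights
from the predictor-response covariance, scores, loadings, rank-one
deflation of X and y. X and y are mean-centered; unit-variance scaling of
X is off by default (the conventional configuration for a design matrix
whose columns share the linlog scale) and available as a flag, since
published analyses are often ambiguous on this point. Coefficients are
back-transformed to the original predictor scale, and the whole
coefficient path (1..a components) is retained. At `a = rank(X)` the fit
coincides with OLS — the implementation's built-in limit check; scores are
mutually orthogonal by construction and verified in tests. If deflation
exhausts the response before the requested component count, extraction
stops and the coefficient path is padded (further components change
nothing); the fit records the effective count.

Component count is chosen by leave-one-out RMSEP with centering (and
scaling, if on) recomputed inside each fold to avoid leakage; component 0
is the fold-mean baseline, and ties at the minimum go to the smaller count.
Explained variance is reported cumulatively for X (Frobenius mass of the
rank-one reconstructions) and for y (R² of the a-component fitted values).

## Neural-network ensemble

A single small network — one hidden layer of two log-sigmoid neurons, a
linear output — trained on ~30 observations overfits differently with each
random initialization. The ensemble converts that into a consensus: many
networks are trained from independent seeded initializations, each
predicts every genotype, the top-k nominations per network are tallied,
and genotypes with nomination frequency strictly above 0.5·f_max form the
selection (an inclusive mode exists; with strict comparison the selection
is provably non-empty).

Inputs are the four linlog promoter values plus one 0/1 presence neuron
per retained isozyme level (eight inputs in the two-level TAL/CHI case).
Targets are standardized internally and back-transformed at prediction.

Training is Levenberg–Marquardt on the sum of squared residuals: solve
(JᵀJ + λI)δ = Jᵀe with the analytic Jacobian, accept the step if the SSE
drops (λ /= 10) and reject otherwise (λ ×= 10), starting at λ = 0.01 —
the damping parameter is the quantity that plays the role of a "learning
rate" in LM, and 0.01 is its conventional initial value. Stopping:
100 epochs, gradient ∞-norm below 1e-7, or λ overflow past 1e10. Weights
initialize uniform(−0.5, 0.5) from the seed; Nguyen–Widrow initialization
is available behind a flag. There is no validation split or early
stopping: overfitting control is the ensemble itself. Iteration-level
top-k ties break by enumeration order, making the whole procedure a pure
function of the master seed.

## Fermentation kinetics

OD600 converts to cell dry weight by a linear calibration factor
(default 0.29 g/L per OD unit — an instrument/strain calibration, not a
constant of nature). Over a user-chosen exponential-phase window, µ is the
least-squares slope of ln(CDW) versus time (invariant to CDW rescaling),
Y_PX = ΔP/ΔX between the window endpoints with linear interpolation at
non-sampled endpoints, and q_p = µ·Y_PX by construction. The window is an
explicit input because its choice is a judgment call; a maximal-log-linear-
R² heuristic (`suggest_window`) is provided but never applied implicitly.
ΔX uses endpoint differences rather than a regression estimate; with clean
exponential growth the two agree, and endpoints are the transparent choice.

## Pipeline and reproducibility

`run_pipeline` chains simulate/ingest → filter → explore → OLS → PLS →
ensemble → rank. One master seed fans out to per-stage seeds through a
`SeedSequence`, so a run is byte-reproducible and stages can be replayed
in isolation. The ranked space is the library reduced to the isozyme
levels that survived filtering. Artifacts (filtered dataset, design
matrix, correlation table, RMSEP curve, top-k tables, ensemble selection,
JSON + text report) are written when an output directory is configured.
The thin `pathwayopt` CLI exposes each stage as a subcommand over
intermediate files.

## Problem sizes and numerical choices

The test suite and the acceptance script run everything at the scale the
method is designed for (190-colony screens, 30–35-strain model sets, the
full 160,000-genotype ranking) except the ensemble, which uses a few
hundred iterations rather than the canonical 1000 — the consensus is
already stable there, and the 1000-iteration setting remains the library
default. Monte-Carlo checks (growth-rate recovery, Hill-constant recovery,
familywise-error simulation, ensemble-optimum recovery) use 100–2000
replicates with fixed seeds. Tolerances in tests follow the quantity's
conditioning: exact algebraic identities at 1e-8–1e-10, solver-dependent
recoveries at 1e-4, Monte-Carlo summaries at their sampling error.

## Known limitations

- The landscape/biosensor defaults are calibrated stand-ins; conclusions
  about any real screen require its own data and TIF table.
- Backward elimination inherits the known pathologies of stepwise
  selection (outlier sensitivity, post-selection inference); the PLS and
  ensemble models are the robust references, mirroring how the three
  models are meant to be compared.
- The Grubbs test handles a single outlier; iterated variants are out of
  scope.
- PLS is single-response; VIP scores and multi-response extensions are not
  implemented.
- LM training is exact Gauss–Newton-with-damping on a dense Jacobian —
  appropriate for tiny networks, not a general MLP trainer.
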