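# Methods

## Data model

A scan is represented by a 3-D field of log-Jacobian determinants on a
common grid: the *absolute* determinant measures total volume change
(global brain scaling included) relative to the consensus space, the
*relative* determinant only the local deformation. For one scan the two
differ by a spatial constant, the log global brain scale; all synthetic
generation happens on the log scale so this decomposition is exactly
additive. Structure volumes follow from an integer label atlas as
`Σ voxel_volume · exp(logdet)` over each label (label 0 = background,
excluded from brain volume); relative volume is `100 · V / V_brain`
(percent of brain). Images travel as NIfTI-1, tables as CSV, atlas names
as two-column TSV.

## Mixed-effects engine

All dimorphism tests are linear mixed models with a per-mouse random
intercept, fitted by maximum likelihood. ML (not REML) is required
because the tests compare models that differ in their *fixed* effects;
REML likelihoods for different fixed structures are not comparable.

Because mass-univariate mapping refits the same design for tens of
thousands of voxel responses, the engine profiles the likelihood in the
single variance ratio λ = σ²_mouse/σ²_resid: for fixed λ the GLS solve
reduces to group-sum corrections of the OLS normal equations, shared
across responses. λ is found on a deterministic log grid (51 points over
10⁻⁶–10⁴) followed by 35 fixed ternary-search refinements, with the
λ = 0 boundary always compared — so results are bit-reproducible and
independent of chunking or execution order. The scalar path agrees with
`statsmodels.MixedLM(reml=False)` to ~10⁻⁶ in coefficients and
log-likelihood (asserted in the suite). A two-component (random
intercept + slope) variant exists for the random-growth robustness
check; it is optimized per response and therefore reserved for
structure-level fits and small masks.

Likelihood-ratio tests use the Wilks χ²_Q reference, Q = difference in
fixed-effect counts. Negative statistics within 10⁻⁶ (optimizer noise)
are clamped to zero; larger negatives raise a convergence error.
*Finite-sample caveat*: at the study's design size (28 mice × 9
timepoints, 18- vs 9-parameter designs) the ML LRT carries the classical
Bartlett-type inflation ≈ N/(N−p) ≈ 1.08, so the Q = 9 structure test
runs a type-I error near 0.07 at nominal 0.05. This is a property of the
standard test itself, reproduced identically by independent ML fitters;
no correction is applied because the plain Wilks reference is the method
being implemented. The voxel-level Q = 2 test (4-parameter design) is
calibrated to within Monte-Carlo error.

### Satterthwaite contrasts

t-type inference on fixed-effect contrasts (dimorphism timing,
age-centered maps, RMSD improvement steps) uses the Satterthwaite
effective df, `df = 2·Var(c'β̂)² / Var̂[Var(c'β̂)]`, with the gradient of
`Var(c'β̂)` in θ = (σ²_mouse, σ²_resid) by central finite differences and
Var̂(θ̂) from the observed information of the θ-profiled criterion. The
variance components for this step are re-profiled under the *restricted*
(REML) criterion at the same design — the established practice for
mixed-model contrast inference — because the pure-ML information ignores
fixed-effect estimation and yields df ≈ m instead of the classical m − 2
for a between-group contrast in a balanced m-group design (the suite
asserts the m − 2 oracle, the σ²_mouse → 0 limit df → N − p, and the
monotone decrease of the grand-mean df with intraclass correlation).
Likelihood-ratio tests are unaffected. Boundary fits (σ²_mouse ≈ 0) fall
back to the residual df; singular information falls back with a warning.

### Multiple comparisons

Benjamini–Hochberg step-up q-values over the tested mask; NaN p-values
(non-converged voxels) are excluded from the correction and counted. For
age-centered map series, the q < 0.1 cut is taken from the model
centered at the oldest age and its p-threshold applied to all ages, so
maps are comparable across development.

## Voxel-wise models

Default growth is linear in age with a sex × age interaction (Q = 2
against the no-sex model). Variants mirror the robustness checks:
equally-spaced time coding (rank of age), quadratic growth (adds t² and
s·t², Q = 3), absolute-determinant response, and a per-mouse random age
slope. The age axis is rescaled by its maximum for conditioning; LRTs
and t-statistics are invariant to this. Determinant fields are not
smoothed before testing (no smoothing is assumed anywhere; a Gaussian
pre-smoothing hook exists, default off). The age-centered model
`y = α₁ + α₂s + α₃(t−t′) + α₄s(t−t′) + β₀ᵢ + ε` is a pure
reparameterization of the linear model — log-likelihoods agree to 10⁻⁶
and the sex coefficient equals α₂ + α₄t′ to 10⁻⁸ (asserted for every
cohort age).

## Effect-size trajectories and clusters

Cohen's d uses maximum-likelihood (divide-by-n) group variances, which
makes `(μ₁−μ₀)√((n₁+n₀−2)/(n₁σ₁²+n₀σ₀²))` exactly the classic pooled-SD
d; positive = larger in males, and flipping all sex labels negates the
matrix. Voxels entering the matrix are those with q < 0.1 in the
voxel-wise test. k-means (Euclidean, best of 20 restarts, seeded) is run
at k = 4 with a within-cluster sum-of-squares curve over k = 1..8 for
the elbow diagnostic; rows are not re-standardized (effect sizes already
share a dimensionless scale; a flag exists). Cluster summaries are
unweighted means over member voxels.

Growth rates: per voxel and subject, the determinant-vs-age series is
fitted with splines of order df ∈ 1..5 — df = 1 linear, 2 quadratic,
3 full cubic, 4–5 cubic B-splines with interior knots at age quantiles —
and the AIC-minimizing order retained (Gaussian ML variance; ties toward
smaller df; RSS floored at numerical precision so exact fits tie). The
basis is deliberately unconstrained at the boundaries so polynomial
growth up to cubic order is represented exactly and the derivative —
taken analytically from the B-spline — matches the analytic derivative
of noiseless polynomial data. Subjects with fewer than four scans are
skipped and counted.

## Expression enrichment

Preferential expression = fold-change, the arithmetic-mean expression in
an ROI over the whole brain (invariant to global rescaling of a map,
bounded by 1/ROI-fraction). The sex-chromosome bias test is a one-sample
one-sided KS of sex-chromosome fold-changes against the empirical CDF of
all genes (the sex-chromosome genes included in the background by
default; a flag excludes them), `D⁻ = sup(F_background − F_sample)`,
large when sex-chromosome genes sit high. The p-value is the exact
one-sided Smirnov tail at every n: the asymptotic `exp(−2nD⁻²)` is
conservative enough below n ≈ 10³ to distort null calibration, while the
exact tail is uniform under the null and agrees with the asymptotic form
to two decimals for n in the hundreds.

## Individualization

For target age t and accessed bound x < t, each structure is modelled by
least squares of the training subjects' volumes at t on their own
volumes at all timepoints ≤ x (intercept included, uniform weights;
row-weight and whole-brain-covariate hooks, and a random-forest
predictor, exist as robustness options). Training always excludes the
predicted subject and every row later than t; missing accessed scans are
linearly interpolated within subject on age (constant extrapolation at
the ends). No random term enters because each training subject
contributes one response row. Accuracy is RMSD over the J structures and
the scale-free RMSPD (identical to RMSD on brain-normalized inputs,
asserted to 10⁻¹⁰).

Specificity: the n × n matrix of RMSD between observed rows and
predicted columns; diagonal entries are tested one-sided against the
empirical CDF of the off-diagonal entries (exact Smirnov tail for
n < 50), and a centered variant (columns shifted so the diagonal is 0)
is emitted for display. The specificity probability is the fraction of
subjects whose self-RMSD is below the median of their column's
off-diagonal values.

Timing: RMSD vs accessed-timepoint factor × sex with a random mouse
intercept; one-sided consecutive-step improvement contrasts per sex
(Satterthwaite df; versus-baseline contrasts also available). The
individualization window runs from the first timepoint where either sex
improves at p < 0.05 to the first where both improve at p < 0.01 (if the
latter never occurs the window closes at the last accessed age). Each
subject's RMSD series is Z-scored over accessed ages; the statistic is
the female − male difference in mean windowed Z-RMSD, and its p-value
the fraction of sex-label permutations with a difference ≥ observed,
identity permutation included, so p ≥ 1/n_perm by construction and the
test is deterministic given the seed.

## Cortical thickness

The harmonic potential is solved on the ribbon by 6-neighbour red-black
successive over-relaxation (ω = 1.9), Dirichlet 0/1 on the inner/outer
boundary voxel sets, reflecting (zero-flux) treatment of out-of-domain
neighbours, convergence when the maximum update falls below 10⁻⁶
(default); free voxels with no 6-connected path to a boundary are
excluded with a warning. Streamlines start at ribbon voxels adjacent to
the outer boundary and are integrated both ways by RK4 on the normalized
gradient (trilinear interpolation, step 0.1 voxel, length cap 10× the
grid diagonal). Gradients come from a boundary-aware finite-difference
stencil: one-voxel differences are used only when both endpoints are in
the domain and at least one is free — plain central differences flatten
the gradient exactly at the Dirichlet nodes where streamlines end. A
march ends when its next sample would enter a boundary voxel; the
remaining distance to the exact φ = 0 / φ = 1 crossing is added
first-order as residual/|∇φ|, so thickness is measured
surface-to-surface. On phantoms this recovers a 10-voxel slab to <0.1%
and a (5, 8) spherical shell's thickness 3 to ~0.6% (median), and
halving the voxel size roughly halves the median error.

Phantom geometry: boundary voxel shells sit within half a voxel of the
geometric surfaces (so Dirichlet node centers average onto the surface),
and the ribbon is every voxel strictly between the surfaces; the shells
overlap the ribbon's edge voxels, and the solver treats
free = ribbon ∖ boundaries. One discretization consequence matters for
validation: a voxelized Dirichlet band screens at its nodes *facing the
free region*, so the discrete solution corresponds to the continuum
problem with boundaries at those screening surfaces (mean radius of
boundary voxels adjacent to the ribbon — computable from the labels
alone). Potential-accuracy checks therefore compare the
trilinear-sampled radial profile against the harmonic between the
screening radii; against the nominal radii the voxelization alone
contributes a 2–3% bias on a 3-voxel-thick shell.

## Synthetic cohorts: what they emulate, and what they do not

The generator reproduces the study design: nine postnatal timepoints
(days 3–65), 14 mice per sex by default (11–15 observed per timepoint in
the real design), per-mouse random intercepts, occasional missing scans
(default 5%, never a subject's first or last scan — a deliberate
deviation from fully random missingness so individualization curves are
computable for every subject), and a saturating (Gompertz) whole-brain
growth curve plateauing near 435 mm³, the adult volume implied by the
bundled canonical-structure table. Four archetypal sex-effect curves on
log relative volume are plantable in table structures or field ROIs:
early male-larger (saturating by ~day 10), late male-larger (sigmoid at
~day 25), a crossover changing sign once at day 20, and a late-emerging
female-larger effect (zero before day 17).

No per-structure variance components are published for this design, so
the defaults are stated assumptions, not estimates: σ_mouse = 0.015 and
σ_noise = 0.015 on the log-volume scale. They are calibrated to the
printed detection strength of the canonical structures — a χ²₉ of ~77
for a ~4.5% relative dimorphism at n ≈ 14/sex implies a between-mouse
relative-volume SD near 1.5% — and planted 5% effects then yield LRT
statistics in the reported 28–77 range. Passing tests on these cohorts
demonstrates the statistical machinery under the design's structure;
they do not capture registration error, spatial autocorrelation of
determinant noise, hemispheric symmetry, or age-dependent variance, so
recovery rates here are upper bounds on real-data performance.
Individualization cohorts switch on persistent per-(mouse, structure)
offsets (SD 0.10–0.15 log units) at a configurable onset age per sex;
equal onsets make the sexes exchangeable and serve as the permutation
null.

## Pipeline

`run_pipeline` executes simulate → structure tests → voxel maps →
clustering → enrichment → individualization → thickness → report, each
stage reading and writing declared files in the run directory (any stage
can be re-run in isolation), with the config and per-stage timings
serialized alongside. Identical config and seed reproduce byte-identical
tables. Default problem sizes (24³ grid, 14/sex, 1000 permutations) run
the full chain in well under a minute on one CPU; the acceptance script
uses 2000 null cohorts for LRT calibration, 5 voxel-map replicates, and
10⁴ permutations for the timing test.

## Known limitations

- Voxel-wise inference is mass-univariate with BH FDR; no spatial
  random-field or cluster-extent correction.
- The LRT's finite-sample inflation at Q = 9 (above) is inherited from
  the standard method; consumers needing exact small-sample calibration
  should permute.
- The individualization predictor is the plain per-structure least-squares
  formulation described above; weighted and mixed-effects variants of the
  predictor are plausible alternatives and only partially covered by the
  provided hooks.
- Real gene-expression-atlas ingestion is out of scope: the enrichment
  stage consumes any expression maps aligned to the analysis grid.
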