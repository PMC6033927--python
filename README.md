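# dimorphmap

Mixed-effects mapping of sexually dimorphic mouse brain development from
longitudinal deformation-based morphometry.

Longitudinal in vivo MRI of neonatal-to-adult mice (manganese-enhanced,
nine postnatal timepoints: days 3, 5, 7, 10, 17, 23, 29, 36, 65) yields,
after registration, a log-Jacobian determinant field per scan — the local
volume change mapping each brain to a common consensus space — plus
atlas-derived structure volumes. `dimorphmap` implements the statistical
machinery that turns those outputs into a developmental account of sex
differences, for researchers in rodent neuroimaging and developmental
neuroscience:

- **Structure-level dimorphism tests.** For a structure volume
  `y_ij` (mouse *i*, scan *j*), the full model
  `y_ij = α₁ + α₂ sᵢ + Σₖ α τₖ + Σₖ α sᵢτₖ + β₀ᵢ + ε_ij`
  (sex `s`, timepoint factor `τ`, random mouse intercept `β₀ᵢ`) is
  compared with the no-sex model by the likelihood-ratio statistic
  `D = −2 ln(L_p/L_f) ~ χ²_Q` (Wilks), `Q = 9` with nine timepoints.
  Satterthwaite-df contrasts date when each dimorphism emerges, and an
  F-test compares variances between the sexes.
- **Voxel-wise maps.** The same machinery per voxel on relative
  log-determinants, `y = α₁ + α₂s + α₃t + α₄st + β₀ᵢ + ε` vs the no-sex
  model (`Q = 2`), Benjamini–Hochberg q-values over the brain mask, and
  age-centered reparameterizations whose sex coefficient reads out the
  difference at any chosen age. The fits use a dedicated profiled-ML
  random-intercept solver vectorised across voxels (whole-grid maps in
  seconds on one CPU), cross-checked against `statsmodels.MixedLM`.
- **Trajectory clustering.** Per-voxel, per-timepoint effect sizes
  `d = (μ_M − μ_F)·√((n_M+n_F−2)/(n_M σ²_M + n_F σ²_F))` (positive =
  larger in males) form voxels × 9 trajectories, clustered with k-means
  (k = 4); AIC-selected spline fits per voxel and subject give analytic
  growth-rate curves.
- **Expression enrichment.** Fold-change (ROI mean over brain mean) of
  gene-expression maps in dimorphic regions, and a one-sided
  Kolmogorov–Smirnov test for sex-chromosome bias.
- **Neuroanatomy individualization.** Leave-one-out prediction of each
  subject's structure volumes at a target age from its own earlier scans
  (`RMSD = √(1/J Σ (ŷⱼ − yⱼ)²)`, scale-free `RMSPD`), a prediction
  specificity matrix with one-sided KS test, and a sex-label permutation
  test for which sex individualizes earlier.
- **Cortical thickness.** Laplace's equation solved over the cortical
  ribbon (inner surface φ=0, outer φ=1, successive over-relaxation);
  thickness = arc length of RK4 streamlines of ∇φ connecting the two
  surfaces.
- **Synthetic cohorts.** A first-class generator emulating the study
  design — balanced sexes, nine timepoints, per-mouse random intercepts,
  occasional missing scans, four archetypal dimorphism trajectories
  (early male-larger; late male-larger; male→female crossover;
  late-emerging female-larger), expression panels and thickness
  phantoms — so every stage is testable with known ground truth.

## Worked example

`examples/05_individualization.py` builds a cohort whose subject-specific
anatomy switches on at day 7 in males and day 17 in females, and asks
when leave-one-out prediction of day-36 anatomy starts to work:

```
specificity: D+ = 0.995, p = 2.7e-46, 100% of subjects matched their own prediction best

mean RMSD by accessed timepoint (males vs females):
sex            F       M
accessed
3.0       0.5858  0.5835
5.0       0.6045  0.6019
7.0       0.5824  0.2655
10.0      0.6250  0.2429
17.0      0.1493  0.1511
...

individualization window: p7-p17; mean Z-RMSD female-male = +0.93; permutation p = 0.0002
```

Male prediction error collapses once day-7 data are accessible, female
error only from day 17; the permutation test on the windowed Z-RMSD
difference recovers the planted 10-day male lead. The other examples
print structure-level χ² tests (`01`), voxel maps whose age-centered
t-statistics flip sign in the crossover ROI (`02`), the four k-means
centroid trajectories (`03`), sex-chromosome enrichment (`04`), and
phantom thickness accurate to <1% (`06`).

A thin CLI replays the whole chain into a run directory with a
provenance manifest:

```sh
dimorphmap replay --seed 1 --outdir run1
```

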