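# Methods

## Observation model

A compound's IR spectrum is modeled as a smooth absorbance function
ν_i(α) of wavenumber α (cm⁻¹), observed with noise at a finite,
compound-specific set of wavenumbers: ν_ij = ν_i(α_j) + ε_ij. The
response of interest is binary per functional group,
y_i = 1{compound i contains the group}, for each of amide, aniline,
benzene and piperidine. The four binary calls are combined into one of
nine mutually exclusive composition classes (four singletons, the four
observed pairs, none); predicted flag combinations outside those nine are
reported verbatim as `other_combo` rather than coerced to a nearest
class, since coercion would hide model behavior.

## Preprocessing

Stages run in the order rescale → interpolate → baseline-correct; the
order of the first two is not identifiable from first principles and is
documented as a package choice (both are cheap to swap via config).

- **Unit-SD rescaling** divides each curve by its sample standard
  deviation (ddof = 1). Zero-variance curves are rejected, and rejected
  compounds are dropped with a logged warning, never imputed.
- **Common grid**: linear interpolation onto 500–4000 cm⁻¹, step 4
  (p = 876). Grid points outside a spectrum's native range take the
  nearest endpoint value; constant extrapolation avoids inventing trends
  outside measured support. Linear interpolation reproduces affine
  curves exactly, which the tests exploit as an oracle.
- **Baseline correction** subtracts the straight line through the
  curve's global minimum (earliest index on ties, for determinism) and
  its right endpoint, zeroing both anchors. Because only visibly tilted
  spectra warrant correction, it triggers when |OLS slope| × grid span
  exceeds `baseline.trigger_ratio` (default 0.5) times the value range —
  a deterministic, unitless criterion. On curves whose peaks vanish at
  the anchors the operation is idempotent; broad peak tails at the right
  endpoint can re-trigger a second, tiny correction, which is why the
  idempotence test constrains itself to compact interior peaks.
- No smoothing of the data is performed at any stage.

## Penalized FPCA

The sample covariance σ(s,t) = (n−1)⁻¹ Σ_i [ν_i(s)−ν̄(s)][ν_i(t)−ν̄(t)]
is discretized on the grid and diagonalized under the trapezoid-rule
inner product (weights w). Roughness of eigenfunctions is penalized
through the integrated squared second derivative via the half-inverse
construction: with R = h·D₂ᵀD₂ (D₂ the central second-difference
operator) and S = (I + τR)^(−1/2), the symmetric eigenproblem is solved
for S W^(1/2) Σ W^(1/2) S, eigenvectors are mapped back through S and
W^(−1/2), and the result is re-orthonormalized by modified Gram–Schmidt
under the quadrature inner product. The re-orthonormalization is exact
bookkeeping: the half-inverse map leaves smoothed eigenvectors only
approximately W-orthonormal, and downstream score formulas assume an
orthonormal basis. At τ = 0 the whole construction reduces to plain
weighted-matrix PCA, which the tests verify against an independent dense
eigensolver.

Numerical conventions: eigenvalues are clamped at zero and sorted
descending; each eigenfunction's sign is fixed so its largest-magnitude
grid value is positive (stable across linear-algebra backends);
quadrature is the trapezoid rule, exact for the piecewise-linear curves
the interpolation stage produces.

Tunable parameters: `fpca.penalty` (default 10⁻² on the
rescaled-absorbance scale — mild smoothing that leaves broad spectral
features untouched; the reference software's exact setting is unknown,
so a reproducible fixed default was preferred over silent auto-tuning),
`fpca.k_max` (default 50), `fpca.variance_threshold` (default 0.80; K is
the smallest component count whose cumulative eigenvalue share reaches
it).

## Functional logistic regression

In the PC basis the functional linear predictor
l_i = β₀ + ∫ β(α)[ν̂_i(α) − ν̄(α)] dα collapses to
l_i = β₀ + Σ_{k≤K} β_k f_ik, an ordinary logistic regression on scores.
Fitting is Newton/IRLS with step-halving; convergence is declared when
the log-likelihood improves by less than 10⁻⁸ or the gradient max-norm
falls below 10⁻⁶, within 100 iterations. Perfect separation — plausible
for the small piperidine class — is detected (near-zero deviance with
runaway coefficients) and handled by refitting with a ridge of 10⁻⁴ on
the slopes (never the intercept) plus a warning; the flag is recorded on
the model. Classification uses a strict `p > threshold` comparison
(default 0.5), so a probability of exactly 0.5 is negative.

All four group models share one FPCA basis fitted on the full training
set; scores are computed once. The piperidine model's positives are
oversampled with replacement to a target of 100 before fitting (seeded,
originals retained, negatives untouched, output order shuffled by the
same seed); targets are configurable per group. The source corpus's
piperidine bookkeeping is internally inconsistent (10 positives out of
478 quoted in prose vs 26 of 506 implied by its class table), so the
operation is parameterized rather than hard-coded to either reading.

## Evaluation

Binary confusion matrices follow the prediction-versus-truth convention;
FPR = FP/(FP+TN), FNR = FN/(FN+TP); rates with empty denominators are
reported as undefined (None), not errors. ROC curves sweep every
distinct predicted probability (plus sentinels), so the trapezoid AUC
equals the Mann–Whitney concordance probability with ties counted ½ —
asserted exactly against a brute-force pairwise oracle in tests. The
joint nine-class confusion cross-tabulates derived labels, with
exact-match accuracy its diagonal share. The misclassification taxonomy
compares true and predicted group sets per compound: exact (equal),
partial (unequal but overlapping), missed (truth nonempty, prediction
empty), spurious (truth empty, prediction nonempty), disjoint (both
nonempty, no overlap). These definitions were reverse-engineered to
reproduce the reference study's published 12/4/3/7 error split and are
checked against it.

## Synthetic corpus generator

The generator emulates the features of the real corpus that the analysis
depends on: nine-class composition structure with heavily imbalanced
counts (506 training / 126 test by default; any total can be requested
via largest-remainder rescaling of the class proportions), irregular
native wavenumber sampling (spacing jittered in 1–6 cm⁻¹, ranges mostly
starting near 500 cm⁻¹ with a minority extending down toward 243 cm⁻¹),
occasional linear baseline slope, and additive Gaussian noise
(default SD 0.02 relative to the strongest band).

Each group contributes absorption bands at standard correlation-table
positions — amide C=O ≈ 1665 cm⁻¹ with amide-II ≈ 1550 and N–H ≈ 3300;
the aromatic set 690/750/1030/1500/1600/3030; the aniline N–H pair
3350/3450 added on top of the aromatic set, so aniline and benzene share
structure and their confusability in real spectra carries over
qualitatively; piperidine C–N ≈ 1120, strong CH₂ stretches 2850/2930 and
a ring band ≈ 860 — plus weak aliphatic backbone bands common to all
compounds. Band shapes are Gaussian by default (Lorentzian available);
centers and intensities are jittered per compound.

Beyond the group bands, every compound draws a Poisson number
(mean 20) of idiosyncratic skeletal fingerprint bands. Without them the
covariance of the corpus collapses onto the handful of group-template
directions, and the 80 %-variance rule then selects so few components
that rare-class contrasts are truncated away — unlike real corpora,
whose eigen-spectra decay slowly. Skeletal centers are drawn from
windows (1150–1420 and 1750–2750 cm⁻¹) that avoid the
group-characteristic regions, keeping the class contrasts linearly
separable in score space. This windowing is the generator's main
departure from realism: real fingerprint bands do overlap functional-
group regions, which is one reason real-data accuracy (ca. 87–96 % per
group) is far below the near-perfect synthetic results. Passing the
synthetic end-to-end checks therefore demonstrates the pipeline's
statistical correctness and internal consistency, not its real-world
error rates. Generated absorbance is clipped at zero (physical
nonnegativity) before preprocessing.

## Problem sizes and checks

The test suite and acceptance script run the full pipeline on 400
training and 200 test spectra in the reference class proportions, a size
at which the covariance eigen-decomposition (876 × 876) and four model
fits complete in seconds while every class keeps at least two test
compounds. Smaller 80-point grids serve the linear-algebra oracle tests.
The noise-free separability check (noise and band jitter zero) asserts
per-group accuracy ≥ 99.5 %, allowing at most one residual margin case
per group rather than demanding bit-exact perfection of an asymptotic
property.

## Known limitations

- The baseline-trigger criterion, penalty value and skeletal-band design
  are package choices where the source material is silent; all are
  config-exposed.
- JCAMP-DX support covers AFFN, SQZ, DIF and DUP forms with Y-check
  validation; PEAK TABLE blocks and exotic dialects are rejected.
- The multiclass (multinomial) extension of the GLM, AUC confidence
  intervals and probability calibration are out of scope.
- Solid-phase spectra, thermal broadening and instrument line shapes are
  not modeled by the generator.
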