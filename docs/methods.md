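# Methods

This note documents the statistical models the package implements, the
synthetic data it tests itself on, and the numerical and design choices
behind both.

## Network connectivity statistics

Each subject contributes a `T x N` matrix of ROI time courses; functional
connectivity `A_ij` is the Pearson correlation of columns `i` and `j`.
Given a partition of the `N` nodes into `K` named networks (the shipped
default is the ten-system, 227-node split with community sizes DMN 58,
SN 18, FPN 25, CON 14, SMN 35, VN 31, VAN 9, DAN 11, AN 13, SUB 13), the
matrix is condensed into `K` within-network and `K(K-1)/2` between-network
values:

    W_a   = ( sum_{i,j in a} A_ij ) / N_a^2
    PB_ab = ( sum_{i in a, j in b} A_ij ) / (N_a N_b),  a != b

`W_a` as written sums all ordered pairs including the unit diagonal and
counts each undirected link twice. The package's default
(`diagonal_policy="literal"`) computes exactly that; the conventional
alternative (`"exclude_diagonal"`, the mean of strictly off-diagonal
entries) is exposed because the two are related by an exact affine map,
`W_literal = ((N_a - 1) W_excl + 1) / N_a`, so downstream correlation
analyses are unaffected by the choice. Raw correlations are averaged by
default; Fisher's z transform before averaging is available with the
off-diagonal policy. Negative correlations are retained as-is; no
thresholding is applied.

## Correlation screen

Each of the 55 connectivity measures is tested against a behavioral score
by partial Pearson correlation: both variables are residualized by OLS on
an intercept plus covariates, the residuals correlated, and a two-sided
p-value taken from `t = r sqrt(df / (1 - r^2))` with `df = n - 2 - k`.
Two covariate presets are shipped: `basic` (age, sex) for the
stress-connectivity screen and `extended` (age, sex, current stress) for
behavior-behavior correlations and the prediction analysis.
Benjamini-Hochberg step-up correction (via statsmodels) is applied over
all measures tested in one screen invocation — the conservative joint
family; a per-family split is possible by invoking the screen on subsets.

## Prediction

An epsilon-insensitive linear SVR predicts the behavioral score from all
connectivity features under balanced k-fold cross-validation (default
`k = 4`, `C = 1`, `epsilon = 0.1`, no inner tuning loop). Balancing:
subjects are sorted by the outcome, cut into consecutive groups of `k`,
and each group is dealt round-robin into folds with seeded within-group
order, so every fold spans the outcome distribution. Feature
standardization and the optional covariate regression of the outcome are
fit on training folds only and applied to the held-out fold; a canary test
asserts that perturbing a held-out subject cannot move its fold-mates'
predictions. The statistic is the Pearson correlation between pooled
out-of-fold predictions and observed (residualized) outcomes, with
significance from a permutation test,
`p = (1 + #{r_perm >= r_obs}) / (1 + n_perm)`.

Hyperparameters are fixed rather than tuned to mirror a fixed-model
design; only the outcome is residualized on covariates (feature
residualization is available behind a flag). `k = 4` is the default fold
count, with `k` configurable.

## Mediation

The single-mediator model fits three OLS equations sharing one covariate
set (default age and sex); X, M, Y are z-scored first so the paths `a`,
`b`, `c`, `c'` are standardized, and `c = c' + a b` holds exactly. The
indirect effect `a b` is tested by case resampling (default 2,000
resamples): the bias-corrected interval shifts the percentile positions by
`z0 = Phi^{-1}(fraction of bootstrap estimates below the point estimate)`,
reading quantiles at `Phi(2 z0 +/- z_{1-alpha/2})`; ties at the point
estimate count half, an explicit convention needed for discrete data. The
acceleration-corrected (BCa) variant is not implemented. Variables are
standardized once on the full sample and rows then resampled, so the
decomposition identity holds within every resample. Degenerate resamples
(constant X or M) are redrawn and counted. An interval excluding zero is
reported as a significant indirect effect. If the whole bootstrap mass
falls on one side of the point estimate, the proportion is clamped and the
result flagged pathological rather than erroring.

The two headline models share X = early-life stress and Y = depression:
model 1 uses the VAN within-network connectivity as mediator, model 2 the
sad-face attention bias. Current stress is not in the default mediation
covariate set; the extended preset can be passed explicitly.

## Dot-probe scoring

Per emotion condition, with R/L the probe side and `e` the emotional-face
side, the bias score is `1/2 [(RpLe - RpRe) + (LpRe - LpLe)]` over
per-cell mean RTs (median optional), which equals mean incongruent minus
mean congruent RT; positive values indicate attention toward the emotional
face. A score is emitted only when all four cells are nonempty; otherwise
the row is flagged with the empty cells named. Default trial hygiene —
correct responses only, RT in [200, 1500] ms, no SD clip — is a
conventional choice of this package and every threshold is configurable.
The four conditions are neutral-happy (NH), neutral-sad (NS),
neutral-anger (NA) and neutral-fear (NF), with per-block counts
40/37/37/37 over two blocks (302 trials per subject).

## Synthetic cohort generator

The generator exists so every stage can be tested against planted truth.

*Time series.* Each subject's node covariance is compound-symmetric per
network block: unit variances, correlation `w_a` within network `a`,
`b_ab` between networks. Writing `F` for the `K x K` matrix with `w_a` on
the diagonal and `b_ab` off it, the covariance is
`blockdiag((1 - w_a) I) + E F E^T`, positive definite iff `w_a < 1` and
`F` is PSD — checked at spec construction (eigenvalue tolerance 1e-10).
Sampling uses the factor form (node noise plus `K` shared network
factors), so realized correlations converge to the targets at the
Fisher-z rate `~1/sqrt(T-3)`. Defaults: `T = 230` time points (an
8-minute scan at TR = 2 s minus discarded initial volumes), within target
0.30, between target 0.10 — typical resting-state magnitudes.

*Inter-subject variance and planted effects.* Per-subject targets are
drawn around the spec targets (perturbation SD 0.05), truncated to a valid
range and, if a perturbed `F` loses PSD-ness, shrunk deterministically
toward the validated base targets. The latent deviation of selected
measures is tilted by the subject's standardized stress score X: the focal
mediator measure (default `within:VAN`) at loading `a`, plus a halo of
secondary measures (DAN/SN/SMN within, VAN-DAN/VAN-SMN/VAN-VN between) at
`0.6 a`, emulating a correlated effect pattern across attention-related
systems. Defaults plant `(a, b, c') = (0.35, 0.30, 0.20)`.

*Behavior.* Y is generated as `c' X + b M_z + Normal(0, noise_sd)` where
`M_z` is the standardized realized mediator (connectivity computed from
the simulated time series, or a directly drawn behavioral mediator).
Scores are mapped onto the instruments' mean/SD scales (stress 37.35 +/-
8.34; depression 7.05 +/- 6.45; current stress 46.70 +/- 20.88) without
truncation at nominal instrument bounds — truncation would attenuate the
planted paths and break exact recovery; real questionnaire data are
bounded and discrete, which this generator does not emulate. Age
(truncated normal 19.42 +/- 1.40 on [16, 26]) and sex (Bernoulli 157/528)
are cosmetic covariates; current stress loads on X at 0.20 by default.

*Dot probe.* Trials draw face and probe sides uniformly; incongruent
trials add the per-emotion shift to a 500 ms base RT with 60 ms Gaussian
noise (no RT distribution is claimed beyond this; an ex-Gaussian shape is
not modeled); negative RTs are resampled; errors are flagged at rate 0.03.

*What passing tests do not show.* The generator has no autocorrelated
hemodynamics, no motion or physiological artifacts, no site effects, and
Gaussian (not skewed, bounded, discrete) behavioral scores. Passing
recovery tests demonstrates the estimators are correct and calibrated
under the assumed model, not that real acquisitions meet those
assumptions.

## Reproducibility and problem sizes

All randomness flows from explicit seeds: the pipeline's master seed
spawns per-stage sub-seeds via `numpy.random.SeedSequence`, and the
generator keys per-subject streams on (seed, stage, subject), so any stage
or subject can be regenerated in isolation. The test suite exercises the
chain at desk scale: oracle equivalence on 20-node matrices, FDR control
over 500 null screens (n = 200, 55 measures), mediation CI coverage over a
3x3 effect grid (n = 500, 300 replicates, 1,000 resamples), and 50
end-to-end replicates of the default 300-subject cohort. The bootstrap is
vectorized with batched normal-equation solves, which is what makes the
coverage grid and the 2,000-resample default cheap.

## Known limitations

- Compound-symmetric blocks cannot represent within-network community
  substructure (e.g. a hand subnetwork of the sensorimotor system).
- BC (not BCa) bootstrap; product-of-paths intervals are conservative at
  the complete null, so empirical coverage there exceeds the nominal
  level — expected behaviour, not a defect.
- The SVR uses a liblinear-style solver; with strongly collinear features
  the fitted coefficients (not the CV statistic) can depend on iteration
  limits.
- Dot-probe scoring assumes the documented CSV dialect; raw E-prime
  exports must be converted by the user.
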