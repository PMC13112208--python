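# Methods

`facedcm` implements a desk-scale causal analysis of hemispheric
lateralization in the core face-perception network: a six-region bilinear
dynamic causal model (DCM) with a balloon-model observation equation,
subject-level inversion by variational Laplace, a group-level parametric
empirical Bayes (PEB) hierarchy with laterality covariates, Bayesian model
reduction (BMR) over a factorial hypothesis space plus an automatic greedy
search, and a bootstrap lateralization-index (LI) estimator. Because no
human data ship with the package, a synthetic-cohort generator with planted
group effects provides the study conditions for every test.

## Generative model

### Neural dynamics

Six regions — left/right early visual cortex (EVC), occipital face area
(OFA) and fusiform face area (FFA) — follow the bilinear state equation

    dz/dt = (A~ + sum_j u_j B~_j) z + C u ,

with two box-car inputs: *visual* (any stimulus block) and *faces* (face
blocks only). The baseline graph (A) contains bidirectional OFA–FFA
connections within each hemisphere, homotopic interhemispheric OFA–OFA and
FFA–FFA connections, and feedforward projections from each EVC to its
ipsilateral OFA and FFA. Visual input drives both EVCs through C and
modulates all six self-connections; face input modulates the sixteen
remaining connections (the four OFA/FFA self-connections, four homotopic
interhemispheric, four EVC feedforward, four intra-hemispheric OFA–FFA),
giving 22 modulatory parameters. Self-connections are parameterized as
`-0.5 * exp(x)` Hz — a log-scaling `x` of the default -0.5 Hz
self-inhibition, so they stay negative for any finite `x`; when an input
modulates a self-connection the log-scalings add inside the exponential,
preserving the sign constraint.

### Hemodynamics

Each region's neural state drives the standard balloon–Windkessel cascade
(vasodilatory signal, blood flow, venous volume, deoxyhemoglobin) with
conventional constants: signal decay κ = 0.64 s⁻¹, autoregulation
γ = 0.32 s⁻¹, mean transit time τ₀ = 2 s, stiffness α = 0.32, resting
oxygen extraction E₀ = 0.4. BOLD is the classic static observation
equation with 3 T coefficients (TE = 25 ms, ϑ₀ = 40.3 s⁻¹, r₀ = 25 s⁻¹,
intravascular/extravascular ratio 1), in percent-signal units (V₀ = 4).
Per-region transit time and neurovascular efficacy are free parameters
(log-scalings); the remaining constants are fixed.

### Integration

Inputs are piecewise constant at microtime resolution (TR/16), so the
neural update over one bin is computed exactly with an augmented matrix
exponential per distinct input pattern (at most three patterns per run).
Hemodynamics use classical RK4 with one step per bin, whose begin / mid /
end stage inputs are the exact neural states at half-bin resolution (the
half-bin propagator is the same augmented exponential), so no input
interpolation error enters; BOLD is sampled at the end of every scan.
Halving the step changes predictions by < 1e-6 RMS. The integrator
is written twice — a vectorized NumPy reference and a numba-compiled
kernel — and the two are asserted equal to 1e-10 in the test suite; the
compiled kernel evaluates batches of parameter vectors, which is what the
finite-difference Jacobian consumes.

## Subject-level inversion

Variational Laplace maximizes the negative free energy F over a Gaussian
posterior. Priors are zero-mean with variances 1/64 on A off-diagonals,
1/256 on self log-scalings, 1 on B and C entries, and 1/256 on the
hemodynamic log-scalings; structurally absent entries have prior variance
exactly zero and never move. Observation noise is i.i.d. Gaussian per
region with one log-precision hyperparameter per region (log-normal
hyperprior, mean 0, variance 32) updated by Newton steps between
Gauss–Newton parameter updates. Gradients come from central finite
differences (step 1e-4) evaluated in one batched forward call.
Gauss–Newton steps are Levenberg-regularized; a candidate step is first
screened with the current Jacobian (one forward run) and then accepted
only if the fully re-evaluated F (fresh Jacobian) increases, so the
accepted-step F trace is non-decreasing by construction. Convergence is
declared after four consecutive accepted steps with ΔF < 0.01 nats
(maximum 128 iterations; failure to find any improving step at maximal
damping also terminates). On linear-Gaussian problems the scheme
reproduces the conjugate closed form (posterior and evidence) to
machine-level accuracy, which the acceptance suite asserts at 1e-6.

Model accuracy is summarized as explained variance,
`100 * (1 - RSS/TSS)` of the posterior-mean prediction; subjects below
10 % are excluded from group analysis (none are, under the default
conditions).

## Group level: PEB, BMR, model comparison

The hierarchy is θᵢ = X βᵢ + εᵢ over the 22 modulatory parameters. X has
six regressors: an all-ones commonality column and five mean-centered
covariates (LI_FFA, LI_OFA, handedness, age, gender). Each subject's
inversion enters through its posterior/prior density ratio, kept in
natural (precision) form `exp(-0.5 θ'Hθ + θ'b)` with H = Pq − P0 clipped
to positive semi-definite — directions in which the data added no
precision contribute exactly nothing. Between-subject deviations are
Gaussian with covariance `(1/16) exp(-γ) I`; conditional on the scalar
log-precision γ the β posterior (132 cells = 6 × 22, prior variance 1/16
per cell) is an exact conjugate Gaussian, and γ is optimized on the group
free energy with a N(0, 1) hyperprior — an empirical-Bayes scheme that is
deterministic and needs no sampling.

Reduced models switch β cells off by setting their prior variance to zero;
their evidence and posteriors follow analytically from the full-model
posterior by Gaussian BMR, with the delta-prior case handled by
conditioning (switched-off cells have posterior mean and variance exactly
zero). BMR is validated against direct re-inversion on linear-Gaussian
instances at 1e-6.

The factorial space crosses hemisphere (LEFT/RIGHT/BOTH) × region
(OFA/FFA/BOTH) × connection type (INPUT = EVC feedforward, SELF, BASE =
intra- plus interhemispheric OFA/FFA, ALL), 36 models plus a null model
with no face modulations; visual self-modulations are always on. A face
parameter belongs to a model iff the *target* region and hemisphere of its
connection match the model's levels — this target convention is an
inference from the printed descriptions of the single-cell left-OFA-self
model and the FFA-BASE model, and the membership table is emitted in
reports so it can be audited. Enumeration is lexicographic over (type,
region, hemisphere) with the full model first and the null model last.

The comparison assigns one of the 37 masks independently to each of the
three covariates of interest (commonality, LI_FFA, LI_OFA) — nuisance
rows are never reduced — and scores all 37³ = 50,653 combinations by BMR
(about one minute on one CPU). Joint posterior probabilities are the
softmax of the log evidences; covariate-wise marginals sum the joint over
the other covariates' assignments; factor families pool marginal Pp over
their member models (the null model forms the NONE family). Bayesian model
averaging moment-matches the Gaussian mixture of reduced posteriors over
the models carrying essentially all the posterior mass (cumulative weight
1 − 1e-9, capped at 4096 components); per-cell Pp(nonzero) is the summed
probability of the models in which the cell is free. Cells are flagged at
Pp(nonzero) strictly above 0.75.

The automatic search greedily prunes the 132 cells: each iteration scores
every single-cell removal, takes the (up to) eight most dispensable
candidates whose removal does not reduce the evidence, exhaustively scores
their 2⁸ = 256 on/off combinations, and jumps to the best; at convergence
the BMA is computed over the 256 models of the final iteration (the
candidate list is padded with the most recently pruned cells when fewer
than eight remain undecided).

## Lateralization index

LI = (A_L − A_R)/(A_L + A_R) ∈ [−1, 1], positive = left-dominant, with
activity A measured as the sum of suprathreshold t-values in the ROI (the
sum-of-t choice is recorded in the result metadata). The bootstrap draws
100 resamples of size ⌈0.25 N⌉ per hemisphere (with replacement), forms
all 10,000 pairwise LIs of the resampled masses, and keeps the mean of the
central 50 %. This repeats over 20 regularly spaced thresholds from just
above zero to the smaller of the two ROI maxima (a threshold where either
side is empty is skipped), and the overall LI weights each threshold's
trimmed mean by the threshold itself. Dominance is classified by the
conventional ±0.2 rule, boundaries bilateral. Each hemisphere's resampling
stream is seeded from its value multiset rather than its argument slot, so
swapping the left/right inputs negates every LI exactly — an invariant the
suite asserts to machine precision. Conjunction maps are the voxelwise
minimum of two t-maps; subject-specific ROI centers are the local maximum
nearest the group peak among those inside the anatomical box with t ≥ 3.1
and at least the group-peak value, falling back to the group peak itself.

## Synthetic cohort: the study conditions

The generator plants a commonality effect on every face modulation
(+0.5 on the four self-modulations, +0.1 on the twelve between-region
modulations), an LI_FFA effect of −2.0 on the left-OFA face
self-modulation, and opposite-signed LI_OFA effects of −1.0 / +1.0 on the
two interhemispheric FFA connections; handedness, age and gender have no
true effect. Baseline connectivity is A = 0.2 (EVC feedforward), 0.1
(intra-hemispheric), 0.05 (interhemispheric), C = 1.2, visual
self-modulation 0.15 — values within one to two prior standard deviations
of the subject-level priors, so the planted truth is plausible under the
model that will be inverted. Between-subject SDs are 0.1 (between-region
parameters) and 0.05 (self log-scalings); hemodynamics are shared.
Covariates emulate a mostly left-lateralized, mostly right-handed young
cohort; LI_FFA and LI_OFA are drawn independently (their empirical
correlation is near zero). Observation noise is i.i.d. Gaussian with
SD 1.0 in percent-signal units (signal SD ≈ 1.5–2.3), giving explained
variances of roughly 50–85 % — comfortably above the 10 % gate — with no
AR(1) term (the simplest noise model sufficient for recovery testing;
serial correlation is an extension). The stimulus design follows the
blocked paradigm: 14.5 s stimulus blocks of faces/houses/scrambled images
separated by 14.5 s baselines, nine blocks per category, TR 1.45 s,
≈ 13 min — with the condition order pseudo-randomized per three-block
cycle, a convention, since the original order is not published. Sampled
parameter sets whose neural dynamics are unstable under any input
condition (largest real eigenvalue above −0.01) are redrawn; at the
default operating point this affects well under 1 % of draws, so the
population model is in effect truncated to the stable regime.

A statistic-map generator provides the laterality module's inputs: two
mirrored ROIs of 150 voxels whose *count* of active voxels is split so the
bootstrap's rounded resample sizes reproduce a target LI, with active
t-values concentrated near a common scale so the count ratio — and hence
the LI — is approximately threshold-invariant. The calibration was done
against the package's own estimator (targets ±0.6 are recovered within
±0.1 in ≈ 99 % of seeds).

## What the synthetic conditions do and do not show

Passing recovery tests demonstrates that the estimation machinery —
inversion, PEB, BMR, family pooling, search, LI bootstrap — identifies
effects that exist under the model's own assumptions at realistic noise.
They do not establish robustness to real fMRI departures: serial
correlation, motion and physiological confounds, hemodynamic variability
across subjects, ROI misplacement, or model misspecification of the
network graph.

Two scale choices matter when interpreting the group-level tests. First,
the ten-seed recovery studies (n = 50) run the full PEB → 37³ comparison →
family pooling → search pipeline, but on subject-level posteriors emulated
by the generator (posterior mean = truth + noise of SD 0.15, isotropic
covariance) rather than on 50 variational-Laplace inversions per seed,
whose cost is out of scale for a routine test run; full inversion feeds
the group level in the end-to-end pipeline test at n = 8. Second, at a
single subject with this long-block design, face modulations of a region's
input gain and of its self-connection act near-identically on the
steady-state response, so individual inversions cannot attribute the
face effect between SELF and INPUT type — the planted LI_FFA effect is
detected end-to-end (its hemisphere family and its non-nullness) while
its type attribution requires the better-conditioned posteriors that the
emulated route (or a richer design) provides. This degeneracy is a
property of block designs, not of the estimators.

## Numerical choices

- Microtime TR/16; exact neural propagators per input pattern; RK4
  hemodynamics; step-halving convergence < 1e-6 RMS.
- Finite-difference step 1e-4 on the natural parameter scale.
- VL damping: Levenberg factor ×10 on rejection, ×1/2 on acceptance,
  bounds 1e-8–1e8; noise log-precisions clamped to ±32.
- BMR uses Cholesky factorizations throughout; a non-positive-definite
  reduced precision raises a degeneracy error rather than returning NaNs.
- γ optimization: bounded scalar search on [−8, 8], tolerance 1e-4.
- All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning; fixed seeds reproduce cohorts,
  bootstraps and reports bit for bit. Subject inversions contain no
  internal randomness and may run in parallel with identical results.

## Known limitations

- Deterministic, single-state, bilinear DCM only; no stochastic or
  two-state variants, no nonlinear (D-matrix) terms.
- No confound regressors or serial-correlation model at the subject level.
- The target-region/target-hemisphere membership convention of the
  factorial space is an inference (see above) and deliberately not
  configurable.
- Group-level between-subject covariance is isotropic over the 22
  modulatory parameters with a single log-precision hyperparameter.
- The LI estimator's threshold grid endpoints (0, smaller ROI maximum)
  are declared conventions; alternative activity measures (voxel counts,
  β-weighted) are not implemented.
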