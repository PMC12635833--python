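# Methods

## Model

Each subject's parcellated brain (N = 200 cortical nodes grouped into the
seven canonical resting-state networks) is treated as a linear
input-state-output system `x' = A x + B u`. The adjacency `A` is symmetric
with zero diagonal and comes from one of five scenarios: the structural
connectome (SC, nonnegative streamline-type weights), the full-series
Pearson correlation of regional BOLD (sFC), the same with negative
correlations zeroed (sFC_noneg), and windowed Pearson correlations forming
a piecewise-constant adjacency sequence (dFC, dFC_noneg). `B` is a binary
selector placing one input channel on every node of the chosen network, so
each network yields one feature per quantity.

Windows for dynamic FC are consecutive and non-overlapping:
`w = round(window_seconds / TR)` samples each, `M = floor(T / w)` windows,
trailing samples dropped. A partition (rather than overlapping windows)
is required for the piecewise-constant energy composition, and equal-width
windows keep the per-window Gramians comparable. An optional stride
parameter exists for exploratory window sequences.

Initial/final states are columns of the BOLD matrix: the initial index
uniform over the first quartile of time points, the final index over the
last quartile, preserving the chronological plausibility of the
transition. Indices are 0-based internally; file outputs are 1-based only
where noted in the writers.

## Stabilizing normalizations

* Continuous time (energy): `L = diag(rowsum A) − A`, then
  `A ← −L / λ_max(L)` with `λ_max` the maximum absolute eigenvalue. For
  nonnegative adjacency this maps the spectrum into [−1, 0]; the zero
  eigenvalue (Laplacian null space) always remains, so the system is
  marginally, never strictly, stable. For signed FC matrices the signed
  Laplacian can be indefinite and the normalized matrix may retain
  positive eigenvalues; `certify()` reports the margin and the pipeline
  proceeds with finite-horizon Gramians, which remain well defined.
* Discrete time (controllability): `A ← A / (1 + λ_max(A))` with the
  maximum *absolute* eigenvalue in the denominator, giving spectral radius
  `r/(1+r) < 1` for every symmetric input — including FC matrices whose
  most negative eigenvalue dominates, where the plain largest eigenvalue
  would not guarantee stability. A config switch
  (`use_absolute=False`) exposes the plain-largest variant for comparison.

## Gramians and energies

The controllability Gramian restricted to `B` is obtained from the
Lyapunov equation `A W + W Aᵀ + B Bᵀ = 0` when every eigenvalue lies below
−1e−8, and from the finite-horizon integral
`W(τ) = ∫₀^τ e^{At} B Bᵀ e^{Aᵀt} dt` otherwise. Because the Laplacian
normalization always leaves a zero eigenvalue, the pipeline's energies in
practice use the finite-horizon form; the Lyapunov route applies to
strictly stable systems supplied directly (and anchors the cross-checks).

For symmetric `A` the finite-horizon integral has an exact spectral form:
with `A = V diag(λ) Vᵀ`, the integrand is diagonalized and each eigenpair
contributes `(e^{(λ_j+λ_k)τ} − 1)/(λ_j+λ_k)` (→ τ as the denominator
vanishes). This closed form is the default evaluation route; a composite
Simpson quadrature with step halving until successive refinements agree to
1e−8 relative Frobenius norm is retained as an independent numerical
cross-check (`method="simpson"`), and the two agree to better than 1e−6 in
the tests.

Energies are `E = ½ dᵀ W⁺ d`. `W⁻¹` is never formed: with network-level
`B` and finite horizons, `W` at N = 200 is numerically rank deficient, so
a Moore–Penrose pseudo-inverse with relative eigenvalue cutoff 1e−8
(configurable) is used, the effective rank is logged on every result, and
a transition whose projection residual onto the numerically controllable
subspace exceeds 1e−6 is flagged; the reported energy then refers to the
projected component.

For the dynamic energy the horizon is split evenly across the M windows
(`τ_m = τ/M`; the split is configurable since no canonical choice exists),
the mismatch is `d = xf − Φ_M···Φ_1 x0` with `Φ_m = e^{A_m τ_m}`, and the
composed Gramian is `W_dyn = Σ_m P_m W_m P_mᵀ` with
`P_m = Φ_M···Φ_{m+1}` and `W_m` the window-m finite-horizon Gramian over
`[0, τ_m]` — equivalently `S · blockdiag(W_1..W_M) · Sᵀ` for the block-row
`S` of suffix propagators, which the implementation exposes for
validation. With all windows equal the construction reduces exactly to the
static energy; with the zero matrix and full control it reduces to
`E = ½‖xf−x0‖²/τ`. Correctness is additionally checked against an
Euler-discretized least-squares minimum-norm control oracle and by
simulating the reconstructed optimal input
`u*(t) = Bᵀ e^{Aᵀ(τ−t)} W⁺ d` through the state equation.

Log-energies use the natural logarithm (the base is a single constant;
ratios of log-energies depend on it only through a common factor). The
dynamic-efficiency feature is `log E_static / log E_dynamic` for the
pairings (sFC, dFC), (sFC_noneg, dFC_noneg) and (SC, dFC). The default
control-time grid is 10–390 in steps of 20; the headline set used for the
summary tables is {30, 50, 100, 200} with window sizes 30/50/100 s and a
headline window of 50 s.

## Controllability features

From the Schur-normalized system, `AC_i = Σ_j v_ij²/(1−λ_j²)` (equal to
`[(I−A²)⁻¹]_ii`, hence ≥ 1) and `MC_i = Σ_j (1−λ_j²) v_ij²` (in (0, 1]).
Network values are arithmetic means over the network's nodes — chosen to
match the convention of reporting mean network values — and for windowed
adjacency each window is normalized and decomposed separately with the
per-window network means averaged across windows (mean by default, median
available; the across-window reduction is not canonical and is therefore
configurable).

## Graph covariates

Network strength is the mean over the network's nodes of the summed
absolute edge weights to all other nodes; density is the fraction of
suprathreshold (|A_ij| > eps, default eps = 0) within-network edges. Both
are deliberately minimal — they serve as covariates, where only
within-run consistency matters — and both parameters are exposed. They are
computed per scenario (windowed scenarios: per-window values averaged);
note that correlation matrices are fully dense, so at eps = 0 the density
covariate is constant for FC scenarios and is automatically dropped from
the covariate-adjusted regression of such cells.

## Synthetic cohort generator

The generator emulates the *statistical structure the analysis assumes*,
not raw fMRI physics:

* **BOLD**: zero-mean vector AR(1) fluctuations whose innovation
  covariance is matched so the stationary correlation equals a target
  block matrix — within-network level 0.45, between-network level 0.20,
  per-subject block perturbations (sd 0.03), and an additive group shift
  (default −0.06) on the affected network's within-block level (default
  DMN, affected group "HL"). Block targets are repaired to the nearest
  correlation matrix by eigenvalue clipping and diagonal rescaling. The
  temporal nonstationarity that sliding-window FC is designed to capture
  is emulated by three latent connectivity states per subject (block
  levels re-perturbed with sd 0.05) visited by a Markov chain with ~40 s
  mean dwell; a single state recovers a stationary AR(1). The lag-1
  coefficient is 0.4 (hemodynamic smoothness at TR = 2 s) and the series
  is scaled by an arbitrary amplitude of 20 units, emulating
  nuisance-regressed regional residuals (correlations are amplitude
  invariant; log-energies shift by a common constant). The correlation
  levels correspond to a pipeline in which the global signal is retained,
  keeping FC predominantly positive — this matters because strongly
  negative windowed FC makes the signed-Laplacian-normalized windows
  markedly non-stable and the composed dynamic Gramian ill conditioned.
* **SC**: `exp(−d/0.35)` on latent 3-D coordinates in the unit cube,
  scaled to a 0–100 weight range with symmetric log-normal edge noise —
  heavy-tailed, distance-ruled weighted networks without tractography.
* **Metadata**: age uniform per group (NH 48–72, HL 52–76), sex Bernoulli
  with group-specific male fractions (0.33 / 0.69), per-ear PTA and SRT
  normal with group-specific means (NH ≈ 15/12 dB, HL ≈ 50/39 dB, clipped
  at 0) — magnitudes chosen so the rank structure used by the Spearman
  analyses is realistic. Default cohort size is 15 + 15.

What the generator does **not** emulate: voxelwise signals, head motion,
physiological noise, hemodynamic response shape, spatial autocorrelation
within networks beyond the block structure, and the empirical coupling
between a subject's SC and FC (the two are generated independently).
Passing tests therefore demonstrate the correctness and stability of the
feature extraction and statistics on data with the assumed block/state
structure — not performance on real fMRI.

## Experiments and statistics

* **Intra-individual**: for a few subjects, energies for every scenario ×
  control time × window across 20 random state pairs; the CoV
  (100·sd/|mean|, sample sd with n−1) of the log-energy per cell,
  averaged over subjects. On the default subject the static-scenario CoV
  stays below 5% and all five scenarios stay in the low single digits.
* **Inter-individual**: one shared state-pair index for all subjects;
  log-energies at the headline control times, the three efficiency
  ratios, AC/MC, strength and density per scenario and network; then
  per-group CoV, OLS group effects (feature ~ const + age + sex + group,
  sex and group as single indicators, no interactions; optionally adding
  strength/density), ROC-AUC in the Mann–Whitney formulation with ties at
  ½ (both orientations reported, since either direction of a shift is a
  usable discriminator), Spearman correlations against the four per-ear
  clinical scores, and pooled-variance two-sample t tests
  (dof = n_a + n_b − 2). Benjamini–Hochberg FDR is applied across the
  networks within each (feature, scenario, τ, window) family — the
  multiple-comparison family is the set of networks, with other groupings
  available; descriptive significance is q < 0.05.

## Numerical choices

Symmetric eigenroutines everywhere; invariant checks at 1e−10; Gramian
pseudo-inverse cutoff 1e−8 (relative); Lyapunov-route eigenvalue guard
1e−8; Simpson refinement target 1e−8; optimal-control verification via
`solve_ivp` at rtol 1e−10. Matrix exponentials of symmetric matrices are
evaluated through the eigendecomposition. Degenerate inputs (all-zero
graphs, constant time courses, zero-mean CoV denominators, single-class
ROC, constant Spearman inputs, zero pooled variance) raise typed errors
rather than returning NaN.

## Problem sizes

The test suite exercises the full 200-node scale where the claim depends
on it (normalization bounds over 100 random 200-node matrices, the
default-subject and default-cohort CoV analyses) and 4–50-node systems
where an independent oracle must be computed (quadrature, discretized
least-squares control, resolvent identities). Replicated statistical
checks (null type-I control over 200 cohorts; effect-localization over 20
cohorts) use a 28-node, seven-network scheme so that one suite run stays
fast.

## Known limitations

* On the default synthetic cohort the windowed (dFC) mean log-energy at
  short control times comes out slightly *above* the static-FC value,
  whereas on real connectome data the dynamic scenario is reported as
  cheaper. In this formalism that advantage traces to propagator
  amplification from non-stable signed-Laplacian windows; generator
  settings that reproduce it also make the composed Gramian collapse at
  long horizons, inflating the CoV of the log-energy far beyond the
  observed range. The default generator prioritizes the variability
  regime (well-conditioned windows); the corresponding directional test
  in the suite documents the discrepancy rather than hiding it. Real
  BOLD appears to occupy a regime that block-correlation structure alone
  does not reach.
* Energies depend on the pseudo-inverse cutoff through the effective
  rank; cross-study comparisons should fix `rcond` and report it (the
  result objects carry it).
* The per-window horizon split `τ_m = τ/M` is a convention; alternative
  splits change `E_d` and are accepted via the `taus` argument.
* Efficiency ratios are unstable when the dynamic log-energy approaches
  zero; the implementation raises on exact zero but values near zero
  propagate.
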