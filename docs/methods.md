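# Methods

## The problem

Metric time-series analysis has a standard first diagnostic: plot the
autocorrelation function (ACF) and the partial autocorrelation function
(PACF).  For a purely autoregressive process of order p the PACF cuts off
after lag p, so the model order can be read off a stem plot.  No comparable
convention exists for *symbolic* sequences — ion-channel open/close records,
spin states, EEG microstate label strings — whose values carry no metric
structure, making covariances meaningless.

This package implements the information-theoretic analogue.  For a
stationary process X_n over a finite alphabet of L symbols:

* **Autoinformation (AIF)** — lagged mutual information
  `alpha_k = I(X_{n+k}; X_n) = H(X_{n+k}) + H(X_n) − H(X_{n+k}, X_n)`,
  the analogue of the ACF.  Cost is independent of the lag (only 1- and
  2-symbol distributions are involved).
* **Partial autoinformation (PAIF)** — conditional mutual information
  `pi_k = I(X_{n+k}; X_n | X_{n+k−1}, …, X_{n+1})`,
  the analogue of the PACF.  With the conventions `pi_0 = alpha_0 = H_1`
  and `pi_1 = alpha_1`, the stationary identities

      pi_k = h_{k−1} − h_k = a_k − a_{k−1} = −(H_{k+1} − 2 H_k + H_{k−1})

  connect the PAIF to the finite-history entropy rate
  `h_k = H(X_{n+1} | X_n^{(k)})` and the active information storage
  `a_k = I(X_{n+1}; X_n^{(k)})`, which themselves satisfy the conservation
  `H_1 = a_k + h_k`.  For a stationary Markov chain of order M,
  `h_k = h_M` for all k ≥ M, hence **pi_k = 0 for every k > M**: the PAIF
  cuts off at the Markov order, exactly as the PACF cuts off at the AR
  order.  The cost grows like `L**(k+1)` (the joint histories must be
  tabulated), which is the method's intrinsic limitation at large lags.

All entropies are plug-in (maximum-likelihood) estimates in bits.  No bias
correction is applied: the finite-sample inflation of joint-entropy
estimates is part of the phenomenology the diagnostics must cope with (see
"Undersampling" below).

## Estimation modes

Plug-in estimates of different orders can be combined in two ways, selected
by `mode=` everywhere it matters:

* **pooled** (default) — every `H_k` comes from its own pass over all
  `N − k + 1` contiguous windows; derived quantities combine entropies whose
  window sets differ by a few boundary windows.  Identities then hold only
  up to O(k/N) discrepancies (measured ~1e−6 relative at N = 1e6) and
  `pi_k` can be marginally negative; such values are reported as-is, never
  clipped in tables.
* **consistent** — every quantity at history length k is a marginal of the
  single empirical (k+1)-window distribution.  The conservation and
  difference identities become exact floating-point identities and
  `h_k, a_k, pi_k >= 0` by construction (they are genuine conditional
  entropies / mutual informations of one joint distribution).

The pooled mode is the default because it reflects the common practice of
estimating each entropy from all available windows; the consistent mode is
the numerically clean reference used by the oracle tests (PAIF versus
direct conditional-MI summation).

In pooled mode the conservation defect `H_1 − a_k − h_k` is not identically
zero because `a_k` is computed as the mutual information of the aligned
(k+1)-window distribution (each of its three entropies from that window
set) while `h_k` is the difference of two independently pooled joint
entropies.  This reproduces the tiny boundary-effect violation expected of
independently windowed estimates (~1e−6 relative at N = 1e6, bounded by
7.25e−4 in the acceptance check).

Histories are encoded as base-L integers with the most recent symbol in the
lowest digit whenever `L**k` fits 64 bits (then counted with `bincount`);
otherwise counting falls back to tuple keys.  Both paths count the same
windows, so results are identical by construction.

## Surrogate confidence bands

Significance of AIF/PAIF coefficients is judged against an iid null built
from the data itself: each surrogate is a seeded random permutation of the
observed symbols (marginal distribution preserved exactly, temporal order
destroyed).  Per lag, the band is the empirical [alpha/2, 1 − alpha/2]
percentile interval across `n_surrogates` (default 100) surrogate
statistics; percentile bands make no distributional assumption.  Defaults:
alpha = 0.05; maximum lag 50 for the AIF and 8 for the PAIF (the PAIF's
`L**(k+1)` tables undersample quickly; see below).

Both band edges are reported, but the `significant` mask for AIF/PAIF is
**one-sided** (value > upper edge).  Plug-in MI/CMI estimates are
non-negative, and their null bias grows with the occupied support; a
structured process occupies *fewer* k-tuples than its permutation
surrogates (forbidden words), so its null-lag coefficients sit slightly
below the iid band.  Falling below the band is a support effect, not
evidence of dependence; only exceedance of the upper edge is.  Signed
profiles (ACF/PACF) use the two-sided rule with the classical
±z_{1−alpha/2}/√N band.

When reading band-based masks across many lags or replicates, remember each
lag is a ~2.5% one-sided trial: the test-suite's multi-lag assertions allow
the expected false-positive count rather than demanding zero exceedances.

## Markov-order tests

**Likelihood-ratio (G) tests.**  The order-m test (m = 0, 1, 2) compares
Markov order m against order m+1 on (m+2)-tuple counts,
`G = 2 Σ n_w ln(n_w · n_mid / (n_left · n_right))`, asymptotically
chi-square with `L**m (L−1)²` degrees of freedom (standard asymptotic dof;
zero cells contribute zero by the `n ln n → 0` convention).  Structural
zeros (forbidden words) are left in place; the test is invariant under
relabelling of the alphabet.

**Conditional-entropy surrogate test.**  For each candidate order
M = 0..M_max (default 5): estimate the order-M transition table by maximum
likelihood, generate `n_surrogates` (default 100) order-M Markov surrogates
*of the data's own length* (equal length keeps the plug-in bias of data and
surrogates comparable), and form the per-(M, k) percentile band of the
surrogate entropy rates h_k for k = 1..k_max.  The identified order is the
smallest M whose bands contain every data h_k; if none qualifies the report
carries the sentinel "none <= M_max".  `k_max` defaults to `M_max + 1`, the
smallest range that can discriminate all candidate orders while limiting
the `L**(k+1)` blow-up.  The conjunction over k is the test's own
multiple-comparison rule; no further correction is applied.  Markov
surrogates are initialized with a draw from the empirical M-history
distribution and extended by inverse-CDF sampling; if an unobserved history
is ever reached (possible when the data end in a unique context) the
current history is redrawn from the history distribution and the event is
logged.

## The shipped test processes

These generators define the package's validation conditions; their defaults
are the study conditions, not tuning knobs.

* **Two-state Markov chain** (rates p, q): closed forms
  `H = psi(p_A)`, `h = p_A psi(p) + p_B psi(q)`, `a = H − h` with
  `psi(x) = −x log2 x − (1−x) log2 (1−x)` and stationary distribution
  `(p_A, p_B) = (q, p)/(p+q)`; used as exact anchors for the estimators.
* **Random order-3 chain** (L = 2): every next-symbol distribution an
  independent normalized-uniform simplex draw; PAIF must cut off after
  lag 3.
* **Lag-skipping order-3 chain** (L = 3): the transition depends only on
  the symbol three steps back, so the chain splits into three interleaved
  first-order chains — AIF with period 3, PAIF with a single peak at
  lag 3.  The three conditionals are rejection-sampled to a minimum
  pairwise total-variation distance of 0.2 so the dependence cannot be
  statistically invisible.
* **Even process** (2 hidden states): 1s emitted only in even-length
  blocks; no finite Markov order — the PAIF stays above the band at every
  tested lag and the conditional-entropy test accepts no order <= 5.
  Sampling starts in the block-boundary state A (a stationary hidden start
  could begin mid-pair and emit a lone leading 1, breaking the parity
  invariant); only a sample's final run can be truncated to odd length.
* **Golden-mean process, 2-state presentation**: no two consecutive 1s;
  emitted process exactly first-order Markov with transition matrix
  [[1/2, 1/2], [1, 0]].
* **Golden-mean process, 7-state presentation**: a constructed edge list
  (shipped as `data/golden_mean_7state_synthetic.txt`, swap the file to use
  another presentation).  The emission probability of a 1 depends on the
  number of trailing zeros t, capped at four: q = (0.3, 0.7, 0.2, 0.6) for
  t = 1, 2, 3, >=4.  This makes the observable process golden-mean-supported
  and *exactly* fourth-order Markov (histories (1,0,0,0) and (0,0,0,0)
  carry different laws; longer histories add nothing).  The q values are
  chosen so each depth-j conditional is well separated from the stationary
  mixture of the deeper ones — otherwise a PAIF coefficient inside lag 4
  can cancel accidentally.  The hidden graph pads the minimal 5-state
  trailing-zero machine with duplicated "just emitted a 1" and
  "one trailing zero" states to a strongly connected 7-state presentation.
  HMM samplers otherwise start from the stationary hidden distribution
  (no transient).

* **2D Ising lattice site**: raster-scan Gibbs (heat-bath) sweeps with
  periodic boundaries, one recorded value per sweep after a burn-in
  (default 1e4 sweeps), J = k_B = 1, default lattice 50×50, critical
  temperature 2/ln(1+√2) ≈ 2.269.  Far above T_c the site series
  decorrelates within a few sweeps; at T_c the AIF decays as a power law
  and the PAIF stays significant over many lags (long-range memory).  The
  qualitative tests run a 32×32 lattice for 1e5 sweeps, which preserves
  both signatures at a fraction of the cost.  For validation, tiny
  (<= 20-site) lattices can record whole-configuration codes, compared in
  the tests against the exactly enumerated Boltzmann distribution.
* **Double-well "ion channel"**: Euler iteration
  `X_{n+1} = X_n + (a X_n − b X_n³) dt + xi_n` with per-step Gaussian noise
  of scale `noise_sigma`, dt = 1e−3, minima at ±√(a/b); thresholding at 0
  maps to closed/open symbols (exact zeros → closed, for determinism; no
  subsampling).  Defaults a = b = 1, noise_sigma = 0.025: the induced
  stationary measure has effective temperature sigma²/(2 dt) ≈ 0.31 against
  a barrier a²/(4b) = 0.25, giving a clearly bimodal density with modes at
  ±1 and well switches every ~1e4 steps.  (Much larger noise scales destroy
  bistability outright: already at sigma ≈ 0.1 the effective temperature
  exceeds the barrier twentyfold.)

  A caveat the tests make explicit: a thresholded diffusion is not exactly
  first-order Markov at the integration-step scale.  Crossing the threshold
  takes many small steps, and those recrossings leave a real residual
  pi_2 ~ 5e−3 bit — two orders of magnitude below pi_1 ≈ 0.96 bit, hence
  invisible on any PAIF plot, but resolvable by a surrogate test at
  N >= 3e4.  The first-order verdict is therefore asserted on the magnitude
  scale (pi_k < 2% of pi_1 for k > 1), which is what a visual cutoff
  reading measures.  This trade-off (per-step noise must be small for
  bistability, large for single-step crossings) is intrinsic to the model.

* **AR(p) simulation** uses `scipy.signal.lfilter` on Gaussian innovations,
  discarding a 10·p-sample transient; the reference model is
  `X_n = 0.85 X_{n−1} − 0.2 X_{n−2} + 0.1 X_{n−3} + eps_n`.  ACF/PACF come
  from statsmodels (biased autocovariance; PACF via Durbin–Levinson,
  cross-checked in the tests against an independent Toeplitz
  precision-matrix partial-correlation oracle to 1e−6).

## Undersampling

Joint histories grow like `L**k`: for L = 4 and k = 50 the table would have
more than 1e30 cells.  A warning is logged whenever `L**k` exceeds one
tenth of the available windows — beyond that point plug-in PAIF
coefficients *rise* with lag purely from estimation bias (visible in
4-symbol sequences of ~1.5e5 samples beyond k ≈ 8, which motivates the
PAIF default max lag of 8).  The CLI summary repeats the warning per lag;
lags whose state space exceeds a configurable hard cap raise an error
instead of silently thrashing.

## What the synthetic generators do and do not emulate

Every validation runs on sequences from the package's own generators with
known ground truth (exact Markov orders, closed-form entropies, enumerable
Boltzmann weights and word probabilities).  They cover finite-order Markov
structure, hidden-state non-Markov memory, critical long-range correlations
and threshold-induced symbolization — but they are all stationary, with
known alphabets and no artefacts such as missing samples, nonstationary
drift, or label noise.  Passing tests therefore demonstrate estimator and
test correctness under stationarity, not robustness to the nonstationary
structure of real recordings (e.g. full EEG sessions); for such data the
stationarity of the label sequence must be argued or tested separately.

## Problem sizes used by the test-suite and acceptance script

Reference analyses use 1e6-symbol samples (golden-mean machines, even
process, order-3 chains), matching the scale at which the published
reference values were obtained.  Seed-robustness checks (order specificity,
two-state convergence, double-well verdicts) use 20 replicates at 2e5–5e5
samples with 40–60 surrogates — sizes chosen so each check completes in
seconds while keeping its statistical power; the Ising contrast uses a
32×32 lattice for 1e5 sweeps.  All randomness flows from explicit seeds;
`scripts/acceptance.py` derives every generator seed from the single
`--seed` argument via `numpy.random.SeedSequence`.

## Known limitations

* Plug-in estimation only; the optional bias-correction literature
  (Miller–Madow and beyond) is deliberately not wired into the defaults.
* The PAIF is undefined beyond lags where `L**(k+1)` approaches the sample
  size; the implementation warns and caps rather than extrapolating.
* The conditional-entropy test inherits the alpha = 0.05 conjunction rule:
  with 6 history lengths per order it over-rejects the true order in
  roughly 5–15% of runs, typically returning the next order up.
* AIF/PAIF carry no directional information (mutual information is
  symmetric); transfer-entropy-style measures are out of scope.
* Continuous-alphabet estimators (binning, k-nearest-neighbour) are out of
  scope; metric series enter only through the AR/ACF/PACF companion module
  and explicit thresholding.
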