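# Methods

## The rate-domain model

The package treats the reciprocal of reaction time, r = 1/RT (s⁻¹), as the
primary random variable. The working model is that r is Normal(μ, σ²)
left-truncated at a = 1/60 s⁻¹ (the rate implied by the 60-s trial
time-out), so RT is reciprocal-truncated-Normal. The principal alternative
is a first-passage account: RT inverse Gaussian — parameterized here by its
mean μ (s) and variance σ² (s²), shape λ = μ³/σ² — or, for two-alternative
choice, the two-boundary drift-diffusion first-passage densities. The
discriminating statistic is the shape of the *rate* distribution: truncated
Normal rates standardize onto the Normal probit line over the 5–95% band;
reciprocal-IG rates remain positively skewed and bend off it.

## Preprocessing

Recorded RTs are integer milliseconds. Reciprocating quantized values clumps
the upper rate histogram, so each RT receives an independent U(−0.5, +0.5) ms
dither before the reciprocal transform; this is statistically invisible in
the time domain but removes the rate-histogram gaps. RTs below 0.15 s (rate
above 6.67 s⁻¹) are treated as anticipations and masked *after* dithering
(the dither can move a 150-ms RT across the bound; the rule is strict
"< 0.15 s"). Timed-out trials enter the rate series at the bound value
(left-censoring semantics) and stay flagged: they are retained for moments,
and set to NaN for AR fitting so that lag adjacency is preserved while the
affected regression rows drop out. Counts always reconcile:
n_input = n_used + n_anticipatory, with time-outs tracked separately.

Per-block truncated-Normal ML fits use Nelder–Mead simplex over (μ, log σ)
(positivity by construction), initialized at the sample moments, tolerance
1e−8, at most 10⁴ evaluations; the survival normalizer is evaluated through
`log_ndtr` so deep truncation stays finite. A negative fitted mean is
permitted — it simply puts most of the underlying Normal below the bound.
Blocks are classed by the ML coefficient of variation σ̂/μ̂ with threshold
0.4; the boundary value and negative means go to the "truncated" side.
z-scores use each block's ML moments; the truncated group keeps only z > 0
because truncation under-represents the negative half. Probit plotting
positions are (i − 3/8)/(n + 1/4), the conventional Normal-QQ choice.

## Sequential dependency

The temporal model is a stationary AR(m): r_n = Σ a_j r_{n−j} + u_n with
u_n i.i.d. Normal(μ_u, σ_u²). PACF uses Yule–Walker/Durbin–Levinson on
biased (1/n) autocovariances (statsmodels), per block with the first 10
trials dropped, averaged across blocks. AR estimation defaults to
conditional Gaussian ML: pooled least squares on per-block lagged
regressions with no cross-block lag pairs. Each block is centered before
pooling — blocks from different conditions have different stationary means,
and a single pooled intercept would let between-block mean variance
masquerade as autocorrelation (this inflates every weight by ~0.05–0.1 if
omitted). The input mean is recovered as r̄·(1 − Σâ) per block. An exact-
likelihood option (statsmodels ARIMA per block, weights averaged) is
available; at ~190 trials per block the two agree to well under one standard
error.

AR→MA conversion takes poles from the characteristic polynomial and
residues from the partial-fraction expansion of B(z) (`scipy.signal.residuez`),
b_i = Σ_k ρ_k λ_k^i with b_0 = 1; complex-conjugate pole pairs must cancel to
< 1e−10 imaginary residue, repeated roots fall back to the direct recursion
b_i = Σ_j a_j b_{i−j} (which is exact in all cases and serves as the test
oracle). The weight sequence truncates at the first |b_i| < 1e−10, capped at
10⁴ terms. Mean gain Σb_i = 1/(1 − Σa_j); SD gain √(Σb_i²), cross-checked
against the Yule–Walker identity σ_r²/σ_u² = 1/(1 − Σ a_j ρ_j).

The stationary rate density is the convolution of scaled input-density
copies (1/|b_i|)p_u(x/b_i). It is evaluated on a uniform grid (≥ 2¹² points
spanning ±8 output SDs) with *trapezoid-rule* discrete convolution. The
trapezoid end-correction makes the convolution of two positive-support
densities exactly zero at the origin — the analytic smoothing-of-truncation
result falls out of the quadrature rather than being special-cased. Terms
with |b_i| below 1e−6 of the grid's resolving power contribute only a mean
shift b_i·E[u] and are applied as such. Normalization off by more than 1e−3
raises a resolution error.

Spatial history uses the 4-lag repeat/alternate binary code (repeat → 0,
alternate → 1, earliest transition most significant; the last symbol is the
current trial), giving codes 0–15. Note a 4-bit code cannot reach 16; the
all-alternate history AAAA is 1111 = 15. Per-code means use per-subject
centering (within-subject SEs) and a one-way repeated-measures F across the
16 codes with subjects as the blocking factor — df = (15, 15·(n_subj − 1));
codes with empty cells are reported missing and excluded from the F.

## Synthetic experiment

The generator emulates the study design end to end: 24 subjects × 4 blocks ×
200 trials, one block per condition, condition orders cycling through the 24
distinct permutations of {AE, AD, UE, UD} (a balanced design). Per block the
latent rate follows the AR(3) above with weights (0.222, 0.104, 0.076) and
zero pre-history, so each block opens with the characteristic transient that
dies within ~10 trials. The observation is the latent rate censored from
below at 1/60 s⁻¹ (recorded at the 60-s time-out and flagged); the AR
recursion itself runs on the latent value. RT = 1/r is rounded to integer
milliseconds. Sides are Bernoulli(0.5); in the easy conditions the trial's
rate receives an additive offset keyed by its 4-lag repeat/alternate code
(default −0.12 s⁻¹ at codes 1, 9, 14 — the slow histories; the offset does
not feed back into the recursion). Errors are Bernoulli at the condition's
error rate and share the rate process (no separate error-RT model).

Default condition parameters (input-rate mean, SD in s⁻¹; error rate):
AE (2.0, 0.3, 1%), UE (2.2, 0.3, 1%), AD (0.35, 0.3, 24%), UD (0.5, 0.3,
24%). With the mean gain 1.67 these give steady-state rates ≈ 3.3/3.7 s⁻¹
(RT ≈ 300/270 ms) for the easy conditions and ≈ 0.59/0.84 s⁻¹ for the
difficult ones, i.e. a mixture of clearly untruncated blocks (CV ≈ 0.09)
and heavily truncated ones (AD: CV ≈ 0.54, ~3% time-outs). σ_u = 0.3 s⁻¹ is
the scale of the theoretical illustrations; error rates follow the 1%/24%
design targets. Everything derives from one seed and is byte-reproducible.

Parametric surrogates ("clones") replace each block's RTs with draws at that
block's fitted moments and identical n — reciprocal truncated Normal at the
ML fit, or inverse Gaussian at the block's RT sample mean/variance —
preserving all design columns. When surrogate pools are analyzed, the
truncation-class labels of the *base* experiment are reused: the surrogate
replays the same blocks, so group membership is a property of the block, not
of the draw.

What the generator does not emulate: luminance psychophysics, foreperiod
effects, fatigue/drift within a session, any separate error-RT mechanism,
and inter-block rest structure. Passing tests therefore certify the
*analysis chain* — that the pipeline recovers known distributional shape,
AR structure, and injected history effects at realistic scale — not that
real data must behave this way.

## Optimal timing

Expected gain G(t) = (U⁺+U⁻)p(t) − U⁻ with the default exponential accuracy
function p(t) = 1/2 + (1 − e^(−ε̂t))/2 (p(0) = 1/n alternatives, here 1/2).
The break-even time solves p(t_min) = 1/(U⁺/U⁻ + 1) by bracketed Brent
iteration; the optimum of G(t)/(t + T_ND) solves
(t + T_ND)G′(t) = G(t) on (t_min, ∞), bracket grown geometrically until sign
change, and is verified as a maximum against t*·(1 ± 0.01). Derivatives are
analytic for the exponential form, central differences (h = 1e−6·max(t, 1))
for user-supplied p. Power-law fits regress log₁₀ t* on log₁₀ ε̂ over a
default grid of 50 log-spaced points on [0.01, 1] (a config knob, reported
with every fit): k = 1 exactly at T_ND = 0; for T_ND > 0 the fitted k lies
strictly in (0, 1). k is *not* monotone in T_ND at the default grid
(≈ 0.894, 0.822, 0.837 at T_ND = 10, 100, 1000): when ε̂·T_ND ≪ 1 on part of
the grid the exact k = 1 law reasserts itself, so small non-decision times
pull the fitted exponent back toward 1.

## Numerical notes and limitations

* The two-boundary first-passage sine series is summed past its envelope
  peak k* = w/(πs√t) before truncation at relative 1e−10 (cap 10⁴ terms);
  below t = 1e−6 the density is returned as 0. The small-t regime converges
  slowly; the Monte-Carlo oracle in the tests uses Brownian-bridge crossing
  detection, since a plain Euler walk is biased long by O(√dt).
* Truncated-Normal sampling uses `scipy.stats.truncnorm`; IG sampling uses
  `scipy.stats.invgauss` with shape μ_s = σ²/μ², scale λ = μ³/σ².
* PACF estimates at block length ~200 carry the usual small-sample downward
  bias (~0.02 at lag 1); block-averaged values are compared against ±3 SE
  bands, exact Yule–Walker values only against long series.
* Problem sizes in the test-suite simulations (e.g. 10⁵ Monte-Carlo walks,
  100 ML-recovery replicates at n = 10⁴, one full-scale 19 200-trial
  experiment shared across tests) were chosen to keep each check's sampling
  error an order of magnitude below the tolerance it asserts.
* The extended DDM with across-trial drift/start-point variability, ML
  fitting of the DDM, spectral/1/f analysis, and the hyperbolic-weighted
  spatial scheme are out of scope.
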