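# Methods

## The tuning model

AMMC-B1 responses to pulse songs are summarized per individual as ten
normalized peak ΔF/F values, one per tested IPI x ∈ {15, 25, …, 105} ms,
normalized to sum to 1.  The model is

    y(x) = a·exp(−x/τ_b) − c·exp(−x/τ_d),

motivated by the circuit's architecture: a slow excitatory drive (intercept
a, time constant τ_b, ~84 ms) minus a fast feed-forward inhibition
(intercept c, time constant τ_d, ~4 ms).  With τ_b > τ_d and
c·τ_b > a·τ_d the function has a unique interior maximum at

    x* = [τ_b·τ_d/(τ_b − τ_d)]·ln(c·τ_b/(a·τ_d)),

the *peak IPI*.  All IPIs and time constants are in milliseconds; a and c
are unitless on the normalized-response scale.

### Hierarchical Bayesian estimation

For one species with individuals i = 1..N:

    log θ_ik ~ Normal(μ_k, σ_k),  k ∈ {a, τ_b, c, τ_d}
    y_ij     ~ Normal(y(θ_i, x_j), σ_obs)

with weakly-informative hyperpriors μ_k ~ Normal(0, 5) on the log scale,
σ_k ~ HalfNormal(1) and σ_obs ~ HalfNormal(0.05).  The log-scale hierarchy
guarantees positivity; the sum-to-one coupling of the normalized data is
deliberately not modelled (the data are treated as a function of IPI, not
as a composition — its only visible effect is a common ≲0.3% rescaling of
a and c by the tuning-function sum over the ten IPIs).

The sampler is a blocked Metropolis-within-Gibbs scheme, vectorized across
chains (default 4 chains × 1500 warmup + 1500 draws, seeded and exactly
reproducible):

1. per-individual 4-dim random-walk Metropolis on log θ_i, proposal
   covariance = Gauss–Newton approximation of the *conditional* posterior
   (J'J/σ_obs² + diag(1/σ_k²))⁻¹, refreshed twice during warmup;
2. a shared-shift Metropolis move translating all individuals and μ by one
   draw from the pooled Gauss–Newton covariance;
3. a slice sampler along the curved ridge direction (below);
4. exact conjugate Gibbs draws of each μ_k;
5. centered log-scale Metropolis on each σ_k, plus interweaved
   *non-centered* moves (a joint rescale Metropolis and per-scale slice
   moves for σ_c and σ_τd) that cross the funnel between a scale and its
   individuals' spread;
6. log-scale Metropolis on σ_obs.

Proposal scales adapt only during warmup (Robbins–Monro); the post-warmup
kernel is fixed.  Scale parameters carry a numerical floor of 1e-6 so that
exact (noise-free) inputs do not drive them to zero.  Diagnostics are
rank-normalized split R̂ and bulk ESS over all hyperparameters and
individual parameters (ArviZ); a fit with max R̂ ≥ 1.01 is *flagged*, never
silently returned as passing.  The sampler has no divergence concept (it is
not Hamiltonian); acceptance rates are reported instead.

### Identifiability: the (c, τ_d) ridge

With τ_d ≈ 4 ms, the inhibition term c·e^(−x/τ_d) contributes ≈ 0.04 at
x = 15 ms, ≈ 0.003 at 25 ms, and essentially nothing beyond.  The data
therefore constrain (c, τ_d) almost solely through the product
c·e^(−15/τ_d): the likelihood has a long curved ridge along which c and
τ_d trade off.  At observation noise sd 0.005 with 12 individuals the
pooled Fisher information bounds the posterior at sd(log c) ≈ 0.7 and
sd(log τ_d) ≈ 0.18 — c cannot be recovered to 10% from this design no
matter the sampler.  The peak IPI, by contrast, is well identified
(≈ 0.5 ms along the ridge), because the compensating movements of c and
τ_d nearly cancel in x*.  Consequences:

* fits at realistic noise are usually *flagged* (R̂ ≈ 1.05–1.4 on the ridge
  coordinates) — an honest reflection of a posterior that is wide and
  slowly mixing along a near-unidentified direction;
* the species-average c (back-transformed with the log-normal mean
  correction exp(μ + σ²/2), so that the Average row is the mean of the
  between-individual distribution and the tabulated Average peak equals the
  closed-form peak of the Average parameters) is heavy-tailed upward;
* posterior-mean peak summaries are slightly conservative (biased low by
  ~2–5% at noise 0.005; the bias vanishes at noise ≤ 0.001) because the
  posterior is asymmetric around the peak along the ridge.

Point summaries are medians across chains of within-chain means, which
keeps a single non-mixed chain from dominating a flagged fit.  Chain
initialization anchors at a box-constrained least-squares fit of the
cohort-mean curve (bounds a ∈ [1e-3, 10], τ_b ∈ [10, 500] ms,
c ∈ [1e-3, 50], τ_d ∈ [0.8, 20] ms — generous physiological ranges that
only bind when the unconstrained optimum diverges along the ridge);
individual least-squares solutions are clipped to a log-scale window
around the anchor.

The deterministic per-individual fit (`fit_individual`) minimizes the sum
of squared residuals over log-parameters (scipy trust-region reflective),
multi-started from the caller's initialization and a canonical band-pass
start, returning the lower-cost solution that satisfies the band-pass
constraints; on noiseless data it recovers parameters to ≈ 1e-4 relative
and is robust to starts across [0.01, 1] × the parameter magnitudes.

## Trace processing

Frames are timestamped at frame start; windows are half-open [start, end)
seconds from trace start.  The chain: (1) centered 3-frame moving average
with shrunken windows at the edges (no invented padding); (2) ordinary
least-squares line through the frames in two quiet windows — [0,1) ∪ [4,5) s
for pulse songs, [0,2) ∪ [13,15) s for pure tones — subtracted after
re-centering to its mean over the pre-onset baseline second, so the
bleaching trend is removed but the absolute level (hence a positive ΔF/F
denominator) is preserved; (3) ΔF/F against F_base = mean corrected
fluorescence over the 1 s before onset; (4) peak = max ΔF/F from onset to
onset + stimulus duration, extended by a 0.5 s grace for pulse trains to
absorb indicator lag (pulse-train duration = 20 pulses × IPI; pure tones
use their nominal 3 s); (5) trial aggregation as the mean of per-trial
peaks (robust to trial-wise timing jitter; the alternative — peak of the
trial-averaged trace — is not used); (6) normalization by the sum over the
ten IPIs.  Bleach correction is idempotent and the whole chain is invariant
to rescaling the raw trace.

## Group statistics

`exact_wilcoxon` enumerates the Mann–Whitney U null exactly by the shift
algorithm (the Gaussian-binomial recurrence, exact integer arithmetic, no
normal approximation) for tie-free samples up to n1+n2 = 60, with two-sided
p = min(1, 2·min(P(U ≤ u), P(U ≥ u))) — the convention under which complete
separation at 12 vs 13 gives exactly 2/C(25,12) = 3.85×10⁻⁷.  Ties fall
back to a seeded Monte-Carlo permutation of the mid-rank statistic, flagged
in the method tag.  The drop (Δresponse) comparisons use Welch's
unequal-variance two-tailed t by default (configurable to pooled), with
Bonferroni family size equal to the number of IPIs actually tested.  The
pure-tone analysis is a Gaussian identity-link linear model
`response ~ frequency + species + frequency:species`.

## Behavioural survival analysis

Cumulative copulation rate = 1 − Kaplan–Meier survival of
time-to-copulation (lifelines), with pairs that have not copulated censored
at the 35-min observation limit.  RMTL(τ) integrates that step function
exactly; RMTL + RMST = τ holds identically, and τ may exceed the last
observation only when the curve has reached 1.  RMTL summaries default to
the full 35-min window.  The Cox model administratively censors at the end
of the proportionality window (default 0–7 min), codes IPI categorically
with 35 ms as reference, uses Efron tie handling, and reports
exp(interaction coefficient) per non-reference IPI with Wald p-values and
95% CIs; a cell with no events in the window yields a flagged non-estimable
row.

## Synthetic data

The generator's defaults are the study conditions: 12 + 13 individuals,
ten IPIs × 3 trials, 10 frames/s; 45 pairs per species × IPI cell censored
at 35 min.  Individual parameters are independent log-normals per
coordinate with means set to the published species-average estimates and
CVs computed from the published per-individual rows (a: 0.27/0.19%,
τ_b: 0.89/0.72%, c: 12.8/3.5%, τ_d: 3.1/1.3% for
melanogaster/simulans) — shipped in `default_profiles.yaml`, labeled
calibrated-not-measured.  Traces are

    f0 + slope·t + gain·y_norm·k(t − onset) + Gaussian noise,

with y_norm the tuning value at the stimulus IPI normalized over the ten
IPIs, and k a unit-amplitude double exponential (0.1 s rise, 1.0 s decay)
starting at onset — the indicator kernel is a design choice (no published
value exists) that puts the transient peak ~0.26 s after onset, inside
every stimulus window at 10 frames/s.  Fluorescence constants
(f0 = 100 a.u., gain = 400 a.u. per unit normalized response, noise
sd = 0.5 a.u., bleach slope ∈ [−0.5, −0.1] a.u./s) are free parameters
chosen to resemble GCaMP6f recordings; no noise magnitudes were published.
Because the kernel shape is identical across stimuli, measured peaks are
exactly proportional to the generating tuning values, so the zero-noise
round trip recovers the normalized curve to ≲ 0.01% — the 2% contract
bound is loose by design.

Copulation times are exponential per (species, IPI) cell.  Default hazards
are calibrated, not measured: melanogaster base rates peak at the
conspecific 35-ms song; simulans rates are 0.6 × base × the published
interaction ratios (1.44, 1, 2.30, 1.01, 0.93 at 15/35/55/75/95 ms), so the
35-ms-referenced interaction hazard ratios equal the published values by
construction and the 0–7 min proportional-hazards window holds exactly.

### What the generator does and does not emulate

It reproduces the statistical structure the pipeline assumes — band-pass
tuning with log-normal individual variation, linear bleaching, Gaussian
trace noise, constant hazards with administrative censoring.  It does not
emulate motion artifacts, non-linear indicator saturation, trial-wise
response adaptation, correlated parameter variation across individuals,
non-constant (e.g. burn-in) copulation hazards, or dropout before the
assay end.  Tests passing on synthetic data therefore validate the
*computations*, not the biology of real recordings; quantities that require
the raw recordings (the real behavioural hazard p-values, the real
Δresponse t-test, the real frequency-interaction estimate) are covered by
recovery simulations instead.

## Numerical choices and degenerate inputs

Least-squares and sampler tolerances are stated above; other contracts:
moving-average windows must be odd and no longer than the series; bleach
fits need ≥ 2 frames with distinct times; ΔF/F refuses a non-positive
baseline; normalization refuses a non-positive peak sum; Δresponses
require the 25-ms reference; the analytic peak refuses parameter sets
without an interior maximum (c·τ_b ≤ a·τ_d or τ_b ≤ τ_d); parameter
sampling rejects and redraws invariant-violating draws with a bounded retry
count and an explicit failure naming the violated constraint; the
rank-sum exact mode requires tie-free data and n1+n2 ≤ 60; RMTL refuses a
horizon beyond follow-up while pairs remain at risk; zero-variance t-test
cells with equal means give p = 1 by convention.

## Problem sizes

Defaults used throughout the tests and the reproduction script: cohorts of
12 and 13 individuals at noise sd 0.005 (20 seeded repetitions for the
recovery study, 5 for the reproduction script), 4×(1500+1500) MCMC
iterations per fit, 200 Cox replicates at 45 pairs/cell (100 in the
script), 1000 random censored datasets for the RMTL identity, and 10⁴
null simulations for the rank-sum size check.

## Known limitations

* c and τ_d are individually near-unidentifiable from ten IPIs at
  realistic noise (see the ridge section); only their ridge combination
  and the peak IPI are meaningfully estimated.  Tight published
  per-individual c estimates are consistent with strong shrinkage or prior
  information in the original estimation procedure, whose exact priors and
  backend are not public.
* Fits at realistic noise report R̂ above 1.01 on the ridge coordinates and
  are flagged; estimates of the identified quantities are nonetheless
  stable (peak sd ≈ 0.7 ms across seeded cohorts).
* The exact Wilcoxon falls back to permutation on tied data; published
  4-decimal parameter tables contain ties in a, so the a-comparison is
  permutation-based rather than exact there.
* The behavioural hazards are piecewise-constant by construction; real
  copulation hazards need not be, and the RMTL horizon of the published
  figures is not stated (we default to the full 35 min).
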