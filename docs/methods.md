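# Methods

## Model

A genomic copy-number (GCN) signal is a sorted series `D = {g_k, x_k}`,
`k = 1..M`: array-CGH log2-ratios per probe, or mean-centred read counts
per window.  The underlying profile is assumed piecewise constant — `N`
non-overlapping segments, segment `j` covering 1-based probe indices
`[s_j, s_j + w_j - 1]` with amplitude `a_j`, zero baseline elsewhere — and
the observations carry iid Gaussian noise with variance `sigma^2`.  The
log-likelihood is `-psi^2/2 - (M/2) ln(2 pi sigma^2)` with
`psi^2 = sum_k (x_k - f_k)^2 / sigma^2`.

Non-overlap is enforced because overlapping step levels are not
identifiable from the summed spectrum.  Internally everything is 1-based
inclusive probe-index arithmetic (end `e = s + w - 1`); genomic output
converts through each probe's bp location to 0-based half-open BED.

Priors: `p(s_j) = p(w_j) = 1/M` (uniform), `a_j ~ N(tau, kappa^2)`,
`sigma^2 ~ InvGamma(alpha, beta)`.  `p(N) = 1/N_max` is constant within a
fixed-N fit and dropped.  An *informative window* restricts a segment's
start to `[a, b]` and width to `[c, d]` (uniform inside, zero outside) —
the mechanism for refining an externally supplied candidate CNV.  For
clean read-depth data the amplitude prior may instead be a finite level
set, by default `{-c, +c, +2c}` for haploid mean depth `c` (one-copy
loss, one-copy gain, two-copy gain relative to diploid), with multinomial
masses.

Defaults and why they matter:

| parameter | default | meaning |
|---|---|---|
| `tau, kappa` | 0, 100 | amplitude prior mean/sd; flat at log-ratio scales |
| `alpha, beta` | 1, 1 | weak inverse-gamma prior on `sigma^2` |
| `w_min, w_max` | 2, min(M, 500) | width bounds of the discrete scan; 1-probe CNVs are indistinguishable from outliers, the cap bounds the O(M·W) scan |
| `n_iter, burn_in` | 500, 100 | sweeps kept / discarded; chains converge in tens of sweeps on array-scale signals |
| `n_chains` | 2 | independent chains from dispersed starts; best kept by mean post-burn-in log posterior |
| `delta` | 0.01 | defensive-mixture weight of the stabilized evidence estimator |

The prior density function deliberately does not re-check segment bounds
(that is an invariant of the state, enforced by the sampler); it returns
`-inf` only for states outside informative-window or amplitude-level
support.  This keeps the implemented `1/M x 1/M` start/width mass exactly
normalised, which the test suite verifies by direct summation.

## Sampling

One sweep updates each segment, then the variance:

1. `(s_j, w_j)` from a discrete conditional over all candidates
   `s in [1, M]`, `w in [w_min, w_max]`, `s + w - 1 <= M`, excluding
   windows that touch other segments or fall outside an informative
   window.  Residual prefix sums make each candidate O(1); the scan is
   O(M·W) per segment and takes a few milliseconds at M=1000, W=500.
2. `a_j` from its conjugate normal conditional with mean
   `[(1/kappa^2) tau + (w_j/sigma^2) xbar_j] / (1/kappa^2 + w_j/sigma^2)`
   and variance `1 / (1/kappa^2 + w_j/sigma^2)`, `xbar_j` being the mean
   residual inside the segment — or from the discrete conditional over
   the amplitude levels.
3. `sigma^2 ~ InvGamma(alpha + M/2, beta + RSS/2)` with RSS the residual
   sum of squares about the *current fitted spectrum* (the only reading
   of the conditional that targets the stated posterior).

Two variants of step 1 are provided.  The plain variant conditions on the
current `a_j`.  The default *blocked* variant integrates `a_j` out of the
scan analytically (normal prior: a Gaussian integral per candidate;
discrete prior: a logsumexp over levels) and redraws it immediately —
i.e. `(s_j, w_j, a_j)` is sampled as one block.  The fixed-amplitude scan
is sign-trapped on multi-CNV data: a segment whose amplitude has locked
onto a deep negative CNV can never propose a positive one, because every
candidate window is weighted under the current negative amplitude.  The
blocked move weighs each window by its amplitude-marginalised fit and
hops freely between modes.

Initialisation: `sigma^2` starts at the sample variance of the signal and
segments are *activated sequentially during the first sweep* — each new
segment is placed by its own blocked scan on the residuals left by the
segments before it.  This sequential matching-pursuit start picks up the
most prominent CNV first and prevents a fledgling two-probe segment from
squatting inside (and splitting) a large CNV, which was the dominant
failure mode of fully random initialisation in our experiments.  Two
chains from different random streams are run by default and the chain
with the highest mean post-burn-in log posterior is summarised.

Labels are canonicalised by sorting segments by start after every sweep
(skipped when informative windows tie priors to specific labels).
Summaries drop the burn-in and report the posterior mode for discrete
parameters (s, w, e; ties toward the smaller value), the posterior mean
for continuous ones (a, sigma), and 95% credible intervals as
mean ± 1.96 sd.

## Model selection

For `N = 0..n_max` a chain is fitted and the log marginal likelihood
estimated from its post-burn-in likelihood draws: either the harmonic
mean `[mean(1/L_i)]^{-1}` or (default) the Newton–Raftery defensive-
mixture fixed point with `m = delta*K` pseudo-draws at the current
estimate, solved by iteration in log space from the harmonic-mean value
(relative tolerance 1e-10).  The selected N maximises the log Bayes
factor against N=0 under equal model priors; an optional early stop ends
the scan after two consecutive decreases.

**What this estimator can and cannot resolve.**  Both estimators use only
likelihood values at posterior draws.  They reproduce large likelihood-
driven evidence differences faithfully — on the four-CNV benchmark the
log Bayes factors for N=4 and N=1 against the null land within a few
percent of their reference values, and on a one-point conjugate toy the
stabilized estimate matches the analytic marginal likelihood within
Monte-Carlo error.  But a posterior chain never visits the breadth of the
prior, so the estimator cannot see the Ockham penalty of weakly
supported parameters: its finite-sample bias relative to the analytic
marginal grows with posterior concentration (measured on conjugate
null-model toys: +0.03 nats at M=2, +0.38 at M=10, +1.6 at M=25 with 400
draws).  Consequently, on pure-noise data the estimated log Bayes factors
of N>=1 models hover within ~±1 nat of zero instead of the ~-12 nats a
true marginal would give, and the argmax selection rule keeps the null
model in only roughly half of noise replicates rather than nearly all.
For the same reason, once the sampler fits all true CNVs reliably, the
estimated evidence no longer drops sharply for N above the truth; the
peak at the true N can be decided by ~1-nat noise against N_true+1.
Practitioners should read the model-scan table, not just the argmax: real
CNVs enter with evidence jumps of tens to thousands of nats, spurious
ones with ~1.  These are properties of the likelihood-only evidence
estimator at this chain length, documented here rather than patched, and
they are why the null-calibration acceptance check currently fails.

## Read depth

Reads are assigned to non-overlapping tiled windows by start coordinate
(conserving counts exactly); window counts minus their global mean form
the GCN signal, so a homozygous deletion appears at amplitude ≈ -(mean
count).  Window size defaults to 200 bp.  The downsampling experiment
subsamples reads without replacement at given fractions, refits the
one-CNV model per replicate, and reports the posterior sds of the start
and end indices in window units plus the fraction of replicates whose
amplitude credible interval excludes zero ("detected").  On the bundled
synthetic generator (uniform reads, 10x coverage, a 3 kb deletion in
60 kb), positional sd grows monotonically as coverage falls and detection
collapses below ~1x.

## What the simulator does and does not emulate

`simulate_gcn` generates exactly the assumed process: integer probe
locations 1..M, a known step spectrum, iid Gaussian noise.  The
read generator places reads uniformly with Poisson totals and carves
deletions (homozygous or heterozygous).  Real data violate these
assumptions in known ways — probe-specific response, GC/mappability waves
in read depth, outlier probes, heavy-tailed noise — so passing tests here
demonstrate correctness of the inference machinery under the model, not
robustness to platform artefacts.  The Lai-style benchmark (one centred
CNV of given probe width, amplitude = SNR at unit noise) supports
per-probe ROC evaluation with the posterior inclusion frequency — the
fraction of post-burn-in draws placing a probe inside any segment — as
the detection score.

## Numerical notes

- All evidence arithmetic is in log space; log Bayes factors of order
  1500 nats (likelihood ratios ~e^1500) cause no overflow.
- The categorical (s, w) draw subtracts the max log-weight before
  exponentiation; candidate grids are cached per (M, w_min, w_max).
- Degenerate inputs: a constant signal (zero variance) initialises
  `sigma^2` at 1; an informative window fully occupied by other segments
  raises a configuration error rather than silently emptying the
  conditional; burn-in must leave at least one draw.
- Chunked processing (default 1000 features per chunk, overlap 0, both
  configurable) fits each chunk independently; with a nonzero overlap,
  duplicate boundary calls are merged by reciprocal probe overlap >= 50%,
  keeping the higher |mean|/sd amplitude.  An overlap of ~2 w_max is
  recommended when CNVs may straddle chunk boundaries.

## Known limitations

- No per-probe weights, no heavy-tailed likelihood: a single strong
  outlier can seed a two-probe segment (hence `w_min = 2`).
- Model selection inherits the evidence-estimator bias discussed above;
  N is best treated as "number of clearly supported CNVs", with the scan
  table consulted for marginal cases.
- Breakpoint credible intervals assume the window/probe grid is the
  resolution limit; sub-window breakpoints are not interpolated.
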