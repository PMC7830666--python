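# Methods

## The model

`multichaos` estimates how fast initially close states of a dynamical
system diverge, as seen through a single measured variable, and asks
whether that rate is *scale-uniform*. The largest Lyapunov exponent
(LLE) is defined through

    d_j(i) = C_j * exp(LLE * i * dt),

where d_j(i) is the separation of the j-th pair of nearest-neighbour
states after i steps and C_j their initial separation. The package
follows the practical trajectory-tracking estimator for scalar series:
delay-embed the series, pair every state with its nearest neighbour
outside a temporal exclusion window, and fit the slope of the averaged
log-separation curve

    y_p(i) = (1/dt) * < ln d_jp(i) >_j .

The generalization — the package's core — measures *every* distance in
that construction with a Minkowski p-norm

    ||u||_p = (sum_k |u_k|^p)^(1/p),  p > 0,

a true norm for p >= 1 and a "fractional norm" below. Small p weights
the small components of a separation vector (small-fluctuation, SF,
structure), large p its largest component (large-fluctuation, LF).
Sweeping p yields the generalized-LLE spectrum GLLE(p); its width

    delta_W = max_p GLLE(p) - min_p GLLE(p)

is the degree of "multi-chaos": zero when all fluctuation scales diverge
at one rate, positive when they do not. Nearest neighbours are
recomputed at every p because the minimizing neighbour depends on the
norm. Values p <= 0.05 are rejected as numerically unstable.

## Assumptions

* The series samples a stationary attractor; transients are discarded
  by the simulators before analysis.
* Exponential divergence holds only between two floors: the initial
  separation of the selected neighbour pairs (biased low by the
  minimization) and the attractor scale at which folding saturates
  separations. The fit must live between them (see *Fit region*).
* For beat-indexed R-R data the "time" axis is the beat index, so all
  exponents are per beat-step; metadata records this.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| delay J | estimator-chosen | samples between embedding coordinates |
| dimension m | Cao's method | embedding dimension |
| min_sep | mean period of the series | Theiler window: neighbours must be this many samples apart in time |
| k_max | 100 (dt = 1), 500 (flows) | divergence-tracking horizon in steps |
| p-grid | {0.1,0.5,1,2,...,10} (benchmarks), {0.1,0.5,1,2,3,4,5} (R-R) | norm orders |
| fit band | (0.05, 0.50) | scaling-region definition, fractions of the log-divergence rise |

The mean period is the reciprocal of the power-weighted mean frequency
of the spectrum — the classical Theiler-window choice for this
estimator family. All defaults are overridable through `GLLEConfig`.

### Delay estimation

Four criteria are provided. The autocorrelation zero-crossing
(`|acf| <= 0.05`), the first minimum of the histogram mutual
information (16 equal-width bins), and the first minimum of the
correlation integral ln C(J) (probe dimension 2, radius frozen at the
10 % distance quantile of the lag-1 embedding) serve smooth,
oscillatory signals. Both minimum-based scans use a prominence
threshold (5 % of the curve range) so hairline sampling wiggles on
monotone curves do not masquerade as minima, and centre the chosen
minimum over its surrounding valley, since histogram quantization and
subsampling flatten the true minimum into a plateau; an MI curve that
never clears three times its independence bias ((k-1)^2 / 2N) returns
J = 1. For broadband maps all three wander to long, structure-free
lags, so the benchmark driver uses the fourth criterion — the first lag
where the acf drops below 1 - 1/e — which is the classical prescription
in divergence-rate estimation and lands on J = 1 for maps.

### Embedding dimension

Cao's method: E1(d) = E(d+1)/E(d) from mean nearest-neighbour distance
ratios in the maximum norm; m is d + 1 for the first d whose E1 exceeds
0.95 at two consecutive dimensions. E2(d) is returned so stochastic
series (E2 ≈ 1 everywhere) can be flagged.

### Fit region

The divergence curve of a finite series has three regimes: a short
initial stretch biased by the neighbour selection (under noise it shows
a decorrelation jump), the scaling region where the exponential model
holds, and the bend into saturation at the attractor scale. The
automatic fit takes the contiguous run of steps whose values lie within
[5 %, 50 %] of the total log-divergence rise — the lower half of the
rise, clear of both floors — extended forward to at least 5 steps, and
reports the least-squares slope and r² there. The band was fixed by
requiring recovery of the four benchmark systems' literature exponents
(0.69, 0.42, 1.50, 0.09 per unit time) and is not adjusted per series.
An explicit window overrides it. Zero-distance pairs are excluded from
a step's average (their log is undefined), and pairs leave the average
when either member runs off the trajectory matrix.

## Synthetic data

The simulators generate the study conditions: logistic (mu = 4) and
Henon (a = 1.4, b = 0.3) maps at dt = 1 s, and Lorenz
(sigma = 10, R = 28, b = 8/3, dt = 0.01 s) and Rossler
(a = 0.15, b = 0.20, c = 10, dt = 0.1 s) flows under fixed-step RK4,
all sampled through x. Map initial conditions are drawn uniformly from
an interior interval, flows start near (1, 1, 1) with a small seeded
offset; transients of 1000 (maps) / 10000 (flows) steps are discarded;
5000 samples are kept. Gaussian noise of chosen sd can be added with
its own derived seed. These series emulate the *dynamics* of real
physiological signals but none of their nonstationarity, artifacts,
missing beats, or measurement quantization — passing benchmark tests
therefore validates the estimator, not its clinical readiness.

R-R emulation in the tests shifts map output into the 0.4–1.4 s
interval range; it reproduces plausible magnitudes, not cardiac
physiology.

## Behaviour on clean deterministic systems

For noise-free benchmark orbits the estimated spectrum is flat:
GLLE(p) is independent of p to within a few thousandths, so delta_W is
approximately 0 for the logistic, Henon *and* Rossler systems. This is
a structural property of the construction, not a tuning artifact: every
coordinate of a neighbour-difference vector grows at the same
exponential rate, so changing the norm shifts the log-divergence curve
vertically but leaves its early slope unchanged. Additive noise breaks
the uniformity — fractional-p norms retain a longer apparent growth
range under a noise floor — so noisy series (and measured R-R data,
which always carry a random component) produce genuinely positive
widths. Consequently delta_W should be read as a joint property of
dynamics *and* noise level, and clean-system width benchmarks near
zero are the expected output of this implementation.

## Correlation dimension

Grassberger–Procaccia: C(r) is the fraction of Theiler-admissible pairs
closer than r (Euclidean); D2 is the max-r² slope of ln C vs ln r over
a contiguous radius window spanning at least half a decade, radii
log-spaced between the 0.1 % and 20 % distance quantiles (estimated on
a deterministic 1500-row subsample). A best window fitting worse than
r² = 0.98 flags the estimate low-confidence. Noise inflates D2, which
is why the pipeline reports it as a random-component proxy.

## Classification

Features are GLLE(p) on the seven-point R-R grid, times 100. Two
fixed-coefficient logistic scorers ship with the package (healthy vs
pathology at threshold P > 0.46; chf vs af at P > 0.48; both strict).
Refitting uses forward selection by Wald p < 0.05 with backward
elimination at p > 0.10 on a maximum-likelihood logistic model;
separation triggers an L2-penalized fallback with a warning. Classifier
quality uses the precision-recall curve (trapezoidal AUC over recall,
F1-maximizing associated threshold, stratified-bootstrap CI) and the
Matthews correlation coefficient with the zero-marginal-gives-zero
convention — appropriate for the unbalanced group sizes.

## Numerical choices

* Nearest neighbours: exact k-NN via a kd-tree for p >= 1; chunked
  brute force for fractional p (kd-tree pruning assumes the triangle
  inequality). Ties break to the smaller index in the brute-force path;
  both paths are property-tested against an O(M²) oracle.
* RK4 is fixed-step by design (reproducibility; the convergence-order
  test and an adaptive-integrator cross-check guard correctness).
* Henon orbits raise a divergence error past |x| > 1e6; non-finite flow
  states raise with the failing step index.
* Quartiles in group summaries use linear interpolation (type-7).

## Problem sizes

Benchmark analyses use 5000-sample series; the noise ensemble uses 10
realizations per level. One full benchmark spectrum (12 p-values,
embedding estimation included) runs in roughly 10–40 s on one core;
the complete acceptance recomputation takes a few minutes.

## Known limitations

* Lorenz at 5000 samples (50 time units) covers only ~70 orbits; the
  divergence curve then has no extended linear region and the exponent
  is underestimated by roughly 10–25 % with seed-to-seed scatter of
  similar size. Longer series recover the literature value.
* Delay-minimum estimators are unreliable on broadband maps (use the
  1/e criterion there).
* The fixed scorers' coefficients are shipped as published constants
  for reproducibility; they are not re-validated here, and nothing in
  this package constitutes a diagnostic claim.
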