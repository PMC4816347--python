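# Methods

`dtwmic` infers coexpression networks from time-course expression data with
a similarity measure designed for two failure modes of Pearson correlation:
non-linear functional dependence and time shift between profiles.  This
note documents the model, the numerical choices, and what the built-in
synthetic examples do and do not demonstrate.

## The similarity measures

**PCC.** The sample Pearson correlation; the package exposes the signed
value and uses |PCC| for network construction (the unsigned WGCNA
convention).  It is undefined for constant series, which raise an error
rather than returning NaN.

**MIC.** The maximal information coefficient: the largest, over all k x l
grids on the scatterplot with k·l <= B(n) = n^alpha, of the discretized
mutual information normalized by log min(k, l).  The estimator is the
standard heuristic: one axis is equipartitioned into l rows; the column
edges are optimized by dynamic programming over *clumps* (maximal runs of
x-consecutive points in one row, x-ties held together), capped at c·k
superclumps; both orientations are searched.  Maximizing I(P; Q) for fixed
rows is equivalent to minimizing the column-additive conditional entropy
sum_j n_j H(Q | column j), which is what the DP minimizes.  Defaults
alpha = 0.6, c = 15 (the conventional MINE settings).  Decisions:

* constant input returns MIC = 0 with a warning — the no-association limit;
* series shorter than 50 points warn (grid budgets below ~12 cells make the
  statistic unstable) but are still scored; fewer than 4 points is an error;
* a value within 1e-12 of 1 is treated as attaining the upper bound —
  noiseless functional relations reach exactly 1 in exact arithmetic
  because the normalizing log and the maximized information coincide.

**DTW.** Normalized dynamic time warping distance with the symmetric2 step
pattern: local cost |x_i - y_j|, recursion
D(i,j) = min(D(i-1,j) + d, D(i,j-1) + d, D(i-1,j-1) + 2d), D(1,1) = d(1,1),
normalized by n + m.  The diagonal weight 2 makes every admissible path
carry total weight n + m, so the normalization is a per-step average and
the distance is comparable across lengths.  This dialect (rather than
symmetric1 or window-constrained variants) is fixed because it reproduces
the worked E2 value DTW_s(r_40, r) = 0.959 exactly.  Equal-cost
predecessors are broken arbitrarily; no warping path is exposed, so the
tie-break cannot affect any output.  The DP kernel is numba-jitted when
numba is importable, with a bit-identical pure-python fallback.
DTW_s = 1/(1 + DTW_d) maps the distance into (0, 1].

**DTW-MIC.** The root mean square sqrt((DTW_s^2 + MIC^2)/2).  It inherits
[0, 1], symmetry, lies between min and max of its components, and equals 1
iff both components do.

## Network construction

Given the all-pairs similarity matrix S (diagonal 1), the weighted
adjacency is the WGCNA soft threshold a_ij = S_ij^beta with beta = 6 by
default; the diagonal is zeroed (no self-loops — also required for the
Laplacian-based distance below).  beta is a plain parameter; scale-free
tuning is out of scope.  The hard threshold produces a binary graph with
an edge where the weight is *strictly* above tau (a literal reading of
"above a threshold"; flip by passing tau - eps if >= is wanted).
Replicated experiments are concatenated gene-wise, last timepoint of
replicate i followed by the first of replicate i + 1, before computing
similarities — short per-replicate series are unreliable under MIC.

## Network distances

* Hamming: H = sum_{i != j} |a_ij - b_ij| / (n(n-1)).  The n(n-1)
  normalization (ordered off-diagonal pairs) is fixed by the worked E4
  values 1/6 and 1/3.
* Ipsen-Mikhailov: each graph's Laplacian frequencies omega_i =
  sqrt(lambda_i) (the n-1 trailing eigenvalues of D - A) are broadened
  into a Lorentzian density of half-width gamma, normalized to unit mass
  on [0, inf); IM is the L2 distance between the two densities.  gamma is
  calibrated per node count so that IM(empty, full) = 1, by Brent root
  search on a bracket expanded around [1e-3, 1] (the distance is monotone
  decreasing in gamma); the calibration is cached keyed by n only.
* HIM = sqrt(H^2 + IM^2)/sqrt(2), i.e. the distance of the point (H, IM)
  from the origin of the H x IM plane, rescaled to [0, 1].  No
  component-weighting exponent is exposed; the combination is the
  equal-weight one.

Integrals are evaluated by adaptive quadrature (absolute/relative
tolerance 1e-10) on [0, omega_max + 50 gamma] with the Lorentzian centers
passed as breakpoints, plus the analytic-decay tail integrated to
infinity; tests pin the result against an independent fixed-step Simpson
oracle to 1e-6 and check stability under step halving.  Isospectral graphs
score IM = 0 by construction — expected spectral-metric behavior, asserted
on a cospectral non-isomorphic 6-node pair — which is exactly why HIM also
carries the edge-wise Hamming term.

## Null-model significance

The no-information level of DTW_s is estimated by drawing 2N vectors
uniform on [m, M]^n_points (bounds taken from the data range under
scrutiny), pairing them, and averaging the N DTW_s values; an observed
similarity is significant when it strictly exceeds this mean.  "Student
bootstrap" confidence interval: B = 1000 bootstrap resamples of the mean,
interval mean +/- t_{(1+level)/2, B-1} · sd(bootstrap means).  This
reading reproduces interval widths of order 1e-3 at N = 1000.  One seeded
generator drives vectors and bootstrap.  Because DTW_d is 1-homogeneous
and shift-invariant, the null mean depends on the bounds only through
M - m (a property the tests assert); with the bounds of the noise-free
E2 family the mean and CI reproduce the published k = 0 threshold to all
four printed digits.  The analogous thresholds for the noisy families
(k = 1, 2) do not match the published ones under any reading of the noise
envelope we could construct; the discrepancy and the range analysis are
documented in the acceptance test for the k = 2 value, which is left
failing rather than fitted.

## Synthetic fixtures

The worked examples are generated from closed forms (time index 1-based,
i = 1..100; unadorned log read as log10, which the E1 correlation bounds
force; the E2 reference is r(i) = (1/10) i^{3/2} e^{-2i/25} sin(3i/20),
the unique reading consistent with the printed DTW values).  Uniform
noise eps(z) ~ U(-z, z) with eps(0) = 0 keeps noise-free members exactly
deterministic.  Spot values of every fixture are pinned in tests so
refactors cannot silently alter them.

`simulate_timecourse` exists so the full pipeline (simulate -> infer ->
HIM-score against truth) can be tested end to end against a known truth
network.  It is a deliberately small linear-dynamics generator, not a
reimplementation of any published kinetic simulator: genes decay (rates
U(0.3, 1)), receive a signed step perturbation (|b| ~ U(0.5, 1.5)) on the
first half of the timepoints, couple diffusively (strength 0.7,
degree-normalized) along the ground-truth edges, and accumulate Gaussian
process noise (sd 0.3 per step).  The process noise is what individuates
unconnected genes: without it every noiseless trajectory is a smooth
function of time, all pairs become functionally dependent, and MIC
saturates at 1 regardless of the graph.  Observation noise (`noise_sd`)
is added on top.  What the end-to-end test shows is therefore modest and
qualitative — inference degrades monotonically with observation noise on
average — not that the method recovers realistic regulatory kinetics,
saturating dynamics, or measurement-specific noise models, none of which
the generator emulates.

## Problem sizes

The test-suite defaults are desk scale by design: 100-point series,
N = 1000 null pairs, networks of 4-20 nodes, and an 8-gene / 60-timepoint
end-to-end simulation over 3 seeds and 2 noise levels; the full suite runs
in well under a minute.

## Known limitations

* MIC overestimates dependence on short or noiseless smooth series (the
  known false-positive bias); the soft threshold is the mitigation used
  here, not a correction of the estimator.
* The MIC maximization is the standard heuristic, not the exact grid
  optimum; values are lower bounds of the exact statistic.
* IM cannot separate isospectral graphs; HIM can only via the Hamming term.
* PCC significance and multiple-testing control across gene pairs are out
  of scope, as are directed networks and DTW variants (derivative,
  windowed, complexity-invariant).
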