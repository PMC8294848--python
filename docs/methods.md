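# Methods

## Model

A place cell is a perceptron over a population of grid-like inputs. Space
is discretized into bins indexed by j. Module m has integer period λ_m (in
bins) and λ_m cells; cell i of module m is active at location j iff
(j − i) mod λ_m = 0 (0-based throughout, a harmless index-origin shift of
the usual 1-based convention). Each location's population vector has
exactly one active cell per module, and the code repeats after
L = LCM(λ₁…λ_M) bins. The read-out is y(x) = [w·x − θ > 0].

Strict separation is decided as a *unit-gap* linear program: find (w, θ)
with w·x_j − θ ≥ +1 on fields and ≤ −1 elsewhere. Any strictly separating
pair rescales to satisfy these constraints, so the realizable set is
exactly the strictly separable one while feasibility becomes a closed LP
(solved with scipy's HiGHS). The all-zero and all-one labelings are
realizable (w = 0 with θ = ±1); the closed-form counts include them.

## Counting

For two modules, realizable arrangements biject with lonesum matrices on
the λ₁ × λ₂ module-phase grid (binary matrices avoiding both 2×2
permutation submatrices; equivalently, matrices whose row supports nest).
The total count is the poly-Bernoulli number B_{λ₂}^{(−λ₁)}, evaluated
exactly through the finite double-Stirling sum with sympy integer
arithmetic — no floating point enters any count. The equivalence
lonesum ⇔ LP-realizable is not assumed: it is verified exhaustively on
small codebooks in the test suite, and the closed form is checked against
exhaustive LP enumeration for module pairs up to {3,4} (4096 labelings).

Small-K counts for arbitrary module numbers are obtained by enumerating
K-subsets against the LP oracle; the growth exponent of the K-field count
in λ (at fixed M, K) is estimated by log–log regression and approaches
M + K − 1. The exact closed form for these counts is not reproduced here;
enumeration is the source of truth.

Cover's function C(P, N) = 2·Σ_{k<N} C(P−1, k) provides the
general-position baseline; the affine (free-threshold) case is C(P, N+1).

## Capacity

For shift-generated codes the contiguous-separating capacity equals the
rank of the input matrix. The rank follows by inclusion–exclusion over the
GCDs of period subsets:

    R = Σ λ_i + Σ_{k≥2} (−1)^{k−1} Σ_{|S|=k} GCD(S),

reducing to Σ − M + 1 for pairwise-coprime periods. `contiguous_capacity`
measures l\* independently by enumerating all 2^l labelings of a leading
window and testing each with the LP; translation invariance (verified
explicitly over all window origins) justifies the single window. Windowed
enumeration is capped at l ≤ 16; beyond the cap results are reported from
the rank formula and tagged `rank_only`.

Real-valued periods are handled at finite phase resolution q via
R_q = R_int(⌊qλ₁⌋, …); the ratio R_q/(qΣ) is bounded by 1 and rises toward
1 as q grows, so capacity approaches Σ for generic real periods.

For d = 2, module m contributes λ_m² cells one-hot coding its 2D phase.
The full 2D code over the LCM × LCM torus visits every cross-module phase
combination, making it a modular-one-hot code with module sizes λ_m² —
so its rank obeys the same inclusion–exclusion formula applied to the
squared periods (12 for periods {2,3}, slightly below the sum of squared
periods Σ₂ = 13 because of the coprime correction). `capacity_2d` reports
the numeric rank alongside Σ₂ and tests axis-aligned rectangles for
realizability-completeness; note a 1×n strip only ever exercises λ_m
phases per module, so completeness of a strip is governed by the 1D rank,
not the 2D one.

## Margins and robustness

The margin of a realizable arrangement follows the two-class-sum
convention: the smallest point-to-boundary distance per class, summed over
classes; at the hard-margin optimum this equals 2/‖w‖. Margins are
computed with scikit-learn's SVC (linear kernel, C = 10¹⁰, free threshold,
unconstrained weights). If SVC fails to strictly separate a labeling that
the LP certifies realizable (rare, near-degenerate cases), the margin is
reported from the L1-minimizing unit-gap LP separator as a lower bound and
tagged `lp_lower_bound`.

Fair-comparison contract: all compared codebooks must have identical cell
count, pattern count, and unit-L1 columns (margins scale linearly with
pattern norm); this is asserted before any comparison.

Sampling realizable arrangements is not uniquely defined, and the choice
matters. Two samplers are provided:

- `weights`: draw w i.i.d. uniform [0,1] and place θ between the K-th and
  (K+1)-th largest weighted input sums — exactly K supra-threshold
  patterns, realizable by construction. This models how a cell with random
  non-negative weights actually produces arrangements, and for grid codes
  its margin statistics match unbiased sampling empirically.
- `uniform`: rejection-sample K-subsets against the LP oracle — unbiased
  over K-subsets but expensive when the realizable fraction is small.

Margin comparisons use `weights` for the grid code and `uniform` for
shuffled and random codes: for unstructured codes the weight sampler
preferentially finds the rare large-gap dichotomies and inflates their
margins, masking the structural advantage of the grid code. The sampler
used is recorded in every report's metadata. At the full {31,43} scale,
comparisons use K = 3 (rejection acceptance ≈ 8% for shuffled codes; at
K = 5 it is too small for unbiased sampling at reasonable cost), with the
scaled-down {7,11} code used at K = 5 and larger sample counts.

Nongrid inputs follow the stated generative models: dense noise rows are
i.i.d. uniform on [0, 2μ] with μ = 0.2·μ_g and μ_g = M/N the grid
population mean (2/(λ₁+λ₂) for two modules); sparse cue rows are binary
with exactly Q = round(0.2·L·μ_g) ones at random locations. Augmented
codebooks are re-normalized to unit-L1 columns. "Newly realizable"
arrangements are found by single-label flips of known-realizable
arrangements plus sampling on the augmented codebook, each candidate
verified infeasible-before/feasible-after with the LP; exhaustive search
is impossible at these sizes, so the reported new arrangements are a
sound but non-exhaustive sample.

## Graded tuning and 2D-lattice slices

Graded responses use Gaussian phase tuning
g = exp(−‖φ_m(x) − φ_i‖²/(2σ_g²)) with wrapped phase distance
‖α‖ = min(|α|, 1−|α|) and σ_g = 0.16, giving a tuning curve whose full
width at half maximum is 3/8 of the module period. Quasi-periodic 1D
responses are slices through a 2D hexagonal lattice of Gaussian bumps
(lattice vectors at 0° and 60°, spacing = period, bump width σ_g·period,
per-cell uniform 2D phase offsets); the slice angle is drawn uniformly per
run (seeded) and configurable, as no canonical angle exists.

## Volatility simulation

Defaults (all configurable, echoed in output metadata): a 20 m track at
5 cm bins (400 bins), two modules with rodent-scale periods 0.4 m and
0.6 m, one cell per phase bin per module, K = 8 initial fields. A
realizable K-field arrangement is built by drawing a random-weight
perceptron and placing the threshold between the K-th and (K+1)-th tallest
local maxima of the summed input, so exactly K contiguous supra-threshold
runs (fields) emerge; the labeling is then refit by the hard-margin
program. (Labelings with exactly K isolated supra-threshold *bins* are
near-degenerate on graded inputs — neighboring bins are almost identical —
so fields are defined as runs, with field position the peak bin.)

Hebbian insertion at target t updates w ← w + η·x_t with η the smallest
value lifting the target above threshold by 5% of its original deficit.
Fields before and after are matched within 3 bins (≈ the bump half-width
of the smaller module); unmatched before-fields are deletions, unmatched
after-fields farther than the tolerance from any deliberate target are
off-target insertions. The off-target rate is (insertions + deletions) per
meter. Because the module periods, cell counts, and step-size convention
of the original experiment are unspecified, the absolute rate is treated
as order-of-magnitude only; the tested claims are the qualitative ones
(positive rate, monotone growth with the number of inserted fields, zero
interval shift for surviving field pairs at the bin scale, and alignment
of new-field spacings with input-autocorrelation peaks beyond shuffled
surrogates).

## What the synthetic data does and does not capture

The generators produce idealized rate codes: deterministic binary or
graded activations, no spiking noise, no trial-to-trial variability, no
module rotation or realignment across environments, and exact phase tiling
within modules. Passing tests therefore validate the combinatorial and
geometric claims about the model, not quantitative predictions for
recorded neurons. Noise enters only through the explicit nongrid-input
models and through weight perturbations in the volatility contrast.

## Numerical choices

- LP feasibility at HiGHS default tolerances with ±1 targets; exhaustive
  small-codebook tests pin the resulting behavior.
- Hard-margin SVC at C = 10¹⁰ with one escalation to 10¹³ (capped
  iterations), then the LP fallback described above.
- Enumeration caps: 2²⁰ labelings/patterns, window length ≤ 16; exceeding
  a cap raises or falls back explicitly, never truncates silently.
- Tie-breaks in the weight sampler (equal K-th and (K+1)-th input sums)
  trigger a redraw.
- Degenerate inputs: period-1 modules contribute a constant cell (rank 1);
  all-zero columns are rejected by L1 normalization with their index.
- All stochastic paths accept a seed or `numpy.random.Generator`;
  experiments echo seeds and configuration in their outputs.

## Known limitations

- The closed-form count applies to M = 2 modules; for M ≥ 3 only
  enumeration (small K) and the Young-diagram upper bound are available.
- The uniform sampler is infeasible where the realizable fraction is tiny
  (e.g., grid codes at large K over the full range); the weight sampler is
  then the only practical option and its bias is documented above.
- 2D capacity windows are axis-aligned rectangles only.
- The hexagonal-lattice slice generator models a single module per call;
  multi-module tracks stack independent slices and ignore any cross-module
  phase coupling.
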