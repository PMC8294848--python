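# gridplace

Perceptron models of hippocampal place cells driven by grid-cell inputs.

A place cell is modeled as a thresholded linear read-out of a population of
grid cells organized in modules: module *m* has spatial period λ<sub>m</sub>
and its cells tile all spatial phases, so the population code repeats only
after L = LCM(λ₁, …, λ_M) locations. A *field arrangement* is a binary
labeling of locations (1 = place field), and an arrangement is *realizable*
if some weights **w** and threshold θ produce it:

    y(x_j) = 1  if  w · x_j − θ > 0,   else 0.

The package answers, with exact combinatorics and linear programming:

- **How many** field arrangements can one place cell realize over the full
  range of unique grid states? For two modules the exact count is a
  poly-Bernoulli number, N<sub>λ₁,λ₂</sub> = B<sub>λ₂</sub><sup>(−λ₁)</sup>,
  via the correspondence between realizable arrangements and lonesum
  (staircase / Young-diagram) matrices.
- **Over what contiguous range** is *every* arrangement realizable? This
  contiguous-separating capacity equals the rank of the input matrix,
  l\* = R, with R given in closed form by inclusion–exclusion over the
  GCDs of period subsets (R = Σλ − M + 1 for pairwise-coprime periods).
- **How robust** are grid-driven arrangements? Hard-margin SVM margins for
  grid codes form a small discrete set and dominate those of shuffled-grid
  and random codes of matched dimension, pattern count, and column norm.
- **How volatile** is the arrangement under plasticity? Inserting a single
  field through Hebbian changes to the grid-to-place weights causes
  off-target fields to appear and disappear at locations aligned with peaks
  of the input autocorrelation, while surviving fields do not shift.

Audience: computational neuroscientists studying grid/place coding, and
anyone interested in perceptron capacity for structured (non-general-
position) inputs.

## Worked example

Count the realizable field arrangements of the {2,3} grid code by exhaustive
LP enumeration (all 2⁶ labelings), and compute the contiguous-separating
capacity for periods {3,4}:

```sh
$ gridplace count --periods 2,3 --mode brute
{ "config": {"periods": [2, 3], "mode": "brute", "K": "all"},
  "count": 46, "method": "brute_force", ... }

$ gridplace capacity --periods 3,4
{ "config": {"periods": [3, 4]},
  "l_star": 6, "rank": 6, "sigma": 7.0, "full_range": 12,
  "fraction_curve": {"1": 1.0, "2": 1.0, "3": 1.0, "4": 1.0,
                     "5": 1.0, "6": 1.0, "7": 0.96875},
  "method": "enumeration", ... }
```

Reading the output: of the 64 possible labelings of the six unique {2,3}
grid states, exactly 46 are linearly separable — equal to the closed form
B₃⁽⁻²⁾ = 46 (`gridplace count --periods 2,3 --mode closed_form`). For
periods {3,4} the code is unique over 12 locations, but *every* labeling is
achievable only over windows of up to l\* = 6 contiguous locations — the
rank of the input matrix (Σλ − M + 1 = 6) — and the realizable fraction
drops below 1 at window length 7.

The same functionality is available as a library:

```python
from gridplace import make_grid_codebook, count_realizable, count_two_module

cb = make_grid_codebook([2, 3])
assert count_realizable(cb, "all") == 46 == count_two_module(2, 3).value
```

Other subcommands: `gridplace codebook` (generate/serialize input codes),
`gridplace rank` (capacity for real-valued periods at finite phase
resolution), `gridplace margins` (margin distributions, noise and sparse-cue
effects), `gridplace volatility` (Hebbian field-insertion experiments).

## Layout

- `src/gridplace/codebooks.py` — input-code generators (grid,
  modular-one-hot, one-hot, binary, random, shuffled, graded tuning,
  2D-lattice slices) and noise/cue augmentation
- `src/gridplace/separability.py` — LP realizability engine, hard-margin
  solutions, lonesum checks, arrangement samplers
- `src/gridplace/combinatorics.py` — exact counts (Stirling,
  poly-Bernoulli, Cover) and rank/capacity formulas
- `src/gridplace/capacity.py` — contiguous-separating-capacity experiments
- `src/gridplace/robustness.py` — margin distributions; dense-noise and
  sparse-cue effects
- `src/gridplace/volatility.py` — Hebbian field-insertion simulations
- `docs/methods.md` — model assumptions, parameter choices, numerical
  details, limitations
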