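# Methods

## The procedure

`swarmfs` implements a three-phase classification pipeline for image-derived
feature tables:

1. **Feature extraction (FE).** Images become rows of an `n x D` real-valued
   feature table. The package ships a deterministic descriptor (colour
   histograms + normalized central moments + blob statistics, D = 35 by
   default) and an adapter contract through which an external deep
   convolutional extractor (e.g. a 2048-feature residual-network backbone)
   can supply tables; downstream phases treat every table identically.
2. **Feature selection (FS).** A binary swarm metaheuristic — whale (WO),
   grey wolf (GWO), ant colony (ACO) or particle swarm (PSO) — searches the
   space of non-empty feature subsets, minimizing

   `fitness(S) = w * err_KNN(S) + (1 - w) * |S| / D`

   where `err_KNN(S)` is the K-nearest-neighbour (K = 5) classification
   error on an internal validation split of the training data and
   `w = 0.99`. The size penalty breaks ties between equally accurate
   subsets toward the smaller one, which is why different optimizers return
   different subset sizes.
3. **Training and testing (TT).** An 80/20 stratified split; the classifier
   (a feed-forward network with hidden layers 500-250-125-50, or a linear
   one-vs-rest SVM) trains on the masked training rows and is scored on the
   masked test rows by testing accuracy (TA), precision (P), recall (R) and
   F1.

A nomination loop sweeps every optimizer x classifier combination and keeps
an incumbent that is replaced only when **all four** metrics strictly
improve. This conjunctive rule is deliberately preserved as stated rather
than replaced by a scalar criterion; its consequence — order-dependence when
two combinations are incomparable — is surfaced by logging the evaluation
order instead of being silently normalized.

## Swarm optimizers

All four share: population 10, 50 iterations (the reference setting), one
master seed spawning an independent substream per agent (so shrinking the
population does not reshuffle the survivors' draws), and elitism — the best
mask ever evaluated is what is returned, making the best-so-far trace
non-increasing by construction.

WO, GWO and PSO search in an unbounded continuous position space;
component `x_d` maps to a selection probability via the sigmoid transfer
`T(x) = 1/(1+e^{-x})` and bit `d` is drawn as `u_d < T(x_d)`. An all-zero
draw is repaired by forcing the single highest-probability feature on.
Positions initialize uniformly in (-1, 1), i.e. selection probabilities
start near 1/2.

- **WO** alternates (probability 1/2 each) between the logarithmic-spiral
  move toward the incumbent best, `x' = x* + |x* - x| e^{bl} cos(2 pi l)`
  with `l ~ U(-1,1)` and spiral constant `b = 1`, and the encircling move
  `x' = x* - A |C x* - x|` with per-dimension `A = 2ar_1 - a`, `C = 2r_2`
  and `a` annealed linearly from 2 to 0. Where `|A| >= 1` the reference
  point switches to a randomly chosen agent (exploration). Spiral-only
  whale search cannot explore, so the canonical two-phase form is used with
  the spiral as the bubble-net branch.
- **GWO** lets the three fittest agents (alpha, beta, delta) each propose
  `x_m - A|C x_m - x|` with fresh per-dimension coefficients; the agent
  moves to the mean of the proposals. Populations smaller than three use
  the leaders available.
- **PSO** uses `v' = omega v + c_1 r_1 (pbest - x) + c_2 r_2 (gbest - x)`,
  `x' = x + v'`, with `c_1 = c_2 = 2`, inertia annealed 0.9 -> 0.4 and
  velocities clamped to +/-6 — the scale at which the sigmoid saturates, so
  larger velocities would be invisible to binarization anyway.
- **ACO** has no natural tour over features, so the route-probability rule
  is specialized to a per-feature node formulation: ant `k` samples features
  without replacement with probability proportional to
  `tau_j^alpha * eta_j^beta` until a geometric stopping draw (probability
  `p_stop`, default `2/D` for an expected subset near `D/2`) fires. The
  heuristic desirability `eta_j` is a min-max-scaled one-way F statistic of
  feature `j` against the class labels, floored at 0.01 so no feature's
  sampling weight vanishes. After each iteration pheromone evaporates at
  rate `rho = 0.2` and the iteration-best mask deposits `Q/(fitness + eps)`
  on its features, clamped to `[0.01, 10]`.

Note an asymmetry this creates: ACO starts *informed* (its first constructions
already favour high-F features) while the position-based optimizers start
uniform. On easy problems ACO therefore often wins the sweep with very small
subsets, which is behaviourally correct but not a statement about the
algorithms' general merits.

## Fitness details

The internal validation scheme is a seeded stratified 80/20 holdout of the
data given to the optimizer (k-fold available). The split is drawn once per
run, so fitness is a pure function of the mask within a run and the elitist
trace is meaningful. Distances are Euclidean on raw feature values —
deep-feature activations share scale; descriptor features are designed to —
with an optional z-scoring flag. KNN vote ties break toward the
lexicographically smallest label, deterministically.

Every fitness evaluation can report the sample ids it touched through an
audit hook; `evaluate_combination` records them, and the test suite asserts
the recorded set is disjoint from the test partition. The pipeline splits
**before** selection, so the FS phase never sees test rows.

## Classifiers

The feed-forward network is the stated six-layer architecture: input `D`,
hidden 500/250/125/50 (ReLU), softmax output of one neuron per class.
Internals the architecture statement leaves open are set to standard
choices: cross-entropy loss, Adam updates (learning rate 1e-3), at most 200
epochs with patience-10 early stopping on a 10% validation slice, seeded
initialization and batching. The SVM alternative is a linear-kernel machine
(C = 1) in a one-vs-rest scheme — high-dimensional deep features are
typically linearly separable, making this the cheapest sound default. Both
learners z-score features on train-fitted statistics by default
(off-switchable).

## Metrics

All metrics derive from the `c x c` confusion matrix (rows = true class).
TA is overall correct over total. P, R and F1 use one-vs-rest per-class
counts; the default averaging is **macro** (unweighted mean over classes),
with micro available. Micro averaging makes P = R = TA in single-label
classification, so any report where P differs from TA is necessarily not
micro-averaged — the reason macro is the default here. A class never
predicted gets precision 0 (logged) so macro averages stay totals over all
classes. Per-class accuracy is the row-normalized diagonal, i.e. class
recall.

## Synthetic data

The generator emulates the *shape* of a deep-feature classification problem:
`k` informative columns drawn from class-conditional Gaussians, `D - k`
label-independent noise columns, all with SD `noise_sd`. Class means on the
informative axes sit at the vertices of a regular simplex scaled so every
pair of means is `separation * noise_sd` apart — one knob controls
difficulty, and all class pairs are equally hard. Class proportions are
uniform by default; the `"table2"` preset reproduces the real date-fruit
dataset's five class sizes (1811, 1385, 1295, 1424, 2157 of 8072:
Barhi, Khalas, Meneifi, Naboot Saif, Sullaj).

The desk-scale default is `n = 400, D = 64, k = 8, c = 5, noise_sd = 1`,
with `separation = 5.0` chosen by a one-time calibration scan so that a
K = 5 nearest-neighbour classifier using **all** features scores in the
0.80-0.95 holdout band across seeds (measured mean 0.91) — hard enough that
pruning the 56 noise columns helps, easy enough that the signal is
recoverable at this sample size.

What the generator does **not** emulate: correlated or redundant features,
heavy-tailed or rectified activation distributions, label noise, and
class-dependent covariance — all present in real CNN feature tables.
Passing tests therefore demonstrate that the search, fitness and evaluation
machinery behave correctly under controlled conditions, not that any
optimizer will match its published accuracy on the real image corpus.

The toy image generator draws clusters of ellipses with class-specific hue
and blob-count/size distributions on a 64x64 canvas. It exists so the
image -> descriptor -> selection -> training path can run end to end with no
external data; photorealism is a non-goal, and the descriptor's colour
histograms are expected to separate the classes nearly perfectly.

## Numerical and design choices

- **Split rounding.** Per class, the train share is `round(0.8 * n_c)`
  (half up), repaired so both sides keep at least one row; classes need
  at least 2 samples. Stratification is the default (the original 80/20
  protocol does not state it) with a flag to disable.
- **CSV precision.** Tables are written with `repr` floats (17 significant
  digits), so save -> load -> save is byte-identical and values round-trip
  exactly; loading uses the round-trip float parser.
- **Degenerate inputs.** Empty masks are unrepresentable (constructor
  rejects them); all-zero binarization draws are repaired; single-class
  tables are rejected by the optimizer and the classifiers; `iterations=0`
  returns the best of the random initial population.
- **Wall times** (FS, training, testing) are recorded in sweep records for
  reporting but never asserted — they are hardware facts, not properties of
  the method.
- **Problem sizes.** The shipped tests and the acceptance script run the
  reference swarm settings (10 agents, 50 iterations) on the desk-scale
  synthetic table and the 200-image toy set; these sizes keep a full run in
  the tens of seconds on one CPU while leaving every behavioural property
  (elitism, recovery, no-leakage, determinism) measurable.

## Known limitations

- The conjunctive nomination rule can fail to nominate anything if every
  combination has a zero metric; this raises an explicit `NominationError`
  rather than picking arbitrarily.
- ACO's informed initialization (F-statistic prior) makes cross-algorithm
  comparisons on easy synthetic problems lopsided; set `aco_beta=0` for an
  uninformed ant prior.
- The feed-forward network at its full 500-250-125-50 width is heavily
  over-parameterized for desk-scale tables; early stopping keeps this
  benign, but training-time comparisons against the SVM are not meaningful
  at these sizes.
- Wrapper selection with a KNN surrogate optimizes KNN-measured error; the
  selected subset is not guaranteed optimal for the downstream network/SVM,
  only empirically close.
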