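# Methods

`fitland` implements a model-guided protein design workflow: supervised
sequence-function predictors are trained on a local fitness landscape
(single and double mutants of a wild-type protein), and a stochastic search
uses those predictors to propose variants far beyond the training regime.
Because its scientific claims concern *extrapolation* — how far learned
landscapes remain trustworthy — the package ships a synthetic ground-truth
landscape simulator so that every stage can be exercised and measured
without experimental data.

## The landscape model

The synthetic ground truth assigns each variant `v` (a set of amino-acid
substitutions on a wild-type sequence of length L) the fitness

```
f(v) = b + Σ_(p,a)∈v  A[p,a] + Σ_{(p,a),(q,c)}⊆v  E[(p,a),(q,c)]
```

* `b` — baseline (wild-type) fitness, arbitrary units; default 0.
* `A[p,a]` — additive effect of amino acid `a` at position `p`, drawn
  `Normal(−0.5, 1.0)` with `A[p, wt_p] = 0`. The negative mean encodes the
  empirical rule that most mutations are destabilizing.
* `E` — sparse *specific* pairwise epistasis: each of the `C(L,2)·19²`
  candidate substitution pairs carries a term with probability
  `epistasis_density` (default 0.02), drawn `Normal(0, 1.0)`, and
  contributes only when **both** substitutions are present.

Measurement noise is additive Gaussian on the fitness scale
(`noise_sd`). The real assays the simulator emulates produce
log-enrichment scores with count-level noise; the sort-seq count simulator
(below) provides that alternative noise model. The synthetic scale is in
arbitrary units — no attempt is made to mimic a particular protein's
empirical effect-size distribution.

Dataset generators reproduce the two canonical data regimes:

* `sample_local_dataset` — the wild type, the complete `L·19` single-mutant
  scan, and a uniform random fraction of all double mutants (the
  deep-mutational-scanning regime used for training).
* `combinatorial_dataset` — the complete `20⁴ = 160,000`-member saturation
  library at four chosen sites (the extrapolation benchmark regime; 3- and
  4-mutants are outside a singles+doubles training set).

An important structural fact about the specific-epistasis model: in a
singles+doubles sample, each concrete pair term appears in **at most one**
record, so held-out pairwise epistasis is information-theoretically
unlearnable in that regime. Nonlinear models show their advantage on the
combinatorial library, where each pair term recurs across many 3-/4-mutant
backgrounds. Tests that compare architectures on epistatic ground truth use
the combinatorial regime for exactly this reason.

## Predictors

Four architectures with distinct inductive biases, plus ensembles:

| model | structure | bias |
|---|---|---|
| linear | one weight per (position, amino acid) + bias | purely additive; cannot express epistasis |
| FCN | dense layers (default 100×100, ReLU) on the flattened one-hot | site-specific but nonlinear |
| CNN | two 1-D convolutions (kernel 5, 32 filters) + dense head | parameter sharing along the sequence |
| GCN | two graph convolutions (32 channels) over a residue contact graph + dense head | parameter sharing over structural neighborhoods |

Inputs are one-hot encoded over the alphabetical 20-letter alphabet
(`ACDEFGHIKLMNPQRSTVWY`, frozen). Networks are float64 numpy
implementations with explicit backpropagation; training minimizes mean
squared error with Adam (default learning rate 1e-3, batch 64), records
per-epoch train/validation loss, early-stops on validation loss (patience
10), and restores the best-validation-epoch weights. The initialization
seed fully determines the initial parameters, so two builds with the same
seed are identical — this is what makes ensemble divergence a meaningful
measure of initialization-driven uncertainty.

The GCN propagator is the symmetrically normalized contact adjacency with
self-loops. Contact graphs are built from per-residue 3-D coordinates with
a default 8 Å cutoff (a standard alpha-carbon contact threshold); synthetic
workflows may instead pass an explicit adjacency, and the pipeline's
default stand-in is a compacted 3.8 Å-step random chain that yields both
sequential and long-range contacts.

**Ensembles.** `FitnessEnsemble` aggregates members that share
architecture, hyperparameters and training data and differ only in
initialization seed. The median readout (EnsM-style) is the average-case
prediction; the percentile readout with p = 5 (EnsC-style) is conservative:
95% of members predict at least its value. The percentile uses
lower-interpolation order statistics, so the conservative output is always
an actual member prediction and never exceeds the median. Library default
member count is 100; the scaled test/benchmark panels use 5 members (the
order-statistic properties and the divergence phenomenology do not depend
on the member count, only their resolution does).

## Simulated-annealing design at fixed distance

Design maximizes a model's predicted fitness over all variants at an
**exact** Hamming distance `k` from wild type:

* **Moves.** An exchange move reverts `m` existing substitutions and adds
  `m` new ones, `m ~ zero-truncated Poisson(λ=1)` (mean ≈ 1.582), clamped
  to `k`. New positions are uniform over positions currently wild-type
  *after* the reversion — the just-reverted positions stay eligible, which
  permits within-position amino-acid swaps and keeps the move kernel
  connected at fixed `k`. New residues are uniform over the 19
  non-wild-type amino acids.
* **Acceptance.** Improvements are always accepted; a move with fitness
  change ΔF ≤ 0 is accepted with probability `exp(ΔF/T)`.
* **Schedule.** T follows a log-linear (geometric) gradient from 10³ to
  10⁻⁵ over the run; at the final temperatures acceptance of any
  deterioration underflows to zero and the search becomes greedy.
* **Result.** A run returns the best-so-far variant, not the final state:
  the last steps are effectively greedy, but the best encountered design is
  the quantity of interest if the trajectory ends in an excursion.
  Model outputs are never clamped; extreme extrapolated predictions are
  passed through as-is, and non-finite outputs abort the run with
  diagnostics.

Campaigns run many independent chains (seed = base seed + run index). For
throughput, chains are advanced in lockstep groups so model evaluations are
batched; group membership is fixed by run index, so serial and parallel
execution give identical results. Default step counts follow a
per-combination table (10,000–50,000 steps) in which the smoothest
model/distance combinations use fewer steps: long anneals on near-additive
landscapes funnel all runs to the same optimum, leaving fewer unique
designs than the requested number of clusters (which is raised as an
explicit error rather than silently returning duplicates).

**Representative selection.** Final designs are deduplicated (keeping each
sequence's best predicted fitness), K-means-clustered on their flattened
one-hot encodings (k-means++ init, 10 restarts, fixed seed 0), and the
fittest member of each of the 41 (configurable) clusters is kept — a
diversity-preserving reduction of hundreds of runs to a synthesizable
panel. Within-cluster ties break deterministically by sequence string.

## Extrapolation metrics

* `stratified_spearman` — Spearman rank correlation between predicted and
  observed fitness computed separately within each mutation-count stratum
  (average-rank ties); strata below 3 members are reported as NaN, not
  dropped.
* `recall_at_budget` — the model ranks the population, nominates its top
  `N`, and recall is the fraction of the observed top 100 (configurable)
  captured. Ties break by a stable (score descending, variant label
  ascending) sort, making recall deterministic; the curve is non-decreasing
  in `N` and a perfect predictor reaches 100% at `N = 100`.
* `trajectory_divergence` / `ensemble_disagreement` — member-prediction
  matrices and spread statistics (population std, IQR, min/max) along a
  mutational pathway or over arbitrary sequences, with the median and lower
  5th-percentile rows as the ensemble readouts. Divergence growing with
  mutation count is the signature of initialization-dominated
  extrapolation.

## Sort-seq enrichment scoring

The screening arm turns sorted-population sequencing into per-design
scores. Reads are merged from a forward read and a reverse-complemented
reverse read at a predetermined offset, taking the higher-Phred base in the
overlap (ties → forward). Designs are counted by **exact** nucleotide
match only — synonymous controls are distinct designs by construction —
and designs with fewer than 10 unsorted reads are dropped (the wild type,
which anchors all normalizations, may never be dropped).

With `p_{x,i}` the proportion of design `i` in population `x` (u =
unsorted, d = display-only, b = binding; optionally l/w/h bins):

```
e_bind,i = log10(p_b,i / p_d,i) − log10(p_b,wt / p_d,wt)
e_disp,i = log10((w_b·p_b,i + w_d·p_d,i) / p_u,i) − (same term for wt)
e_x,i    = log10(p_x,i / p_u,i) − log10(p_x,wt / p_u,wt)
```

`(w_b, w_d)` are the relative FACS sizes of the binding and display-only
populations — experiment-specific configuration defaulting to (0.6, 0.4).
All scores are zero for the wild type by construction and invariant to
uniform scaling of any population's counts. A zero count in a score's
numerator or denominator is rescued by adding +1 to **both** members of
that design's population pair, with a flag column; this keeps scores finite
without shifting the wild-type normalization.

Designs are classified into quadrants (displays/not × binds/not) by
thresholds on (e_disp, e_bind), either supplied directly or derived from
calibration designs of known phenotype as the midpoint between the negative
and positive groups' mean scores; a score equal to its threshold counts as
positive. The finer 4-bin call (display-only / low / wild-type-like / high
binding) uses midpoints between adjacent calibration-bin means on a scalar
score.

The count simulator draws multinomial reads per population with design
weights `abundance`, `abundance·display·(1−bind)` and
`abundance·display·bind`; at depth 10⁶ and ~100 designs the recovered
e_bind ranking matches the true binding probabilities at Spearman ρ > 0.9
and replicate simulations correlate at Pearson r > 0.9 — these are the
package's stand-ins for assay reproducibility checks.

Titration curves are fit by least squares to the one-site isotherm
`s = Bmax·c/(KD + c)` (Hill coefficient fixed at 1, since only KD and the
maximal signal are treated as free parameters); all-zero signals degenerate
to Bmax = 0 with KD flagged undefined.

## Sequence analytics

Site diversity of design panels uses Shannon entropy per position in bits
(log₂; base configurable), bounded by log₂20 ≈ 4.32. Design-space maps use
metric MDS: SMACOF stress majorization (Guttman transform) on the pairwise
Hamming distance matrix, initialized from classical (Torgerson) MDS — the
majorization step never increases stress, giving a monotone stress
trajectory and a deterministic embedding. KEX2 protease sites are
operationalized as any `[KR]R` dipeptide (overlaps allowed); whether a site
is structurally *exposed* is outside the package's scope and documented as
a limitation. Reverse translation for oligo design is deterministic per
(sequence, variant index, seed), with distinct variant indices producing
distinct synonymous sequences whenever degenerate codons exist.

## Numerical and design choices

* Positions are 0-based internally and 1-based in mutation strings
  (`D23Y,M31C`) and all reports, matching protein conventions.
* All model math is float64. Batched and single-sequence predictions agree
  to ~1e-15 relative (BLAS batching changes summation order, so equality is
  numerical, not bitwise); campaign determinism is therefore defined at the
  fixed-chain-group level.
* Train/validation/test splits are random by variant, 80/10/10, seeded.
* Checkpoints are self-describing JSON (class, constructor parameters,
  weights, history), portable and diffable.
* Configuration is a validated YAML schema; unknown keys are rejected by
  name, and every pipeline output carries the seed and a configuration
  hash in a sidecar metadata file.

## Scaled benchmark conditions

The end-to-end benchmark (also run by `scripts/acceptance.py`) uses an
L=30 landscape with the generator defaults, singles + 2% of doubles
(noise sd 0.1) for training, an eight-model panel (linear, FCN, three
CNN initializations, GCN, and median/conservative ensembles over five
shared CNNs), and campaigns of 100 runs × 500 SA steps at distances
5–30 with 41 clusters. Distances are capped at L = 30 because a
fixed-distance design cannot exceed the protein length; the grid keeps the
8 × 6 × 41 = 1,968-design cardinality of the full-scale workflow. The
4-site recall benchmark enumerates the complete 160,000-variant library at
L = 18.

## What the synthetic tests do and do not show

The simulator reproduces the *structure* of the target experiments —
dense local training data, combinatorial extrapolation sets, count-based
sort-seq noise, epistatic ruggedness — but not real protein biophysics:
there is no folding thermodynamics, no correlation structure between
additive effects and burial/contact order, and Gaussian effect sizes
rather than the heavy-tailed, bimodal distributions real deep mutational
scans show. Passing tests therefore certify the algorithms (search,
scoring, metrics, statistics) and their contracts, not that any particular
architecture will extrapolate well on a real protein.

## Known limitations

* The GCN's contact graph is an input; no structure prediction is included.
* No GPU path; the numpy networks are sized for small proteins (L ≲ 100)
  and desk-scale ensembles.
* KEX2 detection is sequence-only (see above).
* Read processing supports predetermined-offset merging and exact matching
  only — no alignment, no barcode error correction, by design.
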