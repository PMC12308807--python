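# Methods

## Model

`ptsne` embeds n samples x_i ∈ R^m into R^d (d = 2 by default) with a
feedforward network f_w trained on the t-SNE objective.  The working
assumption is the one underlying all stochastic neighbor embeddings: the
scientifically relevant structure of the data is captured by *local*
neighborhoods, so an embedding that preserves each sample's effective
neighbor distribution preserves the metastable-state structure of an MD
trajectory.  The Student-t kernel's heavy tails allow dissimilar samples
to sit far apart in the embedding without incurring loss (the crowding
fix), which is what turns distinct free-energy basins into visually and
metrically separated islands.

Three properties matter for MD use and shape the implementation:

* **Parametric map.** The embedding is an explicit function, so frames
  outside the training set (longer simulations, new replicas) embed
  consistently.  `transform` is deterministic, row-wise, and independent
  of batch composition.
* **Per-batch affinities.** P is computed within each minibatch, never
  globally.  A global affinity matrix is quadratic in trajectory length;
  per-batch affinities keep training linear in n and are the only
  formulation in which the minibatch KL gradient is exact rather than an
  approximation of a global loss.
* **Calibrated bandwidths.** Each sample's Gaussian width σ_i is set by
  bisection so its conditional distribution's perplexity (base-2
  entropy exponentiated, 2^{H_i}) matches the target P.  Base-2 entropy
  makes "perplexity = effective neighbor count" exact.

## Affinity calibration

Row entropy is non-decreasing in σ, so the target perplexity is found by
bisection on log σ, vectorized over all rows in lockstep.  Defaults:
bracket [1e−20, 1e20] (widened by factors of e^10 if the target is not
bracketed), tolerance 1e−5 on the achieved perplexity, 200 iterations.
Exponentials are evaluated after subtracting each row's maximum exponent;
probabilities are floored at 1e−12 inside logarithms.  Degenerate rows are
handled rather than fatal: all-equal distance rows are pinned at
perplexity n−1 (any σ is a solution; a warning fires if the target is
unattainable), and a row whose off-diagonal exponentials are all zero
(infinite distances) falls back to uniform neighbor weights with a
warning.  Self-affinity is exactly zero throughout, and duplicates are
legal inputs.

## Loss and gradient

The loss is D_KL(P‖Q) in natural log (the base scales the loss, not the
optimum).  The gradient with respect to the embedded coordinates is the
closed form

    ∂D/∂z_i = (2(α+1)/α) Σ_j (p_ij − q_ij) (1 + ‖z_i−z_j‖²/α)^{−1} (z_i − z_j),

which reduces to the classic 4·Σ(p−q)(1+d²)^{−1}Δz at α = 1.  The network
(two hidden layers of width ⌊0.75·m⌋, rectifier activations, linear
output) is evaluated and differentiated in NumPy; `kl_gradient_check`
verifies the analytic gradient against central finite differences, and the
test suite additionally verifies the layer-parameter gradients the same
way.  Training is bitwise-reproducible for a fixed seed on a fixed
platform because all arithmetic is plain double-precision NumPy in a fixed
order.

α defaults to the embedding dimensionality d and is exposed; an optional
exaggeration multiplier on P exists but defaults to 1 (off).

## Training procedure and defaults

| parameter | default | meaning |
|---|---|---|
| perplexity | 30 | effective neighbors per sample |
| batch_size | 1000 | samples per minibatch (P calibrated per batch) |
| max_epochs | 500 | epoch cap |
| learning_rate | 1e−3 | Adam step size (β₁ = 0.9, β₂ = 0.999, ε = 1e−8) |
| val_fraction | 0.20 | held-out split, seeded shuffle |
| early_stop_delta | 1e−6 | convergence precision on validation loss |
| early_stop_patience | 10 | flat epochs that declare convergence |
| hidden_fractions | (0.75, 0.75) | hidden widths as fraction of input dim |
| alpha | d | Student-t degrees of freedom |
| standardize | on | per-feature z-scoring from the training split |

Features are standardized to zero mean and unit variance using training-
split statistics only (toggleable); distance and sin/cos features arrive
on very different scales, and an isotropic Gaussian affinity treats them
equitably only after scaling.

Each epoch reshuffles the training indices with the seeded generator and
cuts them into batches; a final partial batch smaller than
max(perplexity + 2, 16) is dropped, because perplexity calibration is
ill-posed when the target approaches the neighbor count.  Validation loss
is computed every epoch on the held-out split with its own per-batch P
(same batch size, fixed order).

**Early stopping** is a convergence criterion, not a best-model selector:
training stops once successive validation losses differ by less than
`early_stop_delta` for `early_stop_patience` consecutive epochs.  The
embedding KL characteristically passes through a long transient — loss
falls, rises while the embedding reorganizes, then falls to a better
optimum — and a "no improvement over the best" rule halts at the first
local minimum well before the map has formed.  Convergence-of-successive-
values rides through the transient and matches the intent of stopping at
a set precision.  Runs that never flatten stop at `max_epochs`.

Weights are initialized with He/Glorot scaling from the seeded generator;
no pretraining of any kind is used.  A NaN loss aborts with a diagnostic
rather than training on.

## Free-energy estimation

`free_energy` Boltzmann-inverts a 2-D histogram density:
F = −k_B·T·ln(ρ/ρ_max) with k_B = 0.0083144626 kJ/(mol·K), so F is in
kJ/mol, its minimum is 0 at the densest bin, and uniform density rescaling
leaves it unchanged.  The grid defaults to 64×64 bins over the data's
bounding box padded by 5%.  Bins never visited are *masked* (NaN), never
given an infinite value.  Per-sample weights are accepted as a forward
hook for reweighted (biased) ensembles; no reweighting scheme is
implemented.

`barrier_1d` reads a barrier directly off a bin path.  For data that
concentrate on a thin curve in the embedding plane, single-bin reads are
unreliable: a bin that the curve merely clips collects few samples for
geometric reasons and its inverted F spikes by k_B·T·ln(coverage ratio).
`profile_along_path` is the robust alternative — samples are assigned an
arc-length coordinate along a user-supplied polyline, histogrammed in 1-D,
and inverted — and is what the barrier-recovery checks use.  This is the
free-energy-profile-along-a-path construction standard in MD analysis.

## Synthetic data

The generators produce the statistical situations the method is built
for, with known ground truth:

* `make_gaussian_mixture` — k unit-variance isotropic clusters at
  mutually orthogonal means of norm `separation` (default 8, i.e.
  center-to-center distance 8√2 ≫ cluster width: unambiguously separated
  metastable states in feature space, with labels returned only for
  evaluation).
* `make_double_well_angles` — a Metropolis random walk on
  U(θ) = barrier·sin²θ (wells at 0°/180°, default barrier 6 kJ/mol,
  kT = 2.494 kJ/mol ≙ 300 K).  Metropolis sampling is deliberate: the
  output is a *correlated* trajectory like a real torsion trace, not
  i.i.d. draws.  Proposal std 60°, burn-in 1000, thinning 10 (all
  configurable); the proposal scale is chosen large enough that thinned
  samples decorrelate and the empirical histogram passes a
  goodness-of-fit test against the analytic stationary density.
* `make_toy_conformations` — random chains with unit bonds, fixed bond
  angle and uniform random torsions, placed by the natural-extension
  reference frame so the generating torsions are exactly recoverable;
  element labels alternate C/H to exercise heavy-atom selection.

What these fixtures do **not** emulate: anisotropic and curved basins,
state populations spanning orders of magnitude, slow degrees of freedom
entangled across many features, and thermostat/integrator artifacts of
real MD.  Passing tests demonstrate the machinery is correct on data
satisfying the method's assumptions; they do not guarantee embedding
quality on any particular force field or molecule.

## Problem sizes and verification scale

The test suite and the acceptance script run entirely on synthetic data at
desk scale: affinity oracles at n ≤ 8 against brute-force double loops;
calibration at n ∈ {100, 1000} for targets {5, 15, 30}; training on the
3-cluster fixture (300 samples, 10-D) across 5 seeds; barrier recovery
from 100,000 double-well samples; free-energy field recovery from 50,000
draws of a known 2-D Boltzmann density.  These sizes exercise every code
path while keeping a full run in minutes on one CPU.

## Known limitations

* Dense n_batch × n_batch affinities bound the practical batch size (a
  few thousand); no Barnes–Hut or nearest-neighbor approximations.
* Per-batch P means the effective objective depends mildly on batch
  composition; batch sizes well above the perplexity (the default 1000 ≫
  30) make this negligible, but very small batches distort neighborhoods.
* Validation KL on small validation batches is noisy and can drift
  upward even as embedding quality improves; with validation sets of
  hundreds of samples or more it tracks training loss.
* The embedding is only defined up to rotation/reflection and varies
  between seeds; downstream free-energy landscapes are invariant to that,
  barrier values are not tied to any fixed orientation.
* No topology awareness: featurization works on coordinates and index
  selections; bonded-structure parsing is out of scope.
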