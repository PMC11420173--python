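# Methods

## Model

A phenotype network (p-network) is a feedforward classifier. Its genome is a
set of generator networks (g-networks) plus any raw-stored tensors. Each
g-network is a small dense MLP with ReLU hidden units and an identity output
that maps the binary pair label of a (presynaptic, postsynaptic) neuron pair
to one connection strength; bias vectors are generated from the single
neuron's label. Labels are fixed, not learned:

* image pixels — Gray code of x then y (5 bits each at 28×28; width
  ⌈log2 side⌉ in general), so neighbouring pixels get labels differing in
  one bit;
* hidden units — plain binary index (order carries no meaning);
* classes — one-hot.

Bits are most-significant first; the pre label precedes the post label;
indices are 0-based. These conventions are stored in every genome checkpoint
so a decode is self-describing.

Genome size H(G) is the number of g-network parameters plus raw-stored
values; compression is p-network parameters / H(G), reported rounded half
away from zero.

### Accounting conventions

The parameter-count conventions are explicit `bias_mode` fields, not
hard-coded:

* dense configurations — weight g-nets and the hidden-bias g-net carry a
  bias on every layer (`all_layers`); the ten output-class biases are stored
  raw, since a g-network for them would cost more than ten values. With the
  bias net fixed at 10−5−1 this yields genome sizes 613 (GN5), 1,353 (GN20)
  and 1,973 (GN30) against the 636,010-parameter 784–800–10 classifier.
* convolutional configurations — nine `all_layers` weight g-nets
  (20-bit inputs) and nine 8−10−1 bias g-nets carrying only an output bias
  (`output_only`, 91 parameters each), yielding 3,798 / 9,378 / 14,958
  against the 1,369,738-parameter 9-layer all-convolutional classifier. The
  91-parameter bias-net decomposition is one of several structures
  consistent with the printed totals; only the totals constrain it. Note the
  last layer's bias labels are the 10-bit class one-hot at decode time while
  the accounting convention matches the other eight bias nets.

Convolutional layers participate in accounting and label schemes;
in-process training and decoding run on dense specs, which is all the
desk-scale experiments need.

## Intermittent training

Per outer iteration n (default 500 at full scale):

1. start the p-network from `W_n = ε(n)·W_{n−1} + (1−ε(n))·Ŵ_{n−1}`, the
   convex blend of last generation's trained weights and the genome decode,
   with `ε(n) = exp(−n/λ)` and ε(0) = 1 (a naive genome can never destroy
   the initial network). λ = 20 by default; λ = 0 disables annealing, i.e.
   every generation re-initialises directly from the decode. Biases are
   annealed identically to weights.
2. train on the task by minibatch SGD (momentum 0.9, learning rate 0.05,
   minibatch 128) on softmax cross-entropy for a fixed image budget
   (10,000 images at full scale), sampled uniformly without replacement.
3. regress each g-network onto the trained weights with Adam (learning rate
   1e-3) on mean squared error, over a seeded uniform sample of tensor
   entries (1e5 / 1e4 / 1e4 for the dense input-weight / output-weight /
   hidden-bias tensors at full scale; desk-scale tensors are enumerated
   exhaustively). Weight g-nets train 2 epochs with minibatch 100; bias
   g-nets 10 epochs with minibatch 10 — bias tensors are tiny and need the
   longer, finer recipe to track their targets. Adam moment state persists
   across generations.

All randomness fans out from one master seed through named child streams
(initialisation, image sampling, entry sampling, g-net shuffling), so runs
are exactly reproducible and ablations can perturb one stream at a time.

### Initialisation

P-networks and g-network hidden layers use scaled-uniform (Glorot) init. The
g-network *output* layer init is damped by 0.1 so a freshly initialised
genome generates near-zero weights. Without this, a naive genome decodes to
O(1) noise that exceeds the phenotype's weight scale and silences its ReLU
units — the failure mode that motivates annealing in deep stacks — and the
un-annealed loop can never start. This output-scaled initialisation is the
standard choice for networks whose outputs are another network's weights.

### Annealing versus inner budget

The two protection mechanisms trade off measurably. With annealing (λ = 20)
the desk-scale loop converges with a small inner budget (2,000 images ≈ 16
SGD steps per generation). With annealing disabled (λ = 0) each generation
must recover from the decode unaided: at the 2,000-image budget the loop
stalls at chance, while a recovery-scale budget (6,000 images, 100
generations) reaches the same innate accuracy as the annealed run. The
un-annealed full-scale recipe likewise relies on a large inner budget.

## Desk-scale study conditions

The synthetic task is a 10-class noisy-prototype image problem: each class
is a random smooth prototype (Gaussian field low-pass filtered at σ = 2
pixels, rescaled to [0, 1]) on a 12×12 grid; examples add iid Gaussian pixel
noise (σ = 0.5) and clip to [0, 1]; 2,000 training and 1,000 test examples,
class-balanced, disjoint by construction. The p-network is 144–32–10 (4,970
parameters). The capacity ladder keeps the published g-net hidden widths —
(10, 5), (20, 10), (30, 10) — over the narrower desk-scale label widths
(13-bit and 15-bit pair labels), giving genomes of 468 / 1,088 / 1,588
parameters. The nested loop runs 50 generations at a 2,000-image budget.

What the synthetic task emulates: a multi-class image problem with smooth
class-specific spatial structure, learnable to ~97% by the dense classifier,
where Gray-coded pixel labels give the g-network a usable notion of spatial
proximity. What it does not: the within-class style variability, stroke
topology and scale of handwritten digits. Passing desk-scale tests therefore
demonstrates the machinery (compression, innateness, controls) under
realistic statistical structure, not the published full-scale accuracies,
which require the external datasets and the full 500-iteration schedule.

Zero-shot accuracy across the ladder is non-decreasing at the documented
default seed; adjacent rungs can invert within seed variance at other seeds
(the tradeoff statement carries a one-seed-resample tolerance of 0.02).

## Survival and population model

Survival follows `p(t+1) = p(t)·[1 − α(1 − c(t))]`; for constant c this has
closed form `p(t) = p0·(1 − α(1 − c))^t`, which the implementation matches
to 1e-12 relative error. The population simulation is deterministic
proportional replacement: each generation a cohort's fraction is multiplied
by its survival-to-maturity and fractions are renormalised — no mutation,
drift or finite-population noise. The default two-cohort scenario (α = 0.02,
developmental horizon 20 steps, innate cohort at c = 0.9 from birth, learner
rising 0.1 → 0.9 with time constant 8) is illustrative: the published
figures print neither α nor the trajectories. Under it the innate cohort
passes 99% of the population at generation ~37.

## Analyses

* **MDS dimensionality.** Each hidden unit's incoming weight vector is one
  point; metric SMACOF (initialised from deterministic classical scaling, so
  curves are reproducible and non-increasing in dimension) embeds the points
  at dimensions 1–6 and Kruskal stress-1 is reported. Stress-1 is invariant
  to global rescaling of the weights. Genome-generated weights — outputs of
  a small smooth function of the labels — reach a given stress at no more
  dimensions than weights trained without compression. Degenerate inputs
  (all points identical) are rejected.
* **Hot-start alignment.** Fine-tuning curves (test accuracy per epoch) of
  genome-initialised versus randomly initialised networks are overlaid by
  the horizontal shift minimising RMS discrepancy (integer grid search,
  bounded continuous refinement, linear interpolation between samples). The
  aligned residual is compared against a noise floor estimated as the
  aligned residual between two randomly initialised runs with different
  seeds: the genome shifts the curve left without changing its shape.

## Numerical choices and limitations

* g-net regression loss is mean squared error (L1 available); g-net hidden
  activation is ReLU; outputs are unscaled signed reals (no per-layer
  normalisation).
* Evaluation disables dropout, so repeated evaluations agree exactly; argmax
  ties break toward the lowest class index.
* The image budget is consumed exactly; the final minibatch may be partial.
* Genome checkpoints (HDF5 tensors + YAML manifest) round-trip losslessly in
  float64.
* Fixed iteration counts, no early stopping — runs stay comparable.
* Full-scale dense/convolutional training runs are out of desk scope;
  the IDX reader accepts user-supplied files for full-scale reproduction.
* Reinforcement-learning applications and learned label assignments are out
  of scope.
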