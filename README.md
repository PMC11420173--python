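# genebottle

Genomic-bottleneck compression of neural-network connectivity.

## The problem

Animal genomes are far too small to specify brain wiring synapse by synapse,
yet animals are born with elaborate innate abilities. `genebottle` studies
this "genomic bottleneck" in the controlled setting of artificial networks:
can the weight matrix of a task-performing network (the **p-network**, for
*phenotype*) be squeezed through a much smaller **genome** — and decoded back
into a network that performs the task *with no training at all*?

The genome here is a set of small generator MLPs (**g-networks**). Every
neuron carries a fixed binary identity label (an abstraction of a molecular
expression profile): image pixels are labelled by Gray-coded x/y coordinates,
hidden units by plain binary indices, output classes by one-hot vectors. A
g-network reads the concatenated labels of a (pre, post) neuron pair —
20 bits in the standard configurations — and emits that connection's
strength. Genome size H(G) is the total g-network parameter count (plus any
raw-stored values); compression is p-network parameters / H(G).

Genome and phenotype are co-trained in a nested loop (**intermittent
training**): per generation, (1) the p-network starts from the annealed blend
`W_n = ε(n)·W_{n−1} + (1−ε(n))·Ŵ_{n−1}` with `ε(n) = exp(−n/λ)` of last
generation's trained weights and the genome's decode; (2) it trains on the
task for a fixed image budget; (3) each g-network regresses (mean squared
error) onto a sample of the trained weights, addressed by pair labels. The
decoded network's test accuracy with zero task training — its *innate*
performance — is logged every generation. A survival model
`p(t+1) = p(t)·[1 − α(1 − c(t))]` links innate performance c(t) to fitness
and shows why selection favours it.

## Worked example

Desk-scale run: a 10-class noisy-prototype image task (12×12 pixels), a
144–32–10 p-network (4,970 parameters) and a GN30-capacity genome
(1,588 parameters), co-trained for 50 generations:

```python
from genebottle.model import GenomicBottleneck

model = GenomicBottleneck.from_synthetic(seed=0)
results = model.fit(outer_iterations=50, image_budget=2000, lam=20.0,
                    master_seed=0)
print(results.summary())
```

```
Genomic bottleneck — intermittent training results
====================================================
p-network parameters             4,970
genome size H(G)                 1,588
compression                         3×
outer iterations                    50
zero-shot accuracy              0.7610
shuffled-weight control         0.1050
chance level                    0.1000
final trained accuracy          0.9470
```

The genome decodes to a network scoring 76% with zero training (chance is
10%); shuffling the decoded weights within each tensor collapses it to
chance, so the genome encodes position-specific wiring, not merely a weight
distribution.

The standard full-scale accounting (no training required) reproduces the
published genome sizes and compression ratios exactly:

```
$ genebottle account --family dense
config      genome       p-net   compression
GN5            613     636,010        1,038×
GN20         1,353     636,010          470×
GN30         1,973     636,010          322×

$ genebottle account --family conv
config      genome       p-net   compression
GN10         3,798   1,369,738          361×
GN30         9,378   1,369,738          146×
GN50        14,958   1,369,738           92×
```

Other CLI verbs: `train --config cfg.yaml` (see `examples/smoke.yaml`),
`zero-shot`, `transfer`, `evolve-sim`, `mds`, `synth-data`.

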