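"""Shared fixtures: the desk-scale study conditions.

The synthetic task (10 classes, 12×12 images, 2000/1000 train/test, noise
0.5) with a 144–32–10 p-network is the standing desk-scale condition; the
nested loop runs 50 outer iterations with a 2,000-image inner budget and
annealing constant λ=20. Expensive co-training runs are session-scoped so
every test that interrogates a trained genome shares the same one.
"""

import numpy as np
import pytest

from genebottle.model import GenomicBottleneck
from genebottle.tasks import build_pnet, train_pnet

TASK_SEED = 0
MASTER_SEED = 0
OUTER_ITERATIONS = 50
IMAGE_BUDGET = 2000

# weight g-net hidden widths across the genome-capacity ladder
LADDER = {"GN5": (10, 5), "GN20": (20, 10), "GN30": (30, 10)}


def _fit(weight_hidden, lam=20.0, outer=OUTER_ITERATIONS, budget=IMAGE_BUDGET):
    model = GenomicBottleneck.from_synthetic(weight_hidden=weight_hidden,
                                             seed=TASK_SEED)
    return model.fit(outer_iterations=outer, image_budget=budget, lam=lam,
                     master_seed=MASTER_SEED)


@pytest.fixture(scope="session")
def default_run():
    """GN30-capacity genome co-trained under the default conditions."""
    return _fit(LADDER["GN30"])


@pytest.fixture(scope="session")
def ladder_runs(default_run):
    """One co-trained genome per capacity rung, identical task and seeds."""
    runs = {"GN30": default_run}
    for name in ("GN5", "GN20"):
        runs[name] = _fit(LADDER[name])
    return runs


@pytest.fixture(scope="session")
def uncompressed_net(default_run):
    """A p-network trained directly (no genome) with the same total image
    budget as the nested loop consumed, on the same task."""
    model = default_run.model
    pnet = build_pnet(model.pnet_spec, seed=100)
    for i in range(OUTER_ITERATIONS):
        train_pnet(pnet, model.train_ds, IMAGE_BUDGET, seed=1000 + i)
    return pnet


@pytest.fixture(scope="session")
def finetune_curves(default_run):
    """Per-epoch test-accuracy curves: genome-initialised, and two
    randomly-initialised runs (the pair estimates the seed-noise floor)."""
    from genebottle.tasks import evaluate
    from genebottle.training import generate_pnet_weights

    model = default_run.model

    def curve(pnet, seed, n_epochs=12):
        rng = np.random.default_rng(seed)
        accs = [evaluate(pnet, model.test_ds)]
        for _ in range(n_epochs):
            train_pnet(pnet, model.train_ds, image_budget=len(model.train_ds),
                       seed=rng.integers(2**31))
            accs.append(evaluate(pnet, model.test_ds))
        return np.array(accs)

    genome_params = generate_pnet_weights(default_run.genome, model.pnet_spec)
    return {
        "genome": curve(build_pnet(model.pnet_spec, params=genome_params), 11),
        "random_a": curve(build_pnet(model.pnet_spec, seed=100), 11),
        "random_b": curve(build_pnet(model.pnet_spec, seed=200), 12),
    }
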