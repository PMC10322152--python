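"""Shared fixtures: planted worlds, ensembles and a trained state network.

Everything is generated programmatically with fixed seeds; expensive
artifacts are session-scoped so the suite builds them once.
"""

import numpy as np
import pytest

from statecoev import coevolution, state_classifier as sc, synthetic


@pytest.fixture(scope="session")
def classifier_world():
    """Five-state world with binary exclusive contacts (6 per state), shared
    background, and flexible pairs outside contact range."""
    world = synthetic.make_state_defs(L=60, n_exclusive=6, n_background=8,
                                      n_noise=20, seed=0)
    maps, dms, coords = synthetic.make_state_ensembles(
        world, L=60, n_per_state=5, noise_sd=0.5, seed=10,
        neighbor_distance=synthetic.BROKEN_DISTANCE, noise_range=(8.0, 18.0))
    cmap = synthetic.planted_coevolution_map(world, L=60, seed=0)
    return world, maps, dms, cmap


@pytest.fixture(scope="session")
def trained_net(classifier_world):
    world, maps, dms, cmap = classifier_world
    pairs = coevolution.top_pairs(cmap, 58)
    cfg = sc.StateNetConfig(filter_pairs=pairs, epochs=500, seed=0)
    net = sc.train_statenet(maps, cfg)
    return net, world, maps


@pytest.fixture(scope="session")
def potts_fit():
    """One planted Potts model, its Gibbs-sampled MSA and the fitted model
    (smaller than the acceptance-scale study for unit-test speed)."""
    world = synthetic.make_planted_potts(L=20, q=6, k=5, seed=0)
    aln = synthetic.sample_potts_msa(world.potts, n=800, seed=0)
    model = coevolution.fit_potts(aln, alphabet=world.potts.alphabet)
    return world, aln, model


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
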