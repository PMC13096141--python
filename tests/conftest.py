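import numpy as np
import pytest

from perturbrank import synth
from perturbrank.graphio import InteractionGraph, normalize_adjacency
from perturbrank.pipeline import RunConfig


@pytest.fixture
def chain_graph():
    """A -> B -> C."""
    return InteractionGraph(["A", "B", "C"], [(0, 1, "signaling", 1), (1, 2, "signaling", 1)])


@pytest.fixture
def fork_graph():
    """A -> {B, C}."""
    return InteractionGraph(["A", "B", "C"], [(0, 1, "ppi", 1), (0, 2, "ppi", 1)])


@pytest.fixture(scope="session")
def small_world():
    """A small but complete synthetic world for cross-module tests."""
    params = synth.GeneratorParams(
        n_proteins=60, n_tfs=10, n_drugs=12, targets_per_drug=2,
        n_train=4, n_test=2, noise_rate=0.0, seed=7,
    )
    return synth.make_benchmark(params)


@pytest.fixture(scope="session")
def small_adjacencies(small_world):
    g = small_world.world.graph
    return normalize_adjacency(g, "forward"), normalize_adjacency(g, "reverse")


def mini_params(seed: int = 3) -> synth.GeneratorParams:
    return synth.GeneratorParams(
        n_proteins=80, n_tfs=12, n_drugs=15, targets_per_drug=3,
        n_train=6, n_test=2, noise_rate=0.0, seed=seed,
    )


def mini_config(seed: int = 5) -> RunConfig:
    return RunConfig(
        vae_initial_hidden=64, vae_layers=2, vae_latent=8,
        vae_batch=128, vae_epochs=3,
        fnn_initial_hidden=32, fnn_layers=2, fnn_epochs=5,
        fnn_batches=(128, 128, 128), fnn_l1=0.0, fnn_l2=0.0,
        fnn_lr=0.002, trials=10, seed=seed,
    )
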