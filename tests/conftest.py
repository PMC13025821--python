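from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import settings

from herbwalk import GeneratorParams, build_transition, generate_study
from herbwalk.diffusion import TransitionSystem

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study():
    """Default synthetic study: network, disease set, herb truth labels."""
    return generate_study(GeneratorParams())


@pytest.fixture(scope="session")
def transition(study):
    network, _, _ = study
    return build_transition(network)


def random_transition_system(rng: np.random.Generator, n: int,
                             sink_fraction: float = 0.2) -> TransitionSystem:
    """A random row-stochastic system with some all-zero (sink) rows."""
    dense = np.zeros((n, n))
    sinks = np.zeros(n, dtype=bool)
    for i in range(n):
        if rng.random() < sink_fraction:
            sinks[i] = True
            continue
        k = int(rng.integers(1, min(n, 5) + 1))
        cols = rng.choice(n, size=k, replace=False)
        weights = rng.random(k) + 0.05
        dense[i, cols] = weights / weights.sum()
    if sinks.all():  # keep at least one live row
        sinks[0] = False
        dense[0, int(rng.integers(0, n))] = 1.0
    node_index = [f"N{i:03d}" for i in range(n)]
    kinds = ["protein"] * n
    return TransitionSystem(node_index=node_index, node_kinds=kinds,
                           matrix=sp.csr_matrix(dense), sinks=sinks)


def auroc(scores_positive, scores_negative) -> float:
    """Mann–Whitney AUROC: P(positive score > negative score) + tie credit."""
    wins = ties = 0
    for p in scores_positive:
        for q in scores_negative:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    total = len(scores_positive) * len(scores_negative)
    return (wins + 0.5 * ties) / total
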