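"""Biased random walk with restart over the multiscale interactome.

The walker moves on protein and function nodes only.  At each node the
outgoing probability mass is split among *transition classes* — protein to
protein, protein to function, function to protein, function to parent term,
function to child term — in proportion to configurable layer weights, then
uniformly among the edges inside each class.  Classes that have no edges at a
node cede their weight to the node's populated classes; a node with no
out-edges at all is a sink and its mass is re-injected through the restart
vector each iteration, so total probability is conserved.

The iteration computed here is

    r(k+1) = (1 - alpha) * s + alpha * (r(k) M + s * sum_{j in J} r_j(k))

until the L1 change falls below ``epsilon``.  ``alpha`` is the
walk-continuation weight (0.85 by default): with probability ``1 - alpha``
the walker restarts at the seed distribution ``s``.  The fixed point ``r`` is
the diffusion profile — a network-level signature of the seeded entity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .network_model import AbsentEntityError, DiseaseGeneSet, MultiscaleNetwork

logger = logging.getLogger(__name__)

TRANSITION_CLASSES = (
    "protein_protein",
    "protein_function",
    "function_protein",
    "function_parent",
    "function_child",
)


def default_layer_weights() -> dict[str, float]:
    """Unbiased defaults: every transition class carries weight 1."""
    return {cls: 1.0 for cls in TRANSITION_CLASSES}


@dataclass
class DiffusionConfig:
    """Walk parameters.

    alpha : float
        Walk-continuation weight in [0, 1]; ``1 - alpha`` is the per-step
        restart probability.
    epsilon : float
        L1 convergence tolerance on successive iterates.
    max_iterations : int
        Hard iteration cap; hitting it flags the profile as non-converged.
    layer_weights : dict
        Non-negative weight per transition class.
    """

    alpha: float = 0.85
    epsilon: float = 1e-6
    max_iterations: int = 500
    layer_weights: dict[str, float] = field(default_factory=default_layer_weights)

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        weights = dict(default_layer_weights())
        weights.update(self.layer_weights)
        unknown = set(weights) - set(TRANSITION_CLASSES)
        if unknown:
            raise ValueError(f"unknown transition classes: {sorted(unknown)}")
        if any(w < 0 for w in weights.values()):
            raise ValueError("layer weights must be non-negative")
        if all(w == 0 for w in weights.values()):
            raise ValueError("at least one layer weight must be positive")
        self.layer_weights = weights


@dataclass
class TransitionSystem:
    """Row-stochastic transition matrix over an ordered protein+function index."""

    node_index: list[str]
    node_kinds: list[str]
    matrix: sp.csr_matrix
    sinks: np.ndarray  # boolean mask over node_index

    def __post_init__(self) -> None:
        self._pos = {node: i for i, node in enumerate(self.node_index)}

    @property
    def n(self) -> int:
        return len(self.node_index)

    def index_of(self, node_id: str) -> int:
        return self._pos[node_id]

    def validate(self) -> None:
        rowsums = np.asarray(self.matrix.sum(axis=1)).ravel()
        live = ~self.sinks
        if not np.allclose(rowsums[live], 1.0, atol=1e-12):
            raise ValueError("non-sink rows must sum to 1")
        if np.any(rowsums[self.sinks] != 0):
            raise ValueError("sink rows must be all-zero")


@dataclass
class SeedVector:
    """Restart distribution over the transition system's node index."""

    s: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if np.any(self.s < 0):
            raise ValueError("seed entries must be non-negative")
        total = self.s.sum()
        if not np.isclose(total, 1.0, atol=1e-12):
            raise ValueError("seed vector must sum to 1")
        if not np.any(self.s > 0):
            raise ValueError("seed support must be non-empty")


@dataclass
class DiffusionProfile:
    """Stationary visit distribution for one seed set."""

    r: np.ndarray
    iterations_used: int
    final_l1_delta: float
    converged: bool = True


def _class_adjacency(network: MultiscaleNetwork) -> dict[str, dict[str, list[str]]]:
    """Per transition class, adjacency lists keyed by source node."""
    adj: dict[str, dict[str, list[str]]] = {cls: {} for cls in TRANSITION_CLASSES}

    def add(cls: str, src: str, dst: str) -> None:
        adj[cls].setdefault(src, []).append(dst)

    ppi = network.layers.get("ppi")
    if ppi is not None:
        for a, b in ppi.pairs:
            add("protein_protein", a, b)
            add("protein_protein", b, a)
    annot = network.layers.get("protein_function")
    if annot is not None:
        for protein, function in annot.pairs:
            add("protein_function", protein, function)
            add("function_protein", function, protein)
    hierarchy = network.layers.get("function_hierarchy")
    if hierarchy is not None:
        for child, parent in hierarchy.pairs:
            add("function_parent", child, parent)
            add("function_child", parent, child)
    return adj


def build_transition(
    network: MultiscaleNetwork, config: DiffusionConfig | None = None
) -> TransitionSystem:
    """Assemble the biased row-stochastic transition matrix M.

    Node order is all protein ids (sorted) followed by all function ids
    (sorted), which makes the system deterministic for a given network.
    """
    config = config or DiffusionConfig()
    proteins = network.protein_ids
    if not proteins:
        raise ValueError("network has no protein nodes")
    functions = network.function_ids
    node_index = proteins + functions
    node_kinds = ["protein"] * len(proteins) + ["function"] * len(functions)
    pos = {node: i for i, node in enumerate(node_index)}

    adj = _class_adjacency(network)
    weights = config.layer_weights
    by_kind = {
        "protein": ("protein_protein", "protein_function"),
        "function": ("function_protein", "function_parent", "function_child"),
    }

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    sinks = np.zeros(len(node_index), dtype=bool)
    for i, (node, kind) in enumerate(zip(node_index, node_kinds)):
        populated = [
            cls
            for cls in by_kind[kind]
            if weights[cls] > 0 and adj[cls].get(node)
        ]
        total = sum(weights[cls] for cls in populated)
        if total == 0:
            sinks[i] = True
            continue
        for cls in populated:
            neighbors = adj[cls][node]
            share = weights[cls] / total / len(neighbors)
            for neighbor in neighbors:
                rows.append(i)
                cols.append(pos[neighbor])
                vals.append(share)

    matrix = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(node_index), len(node_index))
    )
    ts = TransitionSystem(
        node_index=node_index, node_kinds=node_kinds, matrix=matrix, sinks=sinks
    )
    ts.validate()
    return ts


def diffuse(
    ts: TransitionSystem, seed: SeedVector, config: DiffusionConfig | None = None
) -> DiffusionProfile:
    """Iterate the restarting walk to its fixed point.

    Sink mass is routed back through the seed vector inside the walk term, so
    every iterate (and the fixed point) sums to exactly 1.
    """
    config = config or DiffusionConfig()
    s = seed.s
    if s.shape[0] != ts.n:
        raise ValueError("seed vector length does not match node index")
    alpha = config.alpha
    r = s.copy()
    if alpha == 0.0:
        return DiffusionProfile(r=r, iterations_used=1, final_l1_delta=0.0)
    sink_mask = ts.sinks
    mt = ts.matrix.T.tocsr()  # column-stochastic form; r_next = M^T r as columns
    delta = np.inf
    for iteration in range(1, config.max_iterations + 1):
        sink_mass = float(r[sink_mask].sum()) if sink_mask.any() else 0.0
        r_next = (1.0 - alpha) * s + alpha * (mt @ r + sink_mass * s)
        delta = float(np.abs(r_next - r).sum())
        r = r_next
        if delta <= config.epsilon:
            return DiffusionProfile(
                r=r, iterations_used=iteration, final_l1_delta=delta
            )
    warnings.warn(
        f"diffusion did not converge in {config.max_iterations} iterations "
        f"(L1 delta {delta:.3g})",
        RuntimeWarning,
        stacklevel=2,
    )
    return DiffusionProfile(
        r=r,
        iterations_used=config.max_iterations,
        final_l1_delta=delta,
        converged=False,
    )


def solve_fixed_point(
    ts: TransitionSystem, seed: SeedVector, config: DiffusionConfig | None = None
) -> np.ndarray:
    """Direct dense solve of the walk's fixed-point equation.

    Solves ``(I - alpha M^T - alpha s 1_J^T) r = (1 - alpha) s``; used as an
    independent check on the iterative solver for small systems.
    """
    config = config or DiffusionConfig()
    alpha = config.alpha
    s = seed.s
    n = ts.n
    dense = ts.matrix.toarray()
    sink_indicator = ts.sinks.astype(float)
    system = np.eye(n) - alpha * dense.T - alpha * np.outer(s, sink_indicator)
    return np.linalg.solve(system, (1.0 - alpha) * s)


def seed_from_proteins(
    proteins: Iterable[str], ts: TransitionSystem, *, entity: str = "entity"
) -> SeedVector:
    """Uniform restart distribution over the given proteins.

    Proteins absent from the node index are dropped with a warning; an empty
    surviving set raises :class:`AbsentEntityError`.
    """
    wanted = sorted(set(proteins))
    present = [p for p in wanted if p in ts._pos]
    missing = len(wanted) - len(present)
    if not present:
        raise AbsentEntityError(
            f"{entity!r} has no associated proteins in the network"
        )
    if missing:
        logger.warning("%s: %d seed proteins outside the network dropped",
                       entity, missing)
    s = np.zeros(ts.n)
    for p in present:
        s[ts.index_of(p)] = 1.0 / len(present)
    return SeedVector(s=s)


def seed_for_entity(
    entity_id: str,
    kind: str,
    network: MultiscaleNetwork,
    ts: TransitionSystem,
    disease: DiseaseGeneSet | None = None,
) -> SeedVector:
    """Restart vector for a herb, compound, or disease.

    Herbs seed at their retained top targets, compounds at their mapped
    target set, and the disease at its curated gene set.
    """
    if kind == "herb":
        proteins: Sequence[str] | set[str] = network.herb_targets.get(entity_id, [])
    elif kind == "compound":
        proteins = network.compound_targets.get(entity_id, set())
    elif kind == "disease":
        if disease is None:
            raise ValueError("disease seeding requires a DiseaseGeneSet")
        proteins = disease.proteins
    else:
        raise ValueError(f"cannot seed entity of kind {kind!r}")
    if not proteins:
        raise AbsentEntityError(f"{kind} {entity_id!r} has no mapped proteins")
    return seed_from_proteins(proteins, ts, entity=f"{kind}:{entity_id}")


def profile_similarity(r_c: DiffusionProfile, r_d: DiffusionProfile) -> float:
    """Pearson correlation between two diffusion profiles.

    Computed as the cosine of the mean-centered vectors; symmetric and
    invariant to common positive rescaling.  Raises ``ValueError`` when
    either profile has zero variance (the correlation is undefined).
    """
    a = np.asarray(r_c.r, dtype=float)
    b = np.asarray(r_d.r, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles live on different node indices")
    ac = a - a.mean()
    bc = b - b.mean()
    na = np.linalg.norm(ac)
    nb = np.linalg.norm(bc)
    if na == 0.0 or nb == 0.0:
        raise ValueError("correlation undefined: a profile has zero variance")
    return float(np.dot(ac, bc) / (na * nb))
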