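"""Planted-truth benchmarks and small hand-built model systems.

Real contextualization benchmarks start from a curated gene-regulatory
network that already explains two stable phenotypes (the gold standard) and
blindly expand it with literature-mined interactions, some of which are
inconsistent with the phenotypes.  ``generate_planted`` emulates that setup
synthetically: it draws a random signed network whose Boolean model has two
well-separated fixed points (the phenotypes), then adds spurious edges each
of which breaks the exact fixed-point property, so the full PKN scores
strictly below 1 while the planted true subnetwork scores exactly 1.

The module also ships the classic three-node didactic system

    a = b AND c,   b = NOT b,   c = a OR b

whose negation self-loop denies it any fixed point — every one of its 8
trajectories is cyclic — which exercises polynomial encoding and cycle
detection, and a two-node toggle switch whose two fixed points are exact
bitwise complements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import sympy

from .engine import FIXED_POINT, build_rules, run_to_attractor
from .fitness import score_subnetwork
from .network import (
    ACTIVATION,
    INHIBITION,
    Edge,
    Phenotype,
    PhenotypeSet,
    SignedDigraph,
)


class FixtureGenerationError(RuntimeError):
    """Raised when no instance satisfying the invariants could be planted."""


@dataclass(frozen=True)
class PlantedInstance:
    """A PKN hiding a known consistent subnetwork.

    Invariants enforced at construction: the true subnetwork's model has
    both phenotypes as exact fixed points (fitness 1), and the full PKN
    does not (fitness < 1); spurious edges never target input nodes, so the
    input set is identical for PKN and truth.
    """

    pkn: SignedDigraph
    true_subnetwork: SignedDigraph
    phenotypes: PhenotypeSet
    spurious_edges: frozenset[Edge]
    seed: int


def _find_phenotype_pair(
    rules, non_input_idx: list[int], rng: np.random.Generator, tries: int
) -> tuple[np.ndarray, np.ndarray] | None:
    """Two distinct fixed points differing on >= half the non-input nodes."""
    n = len(rules.nodes)
    need = math.ceil(len(non_input_idx) / 2)
    found: list[np.ndarray] = []
    for _ in range(tries):
        x = rng.integers(0, 2, size=n).astype(np.uint8)
        for seed_state in (x, (1 - x).astype(np.uint8)):
            traj = run_to_attractor(rules, seed_state, max_steps=200)
            if traj.outcome != FIXED_POINT:
                continue
            fp = rules.state_to_array(traj.attractor_state)
            if any(np.array_equal(fp, prev) for prev in found):
                continue
            for prev in found:
                diff = sum(int(fp[i] != prev[i]) for i in non_input_idx)
                if diff >= need:
                    return prev, fp
            found.append(fp)
    return None


def generate_planted(
    n_nodes: int,
    n_true_edges: int,
    n_spurious: int,
    n_inputs: int,
    seed: int = 0,
    *,
    activation_fraction: float = 0.7,
    max_topology_tries: int = 300,
    state_tries: int = 40,
) -> PlantedInstance:
    """Plant a consistent subnetwork inside a noisy PKN.

    Construction: (i) draw a random signed digraph in which ``n_inputs``
    nodes have in-degree 0 and every regulated node keeps at least one
    activator; (ii) relax random states (and their complements) under the
    model until two distinct fixed points differing on at least half the
    non-input nodes emerge — these become the two phenotypes; (iii) add
    ``n_spurious`` random signed edges, accepting a candidate edge only if
    the expanded network no longer has both phenotypes as exact fixed
    points.  Spurious edges are drawn with the same activation:inhibition
    ratio as the true edges and never target input nodes.  Exhausting the
    retry budgets raises, with a hint to try different sizes.

    With ``n_spurious = 0`` the PKN equals the truth and the score(PKN) < 1
    invariant is deliberately waived (a degenerate mode useful for plain
    dynamics tests).
    """
    if n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    if not (0 < n_inputs < n_nodes):
        raise ValueError("n_inputs must leave at least one regulated node")
    non_input_count = n_nodes - n_inputs
    if n_true_edges < non_input_count:
        raise ValueError(
            "n_true_edges must cover at least one activator per regulated node"
        )
    rng = np.random.default_rng(seed)
    names = [f"G{i + 1:02d}" for i in range(n_nodes)]

    for _attempt in range(max_topology_tries):
        perm = list(rng.permutation(n_nodes))
        inputs = [names[i] for i in perm[:n_inputs]]
        regulated = [names[i] for i in perm[n_inputs:]]

        edges: set[Edge] = set()
        for v in regulated:
            candidates = [u for u in names if u != v]
            u = candidates[rng.integers(len(candidates))]
            edges.add((u, v, ACTIVATION))
        guard = 0
        while len(edges) < n_true_edges and guard < 50 * n_true_edges:
            guard += 1
            u = names[rng.integers(n_nodes)]
            v = regulated[rng.integers(len(regulated))]
            sign = ACTIVATION if rng.random() < activation_fraction else INHIBITION
            edges.add((u, v, sign))
        if len(edges) != n_true_edges:
            continue

        true_net = SignedDigraph.from_edges(edges, nodes=names)
        rules = build_rules(true_net)
        non_input_idx = [i for i, n in enumerate(rules.nodes) if n not in inputs]
        pair = _find_phenotype_pair(rules, non_input_idx, rng, state_tries)
        if pair is None:
            continue
        phenotypes = PhenotypeSet(
            (
                Phenotype("stateA", rules.array_to_state(pair[0])),
                Phenotype("stateB", rules.array_to_state(pair[1])),
            )
        )
        if score_subnetwork(true_net, true_net, phenotypes).f != 1.0:
            continue  # defensive; fixed points guarantee this

        n_act = sum(1 for e in edges if e[2] == ACTIVATION)
        p_act = n_act / len(edges)
        spurious: set[Edge] = set()
        tries = 0
        while len(spurious) < n_spurious and tries < 200 * max(n_spurious, 1):
            tries += 1
            u = names[rng.integers(n_nodes)]
            v = regulated[rng.integers(len(regulated))]
            sign = ACTIVATION if rng.random() < p_act else INHIBITION
            e = (u, v, sign)
            if e in edges or e in spurious:
                continue
            cand = SignedDigraph.from_edges(edges | spurious | {e}, nodes=names)
            if score_subnetwork(cand, cand, phenotypes).f < 1.0:
                spurious.add(e)
        if len(spurious) < n_spurious:
            continue

        pkn = SignedDigraph.from_edges(edges | spurious, nodes=names)
        if score_subnetwork(pkn, true_net, phenotypes).f != 1.0:
            continue
        if n_spurious > 0 and score_subnetwork(pkn, pkn, phenotypes).f >= 1.0:
            continue
        return PlantedInstance(
            pkn=pkn,
            true_subnetwork=pkn.with_edges(edges),
            phenotypes=phenotypes,
            spurious_edges=frozenset(spurious),
            seed=seed,
        )

    raise FixtureGenerationError(
        "could not plant an instance with the requested sizes; try more nodes, "
        "fewer inputs, or fewer spurious edges"
    )


def planted_small(seed: int = 0) -> PlantedInstance:
    """Exhaustive-oracle tier: 6 nodes, 8 true + 4 spurious edges (2^12
    subnetworks enumerable in seconds)."""
    return generate_planted(
        n_nodes=6, n_true_edges=8, n_spurious=4, n_inputs=2, seed=seed
    )


def planted_medium(seed: int = 0) -> PlantedInstance:
    """Performance tier roughly matching a mid-sized curated network:
    40 nodes, ~240 PKN edges."""
    return generate_planted(
        n_nodes=40, n_true_edges=150, n_spurious=90, n_inputs=6, seed=seed
    )


class ToyOscillator:
    """The didactic three-node system with a bespoke AND.

        a' = b * c        (a = b AND c)
        b' = 1 - b        (b = NOT b)
        c' = a + b - a*b  (c = a OR b)

    The explicit functions cannot be produced by the OR-of-activators rule
    used for PKN-derived models (node ``a`` is an AND of two activators);
    the system is shipped verbatim because its negation self-loop makes
    every trajectory cyclic — a crisp oracle for cycle detection.
    """

    nodes = ("a", "b", "c")

    def __init__(self) -> None:
        a, b, c = sympy.symbols("a b c")
        self.symbols = (a, b, c)
        self.polynomials = {
            "a": b * c,
            "b": 1 - b,
            "c": a + b - a * b,
        }

    def update_array(self, x: np.ndarray) -> np.ndarray:
        a, b, c = (int(v) for v in x)
        return np.array([b * c, 1 - b, a + b - a * b], dtype=np.uint8)


def toy_oscillator() -> ToyOscillator:
    """The three-node demonstration system (no fixed point exists)."""
    return ToyOscillator()


def toy_topology() -> SignedDigraph:
    """The interaction graph underlying :func:`toy_oscillator`:
    b->a, c->a (activations feeding the AND), b -| b, a->c, b->c."""
    return SignedDigraph.from_edges(
        [
            ("b", "a", ACTIVATION),
            ("c", "a", ACTIVATION),
            ("b", "b", INHIBITION),
            ("a", "c", ACTIVATION),
            ("b", "c", ACTIVATION),
        ]
    )


def toggle_switch() -> tuple[SignedDigraph, PhenotypeSet]:
    """Mutual inhibition with self-activation: two complementary fixed points.

    Fixed points (A=1, B=0) and (A=0, B=1) are exact bitwise complements,
    which makes algebraic identities (phenotype flipping, role swapping)
    testable exactly.
    """
    net = SignedDigraph.from_edges(
        [
            ("A", "A", ACTIVATION),
            ("B", "B", ACTIVATION),
            ("A", "B", INHIBITION),
            ("B", "A", INHIBITION),
        ]
    )
    phenotypes = PhenotypeSet(
        (
            Phenotype("stateA", {"A": 1, "B": 0}),
            Phenotype("stateB", {"A": 0, "B": 1}),
        )
    )
    return net, phenotypes
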