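"""Fitness of a candidate subnetwork against Booleanized phenotypes.

Each phenotype is injected as the initial state of the candidate's Boolean
model and relaxed to an attractor.  If the trajectory ends in a fixed point
alpha, the phenotype phi is compared to alpha by the normalized Hamming
distance over the scored genes,

    h(phi, alpha) = (1/N_g) * sum_j |phi_j - alpha_j|,

and the overall fitness over the N_p phenotypes is

    f = 1 - (sum_i h_i) / N_p,

the fraction of gene states correctly explained by the model, in [0, 1].
A cyclic or truncated trajectory for any phenotype makes f = 0: the method
models stable phenotypes as point attractors only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .engine import (
    DEFAULT_MAX_STEPS,
    FIXED_POINT,
    RuleSet,
    build_rules,
    run_to_attractor,
)
from .network import Phenotype, PhenotypeSet, SignedDigraph

log = logging.getLogger(__name__)

INIT_ZERO = "zero"
INIT_RANDOM = "random"


def hamming(
    phi: Phenotype | Mapping[str, int],
    alpha: Mapping[str, int],
    genes: Iterable[str],
) -> float:
    """Normalized Hamming distance between two Boolean vectors on ``genes``."""
    states = phi.states if isinstance(phi, Phenotype) else phi
    gene_list = sorted(set(genes))
    if not gene_list:
        raise ValueError("cannot compute a Hamming distance over an empty gene set")
    mism = 0
    for g in gene_list:
        if g not in states:
            raise KeyError(f"gene {g!r} missing from phenotype vector")
        if g not in alpha:
            raise KeyError(f"gene {g!r} missing from attractor state")
        mism += abs(int(states[g]) - int(alpha[g]))
    return mism / len(gene_list)


@dataclass(frozen=True)
class PhenotypeResult:
    """Per-phenotype trajectory outcome and distance."""

    name: str
    outcome: str
    h: float | None
    steps: int


@dataclass(frozen=True)
class FitnessReport:
    """Overall fitness f plus the per-phenotype breakdown."""

    f: float
    per_phenotype: tuple[PhenotypeResult, ...]

    def to_dict(self) -> dict:
        return {
            "f": self.f,
            "per_phenotype": [
                {"phenotype": r.name, "outcome": r.outcome, "h": r.h, "steps": r.steps}
                for r in self.per_phenotype
            ],
        }


def initial_state_array(
    rules: RuleSet,
    phenotype: Phenotype,
    init_fill: str = INIT_ZERO,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Full network state seeded from a phenotype.

    Network nodes without a phenotype value are filled per the policy:
    ``zero`` (deterministic default) or ``random`` (Bernoulli(0.5) from
    ``rng``).  Phenotype genes absent from the network are ignored here;
    they are also excluded from scoring.
    """
    n = len(rules.nodes)
    if init_fill == INIT_ZERO:
        x = np.zeros(n, dtype=np.uint8)
    elif init_fill == INIT_RANDOM:
        if rng is None:
            raise ValueError("init_fill='random' requires an rng")
        x = rng.integers(0, 2, size=n).astype(np.uint8)
    else:
        raise ValueError(f"unknown init_fill policy {init_fill!r}")
    for i, node in enumerate(rules.nodes):
        if node in phenotype.states:
            x[i] = phenotype.states[node]
    return x


def score_rules(
    rules: RuleSet,
    phenotypes: PhenotypeSet,
    scored_genes: Iterable[str],
    init_fill: str = INIT_ZERO,
    rng: np.random.Generator | None = None,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> FitnessReport:
    """Score an already-built rule set (the inner loop of the optimizer)."""
    scored = sorted(set(scored_genes))
    if not scored:
        raise ValueError("scored_genes must be nonempty")
    node_set = set(rules.nodes)
    missing = [g for g in scored if g not in node_set]
    if missing:
        raise ValueError(f"scored genes absent from the network: {missing}")
    results = []
    total_h = 0.0
    any_non_fixed = False
    for phi in phenotypes:
        x0 = initial_state_array(rules, phi, init_fill=init_fill, rng=rng)
        traj = run_to_attractor(rules, x0, max_steps=max_steps)
        if traj.outcome == FIXED_POINT:
            h = hamming(phi, traj.attractor_state, scored)
            total_h += h
        else:
            h = None
            any_non_fixed = True
        results.append(PhenotypeResult(phi.name, traj.outcome, h, traj.steps_taken))
    f = 0.0 if any_non_fixed else 1.0 - total_h / phenotypes.n_p
    return FitnessReport(f=f, per_phenotype=tuple(results))


def score_subnetwork(
    pkn: SignedDigraph,
    subnetwork: SignedDigraph,
    phenotypes: PhenotypeSet,
    scored_genes: Iterable[str] | None = None,
    *,
    init_fill: str = INIT_ZERO,
    rng: np.random.Generator | None = None,
    max_steps: int = DEFAULT_MAX_STEPS,
    inputs_hold_state: bool = True,
) -> FitnessReport:
    """Fitness of a pruned subnetwork against the phenotypes.

    ``scored_genes`` defaults to the phenotype genes that are present in the
    network; phenotype genes missing from the PKN are dropped from scoring
    (with a warning) since the model carries no state for them.
    """
    rules = build_rules(pkn, subnetwork, inputs_hold_state=inputs_hold_state)
    if scored_genes is None:
        in_net = phenotypes.genes & pkn.nodes
        dropped = phenotypes.genes - pkn.nodes
        if dropped:
            log.warning(
                "%d phenotype gene(s) absent from the network are excluded "
                "from scoring: %s",
                len(dropped),
                sorted(dropped),
            )
        scored_genes = in_net
    return score_rules(
        rules,
        phenotypes,
        scored_genes,
        init_fill=init_fill,
        rng=rng,
        max_steps=max_steps,
    )
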