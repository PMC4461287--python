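"""Transient perturbations of contextualized networks.

A perturbation is an instantaneous flip of chosen genes' states applied to a
phenotype's state vector, after which the network updates freely (no
clamping).  Because input nodes hold their state, flipping an input is
effectively persistent while flipping a regulated node is transient.  The
reached attractor is classified against the expected target phenotype:
a run that comes back to the initial phenotype's own attractor "stayed",
a fixed point matching the target at or above the match threshold is the
expected transition, anything else is a different attractor or a
cyclic/truncated trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .engine import DEFAULT_MAX_STEPS, FIXED_POINT, build_rules, run_to_attractor
from .fitness import INIT_ZERO, hamming, initial_state_array
from .network import Phenotype, SignedDigraph

TRANSITION_MATCHED = "transition_matched"
STAYED_INITIAL = "stayed_initial"
OTHER_ATTRACTOR = "other_attractor"
CYCLIC_OR_TRUNCATED = "cyclic_or_truncated"


@dataclass(frozen=True)
class PerturbationSpec:
    """Genes to flip and the state each is forced into (1 or 0)."""

    flips: Mapping[str, int]

    def __post_init__(self) -> None:
        for gene, value in self.flips.items():
            if value not in (0, 1):
                raise ValueError(f"flip target for {gene!r} must be 0 or 1")
        object.__setattr__(self, "flips", dict(self.flips))

    @classmethod
    def activate(cls, *genes: str) -> "PerturbationSpec":
        return cls({g: 1 for g in genes})

    @classmethod
    def inactivate(cls, *genes: str) -> "PerturbationSpec":
        return cls({g: 0 for g in genes})


@dataclass(frozen=True)
class PerturbationOutcome:
    classification: str
    reached: "object"  # TrajectoryResult
    match_fraction: float | None

    def to_dict(self) -> dict:
        return {
            "classification": self.classification,
            "outcome": self.reached.outcome,
            "steps": self.reached.steps_taken,
            "match_fraction": self.match_fraction,
            "attractor": self.reached.attractor_state,
        }


def apply_perturbation(
    state: Mapping[str, int], spec: PerturbationSpec
) -> dict[str, int]:
    """Instantaneously set the listed genes; all other genes unchanged."""
    unknown = [g for g in spec.flips if g not in state]
    if unknown:
        raise KeyError(f"perturbed gene(s) not in the network state: {unknown}")
    out = dict(state)
    out.update(spec.flips)
    return out


def simulate_perturbation(
    network: SignedDigraph,
    pkn: SignedDigraph,
    initial_phenotype: Phenotype,
    spec: PerturbationSpec,
    target_phenotype: Phenotype,
    threshold: float,
    scored_genes: Iterable[str] | None = None,
    *,
    init_fill: str = INIT_ZERO,
    rng: np.random.Generator | None = None,
    max_steps: int = DEFAULT_MAX_STEPS,
    inputs_hold_state: bool = True,
) -> PerturbationOutcome:
    """Flip, relax, classify.

    ``threshold`` is the minimum fraction of scored genes that must agree
    with the target phenotype for the transition to count as matched; it is
    experiment-specific (exact match, 0.75 and 0.5 are all used in
    practice).  The reference "initial" attractor is obtained by relaxing
    the unperturbed initial state once.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    rules = build_rules(pkn, network, inputs_hold_state=inputs_hold_state)
    if scored_genes is None:
        scored_genes = (initial_phenotype.genes & target_phenotype.genes) & pkn.nodes
    scored = sorted(set(scored_genes))
    if not scored:
        raise ValueError("no scored genes shared by the phenotypes and the network")

    x0 = initial_state_array(rules, initial_phenotype, init_fill=init_fill, rng=rng)
    reference = run_to_attractor(rules, x0, max_steps=max_steps)

    perturbed = apply_perturbation(rules.array_to_state(x0), spec)
    traj = run_to_attractor(rules, perturbed, max_steps=max_steps)

    if traj.outcome != FIXED_POINT:
        return PerturbationOutcome(CYCLIC_OR_TRUNCATED, traj, None)

    match = 1.0 - hamming(target_phenotype, traj.attractor_state, scored)
    if reference.outcome == FIXED_POINT and all(
        reference.attractor_state[g] == traj.attractor_state[g] for g in scored
    ):
        return PerturbationOutcome(STAYED_INITIAL, traj, match)
    if match >= threshold:
        return PerturbationOutcome(TRANSITION_MATCHED, traj, match)
    return PerturbationOutcome(OTHER_ATTRACTOR, traj, match)


def perturbation_response_rate(
    networks: Iterable[SignedDigraph],
    pkn: SignedDigraph,
    initial_phenotype: Phenotype,
    spec: PerturbationSpec,
    target_phenotype: Phenotype,
    threshold: float,
    scored_genes: Iterable[str] | None = None,
    **kwargs,
) -> float:
    """Fraction of networks whose simulated response matches the target."""
    networks = list(networks)
    if not networks:
        raise ValueError("need at least one network")
    matched = 0
    for net in networks:
        outcome = simulate_perturbation(
            net,
            pkn,
            initial_phenotype,
            spec,
            target_phenotype,
            threshold,
            scored_genes,
            **kwargs,
        )
        if outcome.classification == TRANSITION_MATCHED:
            matched += 1
    return matched / len(networks)
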