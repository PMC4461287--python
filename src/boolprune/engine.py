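"""Synchronous Boolean dynamics derived from a signed network.

The model is inhibitor-dominant: a regulated node is active at the next step
iff at least one of its retained activators is active and none of its
retained inhibitors is.  In polynomial form, with OR encoded as
x + y - x*y and NOT as 1 - x, the update of node i is

    x_i' = OR(activators of i) * (1 - OR(inhibitors of i))

with the empty-activator OR equal to 0 and the empty-inhibitor factor equal
to 1.  All nodes update simultaneously (synchronous scheme).  Nodes with
in-degree zero in the *reference* PKN are treated as external inputs and
hold their state by default; the flag is recorded at rule-construction time
and inherited by every pruned subnetwork, so pruning all regulators of an
internal node makes it constant 0 rather than promoting it to an input.

Trajectories are iterated until a fixed point (x' = x), a revisit of an
earlier state (a cyclic attractor), or a step cutoff; exact state hashing
over a canonical sorted node order makes detection reproducible across
platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Protocol, runtime_checkable

import numpy as np

from .network import ACTIVATION, INHIBITION, SignedDigraph

FIXED_POINT = "fixed_point"
CYCLE = "cycle"
TRUNCATED = "truncated"

DEFAULT_MAX_STEPS = 1000


@runtime_checkable
class BooleanModel(Protocol):
    """Anything that can advance a Boolean state vector one synchronous step.

    ``nodes`` is the canonical (sorted) node order; ``update_array`` maps a
    uint8 vector in that order to the next state.
    """

    nodes: tuple[str, ...]

    def update_array(self, x: np.ndarray) -> np.ndarray: ...


class RuleSet:
    """Inhibitor-dominant update rules for every node of a network.

    Built from a subnetwork of a reference PKN; activator/inhibitor sets come
    from the subnetwork's edges while the input flags come from the PKN's
    in-degrees.
    """

    def __init__(
        self,
        nodes: tuple[str, ...],
        activators: Mapping[str, frozenset[str]],
        inhibitors: Mapping[str, frozenset[str]],
        inputs: frozenset[str],
        inputs_hold_state: bool = True,
    ) -> None:
        self.nodes = tuple(nodes)
        self.activators = {n: frozenset(activators.get(n, ())) for n in self.nodes}
        self.inhibitors = {n: frozenset(inhibitors.get(n, ())) for n in self.nodes}
        self.inputs = frozenset(inputs)
        self.inputs_hold_state = bool(inputs_hold_state)
        self._index = {n: i for i, n in enumerate(self.nodes)}
        n = len(self.nodes)
        act = np.zeros((n, n), dtype=np.int8)
        inh = np.zeros((n, n), dtype=np.int8)
        for tgt, regs in self.activators.items():
            for src in regs:
                act[self._index[tgt], self._index[src]] = 1
        for tgt, regs in self.inhibitors.items():
            for src in regs:
                inh[self._index[tgt], self._index[src]] = 1
        self._act = act
        self._inh = inh
        self._input_mask = np.zeros(n, dtype=bool)
        for node in self.inputs:
            self._input_mask[self._index[node]] = True

    # -- state plumbing ---------------------------------------------------

    def state_to_array(self, state: Mapping[str, int]) -> np.ndarray:
        try:
            vals = [state[n] for n in self.nodes]
        except KeyError as exc:
            raise KeyError(f"state is missing gene {exc.args[0]!r}") from None
        arr = np.asarray(vals, dtype=np.uint8)
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("state values must be 0 or 1")
        return arr

    def array_to_state(self, x: np.ndarray) -> dict[str, int]:
        return {n: int(v) for n, v in zip(self.nodes, x)}

    # -- dynamics ---------------------------------------------------------

    def update_array(self, x: np.ndarray) -> np.ndarray:
        act_hit = (self._act @ x) > 0
        inh_hit = (self._inh @ x) > 0
        nxt = (act_hit & ~inh_hit).astype(np.uint8)
        if self.inputs_hold_state:
            nxt[self._input_mask] = x[self._input_mask]
        return nxt

    def polynomial_update_array(self, x: np.ndarray) -> np.ndarray:
        """One step via the algebraic encoding (OR as a+b-ab, NOT as 1-x).

        Numerically equivalent to :meth:`update_array`; kept as an
        independent evaluation path for verification.
        """
        out = np.empty(len(self.nodes), dtype=np.uint8)
        for i, node in enumerate(self.nodes):
            if self.inputs_hold_state and node in self.inputs:
                out[i] = x[i]
                continue
            act_or = 0
            for src in sorted(self.activators[node]):
                v = int(x[self._index[src]])
                act_or = act_or + v - act_or * v
            inh_or = 0
            for src in sorted(self.inhibitors[node]):
                v = int(x[self._index[src]])
                inh_or = inh_or + v - inh_or * v
            out[i] = act_or * (1 - inh_or)
        return out

    # -- export -----------------------------------------------------------

    def to_text(self) -> str:
        """Human-readable rules, one line per node; inputs are marked."""
        lines = []
        for node in self.nodes:
            if node in self.inputs:
                lines.append(f"{node} = INPUT")
                continue
            acts = sorted(self.activators[node])
            inhs = sorted(self.inhibitors[node])
            expr = "(" + " | ".join(acts) + ")" if acts else "0"
            if inhs:
                expr += " & !(" + " | ".join(inhs) + ")"
            lines.append(f"{node} = {expr}")
        return "\n".join(lines) + "\n"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"RuleSet({len(self.nodes)} nodes, inputs={sorted(self.inputs)})"


def build_rules(
    pkn: SignedDigraph,
    subnetwork: SignedDigraph | None = None,
    inputs_hold_state: bool = True,
) -> RuleSet:
    """Derive update rules for ``subnetwork`` with input flags from ``pkn``.

    ``subnetwork`` defaults to the PKN itself.  Its edge set must be a
    subset of the PKN's and its node set identical (pruning removes edges
    only); a violation indicates a corrupted candidate and raises.
    """
    if subnetwork is None:
        subnetwork = pkn
    if subnetwork.nodes != pkn.nodes:
        raise ValueError("subnetwork must keep the PKN's full node set")
    if not subnetwork.edges <= pkn.edges:
        extra = sorted(subnetwork.edges - pkn.edges)[:3]
        raise ValueError(f"subnetwork has edges absent from the PKN, e.g. {extra}")
    nodes = pkn.sorted_nodes()
    activators: dict[str, set[str]] = {n: set() for n in nodes}
    inhibitors: dict[str, set[str]] = {n: set() for n in nodes}
    for src, tgt, sign in subnetwork.edges:
        (activators if sign == ACTIVATION else inhibitors)[tgt].add(src)
    inputs = frozenset(n for n, d in pkn.in_degree().items() if d == 0)
    return RuleSet(
        nodes,
        {n: frozenset(v) for n, v in activators.items()},
        {n: frozenset(v) for n, v in inhibitors.items()},
        inputs,
        inputs_hold_state=inputs_hold_state,
    )


def update_state(model: BooleanModel, state: Mapping[str, int]) -> dict[str, int]:
    """One synchronous step on a gene -> {0,1} mapping."""
    arr = _as_array(model, state)
    nxt = model.update_array(arr)
    return {n: int(v) for n, v in zip(model.nodes, nxt)}


@dataclass(frozen=True)
class TrajectoryResult:
    """Outcome of iterating a Boolean model from one initial state."""

    outcome: str  # fixed_point | cycle | truncated
    attractor_state: dict[str, int] | None
    steps_taken: int
    cycle_length: int | None = None

    @property
    def is_fixed_point(self) -> bool:
        return self.outcome == FIXED_POINT


def _as_array(model: BooleanModel, state: Mapping[str, int] | np.ndarray) -> np.ndarray:
    if isinstance(state, np.ndarray):
        if len(state) != len(model.nodes):
            raise ValueError("state vector length does not match model")
        return state.astype(np.uint8)
    if hasattr(model, "state_to_array"):
        return model.state_to_array(state)  # type: ignore[attr-defined]
    try:
        return np.asarray([state[n] for n in model.nodes], dtype=np.uint8)
    except KeyError as exc:
        raise KeyError(f"state is missing gene {exc.args[0]!r}") from None


def run_to_attractor(
    model: BooleanModel,
    x0: Mapping[str, int] | np.ndarray,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> TrajectoryResult:
    """Iterate synchronously until a fixed point, a revisit, or the cutoff.

    ``steps_taken`` is the number of updates needed to first reach the
    attractor state (0 if ``x0`` is already a fixed point).  A revisited
    non-fixed state at any period >= 2 classifies as a cycle; trajectories
    exceeding ``max_steps`` updates are reported truncated (and score zero
    downstream, like cyclic ones).
    """
    if max_steps < 1:
        raise ValueError("max_steps must be positive")
    x = _as_array(model, x0)
    visited: dict[bytes, int] = {x.tobytes(): 0}
    t = 0
    while t < max_steps:
        nxt = model.update_array(x)
        if np.array_equal(nxt, x):
            attractor = (
                model.array_to_state(x)
                if hasattr(model, "array_to_state")
                else {n: int(v) for n, v in zip(model.nodes, x)}
            )
            return TrajectoryResult(FIXED_POINT, attractor, steps_taken=t)
        key = nxt.tobytes()
        if key in visited:
            return TrajectoryResult(
                CYCLE, None, steps_taken=t + 1, cycle_length=t + 1 - visited[key]
            )
        visited[key] = t + 1
        x = nxt
        t += 1
    return TrajectoryResult(TRUNCATED, None, steps_taken=max_steps)
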