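"""State spaces and block decompositions for unidirectional multistate processes.

A multistate process lives on a finite state space ``{0, ..., N}`` with a set
of permitted direct transitions ``j -> k``.  The processes handled here are
*unidirectional*: no state can be revisited, i.e. the directed transition
graph is acyclic.  Two unique decompositions of such a graph drive the
blockwise inference strategies:

* **competing-risk blocks** -- one block per non-absorbing state, collecting
  all direct transitions out of that state (the competing causes); and
* **single-transition blocks** -- one block per permitted transition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from typing import Iterable, Mapping

__all__ = [
    "TransitionGraph",
    "CompetingRiskBlock",
    "TransitionBlock",
    "GraphValidationError",
    "validate_graph",
    "competing_risk_blocks",
    "single_transition_blocks",
    "five_state_progressive_graph",
    "five_state_extended_graph",
]

logger = logging.getLogger(__name__)


class GraphValidationError(ValueError):
    """A transition graph violates the unidirectional multistate contract."""


@dataclass(frozen=True)
class TransitionGraph:
    """State space plus permitted directed transitions.

    Parameters
    ----------
    transitions
        Permitted direct transitions as ordered pairs ``(j, k)``.
    states
        Optional explicit state labels; defaults to the states appearing in
        ``transitions``.  Extra (isolated) states are allowed.
    labels
        Optional display names per state; internal computation always uses
        the integer labels.
    """

    transitions: tuple[tuple[int, int], ...]
    states: tuple[int, ...] = ()
    labels: Mapping[int, str] | None = field(default=None, compare=False)

    def __init__(
        self,
        transitions: Iterable[tuple[int, int]],
        states: Iterable[int] | None = None,
        labels: Mapping[int, str] | None = None,
    ) -> None:
        trans = tuple(sorted({(int(j), int(k)) for j, k in transitions}))
        if states is None:
            st = sorted({s for jk in trans for s in jk})
        else:
            st = sorted({int(s) for s in states})
        object.__setattr__(self, "transitions", trans)
        object.__setattr__(self, "states", tuple(st))
        object.__setattr__(self, "labels", dict(labels) if labels else None)

    def __contains__(self, pair: tuple[int, int]) -> bool:
        return tuple(pair) in set(self.transitions)

    @property
    def absorbing_states(self) -> tuple[int, ...]:
        out = {j for j, _ in self.transitions}
        return tuple(s for s in self.states if s not in out)

    def successors(self, j: int) -> tuple[int, ...]:
        return tuple(k for jj, k in self.transitions if jj == j)

    def label(self, j: int) -> str:
        if self.labels and j in self.labels:
            return self.labels[j]
        return str(j)

    def to_edgelist(self) -> str:
        """Plain-text edge list (one ``j -> k`` per line) for provenance."""
        return "\n".join(f"{j} -> {k}" for j, k in self.transitions) + "\n"

    @classmethod
    def from_edgelist(cls, text: str) -> "TransitionGraph":
        pairs = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            j, k = line.replace("->", " ").split()
            pairs.append((int(j), int(k)))
        return cls(pairs)


@dataclass(frozen=True)
class CompetingRiskBlock:
    """All direct transitions out of one state, viewed as competing causes."""

    initial_state: int
    terminal_states: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "terminal_states", tuple(sorted(self.terminal_states)))
        if not self.terminal_states:
            raise GraphValidationError("competing-risk block needs >=1 terminal state")

    @property
    def transitions(self) -> tuple[tuple[int, int], ...]:
        return tuple((self.initial_state, k) for k in self.terminal_states)

    def __str__(self) -> str:
        return f"B{self.initial_state}->{{{','.join(map(str, self.terminal_states))}}}"


@dataclass(frozen=True)
class TransitionBlock:
    """A single permitted transition treated as a survival block."""

    from_state: int
    to_state: int

    @property
    def initial_state(self) -> int:
        return self.from_state

    @property
    def transitions(self) -> tuple[tuple[int, int], ...]:
        return ((self.from_state, self.to_state),)

    def __str__(self) -> str:
        return f"B{self.from_state}->{self.to_state}"


def validate_graph(graph: TransitionGraph) -> TransitionGraph:
    """Check the unidirectional multistate contract and return the graph.

    Raises
    ------
    GraphValidationError
        If a transition references an unknown state, the graph has a directed
        cycle (a reversible transition set), or no state is absorbing.
    """
    states = set(graph.states)
    for j, k in graph.transitions:
        if j not in states or k not in states:
            raise GraphValidationError(f"transition ({j},{k}) references unknown state")
        if j == k:
            raise GraphValidationError(f"self-transition ({j},{j}) not permitted")
    ts = TopologicalSorter({s: [] for s in graph.states})
    for j, k in graph.transitions:
        ts.add(k, j)
    try:
        order = list(ts.static_order())
    except CycleError as err:
        raise GraphValidationError(
            f"transition graph has a cycle (not unidirectional): {err.args[1]}"
        ) from err
    if not graph.absorbing_states:
        raise GraphValidationError("graph has no absorbing state")
    reachable = set()
    has_out = {j for j, _ in graph.transitions}
    entry_states = [s for s in graph.states
                    if s in has_out and all(k != s for _, k in graph.transitions)]
    frontier = list(entry_states)
    while frontier:
        s = frontier.pop()
        if s in reachable:
            continue
        reachable.add(s)
        frontier.extend(graph.successors(s))
    unreachable = states - reachable
    if unreachable:  # permissive: empty blocks, but worth flagging
        logger.warning("states %s are unreachable from any entry state", sorted(unreachable))
    del order
    return graph


def competing_risk_blocks(graph: TransitionGraph) -> list[CompetingRiskBlock]:
    """Decompose a validated graph into its competing-risk blocks.

    One block per non-absorbing state, ordered by initial-state label; the
    blocks partition the transition set by initial state.
    """
    validate_graph(graph)
    blocks = []
    for j in graph.states:
        terminals = graph.successors(j)
        if terminals:
            blocks.append(CompetingRiskBlock(j, terminals))
    return blocks


def single_transition_blocks(graph: TransitionGraph) -> list[TransitionBlock]:
    """One block per permitted transition, ordered by (from, to) label."""
    validate_graph(graph)
    return [TransitionBlock(j, k) for j, k in graph.transitions]


def five_state_progressive_graph(labels: Mapping[int, str] | None = None) -> TransitionGraph:
    """Five-state progressive multimorbidity scheme with eight transitions.

    State 0 is the entry condition, states 1 and 2 single added conditions,
    state 3 both conditions, state 4 the absorbing death state.
    """
    return TransitionGraph(
        [(0, 1), (0, 2), (0, 4), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4)],
        labels=labels,
    )


def five_state_extended_graph(labels: Mapping[int, str] | None = None) -> TransitionGraph:
    """The progressive scheme extended by the 0->3 and 1->2 shortcuts (10 transitions)."""
    base = five_state_progressive_graph().transitions
    return TransitionGraph(list(base) + [(0, 3), (1, 2)], labels=labels)
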