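"""Discrete Bayesian networks with exact inference by enumeration.

The networks used for evaluating source-attribution evidence are tiny
(three to six nodes, two or three states each), so inference is done the
transparent way: factorize the joint distribution by the chain rule and
sum it over all completions of the evidence.  Every quantity of interest
— a marginal, a posterior, the probability of a body of evidence — is a
ratio of two such sums.  No approximation, no message passing.

Conventions
-----------
* A node's CPT is a mapping from a tuple of parent-state labels (in the
  order of ``parents``) to a probability vector over the node's own
  states (in the order of ``states``).  Root nodes use the empty tuple.
* Evidence is a plain mapping ``{node name: state label}``.
* State labels keep their insertion order; results are keyed by label,
  never by index.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import (
    EvidenceError,
    ImpossibleEvidenceError,
    IncompleteAssignmentError,
    NetworkDefinitionError,
)

#: tolerance for CPT column / distribution normalization checks
NORM_TOL = 1e-9

Evidence = Mapping[str, str]


@dataclass(frozen=True)
class Violation:
    """One structural defect found by :func:`validate_network`."""

    node: str
    parent_states: tuple | None
    defect: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = f" | parents={self.parent_states}" if self.parent_states else ""
        return f"[{self.node}{where}] {self.defect}"


class DiscreteNode:
    """A named finite-state variable with a conditional probability table.

    Parameters
    ----------
    name:
        Unique identifier within the network.
    states:
        Ordered state labels; at least two.
    parents:
        Ordered names of parent nodes (empty for a root).
    cpt:
        ``{parent-state tuple: probability vector}``.  For a root node the
        single key is the empty tuple.  A bare sequence of probabilities is
        accepted for roots as a convenience.
    """

    def __init__(
        self,
        name: str,
        states: Sequence[str],
        parents: Sequence[str] = (),
        cpt: Mapping[tuple, Sequence[float]] | Sequence[float] | None = None,
    ) -> None:
        self.name = str(name)
        self.states = tuple(str(s) for s in states)
        self.parents = tuple(str(p) for p in parents)
        if len(set(self.states)) != len(self.states):
            raise NetworkDefinitionError(f"node {name!r}: duplicate state labels")
        if cpt is None:
            cpt = {}
        if not isinstance(cpt, Mapping):  # root-node shorthand
            cpt = {(): tuple(cpt)}
        self.cpt: dict[tuple, tuple[float, ...]] = {
            tuple(str(s) for s in key): tuple(float(p) for p in vec)
            for key, vec in cpt.items()
        }

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DiscreteNode({self.name!r}, states={self.states}, parents={self.parents})"

    def prob(self, own_state: str, parent_states: tuple) -> float:
        """P(node = own_state | parents = parent_states)."""
        try:
            vec = self.cpt[parent_states]
        except KeyError:
            raise NetworkDefinitionError(
                f"node {self.name!r}: no CPT column for parent states {parent_states}"
            ) from None
        return vec[self.states.index(own_state)]


@dataclass
class Distribution:
    """A probability distribution over the states of one variable."""

    variable: str
    probabilities: dict  # state label -> probability, insertion-ordered

    def __getitem__(self, state):
        return self.probabilities[state]

    def total(self) -> float:
        return float(sum(self.probabilities.values()))

    def as_dict(self) -> dict:
        return dict(self.probabilities)


class Network:
    """A directed acyclic graph of :class:`DiscreteNode` objects."""

    def __init__(self, nodes: Iterable[DiscreteNode] = ()) -> None:
        self.nodes: dict[str, DiscreteNode] = {}
        for node in nodes:
            self.add(node)

    def add(self, node: DiscreteNode) -> "Network":
        if node.name in self.nodes:
            raise NetworkDefinitionError(f"duplicate node name {node.name!r}")
        self.nodes[node.name] = node
        return self

    def __contains__(self, name: str) -> bool:
        return name in self.nodes

    def __getitem__(self, name: str) -> DiscreteNode:
        return self.nodes[name]

    # -- structure ---------------------------------------------------------

    def topological_order(self) -> list[str]:
        """Node names, parents before children.  Raises on cycles."""
        order: list[str] = []
        seen: dict[str, int] = {}  # 0 = visiting, 1 = done

        def visit(name: str, stack: tuple) -> None:
            state = seen.get(name)
            if state == 1:
                return
            if state == 0:
                cycle = " -> ".join(stack + (name,))
                raise NetworkDefinitionError(f"cycle detected: {cycle}")
            seen[name] = 0
            for parent in self.nodes[name].parents:
                if parent not in self.nodes:
                    raise NetworkDefinitionError(
                        f"node {name!r}: unknown parent {parent!r}"
                    )
                visit(parent, stack + (name,))
            seen[name] = 1
            order.append(name)

        for name in self.nodes:
            visit(name, ())
        return order

    # -- evidence handling -------------------------------------------------

    def _check_evidence(self, ev: Evidence) -> dict:
        checked = {}
        for name, state in ev.items():
            if name not in self.nodes:
                raise EvidenceError(f"evidence refers to unknown node {name!r}")
            node = self.nodes[name]
            if state not in node.states:
                raise EvidenceError(
                    f"node {name!r} has no state {state!r}; states are {node.states}"
                )
            checked[name] = state
        return checked

    # -- inference by enumeration -----------------------------------------

    def joint_probability(self, full_assignment: Evidence) -> float:
        """Chain-rule product P(x_1, ..., x_k) for a complete assignment."""
        assignment = self._check_evidence(full_assignment)
        missing = [n for n in self.nodes if n not in assignment]
        if missing:
            raise IncompleteAssignmentError(
                f"assignment misses nodes: {', '.join(missing)}"
            )
        prob = 1.0
        for name, node in self.nodes.items():
            parent_states = tuple(assignment[p] for p in node.parents)
            prob *= node.prob(assignment[name], parent_states)
            if prob == 0.0:
                return 0.0
        return prob

    def probability_of_evidence(self, ev: Evidence) -> float:
        """P(ev): the joint summed over every completion of the evidence."""
        assignment = self._check_evidence(ev)
        order = self.topological_order()

        def recurse(i: int, partial: dict, acc: float) -> float:
            if acc == 0.0:
                return 0.0
            if i == len(order):
                return acc
            name = order[i]
            node = self.nodes[name]
            parent_states = tuple(partial[p] for p in node.parents)
            if name in assignment:
                state = assignment[name]
                partial[name] = state
                out = recurse(i + 1, partial, acc * node.prob(state, parent_states))
                del partial[name]
                return out
            total = 0.0
            for state in node.states:
                p = node.prob(state, parent_states)
                if p == 0.0:
                    continue
                partial[name] = state
                total += recurse(i + 1, partial, acc * p)
                del partial[name]
            return total

        return recurse(0, {}, 1.0)

    def infer_posterior(self, query: str, ev: Evidence = ()) -> Distribution:
        """Posterior P(query | ev) by Bayes' theorem over the full joint."""
        ev = self._check_evidence(dict(ev) if not isinstance(ev, Mapping) else ev)
        if query not in self.nodes:
            raise EvidenceError(f"unknown query node {query!r}")
        if query in ev:
            raise EvidenceError(f"query node {query!r} is itself instantiated")
        numerators = {}
        for state in self.nodes[query].states:
            extended = dict(ev)
            extended[query] = state
            numerators[state] = self.probability_of_evidence(extended)
        total = sum(numerators.values())
        if total <= 0.0:
            raise ImpossibleEvidenceError(ev)
        return Distribution(query, {s: p / total for s, p in numerators.items()})

    def sequential_update(
        self, query: str, evidence_sequence: Sequence[Evidence]
    ) -> list[Distribution]:
        """Posterior of ``query`` after each cumulative prefix of evidence.

        Conditioning is order-invariant, so the final element equals the
        one-shot posterior given the union of all evidence batches.
        """
        cumulative: dict[str, str] = {}
        out = []
        for batch in evidence_sequence:
            for name, state in batch.items():
                if cumulative.get(name, state) != state:
                    raise EvidenceError(
                        f"conflicting evidence for node {name!r}: "
                        f"{cumulative[name]!r} vs {state!r}"
                    )
                cumulative[name] = state
            out.append(self.infer_posterior(query, dict(cumulative)))
        return out

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        """Serialize as ``{"nodes": [...]}`` with "|"-joined parent keys."""
        payload = {
            "nodes": [
                {
                    "name": node.name,
                    "states": list(node.states),
                    "parents": list(node.parents),
                    "cpt": {"|".join(key): list(vec) for key, vec in node.cpt.items()},
                }
                for node in self.nodes.values()
            ]
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, doc: str) -> "Network":
        payload = json.loads(doc)
        net = cls()
        for entry in payload["nodes"]:
            cpt = {
                tuple(key.split("|")) if key else (): vec
                for key, vec in entry["cpt"].items()
            }
            net.add(DiscreteNode(entry["name"], entry["states"], entry["parents"], cpt))
        return net


# ---------------------------------------------------------------------------
# module-level operation surface


def validate_network(net: Network) -> list[Violation]:
    """Collect every structural defect of ``net``; empty list means valid.

    Checks node-level CPT invariants (normalization, range, full coverage
    of the parent-state product) and network-level ones (resolvable
    parents, acyclicity, at least two states per node).  Diagnostic only:
    never raises.
    """
    violations: list[Violation] = []
    for node in net.nodes.values():
        if len(node.states) < 2:
            violations.append(Violation(node.name, None, "fewer than 2 states"))
        unresolved = [p for p in node.parents if p not in net.nodes]
        for p in unresolved:
            violations.append(Violation(node.name, None, f"unknown parent {p!r}"))
        if unresolved:
            continue
        expected = set(
            itertools.product(*(net.nodes[p].states for p in node.parents))
        )
        actual = set(node.cpt)
        for key in sorted(expected - actual):
            violations.append(Violation(node.name, key, "missing CPT column"))
        for key in sorted(actual - expected):
            violations.append(
                Violation(node.name, key, "CPT column for nonexistent parent states")
            )
        for key in sorted(expected & actual):
            vec = node.cpt[key]
            if len(vec) != len(node.states):
                violations.append(
                    Violation(node.name, key, "column length != number of states")
                )
                continue
            if any(p < 0.0 or p > 1.0 for p in vec):
                violations.append(Violation(node.name, key, "entry outside [0, 1]"))
            if not math.isclose(sum(vec), 1.0, abs_tol=NORM_TOL):
                violations.append(
                    Violation(
                        node.name, key, f"column not normalized (sum={sum(vec):.12g})"
                    )
                )
    try:
        net.topological_order()
    except NetworkDefinitionError as exc:
        violations.append(Violation("<network>", None, str(exc)))
    return violations


def joint_probability(net: Network, full_assignment: Evidence) -> float:
    return net.joint_probability(full_assignment)


def probability_of_evidence(net: Network, ev: Evidence) -> float:
    return net.probability_of_evidence(ev)


def infer_posterior(net: Network, query: str, ev: Evidence = ()) -> Distribution:
    return net.infer_posterior(query, ev)


def sequential_update(
    net: Network, query: str, evidence_sequence: Sequence[Evidence]
) -> list[Distribution]:
    return net.sequential_update(query, evidence_sequence)
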