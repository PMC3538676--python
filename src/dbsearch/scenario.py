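"""Scenario parameters and builders for the source-attribution networks.

A :class:`Scenario` is the triple (N, n, gamma) plus an optional prior
vector over the N potential sources:

* ``N`` — size of the closed population of potential sources,
* ``n`` — number of profiled individuals in the database (person 1, the
  suspect, plus persons 2..n), with 1 <= n <= N,
* ``gamma`` — the random match probability: the chance that a person
  other than the true source exhibits the crime-stain profile,
* ``priors`` — P(person i is the source), defaulting to the uniform 1/N.

Person 1 is always the suspect, persons 2..n the other database members,
persons n+1..N everyone outside the database.

Three builders return ready-to-query Bayesian networks:

* :func:`build_island_network` — no database; a single typed suspect.
* :func:`build_two_member_db_network` — the suspect plus exactly one
  other database member, with an explicit exclusion node ``X2``.
* :func:`build_general_db_network` — a database of any size n, with the
  n-1 non-suspect exclusions aggregated into one node.

Each builder folds N, n and gamma into the CPTs by default.  With
``explicit_roots=True`` they are instead materialized as discrete root
nodes (prior mass 1 on the scenario's value, alongside a small menu of
illustrative alternatives); both representations yield identical
posteriors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .bn import DiscreteNode, Network
from .errors import IdempotencyError, ScenarioError, WrongBuilderError

# canonical state labels
H1, H2, H3_N = "H1", "H2", "H3_N"
H2_N, HOUT = "H2_n", "Hn+1_N"
NOT_H1 = "not-H1"
MATCH, NO_MATCH = "match", "no-match"
NO_MATCH_ALL, SOME_MATCH = "no-match-all", "some-match"

# node names
NODE_H = "H"
NODE_M1 = "M1"
NODE_X2 = "X2"
NODE_X_ALL = "X2..Xn"
NODE_SUMMARY = "H1"

_PRIOR_TOL = 1e-9


@dataclass(frozen=True)
class Scenario:
    """A database-search setting: population, database, match rate, priors."""

    N: int
    gamma: float
    n: int = 1
    priors: tuple[float, ...] | None = None

    def __post_init__(self):
        if not (isinstance(self.N, int) and self.N >= 1):
            raise ScenarioError(f"N must be an integer >= 1, got {self.N!r}")
        if not (isinstance(self.n, int) and 1 <= self.n <= self.N):
            raise ScenarioError(f"n must satisfy 1 <= n <= N={self.N}, got {self.n!r}")
        if not (0.0 <= self.gamma <= 1.0):
            raise ScenarioError(f"gamma must lie in [0, 1], got {self.gamma!r}")
        if self.priors is not None:
            priors = tuple(float(p) for p in self.priors)
            object.__setattr__(self, "priors", priors)
            if len(priors) != self.N:
                raise ScenarioError(
                    f"priors must have length N={self.N}, got {len(priors)}"
                )
            if any(p < 0.0 for p in priors):
                raise ScenarioError("priors must be non-negative")
            if not math.isclose(sum(priors), 1.0, abs_tol=_PRIOR_TOL):
                raise ScenarioError(f"priors must sum to 1, got {sum(priors)!r}")

    # -- aggregated prior masses (person 1 | persons 2..n | persons n+1..N) --

    def prior(self, i: int) -> float:
        """P(person i is the source), 1-based index."""
        if not 1 <= i <= self.N:
            raise ScenarioError(f"person index {i} outside 1..{self.N}")
        if self.priors is None:
            return 1.0 / self.N
        return self.priors[i - 1]

    @property
    def pi_suspect(self) -> float:
        return self.prior(1)

    @property
    def pi_other_db(self) -> float:
        """Total prior mass on the other database members, persons 2..n."""
        if self.priors is None:
            return (self.n - 1) / self.N
        return float(sum(self.priors[1 : self.n]))

    @property
    def pi_outside(self) -> float:
        """Total prior mass on persons outside the database, n+1..N."""
        if self.priors is None:
            return (self.N - self.n) / self.N
        return float(sum(self.priors[self.n :]))

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "N": self.N,
            "n": self.n,
            "gamma": self.gamma,
            "priors": list(self.priors) if self.priors is not None else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        priors = d.get("priors")
        return cls(
            N=int(d["N"]),
            n=int(d.get("n", 1)),
            gamma=float(d["gamma"]),
            priors=tuple(priors) if priors is not None else None,
        )


# ---------------------------------------------------------------------------
# helpers for the explicit-root representation


def _root_menu(value, menu: Sequence) -> list[str]:
    """State labels for a root node: illustrative menu plus the actual value."""
    labels = [str(v) for v in menu]
    if str(value) not in labels:
        labels.append(str(value))
    return labels


def _degenerate_prior(labels: Sequence[str], value) -> dict:
    """All prior mass on the scenario's own value."""
    return {(): tuple(1.0 if lab == str(value) else 0.0 for lab in labels)}


def _uniform(k: int) -> tuple[float, ...]:
    return tuple(1.0 / k for _ in range(k))


# ---------------------------------------------------------------------------
# island model: a single typed suspect, no database


def build_island_network(sc: Scenario, explicit_roots: bool = False) -> Network:
    """Network for the island problem: nodes H and M1 (plus optional roots).

    ``H`` has states ``H1`` (the suspect is the source) and ``not-H1``
    (one of the other N-1 islanders is), with prior (pi_1, 1 - pi_1).
    ``M1`` records whether the suspect's profile corresponds to the
    crime stain: certain under H1, probability gamma otherwise.

    The database size ``n`` plays no role here.
    """
    pi1 = sc.pi_suspect
    g = sc.gamma
    net = Network()
    if not explicit_roots:
        net.add(DiscreteNode(NODE_H, (H1, NOT_H1), (), [pi1, 1.0 - pi1]))
        net.add(
            DiscreteNode(
                NODE_M1,
                (MATCH, NO_MATCH),
                (NODE_H,),
                {(H1,): (1.0, 0.0), (NOT_H1,): (g, 1.0 - g)},
            )
        )
        return net

    n_labels = _root_menu(sc.N, (2, 10, 100))
    g_labels = _root_menu(sc.gamma, (0.01, 0.1))
    net.add(DiscreteNode("N", n_labels, (), _degenerate_prior(n_labels, sc.N)))
    net.add(DiscreteNode("gamma", g_labels, (), _degenerate_prior(g_labels, sc.gamma)))
    h_cpt = {}
    for lab in n_labels:
        if lab == str(sc.N):
            h_cpt[(lab,)] = (pi1, 1.0 - pi1)
        else:
            h_cpt[(lab,)] = (1.0 / int(lab), 1.0 - 1.0 / int(lab))
    net.add(DiscreteNode(NODE_H, (H1, NOT_H1), ("N",), h_cpt))
    m_cpt = {}
    for lab in g_labels:
        gv = float(lab)
        m_cpt[(H1, lab)] = (1.0, 0.0)
        m_cpt[(NOT_H1, lab)] = (gv, 1.0 - gv)
    net.add(DiscreteNode(NODE_M1, (MATCH, NO_MATCH), (NODE_H, "gamma"), m_cpt))
    return net


# ---------------------------------------------------------------------------
# two-member database: suspect plus one other profiled individual


def build_two_member_db_network(sc: Scenario, explicit_roots: bool = False) -> Network:
    """Network for a database of exactly two: suspect and individual 2.

    ``H`` distinguishes three source propositions: the suspect (``H1``),
    the other database member (``H2``), and anyone outside the database
    (``H3_N``), with priors (pi_1, pi_2, sum_{i>2} pi_i).  ``X2`` records
    that individual 2's profile does NOT correspond (state ``no-match``
    first): impossible if 2 is the source, probability 1 - gamma
    otherwise.  ``M1`` is the suspect's correspondence as in the island
    model, adventitious (probability gamma) under both H2 and H3_N.
    """
    if sc.n != 2:
        raise WrongBuilderError(
            f"two-member builder requires n=2 (got n={sc.n}); "
            "use build_general_db_network for other database sizes"
        )
    pi1, pi2, pi3 = sc.pi_suspect, sc.pi_other_db, sc.pi_outside
    g = sc.gamma
    net = Network()
    states_h = (H1, H2, H3_N)
    if not explicit_roots:
        net.add(DiscreteNode(NODE_H, states_h, (), [pi1, pi2, pi3]))
        net.add(
            DiscreteNode(
                NODE_X2,
                (NO_MATCH, MATCH),
                (NODE_H,),
                {
                    (H1,): (1.0 - g, g),
                    (H2,): (0.0, 1.0),
                    (H3_N,): (1.0 - g, g),
                },
            )
        )
        net.add(
            DiscreteNode(
                NODE_M1,
                (MATCH, NO_MATCH),
                (NODE_H,),
                {
                    (H1,): (1.0, 0.0),
                    (H2,): (g, 1.0 - g),
                    (H3_N,): (g, 1.0 - g),
                },
            )
        )
        return net

    n_labels = _root_menu(sc.N, (10, 100))
    g_labels = _root_menu(sc.gamma, (0.01, 0.1))
    net.add(DiscreteNode("N", n_labels, (), _degenerate_prior(n_labels, sc.N)))
    net.add(DiscreteNode("gamma", g_labels, (), _degenerate_prior(g_labels, sc.gamma)))
    h_cpt = {}
    for lab in n_labels:
        if lab == str(sc.N):
            h_cpt[(lab,)] = (pi1, pi2, pi3)
        else:
            nn = int(lab)
            h_cpt[(lab,)] = (1.0 / nn, 1.0 / nn, (nn - 2) / nn)
    net.add(DiscreteNode(NODE_H, states_h, ("N",), h_cpt))
    x_cpt, m_cpt = {}, {}
    for lab in g_labels:
        gv = float(lab)
        x_cpt[(H1, lab)] = (1.0 - gv, gv)
        x_cpt[(H2, lab)] = (0.0, 1.0)
        x_cpt[(H3_N, lab)] = (1.0 - gv, gv)
        m_cpt[(H1, lab)] = (1.0, 0.0)
        m_cpt[(H2, lab)] = (gv, 1.0 - gv)
        m_cpt[(H3_N, lab)] = (gv, 1.0 - gv)
    net.add(DiscreteNode(NODE_X2, (NO_MATCH, MATCH), (NODE_H, "gamma"), x_cpt))
    net.add(DiscreteNode(NODE_M1, (MATCH, NO_MATCH), (NODE_H, "gamma"), m_cpt))
    return net


# ---------------------------------------------------------------------------
# general database of size n, exclusions aggregated


def _exclusion_prob(n: int, gamma: float, state: str) -> float:
    """P(none of persons 2..n matches | source group).

    Under H1 or Hn+1_N each of the n-1 profiled non-suspects matches
    adventitiously with probability gamma, independently, so all are
    excluded with probability (1-gamma)^(n-1).  Under H2_n the true
    source sits among them and matches with certainty, so the all-excluded
    event is impossible — except for n=1, where the conjunction is empty
    and trivially true under every proposition.
    """
    if n == 1:
        return 1.0
    if state == H2_N:
        return 0.0
    return (1.0 - gamma) ** (n - 1)


def build_general_db_network(sc: Scenario, explicit_roots: bool = False) -> Network:
    """Network for a database of any size n <= N.

    ``H`` has three states: ``H1`` (suspect), ``H2_n`` (one of the other
    n-1 database members) and ``Hn+1_N`` (someone outside the database),
    with priors (pi_1, sum_{2..n} pi_i, sum_{n+1..N} pi_i).  The n-1
    individual exclusions are aggregated into the single node ``X2..Xn``
    whose ``no-match-all`` state has probability (1-gamma)^(n-1) under H1
    and Hn+1_N and 0 under H2_n.  ``M1`` is the suspect's correspondence.

    For n=N the ``Hn+1_N`` state is kept with prior 0 so the CPT shape
    does not depend on the scenario.
    """
    pi1, pi2n, piout = sc.pi_suspect, sc.pi_other_db, sc.pi_outside
    g, n = sc.gamma, sc.n
    states_h = (H1, H2_N, HOUT)
    net = Network()
    if not explicit_roots:
        net.add(DiscreteNode(NODE_H, states_h, (), [pi1, pi2n, piout]))
        net.add(
            DiscreteNode(
                NODE_X_ALL,
                (NO_MATCH_ALL, SOME_MATCH),
                (NODE_H,),
                {
                    (s,): (_exclusion_prob(n, g, s), 1.0 - _exclusion_prob(n, g, s))
                    for s in states_h
                },
            )
        )
        net.add(
            DiscreteNode(
                NODE_M1,
                (MATCH, NO_MATCH),
                (NODE_H,),
                {
                    (H1,): (1.0, 0.0),
                    (H2_N,): (g, 1.0 - g),
                    (HOUT,): (g, 1.0 - g),
                },
            )
        )
        return net

    n_labels = _root_menu(sc.N, (100, 1000))
    db_labels = _root_menu(sc.n, (2, 10, 100))
    g_labels = _root_menu(sc.gamma, (0.01, 0.1))
    net.add(DiscreteNode("N", n_labels, (), _degenerate_prior(n_labels, sc.N)))
    net.add(DiscreteNode("n", db_labels, (), _degenerate_prior(db_labels, sc.n)))
    net.add(DiscreteNode("gamma", g_labels, (), _degenerate_prior(g_labels, sc.gamma)))
    h_cpt = {}
    for nlab in n_labels:
        for dlab in db_labels:
            nn, dd = int(nlab), int(dlab)
            if (nlab, dlab) == (str(sc.N), str(sc.n)):
                h_cpt[(nlab, dlab)] = (pi1, pi2n, piout)
            elif dd <= nn:
                h_cpt[(nlab, dlab)] = (1.0 / nn, (dd - 1) / nn, (nn - dd) / nn)
            else:
                # unreachable combination (database larger than population):
                # never selected by the degenerate roots, but the CPT column
                # must still be a valid probability vector
                h_cpt[(nlab, dlab)] = _uniform(3)
    net.add(DiscreteNode(NODE_H, states_h, ("N", "n"), h_cpt))
    x_cpt, m_cpt = {}, {}
    for s in states_h:
        for dlab in db_labels:
            for glab in g_labels:
                p = _exclusion_prob(int(dlab), float(glab), s)
                x_cpt[(s, dlab, glab)] = (p, 1.0 - p)
        for glab in g_labels:
            gv = float(glab)
            m_cpt[(s, glab)] = (1.0, 0.0) if s == H1 else (gv, 1.0 - gv)
    net.add(
        DiscreteNode(
            NODE_X_ALL, (NO_MATCH_ALL, SOME_MATCH), (NODE_H, "n", "gamma"), x_cpt
        )
    )
    net.add(DiscreteNode(NODE_M1, (MATCH, NO_MATCH), (NODE_H, "gamma"), m_cpt))
    return net


def attach_summary_node(net: Network) -> Network:
    """Add the binary summary node ``H1`` as a deterministic child of ``H``.

    The node collapses the three-way source proposition to "the suspect
    is / is not the source": state ``H1`` of H maps to ``H1``, every
    other state to ``not-H1``.  Conditioning on ``not-H1`` then
    redistributes H's mass proportionally over the non-suspect states,
    which is how the likelihood-ratio denominator is read off the
    network.  Modifies ``net`` in place and returns it.
    """
    if NODE_SUMMARY in net:
        raise IdempotencyError("summary node H1 is already present")
    h = net[NODE_H]
    cpt = {
        (s,): (1.0, 0.0) if s == H1 else (0.0, 1.0) for s in h.states
    }
    net.add(DiscreteNode(NODE_SUMMARY, (H1, NOT_H1), (NODE_H,), cpt))
    return net
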