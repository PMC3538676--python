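"""Closed-form posterior and likelihood-ratio calculators.

These are the algebraic counterparts of the Bayesian networks in
:mod:`dbsearch.scenario`; they serve both as a fast user-facing
calculator and as an independent check on the network inference path.

Notation (priors pi_i = P(person i is the source)):

* posterior after the suspect's match only::

      pi_1' = pi_1 / (pi_1 + gamma * (1 - pi_1))

* posterior after the match AND the exclusion of persons 2..n (the
  (1-gamma)^(n-1) exclusion factor cancels between numerator and
  denominator)::

      pi_1' = pi_1 / (pi_1 + gamma * sum_{i=n+1..N} pi_i)

* posterior after ONLY the exclusions (uniform priors: 1/(N-n+1))::

      pi_1* = pi_1 / (pi_1 + sum_{i=n+1..N} pi_i)

* the database-search likelihood ratio for the exclusion evidence::

      LR_DB = P(all excluded | H1) / P(all excluded | not H1)
            = (N-1)/(N-n)          (uniform priors, n < N)

  which does not depend on gamma, equals 1 for n=1 and is unbounded for
  n=N (every alternative source has been excluded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DBSearchError, ImpossibleEvidenceError
from .scenario import Scenario

EVIDENCE_MATCH = "{M1}"
EVIDENCE_EXCLUSIONS = "{X2..Xn}"
EVIDENCE_BOTH = "{M1, X2..Xn}"


@dataclass(frozen=True)
class PosteriorReport:
    """Posterior source probabilities for the three-way proposition."""

    scenario: Scenario
    evidence_label: str
    posterior_suspect: float
    posterior_other_db: float
    posterior_outside: float

    def as_dict(self) -> dict:
        return {
            "evidence": self.evidence_label,
            "posterior_suspect": self.posterior_suspect,
            "posterior_other_db": self.posterior_other_db,
            "posterior_outside": self.posterior_outside,
        }


@dataclass(frozen=True)
class LRReport:
    """The database-search likelihood ratio and its two ingredients."""

    scenario: Scenario
    numerator: float
    denominator: float
    ratio: float
    finite: bool

    def as_dict(self) -> dict:
        return {
            "numerator": self.numerator,
            "denominator": self.denominator,
            "ratio": self.ratio if self.finite else None,
            "finite": self.finite,
        }


def island_posterior(sc: Scenario) -> PosteriorReport:
    """Posterior that the suspect is the source given only his match.

    Assumes the suspect matches with certainty if he is the source; any
    other person matches with probability gamma.
    """
    pi1 = sc.pi_suspect
    denom = pi1 + sc.gamma * (1.0 - pi1)
    if denom <= 0.0:
        raise ImpossibleEvidenceError({"M1": "match"})
    post = pi1 / denom
    return PosteriorReport(sc, EVIDENCE_MATCH, post, 0.0, 1.0 - post)


def db_posterior(sc: Scenario) -> PosteriorReport:
    """Posterior for the suspect after his match and all n-1 exclusions.

    The common factor (1-gamma)^(n-1) cancels, leaving
    pi_1 / (pi_1 + gamma * sum_{i>n} pi_i).  The other database members
    are certainly excluded, so their posterior mass is zero.
    """
    pi1, piout = sc.pi_suspect, sc.pi_outside
    denom = pi1 + sc.gamma * piout
    if denom <= 0.0:
        raise ImpossibleEvidenceError({"M1": "match", "X2..Xn": "no-match-all"})
    post = pi1 / denom
    return PosteriorReport(sc, EVIDENCE_BOTH, post, 0.0, sc.gamma * piout / denom)


def exclusion_posterior(sc: Scenario) -> PosteriorReport:
    """Posterior for the suspect after ONLY the n-1 exclusions.

    Excluding persons 2..n renormalizes the prior over the survivors
    {1} and {n+1..N}; with uniform priors this is 1/(N-n+1).
    """
    pi1, piout = sc.pi_suspect, sc.pi_outside
    denom = pi1 + piout
    if denom <= 0.0:
        raise ImpossibleEvidenceError({"X2..Xn": "no-match-all"})
    return PosteriorReport(
        sc, EVIDENCE_EXCLUSIONS, pi1 / denom, 0.0, piout / denom
    )


def predictive_probabilities(sc: Scenario) -> dict:
    """Marginal and conditional predictive probabilities of the findings.

    Returns a mapping with four entries:

    * ``"P(M1)"`` — the suspect's profile corresponds, before any evidence;
    * ``"P(X)"`` — none of persons 2..n corresponds (for n=2 this is the
      single exclusion X2);
    * ``"P(X|M1)"`` — the exclusions given the suspect's match;
    * ``"P(M1|X)"`` — the suspect's match given the exclusions.

    Conditionals whose conditioning event has probability zero raise
    :class:`~dbsearch.errors.DBSearchError`.
    """
    pi1, pi2n, piout = sc.pi_suspect, sc.pi_other_db, sc.pi_outside
    g, n = sc.gamma, sc.n
    excl = (1.0 - g) ** (n - 1)
    p_match = pi1 + g * (pi2n + piout)
    p_excl = excl * (pi1 + piout) if n > 1 else 1.0
    p_joint = excl * (pi1 + g * piout) if n > 1 else p_match
    out = {"P(M1)": p_match, "P(X)": p_excl}
    if p_match <= 0.0:
        raise DBSearchError("P(X|M1) undefined: the match has probability zero")
    out["P(X|M1)"] = p_joint / p_match
    if p_excl <= 0.0:
        raise DBSearchError("P(M1|X) undefined: the exclusions have probability zero")
    out["P(M1|X)"] = p_joint / p_excl
    return out


def db_likelihood_ratio(sc: Scenario) -> LRReport:
    """The database-search likelihood ratio for the exclusion evidence.

    numerator   = P(all n-1 others excluded | suspect is the source)
                = (1-gamma)^(n-1)
    denominator = P(all excluded | suspect is not the source)
                = (1-gamma)^(n-1) * sum_{i>n} pi_i / sum_{i>1} pi_i

    Uniform priors give ratio (N-1)/(N-n): independent of gamma, 1 for
    n=1, and unbounded for n=N, where the exclusions leave the suspect
    as the only possible source — reported as ``finite=False`` with an
    infinite ratio rather than an error, since it is the meaningful
    limiting case.
    """
    pi2n, piout = sc.pi_other_db, sc.pi_outside
    g, n = sc.gamma, sc.n
    numerator = (1.0 - g) ** (n - 1)
    alternatives = pi2n + piout  # prior mass on "not the suspect"
    if n == sc.N or piout <= 0.0:
        return LRReport(sc, numerator, 0.0, math.inf, False)
    denominator = numerator * piout / alternatives
    return LRReport(sc, numerator, denominator, alternatives / piout, True)
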