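"""Individual-level brute-force reference model.

Instead of grouping the N potential sources into three propositions,
this module keeps every person i = 1..N as a distinct source hypothesis
and enumerates the match outcome of each of the n profiled individuals
explicitly.  The full joint table has N * 2^n rows; any posterior is a
ratio of row sums.  This is deliberately the dumbest correct computation
available and is used to validate both the grouped networks and the
closed forms on small instances.

Match outcomes of the N-n unprofiled individuals are never observed and
marginalize out exactly, so they are not enumerated.

Likelihood assignments per row (source = i, outcome of profiled person j):

* P(person j matches | source = j) = 1 (a perfectly accurate method),
* P(person j matches | source = i != j) = gamma, independently.
"""

from __future__ import annotations

import itertools

import pandas as pd

from .bn import Distribution
from .errors import ImpossibleEvidenceError, SizeCapError
from .scenario import Scenario

DEFAULT_CAP = 12


def enumerate_joint(sc: Scenario, cap: int = DEFAULT_CAP) -> pd.DataFrame:
    """Tabulate the full joint over (source, profiled-match outcomes).

    Returns a DataFrame with columns ``source`` (1..N), ``match_j`` for
    each profiled person j = 1..n (boolean: does j's profile correspond)
    and ``probability``.  Row probability is
    ``pi_i * prod_j P(match_j | source=i)``.

    Guarded by ``cap`` on both N and n (the table has N * 2^n rows);
    raise the cap explicitly for larger exact computations, or use the
    grouped network, which is equivalent and scenario-size independent.
    """
    if sc.N > cap or sc.n > cap:
        raise SizeCapError(
            f"N={sc.N}, n={sc.n} exceeds the enumeration cap {cap}; "
            "raise cap= or use the grouped network builders"
        )
    rows = []
    for source in range(1, sc.N + 1):
        pi = sc.prior(source)
        for outcomes in itertools.product((True, False), repeat=sc.n):
            p = pi
            for j, matched in enumerate(outcomes, start=1):
                if j == source:
                    p *= 1.0 if matched else 0.0
                else:
                    p *= sc.gamma if matched else 1.0 - sc.gamma
            rows.append((source, *outcomes, p))
    cols = ["source"] + [f"match_{j}" for j in range(1, sc.n + 1)] + ["probability"]
    return pd.DataFrame(rows, columns=cols)


def oracle_posterior(jt: pd.DataFrame, ev: dict[int, bool]) -> Distribution:
    """Exact posterior over the source index given observed match outcomes.

    ``ev`` maps a profiled person's index j (1-based) to the observed
    outcome (True = profile corresponds).  Unmentioned outcomes are
    marginalized by summation.
    """
    mask = pd.Series(True, index=jt.index)
    for j, matched in ev.items():
        col = f"match_{j}"
        if col not in jt.columns:
            raise KeyError(f"person {j} is not profiled in this joint table")
        mask &= jt[col] == bool(matched)
    sub = jt[mask]
    total = float(sub["probability"].sum())
    if total <= 0.0:
        raise ImpossibleEvidenceError(
            {f"match_{j}": str(v) for j, v in ev.items()}
        )
    by_source = sub.groupby("source")["probability"].sum()
    n_people = int(jt["source"].max())
    probs = {i: float(by_source.get(i, 0.0)) / total for i in range(1, n_people + 1)}
    return Distribution("source", probs)


def aggregate_posterior(dist: Distribution, n: int) -> dict:
    """Collapse a source-index posterior to the grouped H proposition.

    Sums index 1 (suspect), 2..n (other database members) and n+1..N
    (outside the database); matches the state labels of the general
    database network.
    """
    out = {"H1": 0.0, "H2_n": 0.0, "Hn+1_N": 0.0}
    for i, p in dist.probabilities.items():
        if i == 1:
            out["H1"] += p
        elif i <= n:
            out["H2_n"] += p
        else:
            out["Hn+1_N"] += p
    return out


def export_csv(jt: pd.DataFrame, path) -> None:
    """Write the joint table for inspection (columns: source, bits, prob)."""
    jt.to_csv(path, index=False, float_format="%.17g")
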