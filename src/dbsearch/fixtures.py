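"""Seeded random scenario generation for equivalence testing.

The generated scenarios stay within the exact-enumeration oracle's reach
(N <= 12) so that every fixture can be checked three ways: grouped
network, closed form, and full-joint enumeration.
"""

from __future__ import annotations

import numpy as np

from .scenario import Scenario

GAMMA_CHOICES = (0.5, 0.1, 0.01, 0.001)
#: fraction of fixtures that get a non-uniform prior vector
NONUNIFORM_FRACTION = 0.25


def generate_fixtures(seed: int, count: int) -> list[Scenario]:
    """Reproducible pseudo-random scenarios.

    N is drawn uniformly from 2..12, n uniformly from 1..N, gamma from
    {0.5, 0.1, 0.01, 0.001}; about a quarter of the scenarios receive a
    Dirichlet(1, ..., 1) prior vector instead of the uniform default.
    Identical seeds give identical lists.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed)
    scenarios = []
    for _ in range(count):
        N = int(rng.integers(2, 13))
        n = int(rng.integers(1, N + 1))
        gamma = float(rng.choice(GAMMA_CHOICES))
        priors = None
        if rng.random() < NONUNIFORM_FRACTION:
            vec = rng.dirichlet(np.ones(N))
            vec = vec / vec.sum()  # guard against float drift
            priors = tuple(float(p) for p in vec)
        scenarios.append(Scenario(N=N, n=n, gamma=gamma, priors=priors))
    return scenarios
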