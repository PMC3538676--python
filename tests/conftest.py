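import itertools

import pytest

from dbsearch import generate_fixtures

FIXTURE_SEED = 1234
FIXTURE_COUNT = 100


@pytest.fixture(scope="session")
def fixture_scenarios():
    """100 seeded random scenarios with N <= 12, for oracle equivalence."""
    return generate_fixtures(seed=FIXTURE_SEED, count=FIXTURE_COUNT)


def brute_force_evidence_probability(net, ev):
    """Independent P(evidence): multiply CPT entries over every full
    assignment consistent with the evidence, summing the products.

    Written against the raw CPT dictionaries with itertools only, so it
    shares no code path with the package's recursive enumeration.
    """
    names = list(net.nodes)
    total = 0.0
    for combo in itertools.product(*(net.nodes[n].states for n in names)):
        assignment = dict(zip(names, combo))
        if any(assignment[k] != v for k, v in ev.items()):
            continue
        p = 1.0
        for name in names:
            node = net.nodes[name]
            key = tuple(assignment[par] for par in node.parents)
            p *= node.cpt[key][node.states.index(assignment[name])]
        total += p
    return total
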