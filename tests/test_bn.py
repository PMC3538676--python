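"""Engine-level tests: validation, enumeration, posteriors, serialization."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from dbsearch import (
    DiscreteNode,
    EvidenceError,
    ImpossibleEvidenceError,
    IncompleteAssignmentError,
    Network,
    Scenario,
    build_general_db_network,
    build_island_network,
    infer_posterior,
    joint_probability,
    probability_of_evidence,
    sequential_update,
    validate_network,
)
from conftest import brute_force_evidence_probability


def island_100():
    return build_island_network(Scenario(N=100, gamma=0.01))


class TestValidateNetwork:
    def test_builder_output_is_valid(self):
        assert validate_network(island_100()) == []

    def test_unnormalized_column_reported(self):
        net = Network([DiscreteNode("A", ("a", "b"), (), [0.4, 0.5])])
        defects = [v.defect for v in validate_network(net)]
        assert any("not normalized" in d for d in defects)

    def test_cycle_reported(self):
        net = Network(
            [
                DiscreteNode("A", ("x", "y"), ("B",), {("x",): (1, 0), ("y",): (0, 1)}),
                DiscreteNode("B", ("x", "y"), ("A",), {("x",): (1, 0), ("y",): (0, 1)}),
            ]
        )
        defects = [v.defect for v in validate_network(net)]
        assert any("cycle" in d for d in defects)

    def test_missing_cpt_column_and_bad_entries(self):
        net = Network(
            [
                DiscreteNode("A", ("a", "b"), (), [0.5, 0.5]),
                DiscreteNode("B", ("u", "v"), ("A",), {("a",): (1.5, -0.5)}),
            ]
        )
        defects = [v.defect for v in validate_network(net)]
        assert any("missing CPT column" in d for d in defects)
        assert any("outside [0, 1]" in d for d in defects)


class TestJointProbability:
    @pytest.mark.parametrize(
        "h_state, expected",
        [("H1", 0.01 * 1.0), ("not-H1", 0.99 * 0.01)],
    )
    def test_chain_rule_product(self, h_state, expected):
        p = joint_probability(island_100(), {"H": h_state, "M1": "match"})
        assert p == pytest.approx(expected, abs=1e-15)

    def test_incomplete_assignment_rejected(self):
        with pytest.raises(IncompleteAssignmentError):
            joint_probability(island_100(), {"H": "H1"})

    def test_unknown_state_rejected(self):
        with pytest.raises(EvidenceError):
            joint_probability(island_100(), {"H": "H1", "M1": "maybe"})


class TestProbabilityOfEvidence:
    def test_three_person_match_marginal(self):
        net = build_general_db_network(Scenario(N=3, n=2, gamma=0.01))
        assert probability_of_evidence(net, {"M1": "match"}) == pytest.approx(0.34)

    def test_three_person_exclusion_marginal(self):
        net = build_general_db_network(Scenario(N=3, n=2, gamma=0.01))
        assert probability_of_evidence(net, {"X2..Xn": "no-match-all"}) == pytest.approx(
            0.66
        )

    def test_empty_evidence_totals_one(self):
        assert probability_of_evidence(island_100(), {}) == pytest.approx(1.0)

    def test_matches_independent_enumeration(self, fixture_scenarios):
        for sc in fixture_scenarios[:25]:
            net = build_general_db_network(sc)
            for ev in ({}, {"M1": "match"}, {"M1": "match", "X2..Xn": "no-match-all"}):
                assert probability_of_evidence(net, ev) == pytest.approx(
                    brute_force_evidence_probability(net, ev), abs=1e-14
                )


class TestInferPosterior:
    def test_island_match_posterior(self):
        dist = infer_posterior(island_100(), "H", {"M1": "match"})
        assert round(dist["H1"], 4) == 0.5025

    def test_no_evidence_returns_prior(self):
        dist = infer_posterior(island_100(), "H", {})
        assert dist["H1"] == pytest.approx(0.01, abs=1e-12)

    def test_distributions_normalized(self, fixture_scenarios):
        for sc in fixture_scenarios[:25]:
            net = build_general_db_network(sc)
            dist = infer_posterior(net, "H", {"M1": "match"})
            assert dist.total() == pytest.approx(1.0, abs=1e-9)
            assert all(0.0 <= p <= 1.0 for p in dist.probabilities.values())

    def test_impossible_evidence_raises_not_renormalizes(self):
        # everyone is in the database, yet we claim another member is the
        # source AND that all members were excluded: jointly impossible
        net = build_general_db_network(Scenario(N=5, n=5, gamma=0.01))
        with pytest.raises(ImpossibleEvidenceError) as exc:
            infer_posterior(net, "M1", {"X2..Xn": "no-match-all", "H": "H2_n"})
        assert "H2_n" in str(exc.value)


class TestSequentialUpdate:
    def test_three_person_walkthrough(self):
        """Exclude individual 2 first, then observe the suspect's match."""
        net = build_general_db_network(Scenario(N=3, n=2, gamma=0.01))
        steps = sequential_update(
            net, "H", [{"X2..Xn": "no-match-all"}, {"M1": "match"}]
        )
        assert steps[0]["H1"] == pytest.approx(0.5, abs=1e-12)
        assert round(steps[-1]["H1"], 6) == 0.990099

    def test_predictive_along_the_way(self):
        net = build_general_db_network(Scenario(N=3, n=2, gamma=0.01))
        p_joint = probability_of_evidence(
            net, {"M1": "match", "X2..Xn": "no-match-all"}
        )
        p_x = probability_of_evidence(net, {"X2..Xn": "no-match-all"})
        assert p_joint / p_x == pytest.approx(0.505, abs=1e-12)

    def test_order_invariance(self, fixture_scenarios):
        for sc in fixture_scenarios[:25]:
            net = build_general_db_network(sc)
            ev_a, ev_b = {"M1": "match"}, {"X2..Xn": "no-match-all"}
            forward = sequential_update(net, "H", [ev_a, ev_b])[-1]
            backward = sequential_update(net, "H", [ev_b, ev_a])[-1]
            one_shot = infer_posterior(net, "H", {**ev_a, **ev_b})
            for state in forward.probabilities:
                assert forward[state] == pytest.approx(one_shot[state], abs=1e-12)
                assert backward[state] == pytest.approx(one_shot[state], abs=1e-12)

    def test_conflicting_evidence_rejected(self):
        net = island_100()
        with pytest.raises(EvidenceError):
            sequential_update(net, "H", [{"M1": "match"}, {"M1": "no-match"}])


@st.composite
def random_chain_network(draw):
    """A -> B -> C chain with random state counts and random CPTs."""
    net = Network()
    parents = ()
    for name in "ABC":
        k = draw(st.integers(2, 3))
        states = tuple(f"{name.lower()}{i}" for i in range(k))
        keys = (
            [(s,) for s in net.nodes[parents[0]].states] if parents else [()]
        )
        cpt = {}
        for key in keys:
            raw = [
                draw(st.floats(0.01, 1.0, allow_nan=False)) for _ in range(k)
            ]
            total = sum(raw)
            cpt[key] = tuple(x / total for x in raw)
        net.add(DiscreteNode(name, states, parents, cpt))
        parents = (name,)
    return net


@settings(max_examples=50, derandomize=True, deadline=None)
@given(net=random_chain_network(), data=st.data())
def test_enumeration_agrees_with_brute_force_on_random_networks(net, data):
    """The recursive enumerator equals the flat product-sum on random CPTs."""
    ev_node = data.draw(st.sampled_from(list(net.nodes)))
    ev = {ev_node: net.nodes[ev_node].states[0]}
    assert probability_of_evidence(net, ev) == pytest.approx(
        brute_force_evidence_probability(net, ev), abs=1e-12
    )
    query = data.draw(st.sampled_from([n for n in net.nodes if n != ev_node]))
    dist = infer_posterior(net, query, ev)
    assert dist.total() == pytest.approx(1.0, abs=1e-9)
    for state in net.nodes[query].states:
        expected = brute_force_evidence_probability(
            net, {**ev, query: state}
        ) / brute_force_evidence_probability(net, ev)
        assert dist[state] == pytest.approx(expected, abs=1e-12)


class TestSerialization:
    def test_json_round_trip_is_lossless(self):
        net = build_general_db_network(Scenario(N=1000, n=100, gamma=0.01))
        clone = Network.from_json(net.to_json())
        assert clone.to_json() == net.to_json()
        ev = {"M1": "match", "X2..Xn": "no-match-all"}
        assert infer_posterior(clone, "H", ev)["H1"] == infer_posterior(
            net, "H", ev
        )["H1"]

    def test_explicit_roots_round_trip(self):
        net = build_island_network(Scenario(N=100, gamma=0.01), explicit_roots=True)
        clone = Network.from_json(net.to_json())
        assert clone.to_json() == net.to_json()


def test_folded_and_explicit_root_networks_agree():
    """Injecting N, n, gamma as root nodes or folding them into the CPTs
    must give identical posteriors."""
    for sc, builder in [
        (Scenario(N=100, gamma=0.01), build_island_network),
        (Scenario(N=100, n=2, gamma=0.01), build_general_db_network),
        (Scenario(N=1000, n=100, gamma=0.1), build_general_db_network),
    ]:
        folded = builder(sc)
        explicit = builder(sc, explicit_roots=True)
        assert validate_network(explicit) == []
        ev = {"M1": "match"}
        a = infer_posterior(folded, "H", ev)
        b = infer_posterior(explicit, "H", ev)
        for state in a.probabilities:
            assert a[state] == pytest.approx(b[state], abs=1e-12)
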