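"""Execution-graph engine: topology rules, scheduling, scaling, payloads."""

from __future__ import annotations

from collections import Counter, deque

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from riskstream import streamcore as sc


def node(name, kind, fn=None, **kw):
    return sc.NodeSpec(name, sc.NodeKind(kind), fn=fn, **kw)


def identity(payload, key):
    return [payload]


# ---------------------------------------------------------------------------
# Topology construction


class TestBuildTopology:
    def test_minimal_pipeline(self):
        g = sc.build_topology(
            [node("A", "source"), node("B", "middle"), node("C", "leaf")],
            [("A", "B"), ("B", "C")],
        )
        assert len(g.edges) == 2
        assert g.inbound("B") == [("A", "B")]

    def test_cycle_between_middles_is_accepted(self):
        # data may be sent back to a previous stage
        g = sc.build_topology(
            [node("A", "source"), node("B", "middle"), node("B2", "middle"),
             node("C", "leaf")],
            [("A", "B"), ("B", "B2"), ("B2", "B"), ("B", "C")],
        )
        assert ("B2", "B") in g.edges

    def test_unknown_node_rejected(self):
        with pytest.raises(sc.ConfigurationError, match="unknown node"):
            sc.build_topology([node("A", "source")], [("A", "X")])

    def test_duplicate_names_rejected(self):
        with pytest.raises(sc.ConfigurationError, match="duplicate"):
            sc.build_topology([node("A", "source"), node("A", "leaf")], [])

    @pytest.mark.parametrize(
        "edges, err",
        [
            ([("B", "A")], "source"),  # inbound into a source
            ([("C", "B")], "leaf"),  # outbound from a leaf
        ],
    )
    def test_degree_rules(self, edges, err):
        nodes = [node("A", "source"), node("B", "middle"), node("C", "leaf")]
        with pytest.raises(sc.TopologyError, match=err):
            sc.build_topology(nodes, edges)

    def test_zero_instances_rejected(self):
        with pytest.raises(sc.ConfigurationError, match="instances"):
            node("A", "middle", instances=0)
        g = sc.build_topology([node("A", "source")], [])
        with pytest.raises(sc.ConfigurationError):
            sc.scale_node(g, "A", 0)

    def test_from_declarative_config(self):
        g = sc.topology_from_config(
            {
                "nodes": [
                    {"name": "src", "kind": "source"},
                    {"name": "mid", "kind": "middle", "instances": 3,
                     "policy": "exponential", "priorities": {"src->mid": 1}},
                    {"name": "out", "kind": "leaf", "stateful": True},
                ],
                "edges": [["src", "mid"], ["mid", "out"]],
            }
        )
        assert g.nodes["mid"].instances == 3
        assert g.nodes["mid"].input_policy.mode is sc.InputMode.EXPONENTIAL
        assert g.nodes["out"].stateful


# ---------------------------------------------------------------------------
# Running


class TestRunTopology:
    def test_order_preserved_through_identity_middle(self):
        g = sc.build_topology(
            [node("src", "source", fn=[1, 2, 3]),
             node("mid", "middle", fn=identity),
             node("out", "leaf", fn=identity)],
            [("src", "mid"), ("mid", "out")],
        )
        res = sc.run_topology(g)
        assert [e.payload for e in res.leaf_outputs["out"]] == [1, 2, 3]
        assert all(depth == 0 for depth in res.queue_depths.values())

    def test_fan_out_reaches_every_consumer(self):
        g = sc.build_topology(
            [node("src", "source", fn=["a", "b", "c"]),
             node("L1", "leaf", fn=identity),
             node("L2", "leaf", fn=identity)],
            [("src", "L1"), ("src", "L2")],
        )
        res = sc.run_topology(g)
        for leaf in ("L1", "L2"):
            assert [e.payload for e in res.leaf_outputs[leaf]] == ["a", "b", "c"]

    def test_raising_node_dead_letters_and_run_continues(self):
        def broken(payload, key):
            raise RuntimeError("boom")

        g = sc.build_topology(
            [node("src", "source", fn=[1, 2, 3]),
             node("mid", "middle", fn=broken),
             node("out", "leaf", fn=identity)],
            [("src", "mid"), ("mid", "out")],
        )
        res = sc.run_topology(g)
        assert len(res.leaf_outputs["out"]) == 0
        assert len(res.dead_letters) == 3
        assert res.dead_letters[0].node == "mid"

    def test_cycle_terminates_when_messages_stop_recirculating(self):
        # countdown payloads loop back until they reach zero
        def countdown(payload, key):
            if payload > 0:
                return [sc.Envelope(payload - 1, key="loop")]
            return [sc.Envelope("done", key="loop")]

        def router(payload, key):
            return [payload]

        g = sc.build_topology(
            [node("src", "source", fn=[2]),
             node("step", "middle", fn=countdown),
             node("back", "middle", fn=router),
             node("out", "leaf", fn=identity)],
            [("src", "step"), ("step", "back"), ("step", "out"),
             ("back", "step")],
        )
        res = sc.run_topology(g, max_ticks=1000)
        payloads = [e.payload for e in res.leaf_outputs["out"]]
        assert "done" in payloads
        assert res.ticks < 1000

    def test_missing_function_rejected(self):
        g = sc.build_topology(
            [node("src", "source", fn=[1]), node("out", "leaf")],
            [("src", "out")],
        )
        with pytest.raises(sc.ConfigurationError, match="processing function"):
            sc.run_topology(g)


# ---------------------------------------------------------------------------
# Input scheduling


class TestScheduling:
    def test_parity_round_robin(self):
        q = {"e1": deque([1] * 10), "e2": deque([1] * 10)}
        policy = sc.InputPolicy()
        grants = [sc.schedule_next_edge(policy, q, t) for t in range(4)]
        assert grants == ["e1", "e2", "e1", "e2"]

    def test_parity_skips_empty_queues(self):
        q = {"e1": deque(), "e2": deque([1])}
        assert sc.schedule_next_edge(sc.InputPolicy(), q, 0) == "e2"

    def test_all_empty_returns_none(self):
        q = {"e1": deque(), "e2": deque()}
        for policy in (
            sc.InputPolicy(),
            sc.InputPolicy(sc.InputMode.EXPONENTIAL, {"e1": 0, "e2": 1}, 3),
        ):
            assert sc.schedule_next_edge(policy, q, 5) is None

    def test_negative_priority_rejected(self):
        with pytest.raises(sc.ConfigurationError, match="negative priority"):
            sc.InputPolicy(sc.InputMode.EXPONENTIAL, {"e1": -1}, 3)

    def test_exponential_two_of_three_ticks(self):
        # priorities {e1:0, e2:1}: e2 gets 2 of every 3 ticks
        policy = sc.InputPolicy(sc.InputMode.EXPONENTIAL, {"e1": 0, "e2": 1}, 3)
        q = {"e1": deque([1] * 10000), "e2": deque([1] * 10000)}
        grants = Counter(sc.schedule_next_edge(policy, q, t) for t in range(3000))
        assert grants == Counter({"e2": 2000, "e1": 1000})

    def test_exponential_exact_proportions_three_edges(self):
        # weights 1:2:4 over a window of 7 -> grant counts in exact ratio
        pri = {"a": 0, "b": 1, "c": 2}
        policy = sc.InputPolicy(sc.InputMode.EXPONENTIAL, pri, 7)
        q = {e: deque([1] * 100000) for e in pri}
        n = 7 * 100
        grants = Counter(sc.schedule_next_edge(policy, q, t) for t in range(n))
        assert grants == Counter({"a": 100, "b": 200, "c": 400})

    def test_exponential_skips_empty_designated_edge(self):
        policy = sc.InputPolicy(sc.InputMode.EXPONENTIAL, {"e1": 0, "e2": 3}, 9)
        q = {"e1": deque([1]), "e2": deque()}
        assert sc.schedule_next_edge(policy, q, 0) == "e1"


# ---------------------------------------------------------------------------
# Scaling


def _run_counting(instances: int, n_msgs: int = 100):
    g = sc.build_topology(
        [node("src", "source",
              fn=[sc.Envelope(i, key=f"u{i % 7}") for i in range(n_msgs)]),
         node("mid", "middle", fn=identity, instances=instances),
         node("out", "leaf", fn=identity)],
        [("src", "mid"), ("mid", "out")],
    )
    return sc.run_topology(g)


class TestScaling:
    @pytest.mark.parametrize("instances", [2, 4])
    def test_stateless_scaling_preserves_output_multiset(self, instances):
        base = Counter(e.payload for e in _run_counting(1).leaf_outputs["out"])
        scaled = Counter(
            e.payload for e in _run_counting(instances).leaf_outputs["out"]
        )
        assert base == scaled

    def test_keyed_messages_stick_to_one_instance(self):
        # stateful stage tags outputs with its instance id; every key must
        # always land on the same instance
        def factory():
            instance_id = object()

            def fn(payload, key):
                return [{"key": key, "instance": id(instance_id)}]

            return fn

        rng = np.random.default_rng(3)
        keys = [f"user{rng.integers(0, 50)}" for _ in range(1000)]
        g = sc.build_topology(
            [node("src", "source",
                  fn=[sc.Envelope(i, key=k) for i, k in enumerate(keys)]),
             node("agg", "middle", fn=factory, instances=3, stateful=True),
             node("out", "leaf", fn=identity)],
            [("src", "agg"), ("agg", "out")],
        )
        res = sc.run_topology(g)
        seen: dict[str, int] = {}
        for env in res.leaf_outputs["out"]:
            rec = env.payload
            assert seen.setdefault(rec["key"], rec["instance"]) == rec["instance"]
        assert len(res.leaf_outputs["out"]) == 1000

    def test_per_key_order_survives_scaling(self):
        def factory():
            def fn(payload, key):
                return [payload]

            return fn

        items = [sc.Envelope((f"u{i % 3}", i), key=f"u{i % 3}") for i in range(60)]
        g = sc.build_topology(
            [node("src", "source", fn=items),
             node("agg", "middle", fn=factory, instances=4, stateful=True),
             node("out", "leaf", fn=identity)],
            [("src", "agg"), ("agg", "out")],
        )
        res = sc.run_topology(g)
        per_key: dict[str, list[int]] = {}
        for env in res.leaf_outputs["out"]:
            user, seq = env.payload
            per_key.setdefault(user, []).append(seq)
        for seqs in per_key.values():
            assert seqs == sorted(seqs)

    def test_stateful_without_key_is_routing_error(self):
        def factory():
            return identity

        g = sc.build_topology(
            [node("src", "source", fn=[1, 2]),  # envelopes carry no key
             node("agg", "middle", fn=factory, instances=2, stateful=True),
             node("out", "leaf", fn=identity)],
            [("src", "agg"), ("agg", "out")],
        )
        with pytest.raises(sc.RoutingError):
            sc.run_topology(g)

    def test_scale_node_returns_updated_copy(self):
        g = sc.build_topology(
            [node("src", "source"), node("mid", "middle", fn=identity)],
            [("src", "mid")],
        )
        g2 = sc.scale_node(g, "mid", 4)
        assert g2.nodes["mid"].instances == 4
        assert g.nodes["mid"].instances == 1


# ---------------------------------------------------------------------------
# Token filter


@pytest.mark.parametrize(
    "text, allowed, expected",
    [
        ("i feel sad today", {"sad"}, True),
        ("hello world", {"sad"}, False),
        ("Sad!", {"sad"}, True),  # lowercasing tokeniser
        ("", {"sad"}, False),
        ("anything at all", set(), False),  # empty allowed set drops everything
    ],
)
def test_token_filter(text, allowed, expected):
    assert sc.token_filter(text, allowed) is expected


# ---------------------------------------------------------------------------
# Payload serialisation round-trip

json_scalars = (
    st.none()
    | st.booleans()
    | st.integers(min_value=-(2**53), max_value=2**53)
    | st.floats(allow_nan=True, allow_infinity=False)
    | st.text(max_size=20)
)


def sparse_vectors(draw):
    n = draw(st.integers(min_value=1, max_value=30))
    nnz = draw(st.integers(min_value=0, max_value=n))
    idx = draw(
        st.lists(
            st.integers(min_value=0, max_value=n - 1),
            min_size=nnz, max_size=nnz, unique=True,
        )
    )
    vals = draw(
        st.lists(
            st.floats(allow_nan=False, allow_infinity=False, width=32),
            min_size=nnz, max_size=nnz,
        )
    )
    m = sp.csr_matrix(
        (np.array(vals, dtype=np.float64), (np.zeros(nnz, dtype=int), idx)),
        shape=(1, n),
    )
    return m


payloads = st.recursive(
    json_scalars
    | st.builds(lambda lst: np.array(lst), st.lists(st.integers(-100, 100), max_size=8))
    | st.composite(sparse_vectors)(),
    lambda children: st.lists(children, max_size=4)
    | st.dictionaries(st.text(max_size=8), children, max_size=4),
    max_leaves=12,
)


@settings(max_examples=150, derandomize=True, deadline=None)
@given(payloads)
def test_serialise_roundtrip_identity(payload):
    """serialise then deserialise is the identity on supported payloads."""
    assert sc.payload_equal(sc.deserialize(sc.serialize(payload)), payload)


def test_serialised_form_is_compressed_bytes():
    blob = sc.serialize({"user": "u1", "counts": [1, 2, 3]})
    assert isinstance(blob, bytes)
    assert sc.deserialize(blob) == {"user": "u1", "counts": [1, 2, 3]}


def test_unsupported_payload_rejected():
    with pytest.raises(TypeError):
        sc.serialize(object())
    with pytest.raises(TypeError, match="keys"):
        sc.serialize({1: "non-string key"})
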