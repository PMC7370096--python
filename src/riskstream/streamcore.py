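"""In-process stream-processing execution graphs.

A topology is a directed graph (cycles allowed) of processing nodes
connected by FIFO message queues.  Nodes come in three classes:

* **source** — ingests external data; no inbound edges;
* **middle** — transforms or filters messages; inbound and outbound edges;
* **leaf**   — terminal consumer (storage, alerting); no outbound edges.

Each stage can be replicated into several *instances*.  Stateless stages
scale transparently; stateful stages require keyed envelopes, and messages
are partitioned by a stable hash of the key so that any given key is always
handled by the same instance.  Nodes with several inbound edges choose which
queue to read from via an :class:`InputPolicy` — either *parity*
(round-robin over the inputs) or *exponential* (each input is granted a
fraction of scheduler ticks growing as ``2**priority``, apportioned within
a fixed window).

Everything runs single-threaded and deterministically: one scheduler tick is
one message-delivery opportunity, so behaviour is reproducible and
hardware-independent.
"""

from __future__ import annotations

import json
import logging
import re
import zlib
from collections import deque
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Any, Callable, Iterable, Iterator, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

log = logging.getLogger(__name__)

__all__ = [
    "ConfigurationError",
    "TopologyError",
    "RoutingError",
    "Envelope",
    "NodeKind",
    "InputMode",
    "InputPolicy",
    "NodeSpec",
    "TopologyGraph",
    "RunResult",
    "build_topology",
    "topology_from_config",
    "run_topology",
    "schedule_next_edge",
    "scale_node",
    "token_filter",
    "serialize",
    "deserialize",
    "payload_equal",
    "partition_for_key",
]


class ConfigurationError(ValueError):
    """Invalid topology or policy configuration."""


class TopologyError(ConfigurationError):
    """Structural violation of the source/middle/leaf degree rules."""


class RoutingError(RuntimeError):
    """A stateful stage received an envelope that cannot be key-partitioned."""


class NodeKind(str, Enum):
    SOURCE = "source"
    MIDDLE = "middle"
    LEAF = "leaf"


class InputMode(str, Enum):
    PARITY = "parity"
    EXPONENTIAL = "exponential"


@dataclass(frozen=True)
class Envelope:
    """One message on an edge: a structured payload plus a routing key."""

    payload: Any
    key: str = ""
    source_edge: str = ""


@dataclass(frozen=True)
class InputPolicy:
    """How a multi-input node divides its attention across inbound edges.

    ``parity`` serves non-empty inbound queues round-robin and ignores
    priorities.  ``exponential`` grants each edge a fraction
    ``2**priority / sum(2**priority)`` of the ticks inside each scheduling
    window; empty queues are skipped in favour of the next non-empty one.
    """

    mode: InputMode = InputMode.PARITY
    priorities: Mapping[str, int] = field(default_factory=dict)
    window: int = 0

    def __post_init__(self) -> None:
        for edge, p in self.priorities.items():
            if p < 0:
                raise ConfigurationError(
                    f"negative priority {p} for edge {edge!r}"
                )
        if self.mode is InputMode.EXPONENTIAL and self.window < 1:
            # default window: smallest one realising the proportions exactly
            object.__setattr__(
                self, "window", sum(2 ** p for p in self.priorities.values()) or 1
            )


#: Node processing functions.
#:
#: * source: an iterable (or zero-argument callable returning an iterable)
#:   yielding payloads or :class:`Envelope` objects;
#: * stateless middle/leaf: ``fn(payload, key) -> iterable of outputs``
#:   where each output is a payload (key inherited) or an ``Envelope``;
#: * stateful middle/leaf (``stateful=True``): ``fn`` is a zero-argument
#:   factory called once per instance, returning the per-instance worker
#:   with the stateless signature.
NodeFn = Callable[..., Any]


@dataclass(frozen=True)
class NodeSpec:
    name: str
    kind: NodeKind
    fn: NodeFn | Iterable[Any] | None = None
    instances: int = 1
    input_policy: InputPolicy = field(default_factory=InputPolicy)
    stateful: bool = False

    def __post_init__(self) -> None:
        if self.instances < 1:
            raise ConfigurationError(
                f"node {self.name!r}: instances must be >= 1, got {self.instances}"
            )


@dataclass(frozen=True)
class TopologyGraph:
    nodes: Mapping[str, NodeSpec]
    edges: tuple[tuple[str, str], ...]

    def inbound(self, name: str) -> list[tuple[str, str]]:
        return [e for e in self.edges if e[1] == name]

    def outbound(self, name: str) -> list[tuple[str, str]]:
        return [e for e in self.edges if e[0] == name]


def build_topology(
    nodes: Iterable[NodeSpec], edges: Sequence[tuple[str, str]]
) -> TopologyGraph:
    """Validate node/edge declarations and return the execution graph.

    Cycles among middle nodes are permitted (data may be sent back to an
    earlier stage).  Raises :class:`ConfigurationError` for unknown or
    duplicate node names and :class:`TopologyError` when a source has an
    inbound edge or a leaf an outbound one.
    """
    node_map: dict[str, NodeSpec] = {}
    for spec in nodes:
        if spec.name in node_map:
            raise ConfigurationError(f"duplicate node name {spec.name!r}")
        node_map[spec.name] = spec
    for src, dst in edges:
        for endpoint in (src, dst):
            if endpoint not in node_map:
                raise ConfigurationError(f"edge references unknown node {endpoint!r}")
        if node_map[dst].kind is NodeKind.SOURCE:
            raise TopologyError(f"source node {dst!r} cannot have inbound edges")
        if node_map[src].kind is NodeKind.LEAF:
            raise TopologyError(f"leaf node {src!r} cannot have outbound edges")
    return TopologyGraph(nodes=node_map, edges=tuple(edges))


def topology_from_config(config: Mapping[str, Any]) -> TopologyGraph:
    """Build a graph from a declarative description (no functions attached).

    ``config`` holds ``nodes`` — a list of maps with ``name``, ``kind`` and
    optionally ``instances``, ``stateful``, ``policy`` (``parity`` /
    ``exponential``), ``priorities`` and ``window`` — and ``edges``, a list
    of ``[from, to]`` pairs.  Processing functions are attached in code
    afterwards (e.g. via :func:`dataclasses.replace`).
    """
    nodes = []
    for entry in config.get("nodes", []):
        policy = InputPolicy(
            mode=InputMode(entry.get("policy", "parity")),
            priorities=dict(entry.get("priorities", {})),
            window=int(entry.get("window", 0)),
        )
        nodes.append(
            NodeSpec(
                name=entry["name"],
                kind=NodeKind(entry["kind"]),
                instances=int(entry.get("instances", 1)),
                input_policy=policy,
                stateful=bool(entry.get("stateful", False)),
            )
        )
    edges = [(src, dst) for src, dst in config.get("edges", [])]
    return build_topology(nodes, edges)


def scale_node(graph: TopologyGraph, name: str, instances: int) -> TopologyGraph:
    """Return a copy of *graph* with node *name* running *instances* workers."""
    if name not in graph.nodes:
        raise ConfigurationError(f"unknown node {name!r}")
    if instances < 1:
        raise ConfigurationError(f"instances must be >= 1, got {instances}")
    nodes = dict(graph.nodes)
    nodes[name] = replace(nodes[name], instances=instances)
    return TopologyGraph(nodes=nodes, edges=graph.edges)


def partition_for_key(key: str, instances: int) -> int:
    """Stable key → instance assignment (crc32; Python's hash() is salted)."""
    if instances == 1:
        return 0
    return zlib.crc32(key.encode("utf-8")) % instances


# ---------------------------------------------------------------------------
# Input scheduling


def _edge_name(edge: tuple[str, str] | str) -> str:
    if isinstance(edge, tuple):
        return f"{edge[0]}->{edge[1]}"
    return edge


def _window_sequence(priorities: Mapping[str, int], window: int) -> list[str]:
    """Grant sequence for one window under the 2**priority apportionment.

    Counts are assigned by largest remainder so they always sum to the
    window length; when ``sum(2**p)`` divides the window the proportions
    are realised exactly.
    """
    edges = sorted(priorities)
    weights = np.array([2.0 ** priorities[e] for e in edges])
    shares = window * weights / weights.sum()
    counts = np.floor(shares).astype(int)
    remainder = window - counts.sum()
    if remainder > 0:
        order = np.argsort(-(shares - counts), kind="stable")
        for i in order[:remainder]:
            counts[i] += 1
    seq: list[str] = []
    for e, c in zip(edges, counts):
        seq.extend([e] * int(c))
    return seq


def schedule_next_edge(
    policy: InputPolicy,
    queues: Mapping[str, Sequence[Any]],
    tick: int,
) -> str | None:
    """Pick the inbound edge to serve at *tick*; ``None`` iff all are empty.

    Parity mode is a round-robin over the declared edges, skipping empty
    queues.  Exponential mode looks up the edge designated for this position
    of the window and, if its queue is empty, falls through to the next
    non-empty edge of the window sequence.
    """
    names = sorted(queues)
    if not names:
        return None
    if all(len(queues[e]) == 0 for e in names):
        return None
    if policy.mode is InputMode.PARITY:
        start = tick % len(names)
        for i in range(len(names)):
            e = names[(start + i) % len(names)]
            if len(queues[e]) > 0:
                return e
        return None
    priorities = {e: policy.priorities.get(e, 0) for e in names}
    for p in priorities.values():
        if p < 0:
            raise ConfigurationError(f"negative priority {p}")
    window = policy.window or sum(2 ** p for p in priorities.values())
    seq = _window_sequence(priorities, window)
    pos = tick % window
    for i in range(window):
        e = seq[(pos + i) % window]
        if len(queues[e]) > 0:
            return e
    # designated edges all empty this window; serve any backlog
    for e in names:
        if len(queues[e]) > 0:
            return e
    return None


# ---------------------------------------------------------------------------
# Execution


@dataclass
class DeadLetter:
    node: str
    key: str
    payload: Any
    error: str


@dataclass
class RunResult:
    """Observable outcome of one topology run."""

    leaf_outputs: dict[str, list[Envelope]]
    messages_processed: dict[str, int]
    messages_emitted: dict[str, int]
    queue_depths: dict[str, int]
    dead_letters: list[DeadLetter]
    ticks: int


def _as_source_iter(fn: Any) -> Iterator[Any]:
    if fn is None:
        raise ConfigurationError("source node has no attached data")
    if callable(fn):
        fn = fn()
    return iter(fn)


def _coerce_envelope(item: Any, default_key: str, edge: str) -> Envelope:
    if isinstance(item, Envelope):
        return Envelope(item.payload, item.key or default_key, edge)
    return Envelope(item, default_key, edge)


def run_topology(
    graph: TopologyGraph,
    max_ticks: int | None = None,
) -> RunResult:
    """Drive the graph until all sources are exhausted and queues drained.

    Each scheduler cycle offers every source the chance to emit one item and
    every consuming node the chance to process one message (chosen via its
    input policy).  A node function that raises routes the offending message
    to the dead-letter record and the run continues.  Delivery order per
    edge and key equals emission order for any instance count, because
    processing is sequential and queues are FIFO.
    """
    for name, spec in graph.nodes.items():
        if spec.kind is not NodeKind.SOURCE and spec.fn is None:
            raise ConfigurationError(f"node {name!r} has no processing function")

    queues: dict[str, deque[Envelope]] = {
        _edge_name(e): deque() for e in graph.edges
    }
    inbound: dict[str, list[str]] = {
        n: [_edge_name(e) for e in graph.inbound(n)] for n in graph.nodes
    }
    outbound: dict[str, list[tuple[str, str]]] = {
        n: [(_edge_name(e), e[1]) for e in graph.outbound(n)] for n in graph.nodes
    }

    workers: dict[str, list[Callable[..., Any]]] = {}
    for name, spec in graph.nodes.items():
        if spec.kind is NodeKind.SOURCE:
            continue
        if spec.stateful:
            workers[name] = [spec.fn() for _ in range(spec.instances)]
        else:
            workers[name] = [spec.fn] * spec.instances

    sources = {
        n: _as_source_iter(s.fn)
        for n, s in graph.nodes.items()
        if s.kind is NodeKind.SOURCE
    }
    exhausted: set[str] = set()
    rr_counter: dict[str, int] = {n: 0 for n in graph.nodes}
    node_tick: dict[str, int] = {n: 0 for n in graph.nodes}

    processed = {n: 0 for n in graph.nodes}
    emitted = {n: 0 for n in graph.nodes}
    leaf_outputs: dict[str, list[Envelope]] = {
        n: [] for n, s in graph.nodes.items() if s.kind is NodeKind.LEAF
    }
    dead_letters: list[DeadLetter] = []

    def deliver(name: str, env: Envelope) -> None:
        emitted[name] += 1
        for edge_id, _dst in outbound[name]:
            queues[edge_id].append(Envelope(env.payload, env.key, edge_id))

    def dispatch(name: str, env: Envelope) -> None:
        spec = graph.nodes[name]
        if spec.stateful:
            if not env.key:
                raise RoutingError(
                    f"stateful node {name!r} received an envelope without a key"
                )
            idx = partition_for_key(env.key, spec.instances)
        else:
            idx = rr_counter[name] % spec.instances
            rr_counter[name] += 1
        fn = workers[name][idx]
        try:
            outputs = fn(env.payload, env.key)
        except RoutingError:
            raise
        except Exception as exc:  # noqa: BLE001 - dead-letter by contract
            dead_letters.append(DeadLetter(name, env.key, env.payload, repr(exc)))
            log.warning("dead-letter at node %s (key=%r): %r", name, env.key, exc)
            return
        processed[name] += 1
        if outputs is None:
            return
        for item in outputs:
            out = _coerce_envelope(item, env.key, "")
            if spec.kind is NodeKind.LEAF:
                leaf_outputs[name].append(out)
            else:
                deliver(name, out)

    ticks = 0
    consumer_order = [
        n for n, s in graph.nodes.items() if s.kind is not NodeKind.SOURCE
    ]
    for name, spec in graph.nodes.items():
        log.info("node %s started (%s, %d instance(s))", name, spec.kind.value, spec.instances)
    while True:
        progress = False
        for name, it in sources.items():
            if name in exhausted:
                continue
            try:
                item = next(it)
            except StopIteration:
                exhausted.add(name)
                continue
            except Exception as exc:  # noqa: BLE001
                dead_letters.append(DeadLetter(name, "", None, repr(exc)))
                exhausted.add(name)
                continue
            processed[name] += 1
            deliver(name, _coerce_envelope(item, "", ""))
            progress = True
        for name in consumer_order:
            node_queues = {e: queues[e] for e in inbound[name]}
            if not node_queues:
                continue
            edge = schedule_next_edge(
                graph.nodes[name].input_policy, node_queues, node_tick[name]
            )
            if edge is None:
                continue
            node_tick[name] += 1
            dispatch(name, queues[edge].popleft())
            progress = True
        ticks += 1
        if max_ticks is not None and ticks >= max_ticks:
            break
        if not progress and len(exhausted) == len(sources):
            break

    for name in graph.nodes:
        log.info("node %s stopped (%d message(s) processed)", name, processed[name])
    return RunResult(
        leaf_outputs=leaf_outputs,
        messages_processed=processed,
        messages_emitted=emitted,
        queue_depths={e: len(q) for e, q in queues.items()},
        dead_letters=dead_letters,
        ticks=ticks,
    )


# ---------------------------------------------------------------------------
# Token filter (the canonical "middle microservice" example)

_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


def token_filter(text: str, allowed: set[str]) -> bool:
    """Pass a text iff it shares at least one token with *allowed*.

    Tokens are lowercased alphanumeric runs.  An empty allowed set drops
    everything (vacuous intersection), as does an empty text.
    """
    if not allowed or not text:
        return False
    tokens = set(_TOKEN_RE.findall(text.lower()))
    return not tokens.isdisjoint(allowed)


# ---------------------------------------------------------------------------
# Payload serialisation
#
# Envelopes crossing an edge must survive serialise -> deserialise unchanged.
# Supported payloads: None, bool, int, float, str, lists, string-keyed maps,
# numpy arrays and scipy sparse (CSR) matrices, arbitrarily nested.  The
# encoding is fully tagged, so user maps can never collide with the markers.


def _encode(value: Any) -> Any:
    if value is None or isinstance(value, (bool, int, str)):
        return value
    if isinstance(value, float):
        return value
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, (list, tuple)):
        return {"t": "list", "v": [_encode(x) for x in value]}
    if isinstance(value, dict):
        out = {}
        for k, v in value.items():
            if not isinstance(k, str):
                raise TypeError(f"map keys must be strings, got {type(k).__name__}")
            out[k] = _encode(v)
        return {"t": "map", "v": out}
    if isinstance(value, np.ndarray):
        return {
            "t": "ndarray",
            "dtype": value.dtype.str,
            "shape": list(value.shape),
            "data": value.ravel().tolist(),
        }
    if sp.issparse(value):
        csr = sp.csr_matrix(value)
        return {
            "t": "csr",
            "shape": list(csr.shape),
            "dtype": csr.dtype.str,
            "data": csr.data.tolist(),
            "indices": csr.indices.tolist(),
            "indptr": csr.indptr.tolist(),
        }
    raise TypeError(f"unsupported payload type {type(value).__name__}")


def _decode(value: Any) -> Any:
    if not isinstance(value, dict):
        return value
    tag = value["t"]
    if tag == "list":
        return [_decode(x) for x in value["v"]]
    if tag == "map":
        return {k: _decode(v) for k, v in value["v"].items()}
    if tag == "ndarray":
        arr = np.asarray(value["data"], dtype=np.dtype(value["dtype"]))
        return arr.reshape(value["shape"])
    if tag == "csr":
        return sp.csr_matrix(
            (
                np.asarray(value["data"], dtype=np.dtype(value["dtype"])),
                np.asarray(value["indices"], dtype=np.int32),
                np.asarray(value["indptr"], dtype=np.int32),
            ),
            shape=tuple(value["shape"]),
        )
    raise ValueError(f"unknown payload tag {tag!r}")


def serialize(payload: Any) -> bytes:
    """Serialise and compress a structured payload."""
    return zlib.compress(json.dumps(_encode(payload), allow_nan=True).encode("utf-8"))


def deserialize(blob: bytes) -> Any:
    return _decode(json.loads(zlib.decompress(blob).decode("utf-8")))


def payload_equal(a: Any, b: Any) -> bool:
    """Structural equality for supported payloads (NaN compares equal)."""
    if isinstance(a, float) and isinstance(b, float):
        return (a != a and b != b) or a == b
    if isinstance(a, bool) or isinstance(b, bool):
        return a is b
    if isinstance(a, (list, tuple)) and isinstance(b, (list, tuple)):
        return len(a) == len(b) and all(payload_equal(x, y) for x, y in zip(a, b))
    if isinstance(a, dict) and isinstance(b, dict):
        return a.keys() == b.keys() and all(payload_equal(a[k], b[k]) for k in a)
    if isinstance(a, np.ndarray) or isinstance(b, np.ndarray):
        if not (isinstance(a, np.ndarray) and isinstance(b, np.ndarray)):
            return False
        return (
            a.dtype == b.dtype
            and a.shape == b.shape
            and np.array_equal(a, b, equal_nan=a.dtype.kind == "f")
        )
    if sp.issparse(a) or sp.issparse(b):
        if not (sp.issparse(a) and sp.issparse(b)):
            return False
        if a.shape != b.shape:
            return False
        return (abs(a - b)).nnz == 0
    return type(a) is type(b) and a == b
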