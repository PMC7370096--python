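"""The early-detection pipeline as an execution graph, plus front-end parts.

The prediction architecture chains six stages::

    replayer -> text-vectorisation -> aggregator -> tf-idf -> prediction
                                                        .-> probability storer
                                                        '-> alert manager

* the **replayer** (source) emits submissions in global timestamp order,
  standing in for a live crawler;
* **text vectorisation** (middle) maps each submission to sparse term
  counts;
* the **aggregator** (middle, stateful, keyed by user) folds each count
  vector into the user's accumulated representation — it is the only
  stateful stage, and key-partitioned routing keeps per-user state
  consistent when it is scaled out;
* **tf-idf transformation** (middle) normalises the accumulated counts with
  the frozen idf statistics;
* **model prediction** (middle) scores the representation with the sparse
  logistic model;
* the **probability storer** (leaf) records one timeline point per
  submission, and the **alert manager** (leaf) fires at most one alert per
  user, at the first probability strictly above the alert threshold.

Default instance proportions for vectorisation / tf-idf / aggregation /
prediction are 2-4-4-1 (a workload-balancing ratio for the relative cost of
the stages).  Because alerts fire at the first threshold crossing of the
same incremental representation, a replay reproduces exactly the decisions
of the offline incremental policy — the streaming-equals-batch contract.

Also here: the crawler-side helpers (username dedup, priority queue of
users to monitor) and run statistics export.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

from . import streamcore as sc
from .classifier import DepressionModel, predict_proba
from .records import Chronology, Submission
from .synthdata import SyntheticCollection
from .textrep import CountVector, tfidf_transform, tokenize, vectorize

__all__ = [
    "AlertRecord",
    "ReplayResult",
    "UserPriorityQueue",
    "dedup_users",
    "enqueue_user",
    "build_depression_graph",
    "replay_collection",
    "export_stats",
    "DEFAULT_INSTANCE_PROPORTIONS",
]

#: vectorisation : tf-idf : aggregation : prediction
DEFAULT_INSTANCE_PROPORTIONS: tuple[int, int, int, int] = (2, 4, 4, 1)


# ---------------------------------------------------------------------------
# Crawler front-end helpers


def dedup_users(
    usernames: Iterable[str], store: set[str] | None = None
) -> Iterator[str]:
    """Forward each username exactly once, in first-appearance order.

    *store* is the backing key-value set (an external store in a deployed
    crawler; any mutable set here).
    """
    seen = store if store is not None else set()
    for name in usernames:
        if name not in seen:
            seen.add(name)
            yield name


class UserPriorityQueue:
    """Users to monitor, dequeued by descending priority, FIFO within ties."""

    def __init__(self) -> None:
        self._heap: list[tuple[float, int, str]] = []
        self._counter = itertools.count()

    def push(self, user: str, priority: float) -> None:
        if priority != priority or priority in (float("inf"), float("-inf")):
            raise ValueError(f"priority must be finite, got {priority}")
        heapq.heappush(self._heap, (-priority, next(self._counter), user))

    def pop(self) -> str:
        return heapq.heappop(self._heap)[2]

    def __len__(self) -> int:
        return len(self._heap)


def enqueue_user(
    queue: UserPriorityQueue, user: str, priority: float
) -> UserPriorityQueue:
    queue.push(user, priority)
    return queue


# ---------------------------------------------------------------------------
# Prediction graph


@dataclass(frozen=True)
class AlertRecord:
    user: str
    probability: float
    submissions_seen: int
    emitted_at: int  # global stream position (probability records seen so far)


@dataclass
class ReplayResult:
    timelines: dict[str, list[tuple[int, float]]]
    alerts: list[AlertRecord]
    run: sc.RunResult

    @property
    def alerted_users(self) -> dict[str, int]:
        """user -> submissions_seen at the (single) alert."""
        return {a.user: a.submissions_seen for a in self.alerts}


def _vectorise_fn(model: DepressionModel):
    vocab = model.vocabulary

    def fn(payload, key):
        cv = vectorize(tokenize(payload["text"]), vocab)
        counts = {str(i): c for i, c in cv.counts.items()}
        return [sc.Envelope({"user": payload["user"], "counts": counts}, key=payload["user"])]

    return fn


def _aggregator_factory(vocab_size: int):
    def factory():
        states: dict[str, tuple[dict[str, int], int]] = {}

        def fn(payload, key):
            counts, n = states.get(key, ({}, 0))
            merged = dict(counts)
            for idx, c in payload["counts"].items():
                merged[idx] = merged.get(idx, 0) + c
            states[key] = (merged, n + 1)
            return [{"user": payload["user"], "counts": merged, "n": n + 1}]

        return fn

    return factory


def _tfidf_fn(model: DepressionModel):
    weights = model.weights
    size = model.vocabulary.size

    def fn(payload, key):
        cv = CountVector({int(i): c for i, c in payload["counts"].items()}, size)
        x = tfidf_transform(cv, weights)
        return [{"user": payload["user"], "n": payload["n"], "x": x}]

    return fn


def _predict_fn(model: DepressionModel):
    def fn(payload, key):
        p = predict_proba(model, payload["x"])
        return [{"user": payload["user"], "n": payload["n"], "p": p}]

    return fn


def _storer_fn(payload, key):
    return [payload]


def _alert_factory(threshold: float):
    def factory():
        alerted: set[str] = set()
        position = itertools.count(1)

        def fn(payload, key):
            pos = next(position)
            if payload["p"] > threshold and key not in alerted:
                alerted.add(key)
                return [
                    {
                        "user": payload["user"],
                        "probability": payload["p"],
                        "submissions_seen": payload["n"],
                        "emitted_at": pos,
                    }
                ]
            return []

        return fn

    return factory


def build_depression_graph(
    model: DepressionModel,
    alert_threshold: float,
    proportions: Sequence[int] = DEFAULT_INSTANCE_PROPORTIONS,
) -> sc.TopologyGraph:
    """Assemble the prediction topology around a fitted model.

    *proportions* gives the instance counts for the vectorisation, tf-idf,
    aggregation and prediction stages (in that order).
    """
    if not (0.0 < alert_threshold < 1.0):
        raise sc.ConfigurationError(
            f"alert threshold must lie in (0, 1), got {alert_threshold}"
        )
    n_vec, n_tfidf, n_agg, n_pred = proportions
    nodes = [
        sc.NodeSpec("replayer", sc.NodeKind.SOURCE),
        sc.NodeSpec(
            "vectorise", sc.NodeKind.MIDDLE, fn=_vectorise_fn(model), instances=n_vec
        ),
        sc.NodeSpec(
            "aggregate",
            sc.NodeKind.MIDDLE,
            fn=_aggregator_factory(model.vocabulary.size),
            instances=n_agg,
            stateful=True,
        ),
        sc.NodeSpec(
            "tfidf", sc.NodeKind.MIDDLE, fn=_tfidf_fn(model), instances=n_tfidf
        ),
        sc.NodeSpec(
            "predict", sc.NodeKind.MIDDLE, fn=_predict_fn(model), instances=n_pred
        ),
        sc.NodeSpec("prob_storer", sc.NodeKind.LEAF, fn=_storer_fn),
        sc.NodeSpec(
            "alert_manager",
            sc.NodeKind.LEAF,
            fn=_alert_factory(alert_threshold),
            stateful=True,
        ),
    ]
    edges = [
        ("replayer", "vectorise"),
        ("vectorise", "aggregate"),
        ("aggregate", "tfidf"),
        ("tfidf", "predict"),
        ("predict", "prob_storer"),
        ("predict", "alert_manager"),
    ]
    return sc.build_topology(nodes, edges)


def _replayer_items(chronologies: Sequence[Chronology]) -> list[sc.Envelope]:
    """Global timestamp order; ties broken by user then per-user position."""
    flat = []
    for chron in chronologies:
        for seq, sub in enumerate(chron.submissions):
            flat.append((sub.timestamp, sub.user, seq, sub))
    flat.sort(key=lambda t: (t[0], t[1], t[2]))
    return [
        sc.Envelope(
            {
                "user": sub.user,
                "timestamp": sub.timestamp,
                "kind": sub.kind,
                "text": sub.text,
            },
            key=sub.user,
        )
        for _, _, _, sub in flat
    ]


def replay_collection(
    collection: SyntheticCollection | Sequence[Chronology],
    graph: sc.TopologyGraph,
) -> ReplayResult:
    """Feed a collection's test chronologies through the graph.

    Returns per-user probability timelines (one point per submission, with
    submissions_seen strictly increasing) and the fired alerts (at most one
    per user, at the first threshold crossing).
    """
    if isinstance(collection, SyntheticCollection):
        chronologies: Sequence[Chronology] = collection.test
    else:
        chronologies = collection
    items = _replayer_items(chronologies)
    bound = sc.TopologyGraph(
        nodes={
            **graph.nodes,
            "replayer": replace(graph.nodes["replayer"], fn=items),
        },
        edges=graph.edges,
    )
    run = sc.run_topology(bound)

    timelines: dict[str, list[tuple[int, float]]] = {}
    for env in run.leaf_outputs.get("prob_storer", []):
        rec = env.payload
        timelines.setdefault(rec["user"], []).append((rec["n"], rec["p"]))
    alerts = [
        AlertRecord(
            user=env.payload["user"],
            probability=env.payload["probability"],
            submissions_seen=env.payload["submissions_seen"],
            emitted_at=env.payload["emitted_at"],
        )
        for env in run.leaf_outputs.get("alert_manager", [])
    ]
    return ReplayResult(timelines=timelines, alerts=alerts, run=run)


def export_stats(result: ReplayResult) -> dict:
    """JSON-ready run statistics (counts only; no hardware-dependent rates)."""
    return {
        "submissions_processed": result.run.messages_processed.get("replayer", 0),
        "users_analysed": len(result.timelines),
        "alerts_fired": len(result.alerts),
        "dead_letters": len(result.run.dead_letters),
    }
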