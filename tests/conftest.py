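"""Shared fixtures: synthetic collections, fitted models, scripted models."""

from __future__ import annotations

import numpy as np
import pytest

from riskstream.classifier import train_from_chronologies
from riskstream.records import Chronology, Submission
from riskstream.synthdata import (
    erisk2017_mini,
    generate_collection,
    parameter_recovery_config,
)


def make_chronology(user: str, texts: list[str], kind: str = "post") -> Chronology:
    """Chronology with synthetic increasing timestamps."""
    return Chronology(
        user,
        tuple(
            Submission(user, f"2017-01-{i + 1:02d}T00:00:00+00:00", kind, text)
            for i, text in enumerate(texts)
        ),
    )


class ScriptedModel:
    """Policy-test double: probability depends only on the prefix length.

    Mimics the DepressionModel surface the policies use (``vocabulary.size``,
    ``score_counts``, ``score_text``), returning scripted probabilities so
    first-crossing behaviour can be asserted exactly.
    """

    class _Vocab:
        index = {"a": 0}
        size = 1

    vocabulary = _Vocab()

    def __init__(self, prefix_scores: list[float]):
        self._scores = prefix_scores
        self._calls = 0

    def score_counts(self, cv) -> float:
        score = self._scores[min(self._calls, len(self._scores) - 1)]
        self._calls += 1
        return score

    def score_text(self, text: str) -> float:
        return self._scores[-1]

    def reset(self) -> None:
        self._calls = 0


@pytest.fixture(scope="session")
def recovery_collection():
    """delta=0.5, matched length profiles, 40/160 train + 20/80 test, seed 0."""
    return generate_collection(parameter_recovery_config(delta=0.5, seed=0))


@pytest.fixture(scope="session")
def recovery_model(recovery_collection):
    return train_from_chronologies(
        recovery_collection.train, recovery_collection.truth_train, seed=0
    )


@pytest.fixture(scope="session")
def stream_collection():
    """50-user test split (10/40), seed 42 — the streaming-vs-batch fixture."""
    return generate_collection(
        parameter_recovery_config(
            delta=0.5, seed=42, n_depressed_test=10, n_control_test=40
        )
    )


@pytest.fixture(scope="session")
def stream_model(stream_collection):
    return train_from_chronologies(
        stream_collection.train, stream_collection.truth_train, seed=42
    )


@pytest.fixture(scope="session")
def null_collection():
    """delta=0 exchangeable collection with a 400-user held-out split, seed 0."""
    return generate_collection(
        parameter_recovery_config(
            delta=0.0, seed=0, n_depressed_test=80, n_control_test=320
        )
    )


@pytest.fixture(scope="session")
def big_null_collection():
    """1000 users at delta=0 for distribution-recovery checks (seed 7)."""
    return generate_collection(
        parameter_recovery_config(
            delta=0.0,
            seed=7,
            n_depressed_train=500,
            n_control_train=500,
            n_depressed_test=1,
            n_control_test=1,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
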