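"""Sequential decision policies for early risk detection.

Four methods, each emitting exactly one binary decision per user from a
chronologically ordered submission stream:

* **Random** — Bernoulli(0.5) call after the first submission (baseline);
* **Depressed** (all-positive) — labels everyone positive after the first
  submission; perfect recall, precision equal to the prevalence;
* **First-n** — concatenates the oldest ``n`` submissions, scores them once,
  and labels positive iff the classifier probability exceeds 0.5.  The delay
  is ``min(n, n_i)``; with ``n`` at least the longest stream this becomes
  the "All" method;
* **Incremental** — after every submission the accumulated user
  representation is rescored, and a positive decision fires at the first
  probability strictly above the confidence threshold.  If the stream is
  exhausted without a firing, the user is labelled negative with delay
  ``n_i`` (positive-or-wait: the method never emits an early negative).

The incremental policy builds its prefix representation through the same
count-merge path the streaming aggregator uses, so offline decisions and
live replay alerts coincide exactly.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .classifier import DepressionModel
from .records import Chronology, Decision
from .textrep import UserState, merge_counts, tokenize, vectorize

__all__ = [
    "decide_random",
    "decide_all_positive",
    "decide_first_n",
    "decide_incremental",
    "run_policy",
    "STANDARD_THRESHOLDS",
]

#: Confidence thresholds the incremental method is evaluated at.
STANDARD_THRESHOLDS: tuple[float, ...] = (0.5, 0.75, 0.9)


def decide_random(chronology: Chronology, rng: np.random.Generator) -> Decision:
    """Unbiased coin flip right after the first submission."""
    return Decision(chronology.user, int(rng.random() < 0.5), 1)


def decide_all_positive(chronology: Chronology) -> Decision:
    """Assign the depression class to every user after the first submission."""
    return Decision(chronology.user, 1, 1)


def decide_first_n(chronology: Chronology, n: int, model: DepressionModel) -> Decision:
    """Score the concatenation of the oldest n submissions once.

    Users with fewer than n submissions are decided at stream exhaustion,
    so the delay is ``min(n, n_i)``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    k = min(n, len(chronology))
    text = " ".join(s.text for s in chronology.submissions[:k])
    p = model.score_text(text)
    return Decision(chronology.user, int(p > 0.5), k)


def decide_incremental(
    chronology: Chronology, model: DepressionModel, threshold: float
) -> Decision:
    """Rescore the growing user representation after each submission.

    Emits a positive at the first probability strictly greater than
    *threshold*; labels the user negative at exhaustion otherwise.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    state = UserState.empty(chronology.user, model.vocabulary.size)
    for p_idx, sub in enumerate(chronology.submissions, start=1):
        cv = vectorize(tokenize(sub.text), model.vocabulary)
        state = merge_counts(state, cv)
        if model.score_counts(state.counts) > threshold:
            return Decision(chronology.user, 1, p_idx)
    return Decision(chronology.user, 0, len(chronology))


def run_policy(
    chronologies: Sequence[Chronology],
    policy: str,
    model: DepressionModel | None = None,
    n: int | None = None,
    threshold: float | None = None,
    seed: int = 0,
) -> list[Decision]:
    """Apply one named policy to every chronology.

    ``policy`` is one of ``random``, ``all_positive``, ``first_n``
    (requires ``n`` and ``model``), ``incremental`` (requires ``threshold``
    and ``model``).
    """
    if policy == "random":
        rng = np.random.default_rng(seed)
        return [decide_random(c, rng) for c in chronologies]
    if policy == "all_positive":
        return [decide_all_positive(c) for c in chronologies]
    if policy == "first_n":
        if model is None or n is None:
            raise ValueError("first_n requires a model and n")
        return [decide_first_n(c, n, model) for c in chronologies]
    if policy == "incremental":
        if model is None or threshold is None:
            raise ValueError("incremental requires a model and threshold")
        return [decide_incremental(c, model, threshold) for c in chronologies]
    raise ValueError(f"unknown policy {policy!r}")
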