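"""Seeded generator of synthetic early-risk collections.

Real depression screening corpora (per-user Reddit chronologies with golden
truth labels) are access-restricted, so every other module is exercised on
synthetic collections that emulate their structure: a train and a test
split, each holding two user groups — *depressed* (positive) and *control*
(negative) — with per-group submission-count and submission-length
distributions, chronologically ordered synthetic timestamps, and a
controllable vocabulary shift between the groups.

Tokens are drawn from a Zipf-ranked base distribution over an artificial
vocabulary (``w00000`` is the most frequent term).  A fixed set of *marker
terms* has its probability multiplied by ``(1 + delta)`` in the depressed
group (then renormalised), so ``delta`` directly controls class
separability: at ``delta = 0`` the groups are exchangeable and no
classifier should beat chance.  The manifest records the planted markers,
which lets tests check that a fitted sparse model recovers them.

Optionally each depressed user gets one planted "diagnosis" submission
containing an explicit diagnosis phrase; :func:`remove_diagnosis_posts`
strips these again, mirroring the curation step real collections apply so
that classifiers cannot overfit to the phrases used to find the positive
group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from typing import Iterable, Sequence

import numpy as np

from .records import Chronology, Submission

__all__ = [
    "GroupProfile",
    "GeneratorConfig",
    "SyntheticCollection",
    "erisk2017_mini",
    "parameter_recovery_config",
    "generate_collection",
    "remove_diagnosis_posts",
    "DIAGNOSIS_PHRASE",
]

DIAGNOSIS_PHRASE = "i was diagnosed with depression"

#: Zipf rank of the first planted marker term (markers occupy a contiguous
#: run of moderately frequent ranks so the signal is observable but does not
#: dominate the unigram distribution).
_MARKER_FIRST_RANK = 10


@dataclass(frozen=True)
class GroupProfile:
    """Per-group submission behaviour.

    ``mean_submissions`` is the arithmetic mean of a log-normal
    submissions-per-user distribution with log-scale spread
    ``sigma_submissions``; ``mean_words`` parameterises a Poisson draw of
    words per submission (floored at 1).
    """

    mean_submissions: float
    mean_words: float
    sigma_submissions: float = 0.6

    def __post_init__(self) -> None:
        if self.mean_submissions < 1 or self.mean_words < 1:
            raise ValueError("group means must be >= 1")


@dataclass(frozen=True)
class GeneratorConfig:
    n_depressed_train: int = 83
    n_control_train: int = 403
    n_depressed_test: int = 52
    n_control_test: int = 349
    depressed: GroupProfile = field(
        default_factory=lambda: GroupProfile(37.17, 27.6)
    )
    control: GroupProfile = field(
        default_factory=lambda: GroupProfile(65.55, 21.3)
    )
    vocab_size: int = 500
    n_marker_terms: int = 10
    delta: float = 0.5
    inject_diagnosis_post: bool = False
    max_submissions_per_user: int | None = None
    span_days: float = 600.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_depressed_train",
            "n_control_train",
            "n_depressed_test",
            "n_control_test",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.vocab_size < self.n_marker_terms:
            raise ValueError(
                f"vocab_size {self.vocab_size} < n_marker_terms {self.n_marker_terms}"
            )
        if self.vocab_size < _MARKER_FIRST_RANK + self.n_marker_terms:
            raise ValueError(
                f"vocab_size must be >= {_MARKER_FIRST_RANK + self.n_marker_terms} "
                "to place the marker terms"
            )
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")


def erisk2017_mini(seed: int = 0, **overrides) -> GeneratorConfig:
    """Default study profile: 2017-collection group sizes and Table-like
    per-group means, with submission counts scaled down x10 for fast runs."""
    return replace(GeneratorConfig(seed=seed), **overrides)


def parameter_recovery_config(
    delta: float,
    seed: int = 0,
    n_depressed_train: int = 40,
    n_control_train: int = 160,
    n_depressed_test: int = 20,
    n_control_test: int = 80,
) -> GeneratorConfig:
    """Study design for isolating the vocabulary-shift parameter.

    Both groups share one length profile (the control group's), so the only
    systematic group difference is the marker boost ``delta``.  With
    per-group length profiles, document volume alone separates the groups
    (rare-term presence grows with tokens written), confounding any
    assessment of the vocabulary signal — in particular, at ``delta = 0``
    the groups would not be exchangeable.
    """
    profile = GroupProfile(65.55, 21.3)
    return GeneratorConfig(
        n_depressed_train=n_depressed_train,
        n_control_train=n_control_train,
        n_depressed_test=n_depressed_test,
        n_control_test=n_control_test,
        depressed=profile,
        control=profile,
        delta=delta,
        seed=seed,
    )


@dataclass(frozen=True)
class SyntheticCollection:
    train: tuple[Chronology, ...]
    test: tuple[Chronology, ...]
    truth_train: dict[str, int]
    truth_test: dict[str, int]
    manifest: dict


def _zipf_probs(vocab_size: int) -> np.ndarray:
    ranks = np.arange(1, vocab_size + 1, dtype=float)
    p = 1.0 / ranks
    return p / p.sum()


def _group_probs(base: np.ndarray, marker_idx: np.ndarray, delta: float) -> np.ndarray:
    boosted = base.copy()
    boosted[marker_idx] *= 1.0 + delta
    return boosted / boosted.sum()


def _draw_chronology(
    rng: np.random.Generator,
    user: str,
    profile: GroupProfile,
    token_probs: np.ndarray,
    vocab: np.ndarray,
    config: GeneratorConfig,
    plant_diagnosis: bool,
    start: datetime,
) -> Chronology:
    mu = np.log(profile.mean_submissions) - profile.sigma_submissions ** 2 / 2.0
    n_sub = max(1, int(round(rng.lognormal(mu, profile.sigma_submissions))))
    if config.max_submissions_per_user is not None:
        n_sub = min(n_sub, config.max_submissions_per_user)
    words = np.maximum(1, rng.poisson(profile.mean_words, size=n_sub))
    tokens = rng.choice(vocab, size=int(words.sum()), p=token_probs)
    texts: list[str] = []
    pos = 0
    for w in words:
        texts.append(" ".join(tokens[pos : pos + w]))
        pos += w
    if plant_diagnosis:
        insert_at = int(rng.integers(0, len(texts) + 1))
        texts.insert(insert_at, DIAGNOSIS_PHRASE)
    kinds = rng.choice(["post", "comment"], size=len(texts))
    offsets = np.sort(rng.uniform(0.0, config.span_days, size=len(texts)))
    subs = tuple(
        Submission(
            user=user,
            timestamp=(start + timedelta(days=float(off))).isoformat(),
            kind=str(kind),
            text=text,
        )
        for text, kind, off in zip(texts, kinds, offsets)
    )
    return Chronology(user, subs)


def generate_collection(config: GeneratorConfig) -> SyntheticCollection:
    """Generate a full train/test collection; byte-identical given the seed."""
    rng = np.random.default_rng(config.seed)
    vocab = np.array([f"w{r:05d}" for r in range(config.vocab_size)])
    base = _zipf_probs(config.vocab_size)
    marker_idx = np.arange(
        _MARKER_FIRST_RANK, _MARKER_FIRST_RANK + config.n_marker_terms
    )
    depressed_probs = _group_probs(base, marker_idx, config.delta)
    start = datetime(2017, 1, 1, tzinfo=timezone.utc)

    def make_split(split: str, n_dep: int, n_ctl: int):
        chronologies: list[Chronology] = []
        truth: dict[str, int] = {}
        for i in range(n_dep):
            user = f"d_{split}_{i:04d}"
            chronologies.append(
                _draw_chronology(
                    rng,
                    user,
                    config.depressed,
                    depressed_probs,
                    vocab,
                    config,
                    config.inject_diagnosis_post,
                    start,
                )
            )
            truth[user] = 1
        for i in range(n_ctl):
            user = f"c_{split}_{i:04d}"
            chronologies.append(
                _draw_chronology(
                    rng, user, config.control, base, vocab, config, False, start
                )
            )
            truth[user] = 0
        return tuple(chronologies), truth

    train, truth_train = make_split(
        "train", config.n_depressed_train, config.n_control_train
    )
    test, truth_test = make_split(
        "test", config.n_depressed_test, config.n_control_test
    )
    manifest = {
        "format": "riskstream-collection",
        "version": 1,
        "seed": config.seed,
        "delta": config.delta,
        "vocab_size": config.vocab_size,
        "marker_terms": [str(t) for t in vocab[marker_idx]],
        "diagnosis_phrase": DIAGNOSIS_PHRASE if config.inject_diagnosis_post else None,
        "n_users": {
            "train": {"depressed": config.n_depressed_train, "control": config.n_control_train},
            "test": {"depressed": config.n_depressed_test, "control": config.n_control_test},
        },
        "group_profiles": {
            "depressed": {
                "mean_submissions": config.depressed.mean_submissions,
                "mean_words": config.depressed.mean_words,
                "sigma_submissions": config.depressed.sigma_submissions,
            },
            "control": {
                "mean_submissions": config.control.mean_submissions,
                "mean_words": config.control.mean_words,
                "sigma_submissions": config.control.sigma_submissions,
            },
        },
    }
    return SyntheticCollection(train, test, truth_train, truth_test, manifest)


def remove_diagnosis_posts(collection: SyntheticCollection) -> SyntheticCollection:
    """Strip every planted diagnosis submission (no-op if none were planted)."""
    phrase = collection.manifest.get("diagnosis_phrase")
    if phrase is None:
        return collection

    def clean(chronologies: Iterable[Chronology]) -> tuple[Chronology, ...]:
        out = []
        for chron in chronologies:
            kept = tuple(s for s in chron.submissions if phrase not in s.text)
            out.append(Chronology(chron.user, kept) if kept else chron)
        return tuple(out)

    manifest = dict(collection.manifest)
    manifest["diagnosis_phrase"] = None
    manifest["diagnosis_posts_removed"] = True
    return SyntheticCollection(
        train=clean(collection.train),
        test=clean(collection.test),
        truth_train=dict(collection.truth_train),
        truth_test=dict(collection.truth_test),
        manifest=manifest,
    )
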