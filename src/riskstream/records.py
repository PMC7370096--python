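"""Shared record types: submissions, user chronologies, decisions, truth files.

A *submission* is one post or comment by one user.  A *chronology* is a
user's submissions ordered oldest-first; it is the unit consumed by the
sequential decision policies.  A *decision* is the single binary call a
policy emits for a user, together with its delay ``k`` — the number of
submissions seen when the call was made.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping


@dataclass(frozen=True)
class Submission:
    user: str
    timestamp: str  # ISO-8601 instant
    kind: str  # "post" | "comment"
    text: str

    def __post_init__(self) -> None:
        if not self.user:
            raise ValueError("submission user must be non-empty")
        if self.kind not in ("post", "comment"):
            raise ValueError(f"unknown submission kind {self.kind!r}")


@dataclass(frozen=True)
class Chronology:
    """One user's submission stream, oldest first."""

    user: str
    submissions: tuple[Submission, ...]

    def __post_init__(self) -> None:
        if len(self.submissions) < 1:
            raise ValueError(f"user {self.user!r} has an empty chronology")
        ts = [s.timestamp for s in self.submissions]
        if any(a > b for a, b in zip(ts, ts[1:])):
            raise ValueError(f"user {self.user!r}: timestamps must be non-decreasing")

    def __len__(self) -> int:
        return len(self.submissions)

    def texts(self) -> list[str]:
        return [s.text for s in self.submissions]


@dataclass(frozen=True)
class Decision:
    """Binary early-risk call for one user, emitted after seeing k submissions."""

    user: str
    label: int
    k: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        if self.k < 1:
            raise ValueError(f"delay k must be >= 1, got {self.k}")


GoldenTruth = Mapping[str, int]


# ---------------------------------------------------------------------------
# File formats: submissions JSONL, truth TSV, decisions TSV


def write_submissions_jsonl(path: str | Path, chronologies: Iterable[Chronology]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for chron in chronologies:
            for sub in chron.submissions:
                fh.write(
                    json.dumps(
                        {
                            "user": sub.user,
                            "timestamp": sub.timestamp,
                            "kind": sub.kind,
                            "text": sub.text,
                        }
                    )
                    + "\n"
                )


def read_submissions_jsonl(path: str | Path) -> list[Chronology]:
    """Read a JSONL submissions file and regroup into per-user chronologies.

    Within each user, submissions are sorted by timestamp (stable, so equal
    timestamps keep file order).
    """
    per_user: dict[str, list[Submission]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            sub = Submission(rec["user"], rec["timestamp"], rec["kind"], rec["text"])
            per_user.setdefault(sub.user, []).append(sub)
    chronologies = []
    for user, subs in per_user.items():
        subs.sort(key=lambda s: s.timestamp)
        chronologies.append(Chronology(user, tuple(subs)))
    return chronologies


def write_truth_tsv(path: str | Path, truth: GoldenTruth) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        for user, label in truth.items():
            writer.writerow([user, label])


def read_truth_tsv(path: str | Path) -> dict[str, int]:
    truth: dict[str, int] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row:
                continue
            truth[row[0]] = int(row[1])
    return truth


def write_decisions_tsv(path: str | Path, decisions: Iterable[Decision]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        for d in decisions:
            writer.writerow([d.user, d.label, d.k])


def read_decisions_tsv(path: str | Path) -> list[Decision]:
    out = []
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row:
                continue
            out.append(Decision(row[0], int(row[1]), int(row[2])))
    return out
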