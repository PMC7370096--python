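"""Evaluation of early risk decisions: P/R/F1 and the delay-penalised ERDE.

Precision, recall and F1 are computed from the per-user confusion counts in
the usual way (0/0 conventions resolve to 0, so an all-negative baseline
scores 0 on every metric).

ERDE — Early Risk Detection Error — additionally charges true positives for
their delay.  With deadline ``o``, per-user costs are:

* false positive: ``c_fp`` (default: the positive-class prevalence of the
  evaluated set);
* false negative: ``c_fn`` (default 1);
* true positive at delay ``k``: ``lc_o(k) * c_tp`` with the latency cost
  ``lc_o(k) = 1 - 1/(1 + e^(k - o)) = sigmoid(k - o)``;
* true negative: 0;

and ERDE is the mean per-user cost.  The latency factor is ~0 well before
the deadline, exactly 0.5 at ``k = o``, and approaches 1 past it — so a
very late true positive costs as much as a miss (late detection equals no
detection).  Smaller is better.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy.special import expit

from .records import Decision, GoldenTruth

__all__ = [
    "ConfusionCounts",
    "ERDEParams",
    "confusion",
    "precision_recall_f1",
    "latency_cost",
    "erde",
    "evaluate",
    "report_to_table",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ERDEParams:
    """Deadline and cost constants for one ERDE configuration.

    ``c_fp=None`` means "use the positive prevalence of the evaluated set",
    the convention that keeps the trivial all-positive and all-negative
    baselines comparable across collections.
    """

    o: int
    c_fp: float | None = None
    c_fn: float = 1.0
    c_tp: float = 1.0

    def __post_init__(self) -> None:
        if self.o < 1:
            raise ValueError(f"deadline o must be >= 1, got {self.o}")
        for name in ("c_fp", "c_fn", "c_tp"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def _check_users(decisions: Sequence[Decision], truth: GoldenTruth) -> None:
    seen: set[str] = set()
    for d in decisions:
        if d.user in seen:
            raise ValueError(f"duplicate decision for user {d.user!r}")
        seen.add(d.user)
        if d.user not in truth:
            raise KeyError(f"user {d.user!r} missing from golden truth")


def confusion(decisions: Sequence[Decision], truth: GoldenTruth) -> ConfusionCounts:
    """Exact confusion counts; every decided user must appear in the truth."""
    _check_users(decisions, truth)
    tp = fp = fn = tn = 0
    for d in decisions:
        actual = truth[d.user]
        if d.label == 1 and actual == 1:
            tp += 1
        elif d.label == 1 and actual == 0:
            fp += 1
        elif d.label == 0 and actual == 1:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, fn, tn)


def precision_recall_f1(c: ConfusionCounts) -> tuple[float, float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); 0/0 -> 0."""
    p = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else 0.0
    r = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else 0.0
    f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return p, r, f1


def latency_cost(k: int, o: int) -> float:
    """``lc_o(k) = 1 - 1/(1 + e^(k-o))``, monotone in k, 0.5 at the deadline."""
    if k < 1:
        raise ValueError(f"delay k must be >= 1, got {k}")
    return float(expit(k - o))


def prevalence(truth: GoldenTruth) -> float:
    labels = list(truth.values())
    return sum(labels) / len(labels) if labels else 0.0


def erde(
    decisions: Sequence[Decision], truth: GoldenTruth, params: ERDEParams
) -> float:
    """Mean delay-penalised per-user error; lower is better."""
    _check_users(decisions, truth)
    if not decisions:
        raise ValueError("cannot evaluate ERDE on an empty decision set")
    c_fp = params.c_fp if params.c_fp is not None else prevalence(
        {d.user: truth[d.user] for d in decisions}
    )
    total = 0.0
    for d in decisions:
        actual = truth[d.user]
        if d.label == 1 and actual == 1:
            total += latency_cost(d.k, params.o) * params.c_tp
        elif d.label == 1 and actual == 0:
            total += c_fp
        elif d.label == 0 and actual == 1:
            total += params.c_fn
    return total / len(decisions)


def evaluate(
    decisions_by_policy: Mapping[str, Sequence[Decision]],
    truth: GoldenTruth,
    erde_deadlines: Sequence[int] = (5, 50),
    c_fp: float | None = None,
    metadata: Mapping[str, object] | None = None,
) -> dict:
    """One report row per policy: P, R, F1 and ERDE at each deadline.

    Returns a JSON-ready dict mirroring the standard comparison-table
    layout (policies as rows, metrics as columns).
    """
    rows: dict[str, dict] = {}
    for policy, decisions in decisions_by_policy.items():
        c = confusion(decisions, truth)
        p, r, f1 = precision_recall_f1(c)
        row = {
            "precision": p,
            "recall": r,
            "f1": f1,
            "counts": {"tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn},
        }
        for o in erde_deadlines:
            row[f"erde_{o}"] = erde(decisions, truth, ERDEParams(o=o, c_fp=c_fp))
        rows[policy] = row
    return {
        "n_users": len(truth),
        "prevalence": prevalence(truth),
        "erde_deadlines": list(erde_deadlines),
        "policies": rows,
        "metadata": dict(metadata or {}),
    }


def report_to_table(report: dict) -> str:
    """Plain-text table of the report (F1, P, R, ERDE columns)."""
    deadlines = report["erde_deadlines"]
    header = ["policy", "F1", "P", "R"] + [f"ERDE{o}" for o in deadlines]
    lines = ["\t".join(header)]
    for policy, row in report["policies"].items():
        cells = [
            policy,
            f"{row['f1']:.3f}",
            f"{row['precision']:.3f}",
            f"{row['recall']:.3f}",
        ] + [f"{row[f'erde_{o}']:.3f}" for o in deadlines]
        lines.append("\t".join(cells))
    return "\n".join(lines)
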