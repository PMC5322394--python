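"""Contributor quality control: trust scoring, gating, learning effect.

Crowd platforms qualify contributors on hidden gold-standard "test
questions": a quiz before any real work, then one hidden test item per
task.  Here a contributor's *trust* is their running test-question
accuracy.  Gating applies the job's quality parameters — minimum test
accuracy (60%), minimum seconds per task (10 s), a judgment cap (500)
and a grace window of images before trust-based filtering (20) — and
marks, rather than deletes, labels from excluded spans so aggregation
can be run with or without them.

The learning-effect analysis splits each contributor's time-ordered
stream into fixed-size groups (40 images, up to 10 groups), computes
per-group accuracy against reference, and correlates labeling volume
with accuracy across contributors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Contributor",
    "QCPolicy",
    "LearningCurve",
    "update_trust",
    "gate",
    "learning_curve",
]


@dataclass(frozen=True)
class QCPolicy:
    """Job quality parameters influencing labeling performance."""

    min_test_accuracy: float = 0.60
    min_seconds_per_task: float = 10.0
    max_judgments: int = 500
    #: Images to review before trust is computed and filtering applied.
    min_images_before_trust: int = 20
    labels_per_image: int = 3
    quiz_size: int = 5
    #: Task layout: 4 actual images plus one hidden test image.
    task_size: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.min_test_accuracy <= 1:
            raise ValueError("min_test_accuracy must lie in (0, 1]")
        for name in (
            "min_seconds_per_task", "max_judgments", "min_images_before_trust",
            "labels_per_image", "quiz_size", "task_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class Contributor:
    """A contributor's test-question history and derived trust."""

    contributor_id: str
    test_outcomes: tuple[bool, ...] = ()
    n_judgments: int = 0
    policy: QCPolicy = field(default_factory=QCPolicy)

    @property
    def trust(self) -> Optional[float]:
        """Running test-question accuracy; None with no test answers yet."""
        if not self.test_outcomes:
            return None
        return sum(self.test_outcomes) / len(self.test_outcomes)

    @property
    def trusted(self) -> bool:
        """Whether the running trust meets the policy threshold."""
        t = self.trust
        return t is not None and t >= self.policy.min_test_accuracy


def update_trust(contributor: Contributor, outcome: bool) -> Contributor:
    """Append one test-question outcome and recompute trust."""
    return replace(
        contributor,
        test_outcomes=contributor.test_outcomes + (bool(outcome),),
    )


def gate(records: pd.DataFrame, policy: QCPolicy = QCPolicy()) -> pd.DataFrame:
    """Apply the QC policy to one or more contributors' task streams.

    ``records`` needs columns ``contributor_id``, ``timestamp`` (sortable,
    must be non-decreasing per contributor), ``elapsed_seconds``,
    ``is_test_question`` and, for test questions, ``correct``.  Returns a
    copy with ``status`` in {``trusted``, ``untrusted``, ``excluded``} and
    a ``reason`` column; no rows are dropped.

    Exclusions: judgments beyond ``max_judgments`` (``judgment-cap``) and
    tasks faster than ``min_seconds_per_task`` (``fast-task``).  Once a
    contributor has reviewed ``min_images_before_trust`` images, records
    are ``untrusted`` (``low-accuracy``) whenever the running test
    accuracy sits below threshold.
    """
    required = {"contributor_id", "timestamp", "elapsed_seconds",
                "is_test_question"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    out = records.copy()
    out["status"] = "trusted"
    out["reason"] = ""
    for cid, group in records.groupby("contributor_id", sort=False):
        ts = group["timestamp"].to_numpy()
        if np.any(ts[1:] < ts[:-1]):
            raise ValueError(f"contributor {cid}: timestamps not ordered")
        n_correct = n_tests = n_images = n_judgments = 0
        for idx, row in group.iterrows():
            n_judgments += 1
            status, reason = "trusted", ""
            if n_judgments > policy.max_judgments:
                status, reason = "excluded", "judgment-cap"
            elif row["elapsed_seconds"] < policy.min_seconds_per_task:
                status, reason = "excluded", "fast-task"
            else:
                past_grace = n_images >= policy.min_images_before_trust
                below = n_tests > 0 and (
                    n_correct / n_tests < policy.min_test_accuracy
                )
                if past_grace and below:
                    status, reason = "untrusted", "low-accuracy"
            if row["is_test_question"]:
                n_tests += 1
                n_correct += int(bool(row.get("correct", False)))
            n_images += 1
            out.loc[idx, ["status", "reason"]] = (status, reason)
    return out


@dataclass(frozen=True)
class LearningCurve:
    """Per-group accuracy over each contributor's labeling timeline."""

    group_size: int
    n_groups: int
    #: columns: contributor_id, group_index, n, accuracy
    per_group: pd.DataFrame
    #: Spearman ρ between a contributor's total volume and overall accuracy.
    volume_accuracy_correlation: float

    def mean_curve(self) -> pd.Series:
        """Mean accuracy per group index across contributors."""
        return self.per_group.groupby("group_index")["accuracy"].mean()


def learning_curve(
    records: pd.DataFrame, group_size: int = 40, n_groups: int = 10
) -> LearningCurve:
    """Learning-effect analysis of time-ordered scored records.

    ``records`` needs ``contributor_id``, ``timestamp`` and ``correct``
    (agreement with reference).  Each contributor's stream is cut into
    consecutive groups of ``group_size`` records (at most ``n_groups``;
    a final partial group keeps its true size).  The volume–accuracy
    correlation is the Spearman ρ across contributors between number of
    records and overall accuracy (nan with fewer than 3 contributors or
    no variance).
    """
    required = {"contributor_id", "timestamp", "correct"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    rows = []
    volumes, accuracies = [], []
    for cid, group in records.groupby("contributor_id", sort=False):
        ordered = group.sort_values("timestamp", kind="stable")
        correct = ordered["correct"].to_numpy(dtype=float)
        volumes.append(len(correct))
        accuracies.append(float(correct.mean()))
        for g in range(min(n_groups, -(-len(correct) // group_size))):
            chunk = correct[g * group_size : (g + 1) * group_size]
            rows.append(
                {
                    "contributor_id": cid,
                    "group_index": g,
                    "n": len(chunk),
                    "accuracy": float(chunk.mean()),
                }
            )
    per_group = pd.DataFrame(rows)
    if len(volumes) >= 3 and np.ptp(volumes) > 0 and np.ptp(accuracies) > 0:
        rho = float(stats.spearmanr(volumes, accuracies).statistic)
    else:
        if len(volumes) < 3:
            warnings.warn("fewer than 3 contributors; volume correlation undefined")
        rho = float("nan")
    return LearningCurve(
        group_size=group_size,
        n_groups=n_groups,
        per_group=per_group,
        volume_accuracy_correlation=rho,
    )
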