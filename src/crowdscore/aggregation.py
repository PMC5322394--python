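"""Fusion of multiple crowd annotations into one label per image/patient.

Four image-level rules fuse repeated class votes on the same image:

* ``cv``  — maximum crowd votes: the class with the most votes;
* ``ct``  — maximum crowd trust: the class with the largest sum of the
  voters' trust scores;
* ``wcv`` — weighted crowd votes: the class whose interval contains the
  vote-weighted mean positivity  s = Σ_k ω_k·V_k / Σ_k V_k;
* ``wct`` — weighted crowd trust: as ``wcv`` with trust sums T_k in place
  of vote counts V_k.

A fifth rule fuses nucleus *counts*: the per-image median positive and
negative counts across contributors give a positivity index, which is
binned into a class.  Patient-level calls are the median of the patient's
per-image labels on the ordinal scale.

Tie-breaking (the fusion rules alone do not determine a unique winner):
``cv`` ties go first to the tied class with the larger trust sum, then to
the higher ordinal (more positive) class; ``ct`` ties go to the higher
ordinal class.  The positive-leaning fallback keeps the pipeline
deterministic and mirrors the crowd's observed positive bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .label_model import (
    FOUR_CLASS,
    THREE_CLASS,
    LabelClass,
    LabelScheme,
    NoNucleiError,
    UnscorableImageError,
    compute_pindex,
)

__all__ = [
    "CrowdVoteRecord",
    "NucleiCountRecord",
    "AggregatedLabel",
    "MissingTrustError",
    "aggregate_cv",
    "aggregate_ct",
    "aggregate_weighted",
    "aggregate_nuclei",
    "aggregate_patient",
    "aggregate_images",
    "aggregate_nuclei_images",
    "AGGREGATORS",
]

AGGREGATORS = ("cv", "ct", "wcv", "wct")


class MissingTrustError(ValueError):
    """Raised when a trust-based rule is applied to votes without trust scores."""


@dataclass(frozen=True)
class CrowdVoteRecord:
    """One contributor's class vote on one image."""

    image_id: str
    contributor_id: str
    label: LabelClass
    trust: Optional[float] = None
    elapsed_seconds: float = 0.0
    is_test_question: bool = False

    def __post_init__(self) -> None:
        if self.trust is not None and not 0.0 <= self.trust <= 1.0:
            raise ValueError(f"trust must lie in [0,1], got {self.trust}")
        if self.elapsed_seconds < 0:
            raise ValueError("elapsed_seconds must be non-negative")


@dataclass(frozen=True)
class NucleiCountRecord:
    """One contributor's positive/negative nucleus counts for one image."""

    image_id: str
    contributor_id: str
    n_positive: int
    n_negative: int
    has_nuclei: bool = True

    def __post_init__(self) -> None:
        if self.n_positive < 0 or self.n_negative < 0:
            raise ValueError("nucleus counts must be non-negative")
        if not self.has_nuclei and (self.n_positive or self.n_negative):
            raise ValueError("has_nuclei=False requires zero counts")


@dataclass(frozen=True)
class AggregatedLabel:
    """Fused label for one image, with the tallies that produced it."""

    image_id: str
    label: LabelClass
    method: str
    support: dict = field(default_factory=dict)
    n_annotations: int = 0


def _check_votes(votes: Sequence[CrowdVoteRecord]) -> str:
    if not votes:
        raise ValueError("cannot aggregate an empty vote list")
    image_id = votes[0].image_id
    if any(v.image_id != image_id for v in votes):
        raise ValueError("all votes must refer to the same image")
    return image_id


def _tallies(
    votes: Sequence[CrowdVoteRecord], scheme: LabelScheme, need_trust: bool
) -> tuple[np.ndarray, np.ndarray]:
    counts = np.zeros(len(scheme.classes))
    trusts = np.zeros(len(scheme.classes))
    for v in votes:
        rank = scheme.by_code(v.label.code).ordinal_rank
        counts[rank] += 1
        if v.trust is None:
            if need_trust:
                raise MissingTrustError(
                    "vote without a trust score; use the plain vote rule (cv) "
                    "or supply trust for every vote"
                )
        else:
            trusts[rank] += v.trust
    return counts, trusts


def _argmax_tiebreak(*keys: np.ndarray) -> np.ndarray:
    """Row-wise argmax over successive tie-breaking keys.

    Each key is an (n, K) array; later keys resolve ties of earlier ones.
    Remaining ties go to the highest column index (higher ordinal class).
    """
    cand = np.ones_like(keys[0], dtype=bool)
    for key in keys:
        masked = np.where(cand, key, -np.inf)
        cand &= masked == masked.max(axis=1, keepdims=True)
    ncol = keys[0].shape[1]
    return np.where(cand, np.arange(ncol), -1).max(axis=1)


def aggregate_cv(
    votes: Sequence[CrowdVoteRecord], scheme: LabelScheme = FOUR_CLASS
) -> AggregatedLabel:
    """Majority vote: class with most votes (ties: trust sum, then positive)."""
    image_id = _check_votes(votes)
    counts, trusts = _tallies(votes, scheme, need_trust=False)
    rank = int(_argmax_tiebreak(counts[None, :], trusts[None, :])[0])
    support = {f"V_{c.code}": int(n) for c, n in zip(scheme.classes, counts)}
    return AggregatedLabel(
        image_id=image_id,
        label=scheme.by_rank(rank),
        method="cv",
        support=support,
        n_annotations=len(votes),
    )


def aggregate_ct(
    votes: Sequence[CrowdVoteRecord], scheme: LabelScheme = FOUR_CLASS
) -> AggregatedLabel:
    """Trust-weighted vote: class with the largest summed contributor trust."""
    image_id = _check_votes(votes)
    _, trusts = _tallies(votes, scheme, need_trust=True)
    rank = int(_argmax_tiebreak(trusts[None, :])[0])
    support = {f"T_{c.code}": float(t) for c, t in zip(scheme.classes, trusts)}
    return AggregatedLabel(
        image_id=image_id,
        label=scheme.by_rank(rank),
        method="ct",
        support=support,
        n_annotations=len(votes),
    )


def aggregate_weighted(
    votes: Sequence[CrowdVoteRecord],
    mode: str = "wcv",
    scheme: LabelScheme = FOUR_CLASS,
) -> AggregatedLabel:
    """Class-weight fusion: bin the weighted mean positivity into a class.

    ``wcv`` weighs class counts, ``wct`` weighs class trust sums.  The score
    s = Σ ω_k x_k / Σ x_k always lies in [ω_first, ω_last] ⊂ [0,1], so it is
    contained by exactly one class interval.
    """
    if mode not in ("wcv", "wct"):
        raise ValueError(f"mode must be 'wcv' or 'wct', got {mode!r}")
    image_id = _check_votes(votes)
    counts, trusts = _tallies(votes, scheme, need_trust=(mode == "wct"))
    x = counts if mode == "wcv" else trusts
    denom = x.sum()
    if denom == 0:
        raise ValueError(f"{mode}: all tallies are zero, score undefined")
    score = float(x @ scheme.weights / denom)
    label = scheme.bin_fraction(score)
    tag = "V" if mode == "wcv" else "T"
    support = {f"{tag}_{c.code}": v for c, v in zip(scheme.classes, x)}
    support["weighted_score"] = score
    return AggregatedLabel(
        image_id=image_id,
        label=label,
        method=mode,
        support=support,
        n_annotations=len(votes),
    )


def aggregate_nuclei(
    records: Sequence[NucleiCountRecord], scheme: LabelScheme = THREE_CLASS
) -> AggregatedLabel:
    """Median-count fusion: positivity index of median pos/neg counts.

    Contributors reporting no nuclei are treated as detection misses and
    excluded from the medians, provided at least one contributor reports
    nuclei; otherwise the image is unscorable.
    """
    if not records:
        raise ValueError("cannot aggregate an empty record list")
    image_id = records[0].image_id
    if any(r.image_id != image_id for r in records):
        raise ValueError("all records must refer to the same image")
    with_nuclei = [r for r in records if r.has_nuclei]
    if not with_nuclei:
        raise UnscorableImageError(
            f"image {image_id}: no contributor reported nuclei"
        )
    med_pos = float(np.median([r.n_positive for r in with_nuclei]))
    med_neg = float(np.median([r.n_negative for r in with_nuclei]))
    pindex = compute_pindex(med_pos, med_neg)  # NoNucleiError if both medians 0
    label = scheme.bin_fraction(pindex.value)
    return AggregatedLabel(
        image_id=image_id,
        label=label,
        method="nuclei",
        support={
            "median_positive": med_pos,
            "median_negative": med_neg,
            "pindex": pindex.value,
        },
        n_annotations=len(records),
    )


def aggregate_patient(
    labels: Sequence[LabelClass], scheme: LabelScheme
) -> LabelClass:
    """Median of a patient's per-image labels on the ordinal scale.

    For an even number of images the mean of the two middle ranks is taken
    and half-ranks round toward the higher (more positive) class.
    """
    if not labels:
        raise ValueError("cannot aggregate an empty label list")
    ranks = sorted(scheme.by_code(lab.code).ordinal_rank for lab in labels)
    n = len(ranks)
    if n % 2 == 1:
        med = ranks[n // 2]
    else:
        med = math.floor((ranks[n // 2 - 1] + ranks[n // 2]) / 2 + 0.5)
    return scheme.by_rank(int(med))


# ---------------------------------------------------------------------------
# DataFrame (vectorised) interface
# ---------------------------------------------------------------------------


def _pivots(
    votes: pd.DataFrame, scheme: LabelScheme, need_trust: bool
) -> tuple[pd.Index, np.ndarray, np.ndarray]:
    codes = list(scheme.codes)
    unknown = set(votes["label"].unique()) - set(codes)
    if unknown:
        raise ValueError(f"labels not in scheme {scheme.name}: {sorted(unknown)}")
    counts = (
        pd.crosstab(votes["image_id"], votes["label"])
        .reindex(columns=codes, fill_value=0)
        .astype(float)
    )
    have_trust = "trust" in votes.columns
    if need_trust and (not have_trust or votes["trust"].isna().any()):
        raise MissingTrustError(
            "trust column missing or incomplete; use method='cv'"
        )
    if have_trust:
        trusts = (
            votes.assign(trust=votes["trust"].fillna(0.0))
            .pivot_table(
                index="image_id",
                columns="label",
                values="trust",
                aggfunc="sum",
                fill_value=0.0,
            )
            .reindex(index=counts.index, columns=codes, fill_value=0.0)
            .to_numpy(dtype=float)
        )
    else:
        trusts = np.zeros_like(counts.to_numpy())
    return counts.index, counts.to_numpy(), trusts


def aggregate_images(
    votes: pd.DataFrame, method: str = "cv", scheme: LabelScheme = FOUR_CLASS
) -> pd.DataFrame:
    """Fuse a vote table into one label per image.

    ``votes`` needs columns ``image_id``, ``contributor_id``, ``label``
    (class codes) and, for trust-based methods, ``trust``.  Returns a frame
    indexed 0..n with columns ``image_id``, ``method``, ``label``,
    ``n_annotations`` and per-class support tallies.
    """
    if method not in AGGREGATORS:
        raise ValueError(f"method must be one of {AGGREGATORS}, got {method!r}")
    if votes.empty:
        raise ValueError("empty vote table")
    need_trust = method in ("ct", "wct")
    index, V, T = _pivots(votes, scheme, need_trust)
    out = pd.DataFrame({"image_id": index.to_numpy(), "method": method})
    out["n_annotations"] = V.sum(axis=1).astype(int)

    if method == "cv":
        ranks = _argmax_tiebreak(V, T)
    elif method == "ct":
        ranks = _argmax_tiebreak(T)
    else:
        X = V if method == "wcv" else T
        denom = X.sum(axis=1)
        if np.any(denom == 0):
            raise ValueError(f"{method}: images with all-zero tallies")
        scores = X @ scheme.weights / denom
        ranks = scheme.bin_fractions(scores)
        out["weighted_score"] = scores

    out["label"] = [scheme.classes[int(r)].code for r in ranks]
    for j, code in enumerate(scheme.codes):
        out[f"V_{code}"] = V[:, j].astype(int)
        out[f"T_{code}"] = T[:, j]
    cols = ["image_id", "method", "label", "n_annotations"] + [
        c for c in out.columns
        if c not in ("image_id", "method", "label", "n_annotations")
    ]
    return out[cols]


def aggregate_nuclei_images(
    nuclei: pd.DataFrame, scheme: LabelScheme = THREE_CLASS
) -> pd.DataFrame:
    """Median-count fusion for a whole nucleus-count table.

    ``nuclei`` needs columns ``image_id``, ``contributor_id``,
    ``n_positive``, ``n_negative``, ``has_nuclei``.  Images where no
    contributor reports nuclei, or where both median counts are zero, come
    back with label ``NA`` (unscorable) rather than raising, so one bad
    image does not abort a batch; record-level :func:`aggregate_nuclei`
    raises for them.
    """
    if nuclei.empty:
        raise ValueError("empty nucleus-count table")
    n_annot = nuclei.groupby("image_id").size()
    seen = nuclei[nuclei["has_nuclei"].astype(bool)]
    med = seen.groupby("image_id")[["n_positive", "n_negative"]].median()
    med = med.reindex(n_annot.index)
    total = med["n_positive"] + med["n_negative"]
    scorable = total.notna() & (total > 0)
    pindex = pd.Series(np.nan, index=med.index)
    pindex[scorable] = med.loc[scorable, "n_positive"] / total[scorable]
    labels = pd.Series("NA", index=med.index, dtype=object)
    if scorable.any():
        ranks = scheme.bin_fractions(pindex[scorable].to_numpy())
        labels[scorable] = [scheme.classes[int(r)].code for r in ranks]
    return pd.DataFrame(
        {
            "image_id": med.index.to_numpy(),
            "method": "nuclei",
            "label": labels.to_numpy(),
            "n_annotations": n_annot.to_numpy(),
            "median_positive": med["n_positive"].to_numpy(),
            "median_negative": med["n_negative"].to_numpy(),
            "pindex": pindex.to_numpy(),
        }
    )


def aggregate_patients(
    image_labels: pd.DataFrame, scheme: LabelScheme
) -> pd.DataFrame:
    """Patient-level rollup of per-image labels.

    ``image_labels`` needs columns ``patient_id`` and ``label`` (class
    codes); rows with label ``NA`` are dropped.  Returns ``patient_id``,
    ``label``, ``n_images``.
    """
    ok = image_labels[image_labels["label"] != "NA"]
    if ok.empty:
        raise ValueError("no scorable images to roll up")
    rank_of = {c.code: c.ordinal_rank for c in scheme.classes}
    ranks = ok["label"].map(rank_of)
    if ranks.isna().any():
        bad = ok.loc[ranks.isna(), "label"].unique()
        raise ValueError(f"labels not in scheme {scheme.name}: {list(bad)}")

    def _median_rank(r: pd.Series) -> int:
        vals = np.sort(r.to_numpy())
        n = len(vals)
        if n % 2 == 1:
            return int(vals[n // 2])
        return int(math.floor((vals[n // 2 - 1] + vals[n // 2]) / 2 + 0.5))

    grouped = ranks.groupby(ok["patient_id"])
    med = grouped.apply(_median_rank)
    return pd.DataFrame(
        {
            "patient_id": med.index.to_numpy(),
            "label": [scheme.classes[m].code for m in med],
            "n_images": grouped.size().to_numpy(),
        }
    )
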