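"""Crowd-size sensitivity analysis.

How many crowd labels per image are enough?  For each crowd size k the
sweep draws k-label subsets of each image's collected labels, aggregates
every subset, and records agreement of the (scheme-merged) aggregate with
the reference label.  When an image's C(n, k) subsets exceed
``max_combinations`` a seeded sample of distinct subsets is used instead
of full enumeration.  The curve of mean agreement against k typically
rises steeply from k=1 and plateaus around k=3 for above-chance crowds.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregation import (
    AGGREGATORS,
    CrowdVoteRecord,
    aggregate_ct,
    aggregate_cv,
    aggregate_weighted,
)
from .label_model import (
    FOUR_CLASS,
    THREE_CLASS,
    LabelScheme,
    scheme_mapping,
)

__all__ = ["SensitivityCurve", "crowd_size_sweep"]


@dataclass(frozen=True)
class SensitivityCurve:
    """Mean agreement with reference as a function of crowd size k."""

    crowd_sizes: tuple[int, ...]
    mean_agreement: tuple[float, ...]
    #: Std-dev across images of the per-image mean subset agreement.
    dispersion: tuple[float, ...]
    #: Total number of label subsets evaluated at each k.
    n_combinations_used: tuple[int, ...]
    scheme: LabelScheme
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.crowd_sizes,
                "mean_agreement": self.mean_agreement,
                "sd": self.dispersion,
                "n_combinations": self.n_combinations_used,
            }
        )


def _aggregate_subset(
    votes: Sequence[CrowdVoteRecord], aggregator: str, scheme: LabelScheme
) -> str:
    if aggregator == "cv":
        return aggregate_cv(votes, scheme).label.code
    if aggregator == "ct":
        return aggregate_ct(votes, scheme).label.code
    return aggregate_weighted(votes, aggregator, scheme).label.code


def _subsets(n: int, k: int, max_combinations: int, rng: np.random.Generator):
    total = math.comb(n, k)
    if total <= max_combinations:
        yield from itertools.combinations(range(n), k)
        return
    seen: set[tuple[int, ...]] = set()
    while len(seen) < max_combinations:
        combo = tuple(sorted(rng.choice(n, size=k, replace=False).tolist()))
        if combo not in seen:
            seen.add(combo)
            yield combo


def crowd_size_sweep(
    votes: pd.DataFrame,
    reference: Mapping[str, str],
    k_range: Sequence[int],
    aggregator: str = "cv",
    max_combinations: int = 100,
    seed: int = 0,
    vote_scheme: LabelScheme = FOUR_CLASS,
    compare_scheme: LabelScheme = THREE_CLASS,
) -> SensitivityCurve:
    """Agreement-vs-crowd-size curve over subsets of collected labels.

    ``votes`` is the long vote table (``image_id``, ``contributor_id``,
    ``label``, ``trust``); ``reference`` maps image_id to its reference
    class code in ``compare_scheme``.  Aggregated labels are merged from
    ``vote_scheme`` into ``compare_scheme`` before comparison.  Per-image
    subset agreements are averaged per image, then across images.
    """
    if aggregator not in AGGREGATORS:
        raise ValueError(f"aggregator must be one of {AGGREGATORS}")
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range or k_range[0] < 1:
        raise ValueError("crowd sizes must be positive integers")
    missing = set(votes["image_id"]) - set(reference)
    if missing:
        raise ValueError(f"reference missing for images: {sorted(missing)[:5]}")

    merge = {
        code: cls.code
        for code, cls in scheme_mapping(vote_scheme, compare_scheme).items()
    }
    rng = np.random.default_rng(seed)

    per_image: list[tuple[str, list[CrowdVoteRecord]]] = []
    for image_id, group in votes.groupby("image_id", sort=True):
        recs = [
            CrowdVoteRecord(
                image_id=str(image_id),
                contributor_id=str(r.contributor_id),
                label=vote_scheme.by_code(r.label),
                trust=None if pd.isna(r.trust) else float(r.trust),
            )
            for r in group.itertuples()
        ]
        per_image.append((str(image_id), recs))

    k_max = max(k_range)
    for image_id, recs in per_image:
        if len(recs) < k_max:
            raise ValueError(
                f"image {image_id} has {len(recs)} labels, fewer than "
                f"requested crowd size {k_max}"
            )

    means, sds, n_used = [], [], []
    for k in k_range:
        image_means = []
        total_subsets = 0
        for image_id, recs in per_image:
            ref = reference[image_id]
            agreements = []
            for combo in _subsets(len(recs), k, max_combinations, rng):
                subset = [recs[i] for i in combo]
                code = _aggregate_subset(subset, aggregator, vote_scheme)
                agreements.append(1.0 if merge[code] == ref else 0.0)
            image_means.append(float(np.mean(agreements)))
            total_subsets += len(agreements)
        means.append(float(np.mean(image_means)))
        sds.append(float(np.std(image_means)))
        n_used.append(total_subsets)

    return SensitivityCurve(
        crowd_sizes=tuple(k_range),
        mean_agreement=tuple(means),
        dispersion=tuple(sds),
        n_combinations_used=tuple(n_used),
        scheme=compare_scheme,
        seed=seed,
    )
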