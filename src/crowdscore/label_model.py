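"""Ordinal label system for immunohistochemistry (IHC) scoring.

Estrogen-receptor (ER) stained tissue is scored by the fraction of tumour
nuclei that stain positive (brown, DAB) as opposed to negative (blue,
hematoxylin).  That fraction — the *positivity index* — is discretised into
ordered classes:

* ``four_class`` — A (negative, <1%), B (low positive, 1–10%),
  C (positive, 10–50%), D (high positive, >50%);
* ``three_class`` — the pathologist convention Neg / Low Pos / Pos,
  obtained from ``four_class`` by merging D into C;
* ``two_class`` — Neg / Pos, all positive classes merged.

Every interval is half-open ``[lower, upper)`` with the top class closed at
1.0, so each fraction in [0, 1] belongs to exactly one class.  Each class
carries a weight used by the weighted vote-fusion rules: the mid-point of
its interval, with class B kept at the conventional rounded value 0.05
(the exact mid-point of [0.01, 0.1) is 0.055).

Fractions are stored as proportions in [0, 1]; printed percentage
thresholds are divided by 100.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Union

import numpy as np

__all__ = [
    "LabelClass",
    "LabelScheme",
    "PositivityIndex",
    "FOUR_CLASS",
    "THREE_CLASS",
    "TWO_CLASS",
    "SCHEMES",
    "compute_pindex",
    "label_from_fraction",
    "merge_label",
    "scheme_mapping",
    "NoNucleiError",
    "UnscorableImageError",
    "SchemeCompatibilityError",
]


class NoNucleiError(ValueError):
    """Raised when a positivity index is requested for zero counted nuclei."""


class UnscorableImageError(ValueError):
    """Raised when no contributor reports any nuclei for an image."""


class SchemeCompatibilityError(ValueError):
    """Raised when a label cannot be mapped between two schemes."""


@dataclass(frozen=True)
class LabelClass:
    """One ordinal scoring class: a half-open positivity interval plus weight.

    ``weight`` is the class's representative positivity fraction, used by the
    weighted aggregation rules; by construction it lies inside the class
    interval.
    """

    code: str
    ordinal_rank: int
    lower_bound: float
    upper_bound: float
    weight: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower_bound < self.upper_bound <= 1.0:
            raise ValueError(
                f"class {self.code}: bounds must satisfy "
                f"0 <= lower < upper <= 1, got [{self.lower_bound}, {self.upper_bound}]"
            )
        if not self.lower_bound <= self.weight < self.upper_bound:
            raise ValueError(
                f"class {self.code}: weight {self.weight} outside "
                f"[{self.lower_bound}, {self.upper_bound})"
            )

    def contains(self, fraction: float) -> bool:
        """Whether ``fraction`` falls in this class's half-open interval.

        The top class (upper bound 1.0) is closed on the right.
        """
        if self.upper_bound == 1.0 and fraction == 1.0:
            return True
        return self.lower_bound <= fraction < self.upper_bound


@dataclass(frozen=True)
class LabelScheme:
    """An ordered set of :class:`LabelClass` intervals tiling [0, 1]."""

    name: str
    classes: tuple[LabelClass, ...]

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("a scheme needs at least one class")
        lo = 0.0
        for rank, cls in enumerate(self.classes):
            if cls.ordinal_rank != rank:
                raise ValueError(
                    f"scheme {self.name}: ordinal ranks must be 0..K-1 in order"
                )
            if cls.lower_bound != lo:
                raise ValueError(
                    f"scheme {self.name}: class intervals must tile [0,1] "
                    f"without gaps (class {cls.code} starts at {cls.lower_bound}, "
                    f"expected {lo})"
                )
            lo = cls.upper_bound
        if lo != 1.0:
            raise ValueError(f"scheme {self.name}: intervals must end at 1.0")

    # -- lookups ---------------------------------------------------------

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(c.code for c in self.classes)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.classes])

    def by_code(self, code: str) -> LabelClass:
        for cls in self.classes:
            if cls.code == code:
                return cls
        raise KeyError(f"scheme {self.name} has no class {code!r}")

    def by_rank(self, rank: int) -> LabelClass:
        return self.classes[rank]

    # -- binning ---------------------------------------------------------

    def bin_fraction(self, fraction: float) -> LabelClass:
        """Map a positivity fraction to its unique class."""
        return self.classes[int(self.bin_fractions(np.array([fraction]))[0])]

    def bin_fractions(self, fractions: np.ndarray) -> np.ndarray:
        """Vectorised binning; returns ordinal ranks.

        Raises ``ValueError`` if any fraction lies outside [0, 1].
        """
        arr = np.asarray(fractions, dtype=float)
        if np.any((arr < 0.0) | (arr > 1.0)) or np.any(np.isnan(arr)):
            bad = arr[(arr < 0.0) | (arr > 1.0) | np.isnan(arr)]
            raise ValueError(f"fractions outside [0, 1]: {bad[:5]}")
        uppers = np.array([c.upper_bound for c in self.classes])
        idx = np.searchsorted(uppers, arr, side="right")
        # fraction exactly 1.0 lands past the top interval; fold it back
        return np.minimum(idx, len(self.classes) - 1)

    # -- (de)serialisation -----------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "classes": [
                {
                    "code": c.code,
                    "lower_bound": c.lower_bound,
                    "upper_bound": c.upper_bound,
                    "weight": c.weight,
                }
                for c in self.classes
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "LabelScheme":
        classes = tuple(
            LabelClass(
                code=c["code"],
                ordinal_rank=rank,
                lower_bound=float(c["lower_bound"]),
                upper_bound=float(c["upper_bound"]),
                weight=float(c["weight"]),
            )
            for rank, c in enumerate(data["classes"])
        )
        return cls(name=data["name"], classes=classes)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LabelScheme":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class PositivityIndex:
    """Fraction of counted nuclei that are positively stained."""

    value: float
    n_positive: float
    n_negative: float


#: Crowd-facing 4-class scheme with the conventional class weights.
FOUR_CLASS = LabelScheme(
    "four_class",
    (
        LabelClass("A", 0, 0.00, 0.01, 0.005),
        LabelClass("B", 1, 0.01, 0.10, 0.05),
        LabelClass("C", 2, 0.10, 0.50, 0.30),
        LabelClass("D", 3, 0.50, 1.00, 0.75),
    ),
)

#: Pathologist 3-class scheme (Neg / Low Pos / Pos); four_class with D merged into C.
THREE_CLASS = LabelScheme(
    "three_class",
    (
        LabelClass("A", 0, 0.00, 0.01, 0.005),
        LabelClass("B", 1, 0.01, 0.10, 0.05),
        LabelClass("C", 2, 0.10, 1.00, 0.55),
    ),
)

#: Binary Neg / Pos scheme; all positive classes merged into B.
TWO_CLASS = LabelScheme(
    "two_class",
    (
        LabelClass("A", 0, 0.00, 0.01, 0.005),
        LabelClass("B", 1, 0.01, 1.00, 0.505),
    ),
)

SCHEMES: dict[str, LabelScheme] = {
    s.name: s for s in (FOUR_CLASS, THREE_CLASS, TWO_CLASS)
}


def compute_pindex(
    n_positive: Union[int, float], n_negative: Union[int, float]
) -> PositivityIndex:
    """Positivity index PIndex = n_pos / (n_pos + n_neg).

    Counts may be non-integer (e.g. medians across contributors).  Raises
    :class:`NoNucleiError` when both counts are zero — an image with no
    counted nuclei cannot be scored from counts.
    """
    if n_positive < 0 or n_negative < 0:
        raise ValueError("nucleus counts must be non-negative")
    total = n_positive + n_negative
    if total == 0:
        raise NoNucleiError("no nuclei: cannot compute a positivity index")
    return PositivityIndex(
        value=n_positive / total, n_positive=n_positive, n_negative=n_negative
    )


def label_from_fraction(fraction: float, scheme: LabelScheme = FOUR_CLASS) -> LabelClass:
    """Bin a positivity fraction into the unique class whose interval contains it."""
    return scheme.bin_fraction(fraction)


def scheme_mapping(
    from_scheme: LabelScheme, to_scheme: LabelScheme
) -> dict[str, LabelClass]:
    """Class-code mapping for collapsing ``from_scheme`` onto a coarser scheme.

    Valid only when every source interval nests inside a single target
    interval (e.g. four→three merges D into C; three→two merges B and C
    into B).  The identity mapping of a scheme onto itself is allowed.
    """
    if len(to_scheme.classes) > len(from_scheme.classes):
        raise SchemeCompatibilityError(
            f"cannot merge {from_scheme.name} into the finer scheme {to_scheme.name}"
        )
    mapping: dict[str, LabelClass] = {}
    for src in from_scheme.classes:
        lo_target = to_scheme.bin_fraction(src.lower_bound)
        hi_probe = np.nextafter(src.upper_bound, src.lower_bound)
        hi_target = to_scheme.bin_fraction(float(hi_probe))
        if lo_target is not hi_target:
            raise SchemeCompatibilityError(
                f"class {src.code} of {from_scheme.name} spans a boundary of "
                f"{to_scheme.name}"
            )
        mapping[src.code] = lo_target
    return mapping


def merge_label(
    label: LabelClass, from_scheme: LabelScheme, to_scheme: LabelScheme
) -> LabelClass:
    """Map a label into a coarser scheme (A stays A; positives merge)."""
    return scheme_mapping(from_scheme, to_scheme)[label.code]
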