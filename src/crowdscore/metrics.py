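"""Inter-observer reliability and classification-performance statistics.

The pipeline compares aggregated crowd (or automated) calls against
reference pathologist labels with:

* a confusion matrix (rows = actual/reference, columns = predicted) and
  percent agreement A_g = trace / total;
* chance-corrected agreement κ — Cohen's kappa for two raters, Fleiss'
  kappa for more;
* the mean of pairwise Spearman rank correlations between raters
  (ordinal labels, average ranks for ties);
* the intraclass correlation ICC(2,1): two-way random effects, absolute
  agreement, single rater — the standard form when the same raters rate
  all items.

Degenerate inputs (all raters constant, zero between-item variance) make
chance agreement 1 and leave κ/ICC undefined; these return ``nan`` with a
warning rather than raising, so a batch report can still be produced.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats import inter_rater

from .label_model import LabelScheme, SCHEMES, scheme_mapping

__all__ = [
    "ConfusionMatrix",
    "AgreementReport",
    "confusion",
    "percent_agreement",
    "collapse_confusion",
    "kappa",
    "spearman_interobserver",
    "icc",
    "agreement_report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """K×K counts of actual (rows) vs predicted (columns) labels."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        k = len(self.classes)
        if counts.shape != (k, k):
            raise ValueError(
                f"counts must be {k}x{k} for classes {self.classes}, "
                f"got shape {counts.shape}"
            )
        if (counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.classes), columns=list(self.classes)
        )

    def to_csv(self, path) -> None:
        self.to_frame().rename_axis("actual").to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ConfusionMatrix":
        frame = pd.read_csv(path, index_col=0)
        if list(frame.index) != list(frame.columns):
            raise ValueError("confusion CSV must have identical row/column labels")
        return cls(tuple(frame.columns), frame.to_numpy())

    def to_label_pairs(self) -> tuple[list[str], list[str]]:
        """Expand the matrix back into (actual, predicted) label vectors."""
        actual: list[str] = []
        predicted: list[str] = []
        for i, a in enumerate(self.classes):
            for j, p in enumerate(self.classes):
                n = int(self.counts[i, j])
                actual.extend([a] * n)
                predicted.extend([p] * n)
        return actual, predicted


@dataclass(frozen=True)
class AgreementReport:
    """Bundle of agreement statistics for one method/scheme comparison."""

    percent_agreement: float
    kappa: float
    spearman: float
    icc: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def confusion(
    actual: Sequence[str], predicted: Sequence[str], classes: Sequence[str]
) -> ConfusionMatrix:
    """Tally actual vs predicted labels over a fixed ordered class list."""
    if len(actual) != len(predicted):
        raise ValueError(
            f"length mismatch: {len(actual)} actual vs {len(predicted)} predicted"
        )
    classes = tuple(classes)
    lut = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for a, p in zip(actual, predicted):
        if a not in lut or p not in lut:
            raise ValueError(f"label outside class list {classes}: ({a!r}, {p!r})")
        counts[lut[a], lut[p]] += 1
    return ConfusionMatrix(classes, counts)


def percent_agreement(cm: ConfusionMatrix) -> float:
    """A_g: number of agreed labels divided by total number of labels."""
    if cm.grand_total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.grand_total)


def _infer_scheme(classes: Sequence[str]) -> LabelScheme:
    for scheme in SCHEMES.values():
        if tuple(classes) == scheme.codes:
            return scheme
    raise ValueError(
        f"cannot infer a label scheme from classes {tuple(classes)}; "
        "pass from_scheme explicitly"
    )


def collapse_confusion(
    cm: ConfusionMatrix,
    to_scheme: LabelScheme,
    from_scheme: Optional[LabelScheme] = None,
) -> ConfusionMatrix:
    """Merge confusion cells under a class collapse (e.g. 3-class → 2-class)."""
    if from_scheme is None:
        from_scheme = _infer_scheme(cm.classes)
    mapping = scheme_mapping(from_scheme, to_scheme)
    target_codes = to_scheme.codes
    idx = {c: i for i, c in enumerate(target_codes)}
    out = np.zeros((len(target_codes), len(target_codes)), dtype=int)
    for i, a in enumerate(cm.classes):
        for j, p in enumerate(cm.classes):
            out[idx[mapping[a].code], idx[mapping[p].code]] += cm.counts[i, j]
    return ConfusionMatrix(target_codes, out)


def _as_codes(ratings: Sequence[Sequence]) -> np.ndarray:
    """Raters × items matrix of ordinal codes (labels sort lexically: A<B<C<D)."""
    arr = np.asarray(ratings)
    if arr.ndim != 2:
        raise ValueError("ratings must be a raters × items table")
    if arr.dtype.kind in "OUS":
        classes = np.unique(arr)
        lut = {c: i for i, c in enumerate(classes)}
        arr = np.vectorize(lut.get)(arr)
    return arr.astype(float)


def kappa(ratings: Sequence[Sequence]) -> float:
    """Chance-corrected agreement: Cohen's κ (2 raters) or Fleiss' κ (>2).

    ``ratings`` is a raters × items table of labels.  Returns ``nan`` when
    every rater assigns the same single class to every item (chance
    agreement 1, κ undefined).
    """
    arr = _as_codes(ratings)
    n_raters, n_items = arr.shape
    if n_raters < 2:
        raise ValueError("kappa needs at least 2 raters")
    if n_items < 1:
        raise ValueError("kappa needs at least 1 item")
    if np.unique(arr).size == 1:
        warnings.warn("degenerate ratings: all raters constant; kappa undefined")
        return float("nan")
    if n_raters == 2:
        return float(cohen_kappa_score(arr[0], arr[1]))
    table, _ = inter_rater.aggregate_raters(arr.T.astype(int))
    return float(inter_rater.fleiss_kappa(table, method="fleiss"))


def spearman_interobserver(ratings: Sequence[Sequence]) -> float:
    """Mean of pairwise Spearman rank correlations between raters.

    Pairs involving a constant-rating rater have undefined ρ and are
    excluded with a warning; ties get average ranks.
    """
    arr = _as_codes(ratings)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 raters")
    rhos = []
    for i, j in itertools.combinations(range(arr.shape[0]), 2):
        if np.ptp(arr[i]) == 0 or np.ptp(arr[j]) == 0:
            warnings.warn(
                f"rater pair ({i},{j}) has a constant rater; pair excluded"
            )
            continue
        rho = stats.spearmanr(arr[i], arr[j]).statistic
        rhos.append(rho)
    if not rhos:
        warnings.warn("all rater pairs degenerate; spearman undefined")
        return float("nan")
    return float(np.mean(rhos))


def icc(ratings: Sequence[Sequence[float]]) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is an items × raters matrix of ordinal codes (complete,
    no missing cells).  Returns ``nan`` for zero between-item variance.
    """
    arr = np.asarray(ratings, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("icc needs a complete items × raters matrix, ≥2 each")
    n_items, n_raters = arr.shape
    if np.ptp(arr.mean(axis=1)) == 0 and np.ptp(arr) == 0:
        warnings.warn("degenerate ratings: no variance; ICC undefined")
        return float("nan")
    import pingouin  # deferred: pingouin import is slow

    long = pd.DataFrame(
        {
            "item": np.repeat(np.arange(n_items), n_raters),
            "rater": np.tile(np.arange(n_raters), n_items),
            "score": arr.ravel(),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pingouin.intraclass_corr(
            data=long, targets="item", raters="rater", ratings="score"
        )
    # pingouin labels ICC(2,1) either "ICC2" or "ICC(A,1)" depending on version
    mask = table["Type"].isin(["ICC2", "ICC(A,1)"])
    value = float(table.loc[mask, "ICC"].iloc[0])
    if not np.isfinite(value):
        warnings.warn("ICC undefined for this input")
        return float("nan")
    return value


def agreement_report(
    actual: Sequence[str], predicted: Sequence[str], scheme: LabelScheme
) -> AgreementReport:
    """All agreement statistics for one predicted-vs-reference comparison."""
    cm = confusion(actual, predicted, scheme.codes)
    rank_of = {c: i for i, c in enumerate(scheme.codes)}
    a = np.array([rank_of[x] for x in actual], dtype=float)
    p = np.array([rank_of[x] for x in predicted], dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kap = kappa([list(actual), list(predicted)])
        rho = spearman_interobserver([a, p])
        icc_val = icc(np.column_stack([a, p]))
    return AgreementReport(
        percent_agreement=percent_agreement(cm),
        kappa=kap,
        spearman=rho,
        icc=icc_val,
        n=len(actual),
    )
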