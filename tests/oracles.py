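"""Independent brute-force / closed-form oracles used by the test suite.

Everything here is deliberately written from first principles (definitions
and enumeration), not by calling the package's own code paths, so tests
compare two independent routes to the same quantity.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

# ---------------------------------------------------------------------------
# vote fusion
# ---------------------------------------------------------------------------


def majority_label(votes, trusts=None, n_classes=4):
    """Brute-force majority vote with the declared tie-breaks.

    ``votes`` are ordinal ranks.  Ties by count break on summed trust,
    then on the higher rank.
    """
    votes = list(votes)
    trusts = list(trusts) if trusts is not None else [0.0] * len(votes)
    counts = [votes.count(k) for k in range(n_classes)]
    tsums = [
        sum(t for v, t in zip(votes, trusts) if v == k) for k in range(n_classes)
    ]
    best = max(range(n_classes), key=lambda k: (counts[k], tsums[k], k))
    return best


def trust_label(votes, trusts, n_classes=4):
    """Brute-force maximum-trust-sum vote; ties to the higher rank."""
    tsums = [
        sum(t for v, t in zip(votes, trusts) if v == k) for k in range(n_classes)
    ]
    return max(range(n_classes), key=lambda k: (tsums[k], k))


# ---------------------------------------------------------------------------
# closed-form crowd accuracy
# ---------------------------------------------------------------------------

MERGE_4_TO_3 = (0, 1, 2, 2)


def vote_marginal(mean_accuracy: float, kernel: np.ndarray) -> np.ndarray:
    """P(vote = j | true 4-class t) for i.i.d. contributors.

    Accuracy enters linearly, so heterogeneous i.i.d. accuracies reduce to
    their mean.
    """
    return mean_accuracy * np.eye(4) + (1 - mean_accuracy) * np.asarray(kernel)


def aggregated_3class_distribution(
    t4: int, n_votes: int, marginal: np.ndarray
) -> np.ndarray:
    """Distribution of the merged 3-class majority label of n i.i.d. votes.

    Assumes equal contributor trust, so count ties break to the higher
    ordinal class.
    """
    q = np.zeros(3)
    for votes in itertools.product(range(4), repeat=n_votes):
        p = math.prod(marginal[t4, v] for v in votes)
        q[MERGE_4_TO_3[majority_label(votes)]] += p
    return q


def reference_class_mixture() -> dict[int, dict[int, float]]:
    """True 4-class mixture per 3-class reference, for uniform in-class PIndex.

    Reference C spans [0.1, 1]; its 4-class split at 0.5 gives C with
    probability 4/9 and D with 5/9.
    """
    return {0: {0: 1.0}, 1: {1: 1.0}, 2: {2: 4 / 9, 3: 5 / 9}}


def median_rank(ranks) -> int:
    ranks = sorted(ranks)
    n = len(ranks)
    if n % 2 == 1:
        return ranks[n // 2]
    return math.floor((ranks[n // 2 - 1] + ranks[n // 2]) / 2 + 0.5)


def patient_level_cv_agreement(
    mean_accuracy: float,
    kernel: np.ndarray,
    prevalence,
    images_per_patient_probs,
    n_votes: int = 3,
) -> float:
    """Exact expected patient-level 3-class agreement of majority voting.

    Full enumeration: vote outcomes per image, 4-class truth mixture per
    reference class, and the ordinal median over 1–3 images per patient.
    """
    marginal = vote_marginal(mean_accuracy, kernel)
    mix = reference_class_mixture()
    q_r = {
        r: sum(
            w * aggregated_3class_distribution(t4, n_votes, marginal)
            for t4, w in mix[r].items()
        )
        for r in range(3)
    }
    total = 0.0
    for r, prev in enumerate(prevalence):
        p_correct = 0.0
        for m, pm in zip((1, 2, 3), images_per_patient_probs):
            for labs in itertools.product(range(3), repeat=m):
                p = math.prod(q_r[r][l] for l in labs)
                if median_rank(labs) == r:
                    p_correct += pm * p
        total += prev * p_correct
    return total


def image_level_cv_agreement(
    mean_accuracy: float, kernel: np.ndarray, prevalence, n_votes: int = 3
) -> float:
    """Exact expected image-level 3-class agreement of majority voting."""
    marginal = vote_marginal(mean_accuracy, kernel)
    mix = reference_class_mixture()
    total = 0.0
    for r, prev in enumerate(prevalence):
        q = sum(
            w * aggregated_3class_distribution(t4, n_votes, marginal)
            for t4, w in mix[r].items()
        )
        total += prev * q[r]
    return total


# ---------------------------------------------------------------------------
# agreement statistics from their definitions
# ---------------------------------------------------------------------------


def cohen_kappa(a, b) -> float:
    """Cohen's kappa straight from observed vs chance agreement."""
    a, b = list(a), list(b)
    n = len(a)
    classes = sorted(set(a) | set(b))
    po = sum(x == y for x, y in zip(a, b)) / n
    pe = sum(
        (a.count(c) / n) * (b.count(c) / n) for c in classes
    )
    return (po - pe) / (1 - pe)


def fleiss_kappa(table: np.ndarray) -> float:
    """Fleiss' kappa from the items × categories count table."""
    table = np.asarray(table, dtype=float)
    n_items, _ = table.shape
    n_raters = table[0].sum()
    p_j = table.sum(axis=0) / (n_items * n_raters)
    p_i = ((table**2).sum(axis=1) - n_raters) / (n_raters * (n_raters - 1))
    p_bar = p_i.mean()
    p_e = (p_j**2).sum()
    return (p_bar - p_e) / (1 - p_e)


def mean_pairwise_spearman(ratings: np.ndarray) -> float:
    """Mean pairwise Spearman via explicit average ranks and Pearson."""

    def ranks(x):
        x = np.asarray(x, dtype=float)
        order = np.argsort(x, kind="stable")
        r = np.empty(len(x))
        i = 0
        sorted_x = x[order]
        pos = np.arange(1, len(x) + 1, dtype=float)
        while i < len(x):
            j = i
            while j + 1 < len(x) and sorted_x[j + 1] == sorted_x[i]:
                j += 1
            r[order[i : j + 1]] = pos[i : j + 1].mean()
            i = j + 1
        return r

    def pearson(x, y):
        x, y = x - x.mean(), y - y.mean()
        return (x @ y) / math.sqrt((x @ x) * (y @ y))

    ratings = np.asarray(ratings, dtype=float)
    rhos = [
        pearson(ranks(ratings[i]), ranks(ratings[j]))
        for i, j in itertools.combinations(range(ratings.shape[0]), 2)
    ]
    return float(np.mean(rhos))


def icc_2_1(ratings: np.ndarray) -> float:
    """ICC(2,1) from the two-way ANOVA mean squares."""
    x = np.asarray(ratings, dtype=float)
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


# ---------------------------------------------------------------------------
# subset-sweep enumeration
# ---------------------------------------------------------------------------


def exhaustive_sweep_mean(
    per_image_votes, per_image_trusts, reference, k, merge=MERGE_4_TO_3
) -> float:
    """Mean agreement over ALL k-subsets of each image's votes (majority rule)."""
    image_means = []
    for votes, trusts, ref in zip(per_image_votes, per_image_trusts, reference):
        agreements = []
        for combo in itertools.combinations(range(len(votes)), k):
            sub_votes = [votes[i] for i in combo]
            sub_trusts = [trusts[i] for i in combo]
            lab = merge[majority_label(sub_votes, sub_trusts)]
            agreements.append(1.0 if lab == ref else 0.0)
        image_means.append(np.mean(agreements))
    return float(np.mean(image_means))
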