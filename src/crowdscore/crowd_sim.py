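"""Synthetic crowd generator emulating a TMA-scale ER-scoring study.

The motivating study's TMA images and crowd annotations are not
publicly deposited, so every pipeline stage is exercised on simulated
data with the study's statistical structure:

* ~1,853 patients contributing 1–3 TMA images each, most contributing 3;
* 3-class reference prevalence proportional to 452 / 222 / 1179
  (Neg / Low Pos / Pos);
* each image carries a latent positivity fraction drawn uniformly within
  its reference class interval;
* 3 crowd labels per image from contributors with heterogeneous accuracy
  (Beta-distributed); wrong votes follow an adjacent-class-biased error
  kernel that skews residual mass toward positive classes;
* nucleus counts per contributor: a negative-binomial total split by the
  true positivity fraction, then binomially thinned with a *lower*
  detection sensitivity for negative than positive nuclei — reproducing
  the under-detection of negative cells seen in real crowds;
* gold-standard test-question streams (quiz then judgment mode) for the
  QC module.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .label_model import FOUR_CLASS, THREE_CLASS

__all__ = ["SimulationConfig", "simulate_truth", "simulate_contributors",
           "simulate_image_votes", "simulate_nuclei_counts",
           "simulate_test_stream", "simulate_dataset", "default_error_kernel"]


def default_error_kernel() -> np.ndarray:
    """Per-true-class distribution of *erroneous* votes (rows: true A–D).

    70% of error mass goes to adjacent classes (split 0.45 up / 0.25 down
    when both neighbours exist); the residual 30% is spread over the
    remaining classes proportional to ordinal rank + 1, skewing errors
    toward positive calls.
    """
    kernel = np.zeros((4, 4))
    for t in range(4):
        wrong = [j for j in range(4) if j != t]
        adj = [j for j in wrong if abs(j - t) == 1]
        rest = [j for j in wrong if abs(j - t) > 1]
        if len(adj) == 2:
            kernel[t, t + 1] = 0.45
            kernel[t, t - 1] = 0.25
        else:
            kernel[t, adj[0]] = 0.7
        if rest:
            w = np.array([j + 1.0 for j in rest])
            kernel[t, rest] = 0.3 * w / w.sum()
    return kernel


@dataclass(frozen=True)
class SimulationConfig:
    """Study-structure parameters for the synthetic crowd.

    Defaults emulate the full-scale study: 1,853 patients, ~5,340 images,
    3 labels per image, contributor accuracy Beta(6, 4) (mean 0.6,
    matching a pilot-level raw per-vote agreement of about 6/10), ~150
    nuclei per image, and negative-nucleus detection sensitivity below
    positive (0.75 vs 0.95).
    """

    n_patients: int = 1853
    #: P(patient contributes 1, 2, 3 images); mean 2.88 → ~5,338 images.
    images_per_patient_probs: tuple[float, float, float] = (0.02, 0.08, 0.90)
    #: 3-class reference prevalence (Neg, Low Pos, Pos) ∝ 452/222/1179.
    class_prevalence: tuple[float, float, float] = (
        452 / 1853, 222 / 1853, 1179 / 1853,
    )
    n_contributors: int = 150
    #: Beta(α, β) for per-contributor probability of an exactly correct 4-class vote.
    accuracy_alpha: float = 6.0
    accuracy_beta: float = 4.0
    labels_per_image: int = 3
    #: Rows: true 4-class label; columns: vote distribution given an error.
    error_kernel: Optional[np.ndarray] = None
    #: If set, every vote carries this trust instead of the contributor's accuracy.
    constant_trust: Optional[float] = None
    mean_total_nuclei: float = 150.0
    #: Negative-binomial size parameter; larger → less overdispersed totals.
    nuclei_dispersion: float = 10.0
    detection_sensitivity_positive: float = 0.95
    detection_sensitivity_negative: float = 0.75
    #: Expected spurious positive dots per image per contributor.
    false_positive_rate: float = 0.0
    quiz_size: int = 5
    #: Judgment-mode tasks per contributor (one hidden test item per task).
    n_judgment_tasks: int = 40

    def __post_init__(self) -> None:
        for name, probs in (
            ("images_per_patient_probs", self.images_per_patient_probs),
            ("class_prevalence", self.class_prevalence),
        ):
            arr = np.asarray(probs, dtype=float)
            if (arr < 0).any() or not np.isclose(arr.sum(), 1.0):
                raise ValueError(f"{name} must be non-negative and sum to 1")
        if self.error_kernel is not None:
            k = np.asarray(self.error_kernel, dtype=float)
            if k.shape != (4, 4) or (k < 0).any() or not np.allclose(
                k.sum(axis=1), 1.0
            ) or np.any(np.diag(k) != 0):
                raise ValueError(
                    "error_kernel must be 4x4, zero diagonal, rows summing to 1"
                )
        for name in (
            "detection_sensitivity_positive", "detection_sensitivity_negative",
        ):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.n_patients < 1 or self.n_contributors < 1:
            raise ValueError("n_patients and n_contributors must be positive")
        if self.n_contributors < self.labels_per_image:
            raise ValueError(
                "need at least labels_per_image distinct contributors"
            )

    def kernel(self) -> np.ndarray:
        if self.error_kernel is None:
            return default_error_kernel()
        return np.asarray(self.error_kernel, dtype=float)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_truth(config: SimulationConfig, seed=0) -> pd.DataFrame:
    """Patients, images, reference labels and latent positivity fractions.

    Returns one row per image: ``patient_id``, ``image_id``, ``ref_label``
    (3-class code, shared by all of a patient's images), ``true_pindex``
    (uniform within the reference class interval) and ``true_label4``
    (the 4-class bin of ``true_pindex``).
    """
    rng = _rng(seed)
    n_images_per_patient = rng.choice(
        [1, 2, 3], size=config.n_patients, p=config.images_per_patient_probs
    )
    ref_ranks = rng.choice(3, size=config.n_patients, p=config.class_prevalence)

    patient_ids = np.repeat(
        [f"P{i:05d}" for i in range(config.n_patients)], n_images_per_patient
    )
    ref_per_image = np.repeat(ref_ranks, n_images_per_patient)
    n_images = len(patient_ids)
    image_ids = [f"I{i:05d}" for i in range(n_images)]

    lowers = np.array([c.lower_bound for c in THREE_CLASS.classes])
    uppers = np.array([c.upper_bound for c in THREE_CLASS.classes])
    u = rng.random(n_images)
    pindex = lowers[ref_per_image] + u * (
        uppers[ref_per_image] - lowers[ref_per_image]
    )
    label4 = FOUR_CLASS.bin_fractions(pindex)
    codes3 = np.array(THREE_CLASS.codes)
    codes4 = np.array(FOUR_CLASS.codes)
    return pd.DataFrame(
        {
            "patient_id": patient_ids,
            "image_id": image_ids,
            "ref_label": codes3[ref_per_image],
            "true_pindex": pindex,
            "true_label4": codes4[label4],
        }
    )


def simulate_contributors(config: SimulationConfig, seed=0) -> pd.DataFrame:
    """Contributor pool with Beta-distributed true accuracy.

    ``trust`` defaults to the true accuracy (an idealised platform trust
    score); ``constant_trust`` in the config overrides it, which removes
    trust-based tie-breaking effects.
    """
    rng = _rng(seed)
    acc = rng.beta(config.accuracy_alpha, config.accuracy_beta,
                   size=config.n_contributors)
    trust = (
        np.full(config.n_contributors, config.constant_trust)
        if config.constant_trust is not None
        else acc
    )
    return pd.DataFrame(
        {
            "contributor_id": [f"C{i:04d}" for i in range(config.n_contributors)],
            "accuracy": acc,
            "trust": trust,
        }
    )


def _assign_contributors(
    n_images: int, n_contributors: int, k: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_images, k) indices of distinct contributors per image."""
    noise = rng.random((n_images, n_contributors))
    return np.argpartition(noise, k, axis=1)[:, :k]


def simulate_image_votes(
    truth: pd.DataFrame, contributors: pd.DataFrame, config: SimulationConfig,
    seed=0,
) -> pd.DataFrame:
    """Per-image 4-class votes from randomly assigned contributors.

    Each vote equals the image's true 4-class label with the contributor's
    accuracy, otherwise it is drawn from the error kernel row of the true
    label.
    """
    rng = _rng(seed)
    n_images = len(truth)
    k = config.labels_per_image
    assign = _assign_contributors(n_images, len(contributors), k, rng)

    true_rank = np.searchsorted(
        np.array(FOUR_CLASS.codes), truth["true_label4"].to_numpy()
    )
    true_rank_rep = np.repeat(true_rank, k)
    contrib_idx = assign.ravel()
    acc = contributors["accuracy"].to_numpy()[contrib_idx]

    correct = rng.random(n_images * k) < acc
    kernel_cum = config.kernel().cumsum(axis=1)
    draws = rng.random(n_images * k)
    wrong = (draws[:, None] < kernel_cum[true_rank_rep]).argmax(axis=1)
    votes = np.where(correct, true_rank_rep, wrong)

    codes4 = np.array(FOUR_CLASS.codes)
    elapsed = rng.gamma(shape=4.0, scale=12.5, size=n_images * k)  # mean ~50 s
    return pd.DataFrame(
        {
            "image_id": np.repeat(truth["image_id"].to_numpy(), k),
            "contributor_id": contributors["contributor_id"].to_numpy()[contrib_idx],
            "label": codes4[votes],
            "trust": contributors["trust"].to_numpy()[contrib_idx],
            "elapsed_seconds": elapsed,
            "is_test_question": False,
        }
    )


def simulate_nuclei_counts(
    truth: pd.DataFrame, contributors: pd.DataFrame, config: SimulationConfig,
    seed=0,
) -> pd.DataFrame:
    """Per-contributor nucleus counts with asymmetric detection sensitivity.

    A true total per image is drawn negative-binomially around
    ``mean_total_nuclei`` and split positive/negative by the true
    positivity fraction; the split is kept consistent with the image's
    reference class (the realized positive fraction is clamped into the
    class interval), so the pathologist label always agrees with the
    image's actual composition.  Each contributor then observes binomial
    thinnings with the positive and negative sensitivities, plus optional
    Poisson false-positive dots.
    """
    rng = _rng(seed)
    n_images = len(truth)
    k = config.labels_per_image
    r = config.nuclei_dispersion
    p_nb = r / (r + config.mean_total_nuclei)
    totals = rng.negative_binomial(r, p_nb, size=n_images)
    n_pos_true = rng.binomial(totals, truth["true_pindex"].to_numpy())

    # clamp the realized split into the reference class's count interval
    rank3 = np.searchsorted(
        np.array(THREE_CLASS.codes), truth["ref_label"].to_numpy()
    )
    lowers = np.array([c.lower_bound for c in THREE_CLASS.classes])
    uppers = np.array([c.upper_bound for c in THREE_CLASS.classes])
    lo_count = np.ceil(lowers[rank3] * totals).astype(int)
    hi_count = np.where(
        uppers[rank3] >= 1.0,
        totals,
        np.ceil(uppers[rank3] * totals).astype(int) - 1,
    )
    ok = lo_count <= hi_count  # tiny totals may not represent the class
    n_pos_true = np.where(
        ok, np.clip(n_pos_true, lo_count, hi_count), n_pos_true
    )
    n_neg_true = totals - n_pos_true

    assign = _assign_contributors(n_images, len(contributors), k, rng)
    contrib_idx = assign.ravel()
    pos_rep = np.repeat(n_pos_true, k)
    neg_rep = np.repeat(n_neg_true, k)
    obs_pos = rng.binomial(pos_rep, config.detection_sensitivity_positive)
    obs_neg = rng.binomial(neg_rep, config.detection_sensitivity_negative)
    if config.false_positive_rate > 0:
        obs_pos = obs_pos + rng.poisson(
            config.false_positive_rate, size=n_images * k
        )
    has_nuclei = (obs_pos + obs_neg) > 0
    return pd.DataFrame(
        {
            "image_id": np.repeat(truth["image_id"].to_numpy(), k),
            "contributor_id": contributors["contributor_id"].to_numpy()[contrib_idx],
            "n_positive": obs_pos,
            "n_negative": obs_neg,
            "has_nuclei": has_nuclei,
        }
    )


def simulate_test_stream(
    contributors: pd.DataFrame, config: SimulationConfig, seed=0
) -> pd.DataFrame:
    """Gold-standard test-question outcomes: quiz mode then judgment mode.

    Each contributor answers ``quiz_size`` quiz questions followed by one
    hidden test item per judgment task; every outcome is
    Bernoulli(contributor accuracy).
    """
    rng = _rng(seed)
    rows = []
    n_q, n_j = config.quiz_size, config.n_judgment_tasks
    for cid, acc in zip(contributors["contributor_id"], contributors["accuracy"]):
        outcomes = rng.random(n_q + n_j) < acc
        rows.append(
            pd.DataFrame(
                {
                    "contributor_id": cid,
                    "phase": ["quiz"] * n_q + ["judgment"] * n_j,
                    "question_index": np.arange(n_q + n_j),
                    "correct": outcomes,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_dataset(config: SimulationConfig, seed=0) -> dict[str, pd.DataFrame]:
    """Full synthetic study: truth, contributors, votes, nuclei, tests.

    Sub-streams use independent seeds spawned from ``seed`` so each table
    is individually reproducible.
    """
    ss = np.random.SeedSequence(seed)
    s_truth, s_contrib, s_votes, s_nuclei, s_tests = ss.spawn(5)
    truth = simulate_truth(config, np.random.default_rng(s_truth))
    contributors = simulate_contributors(config, np.random.default_rng(s_contrib))
    votes = simulate_image_votes(
        truth, contributors, config, np.random.default_rng(s_votes)
    )
    nuclei = simulate_nuclei_counts(
        truth, contributors, config, np.random.default_rng(s_nuclei)
    )
    tests = simulate_test_stream(
        contributors, config, np.random.default_rng(s_tests)
    )
    return {
        "reference": truth,
        "contributors": contributors,
        "votes": votes,
        "nuclei": nuclei,
        "tests": tests,
    }
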