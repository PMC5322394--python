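import numpy as np
import pandas as pd
import pytest

from crowdscore.aggregation import aggregate_images
from crowdscore.crowd_sim import (
    SimulationConfig,
    default_error_kernel,
    simulate_contributors,
    simulate_dataset,
    simulate_image_votes,
    simulate_nuclei_counts,
    simulate_test_stream,
    simulate_truth,
)


class TestConfigValidation:
    def test_bad_probability_vectors_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(class_prevalence=(0.5, 0.2, 0.2))

    def test_bad_sensitivity_rejected(self):
        with pytest.raises(ValueError, match="sensitivity"):
            SimulationConfig(detection_sensitivity_negative=0.0)

    def test_bad_kernel_rejected(self):
        kernel = np.full((4, 4), 0.25)
        with pytest.raises(ValueError, match="kernel"):
            SimulationConfig(error_kernel=kernel)

    def test_default_kernel_rows_are_distributions(self):
        kernel = default_error_kernel()
        assert np.allclose(kernel.sum(axis=1), 1.0)
        assert np.all(np.diag(kernel) == 0)
        # adjacent classes carry 70% of the error mass
        assert kernel[1, 0] + kernel[1, 2] == pytest.approx(0.7)
        # residual mass skews positive: D gets more than C for true A
        assert kernel[0, 3] > kernel[0, 2]


class TestTruth:
    def test_image_counts_within_per_patient_bounds(self):
        truth = simulate_truth(SimulationConfig(n_patients=200), seed=1)
        per_patient = truth.groupby("patient_id").size()
        assert per_patient.between(1, 3).all()
        assert 200 <= len(truth) <= 600

    def test_degenerate_prevalence_forces_one_class(self):
        config = SimulationConfig(n_patients=100, class_prevalence=(1, 0, 0))
        truth = simulate_truth(config, seed=2)
        assert (truth["ref_label"] == "A").all()
        assert (truth["true_pindex"] < 0.01).all()

    def test_pindex_lies_within_reference_interval(self):
        truth = simulate_truth(SimulationConfig(n_patients=300), seed=3)
        bounds = {"A": (0, 0.01), "B": (0.01, 0.1), "C": (0.1, 1.0)}
        for code, (lo, hi) in bounds.items():
            sel = truth[truth["ref_label"] == code]["true_pindex"]
            assert ((sel >= lo) & (sel < hi)).all()

    def test_prevalence_matches_study_proportions(self):
        truth = simulate_truth(SimulationConfig(n_patients=5000), seed=4)
        per_patient = truth.drop_duplicates("patient_id")
        observed = per_patient["ref_label"].value_counts(normalize=True)
        expected = {"A": 452 / 1853, "B": 222 / 1853, "C": 1179 / 1853}
        for code, p in expected.items():
            assert observed[code] == pytest.approx(p, abs=0.03)


class TestVotes:
    def test_perfect_contributors_reproduce_truth(self):
        config = SimulationConfig(
            n_patients=60, accuracy_alpha=1e6, accuracy_beta=1e-6
        )
        truth = simulate_truth(config, seed=5)
        contributors = simulate_contributors(config, seed=6)
        votes = simulate_image_votes(truth, contributors, config, seed=7)
        lut = dict(zip(truth["image_id"], truth["true_label4"]))
        assert (votes["label"] == votes["image_id"].map(lut)).all()
        agg = aggregate_images(votes, "cv")
        assert (agg["label"] == agg["image_id"].map(lut)).all()

    def test_hopeless_contributors_never_agree(self):
        config = SimulationConfig(
            n_patients=100, accuracy_alpha=1e-6, accuracy_beta=1e6
        )
        truth = simulate_truth(config, seed=8)
        contributors = simulate_contributors(config, seed=9)
        votes = simulate_image_votes(truth, contributors, config, seed=10)
        lut = dict(zip(truth["image_id"], truth["true_label4"]))
        agreement = (votes["label"] == votes["image_id"].map(lut)).mean()
        assert agreement < 0.01

    def test_three_distinct_contributors_per_image(self):
        config = SimulationConfig(n_patients=50)
        data = simulate_dataset(config, seed=11)
        per_image = data["votes"].groupby("image_id")["contributor_id"]
        assert (per_image.size() == 3).all()
        assert (per_image.nunique() == 3).all()


class TestNuclei:
    def test_perfect_detection_gives_identical_counts(self):
        config = SimulationConfig(
            n_patients=40,
            detection_sensitivity_positive=1.0,
            detection_sensitivity_negative=1.0,
        )
        truth = simulate_truth(config, seed=12)
        contributors = simulate_contributors(config, seed=13)
        counts = simulate_nuclei_counts(truth, contributors, config, seed=14)
        per_image = counts.groupby("image_id")[["n_positive", "n_negative"]]
        assert (per_image.nunique() == 1).all().all()

    def test_zero_pindex_never_yields_positive_dots(self):
        config = SimulationConfig(n_patients=60, class_prevalence=(1, 0, 0))
        truth = simulate_truth(config, seed=15)
        contributors = simulate_contributors(config, seed=16)
        counts = simulate_nuclei_counts(truth, contributors, config, seed=17)
        zero_truth = truth[truth["true_pindex"] == 0.0]["image_id"]
        sel = counts[counts["image_id"].isin(zero_truth)]
        assert (sel["n_positive"] == 0).all()

    def test_under_detected_negatives_inflate_observed_pindex(self):
        """With negative sensitivity 0.5 and positive 1.0 the observed
        positivity index concentrates near p/(p + 0.5(1-p)): for true
        p = 0.3 that is 0.3/0.65 ≈ 0.4615."""
        truth = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(400)],
                "image_id": [f"I{i}" for i in range(400)],
                "ref_label": "C",
                "true_pindex": 0.3,
                "true_label4": "C",
            }
        )
        config = SimulationConfig(
            n_patients=400,
            detection_sensitivity_positive=1.0,
            detection_sensitivity_negative=0.5,
            mean_total_nuclei=1000.0,
        )
        contributors = simulate_contributors(config, seed=18)
        counts = simulate_nuclei_counts(truth, contributors, config, seed=19)
        observed = counts["n_positive"] / (
            counts["n_positive"] + counts["n_negative"]
        )
        expected = 0.3 / (0.3 + 0.5 * 0.7)
        assert observed.mean() == pytest.approx(expected, abs=0.01)
        assert observed.mean() > 0.3  # biased upward, mirroring real crowds

    def test_raising_negative_sensitivity_shrinks_neg_to_pos_confusion(self):
        """More reliable negative-nucleus detection monotonically reduces
        how often truly negative images are called positive."""
        from crowdscore.aggregation import aggregate_nuclei_images

        rates = []
        for sens in (0.3, 0.6, 0.9):
            config = SimulationConfig(
                n_patients=300,
                class_prevalence=(1.0, 0.0, 0.0),
                detection_sensitivity_negative=sens,
                false_positive_rate=2.0,
            )
            truth = simulate_truth(config, seed=20)
            contributors = simulate_contributors(config, seed=21)
            counts = simulate_nuclei_counts(truth, contributors, config, seed=22)
            agg = aggregate_nuclei_images(counts)
            rates.append((agg["label"] != "A").mean())
        assert rates[0] > rates[2]
        assert rates[1] >= rates[2]


class TestTestStream:
    def test_perfect_accuracy_passes_quiz(self):
        config = SimulationConfig(
            n_contributors=20, accuracy_alpha=1e6, accuracy_beta=1e-6
        )
        contributors = simulate_contributors(config, seed=23)
        stream = simulate_test_stream(contributors, config, seed=24)
        quiz = stream[stream["phase"] == "quiz"]
        assert quiz["correct"].all()

    def test_coin_flip_contributor_passes_half_the_time(self):
        """P(Binomial(5, 0.5) ≥ 3) = 0.5 exactly, so about half of
        accuracy-0.5 contributors clear a 60% quiz threshold."""
        config = SimulationConfig(
            n_contributors=2000, accuracy_alpha=5e5, accuracy_beta=5e5
        )
        contributors = simulate_contributors(config, seed=25)
        stream = simulate_test_stream(contributors, config, seed=26)
        quiz = stream[stream["phase"] == "quiz"]
        pass_rate = (
            quiz.groupby("contributor_id")["correct"].mean() >= 0.6
        ).mean()
        assert pass_rate == pytest.approx(0.5, abs=0.03)

    def test_quiz_precedes_judgment_stream(self):
        config = SimulationConfig(n_contributors=5)
        contributors = simulate_contributors(config, seed=27)
        stream = simulate_test_stream(contributors, config, seed=28)
        one = stream[stream["contributor_id"] == "C0000"]
        assert list(one["phase"][: config.quiz_size]) == ["quiz"] * 5
        assert (one["phase"][config.quiz_size :] == "judgment").all()


def test_fixed_seed_reproducibility():
    """Generators are pure functions of (config, seed)."""
    config = SimulationConfig(n_patients=40)
    a = simulate_dataset(config, seed=31)
    b = simulate_dataset(config, seed=31)
    for key in a:
        pd.testing.assert_frame_equal(a[key], b[key])
    c = simulate_dataset(config, seed=32)
    assert not a["votes"]["label"].equals(c["votes"]["label"])
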