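import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from crowdscore.aggregation import (
    CrowdVoteRecord,
    MissingTrustError,
    NucleiCountRecord,
    aggregate_ct,
    aggregate_cv,
    aggregate_images,
    aggregate_nuclei,
    aggregate_patient,
    aggregate_weighted,
)
from crowdscore.label_model import (
    FOUR_CLASS,
    THREE_CLASS,
    UnscorableImageError,
)

import oracles


def votes(*specs):
    """Build vote records from (code, trust) pairs or bare codes."""
    out = []
    for i, spec in enumerate(specs):
        code, trust = spec if isinstance(spec, tuple) else (spec, None)
        out.append(
            CrowdVoteRecord(
                image_id="img",
                contributor_id=f"c{i}",
                label=FOUR_CLASS.by_code(code),
                trust=trust,
            )
        )
    return out


class TestMaxVotes:
    def test_strict_majority_wins(self):
        assert aggregate_cv(votes("A", "A", "B")).label.code == "A"

    def test_three_way_tie_breaks_on_trust(self):
        agg = aggregate_cv(votes(("A", 0.9), ("B", 0.6), ("C", 0.6)))
        assert agg.label.code == "A"

    def test_unanimity(self):
        agg = aggregate_cv(votes("B", "B", "B"))
        assert agg.label.code == "B"
        assert agg.support == {"V_A": 0, "V_B": 3, "V_C": 0, "V_D": 0}
        assert agg.n_annotations == 3

    def test_tie_without_trust_goes_positive(self):
        assert aggregate_cv(votes("A", "C")).label.code == "C"

    def test_empty_votes_rejected(self):
        with pytest.raises(ValueError):
            aggregate_cv([])

    def test_mixed_images_rejected(self):
        v = votes("A", "B")
        bad = [v[0], CrowdVoteRecord("other", "c9", FOUR_CLASS.by_code("B"))]
        with pytest.raises(ValueError, match="same image"):
            aggregate_cv(bad)


class TestMaxTrust:
    def test_trust_sum_beats_single_high_trust(self):
        agg = aggregate_ct(votes(("A", 0.9), ("B", 0.6), ("B", 0.6)))
        assert agg.label.code == "B"
        assert agg.support["T_B"] == pytest.approx(1.2)

    def test_high_trust_single_vote_wins(self):
        assert aggregate_ct(votes(("A", 0.9), ("B", 0.3), ("C", 0.3))).label.code == "A"

    def test_single_vote_passthrough(self):
        assert aggregate_ct(votes(("C", 0.5))).label.code == "C"

    def test_missing_trust_instructs_cv(self):
        with pytest.raises(MissingTrustError, match="cv"):
            aggregate_ct(votes("A", "B"))


class TestWeighted:
    def test_weighted_mean_binned(self):
        # (2*0.3 + 1*0.75)/3 = 0.45, inside class C's interval
        agg = aggregate_weighted(votes("C", "C", "D"), "wcv")
        assert agg.support["weighted_score"] == pytest.approx(0.45)
        assert agg.label.code == "C"

    def test_unanimous_class_returns_itself(self):
        assert aggregate_weighted(votes("A", "A", "A"), "wcv").label.code == "A"

    def test_wct_unanimous(self):
        agg = aggregate_weighted(votes(("D", 0.8), ("D", 0.4)), "wct")
        assert agg.support["weighted_score"] == pytest.approx(0.75)
        assert agg.label.code == "D"

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            aggregate_weighted(votes("A"), "cv")

    @given(
        st.lists(
            st.tuples(st.sampled_from("ABCD"), st.floats(0.01, 1.0)),
            min_size=1,
            max_size=8,
        ),
        st.sampled_from(["wcv", "wct"]),
    )
    def test_score_bounded_by_extreme_weights_and_contained(self, specs, mode):
        agg = aggregate_weighted(votes(*specs), mode)
        s = agg.support["weighted_score"]
        assert 0.005 <= s <= 0.75
        assert agg.label.contains(s)


class TestNuclei:
    def counts(self, pos, neg, missing=0):
        recs = [
            NucleiCountRecord("img", f"c{i}", p, n)
            for i, (p, n) in enumerate(zip(pos, neg))
        ]
        recs += [
            NucleiCountRecord("img", f"m{i}", 0, 0, has_nuclei=False)
            for i in range(missing)
        ]
        return recs

    def test_median_counts_to_pindex(self):
        agg = aggregate_nuclei(self.counts([10, 12, 20], [90, 88, 80]))
        assert agg.support["median_positive"] == 12
        assert agg.support["median_negative"] == 88
        assert agg.support["pindex"] == pytest.approx(0.12)
        assert agg.label.code == "C"

    def test_zero_positive_medians_to_negative(self):
        agg = aggregate_nuclei(self.counts([0, 0, 0], [50, 60, 70]))
        assert agg.label.code == "A"

    def test_single_rater_passthrough(self):
        assert aggregate_nuclei(self.counts([5], [95])).label.code == "B"

    def test_no_nuclei_reports_excluded_from_medians(self):
        agg = aggregate_nuclei(self.counts([10, 12], [90, 88], missing=1))
        assert agg.support["median_positive"] == 11
        assert agg.n_annotations == 3

    def test_all_missing_is_unscorable(self):
        with pytest.raises(UnscorableImageError, match="no contributor"):
            aggregate_nuclei(self.counts([], [], missing=3))


class TestPatientRollup:
    @pytest.mark.parametrize(
        "codes, expected",
        [
            (["A", "B", "B"], "B"),
            (["A", "C"], "B"),   # even count: mean rank 1 → B
            (["C"], "C"),
            (["A", "A", "C"], "A"),
            (["B", "C"], "C"),   # half-rank rounds toward positive
        ],
    )
    def test_ordinal_median(self, codes, expected):
        labels = [THREE_CLASS.by_code(c) for c in codes]
        assert aggregate_patient(labels, THREE_CLASS).code == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_patient([], THREE_CLASS)

    @given(st.lists(st.sampled_from("ABC"), min_size=1, max_size=6))
    def test_permutation_invariant(self, codes):
        labels = [THREE_CLASS.by_code(c) for c in codes]
        reversed_ = list(reversed(labels))
        assert (
            aggregate_patient(labels, THREE_CLASS)
            is aggregate_patient(reversed_, THREE_CLASS)
        )


@given(st.sampled_from("ABCD"), st.integers(1, 6))
def test_unanimous_class_returned_by_all_five_methods(code, n):
    v = votes(*[(code, 0.7)] * n)
    assert aggregate_cv(v).label.code == code
    assert aggregate_ct(v).label.code == code
    assert aggregate_weighted(v, "wcv").label.code == code
    assert aggregate_weighted(v, "wct").label.code == code
    # nuclei rule works on the 3-class scheme: counts chosen inside each interval
    pos, neg = {"A": (0, 90), "B": (5, 95), "C": (30, 70), "D": (90, 10)}[code]
    recs = [NucleiCountRecord("img", f"c{i}", pos, neg) for i in range(n)]
    expected = "C" if code in "CD" else code
    assert aggregate_nuclei(recs, THREE_CLASS).label.code == expected


@given(
    st.lists(
        st.tuples(st.sampled_from("ABCD"), st.floats(0.0, 1.0)),
        min_size=1,
        max_size=7,
    )
)
def test_strict_majority_wins_regardless_of_trust(specs):
    counts = {c: sum(1 for s in specs if s[0] == c) for c in "ABCD"}
    top = max(counts.values())
    leaders = [c for c, n in counts.items() if n == top]
    agg = aggregate_cv(votes(*specs))
    if len(leaders) == 1:
        assert agg.label.code == leaders[0]
    else:
        assert agg.label.code in leaders


class TestVectorisedInterface:
    def test_matches_record_level_on_random_table(self, rng):
        codes = np.array(list("ABCD"))
        rows = []
        for img in range(40):
            for c in range(3):
                rows.append(
                    {
                        "image_id": f"I{img:03d}",
                        "contributor_id": f"C{c}",
                        "label": codes[rng.integers(4)],
                        "trust": float(rng.random()),
                    }
                )
        table = pd.DataFrame(rows)
        for method in ("cv", "ct", "wcv", "wct"):
            batch = aggregate_images(table, method)
            for image_id, group in table.groupby("image_id"):
                recs = votes(*zip(group["label"], group["trust"]))
                if method == "cv":
                    expected = aggregate_cv(recs).label.code
                elif method == "ct":
                    expected = aggregate_ct(recs).label.code
                else:
                    expected = aggregate_weighted(recs, method).label.code
                got = batch.loc[batch["image_id"] == image_id, "label"].iloc[0]
                assert got == expected, (method, image_id)

    def test_support_reconciles_with_annotations(self, rng):
        table = pd.DataFrame(
            {
                "image_id": ["i1"] * 3 + ["i2"] * 2,
                "contributor_id": list("abcde"),
                "label": ["A", "B", "B", "D", "D"],
                "trust": [0.5] * 5,
            }
        )
        out = aggregate_images(table, "cv")
        vote_cols = [f"V_{c}" for c in "ABCD"]
        assert (out[vote_cols].sum(axis=1) == out["n_annotations"]).all()


def test_equal_trust_makes_trust_rule_equal_majority_rule():
    """With equal trust, trust sums are proportional to counts, so the two
    rules coincide on every multiset of ≤4 votes (exhaustive enumeration,
    checked against the brute-force oracle)."""
    for size in range(1, 5):
        for combo in itertools.combinations_with_replacement("ABCD", size):
            v = votes(*[(c, 0.7) for c in combo])
            cv_code = aggregate_cv(v).label.code
            ct_code = aggregate_ct(v).label.code
            ranks = ["ABCD".index(c) for c in combo]
            expected = "ABCD"[oracles.majority_label(ranks, [0.7] * size)]
            assert cv_code == ct_code == expected
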