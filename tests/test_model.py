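"""Generative-model primitives: priors, intention/data stages, and the
speaker-consistency sequence likelihood."""

import pytest

from epilex import (
    Corpus,
    GroupSpec,
    InvalidLabelError,
    LabelSpace,
    LabelingEvent,
    ValidationError,
    ZeroProbabilityCorpusError,
    data_distribution,
    intention_distribution,
    knowledgeability_prior,
    sequence_likelihood,
)


@pytest.mark.parametrize(
    "theta, expected",
    [(0.15, (0.15, 0.85)), (0.5, (0.5, 0.5)), (1.0, (1.0, 0.0))],
)
def test_knowledgeability_prior_is_bernoulli_theta(theta, expected):
    belief = knowledgeability_prior(GroupSpec("g", theta))
    assert belief.as_tuple() == expected


def test_group_theta_outside_unit_interval_rejected():
    with pytest.raises(ValidationError):
        GroupSpec("g", 1.2)


class TestIntentionDistribution:
    def test_knowledgeable_is_point_mass_on_category(self, space3):
        dist = intention_distribution("buk", 1, space3)
        assert dict(dist.items()) == {"buk": 1.0, "puk": 0.0, "duk": 0.0}

    def test_unknowledgeable_is_uniform_over_n(self, space3):
        dist = intention_distribution("buk", 0, space3)
        assert all(p == pytest.approx(1 / 3) for _, p in dist.items())

    def test_single_label_space_degenerates_to_point_mass(self):
        space = LabelSpace(("buk",))
        assert intention_distribution("buk", 0, space)["buk"] == 1.0

    def test_unknown_category_raises(self, space3):
        with pytest.raises(InvalidLabelError):
            intention_distribution("dog", 1, space3)


def test_data_matches_intention_exactly(space3):
    # noiseless production: composing with a knowledgeable intention
    # reduces to a delta on the category
    intent = intention_distribution("buk", 1, space3).map_value()
    assert dict(data_distribution(intent, space3).items())["buk"] == 1.0
    assert data_distribution("puk", space3)["puk"] == 1.0


class TestSequenceLikelihood:
    def test_knowledgeable_repeats_of_category(self, space3):
        assert sequence_likelihood(["buk"] * 7, "buk", 1, space3) == 1.0

    def test_unknowledgeable_consistent_sequence_costs_one_draw(self, space3):
        # five repetitions of any single label: one uniform intention draw
        assert sequence_likelihood(["puk"] * 5, "buk", 0, space3) == pytest.approx(1 / 3)

    def test_mixed_tokens_have_zero_likelihood_for_both_k(self, space3):
        assert sequence_likelihood(["buk", "puk"], "buk", 1, space3) == 0.0
        assert sequence_likelihood(["buk", "puk"], "buk", 0, space3) == 0.0

    @pytest.mark.parametrize("t", [1, 2, 7])
    @pytest.mark.parametrize("k", [0, 1])
    def test_invariant_to_repetition_count(self, space3, t, k):
        one = sequence_likelihood(["buk"], "buk", k, space3)
        many = sequence_likelihood(["buk"] * t, "buk", k, space3)
        assert many == one

    def test_knowledgeable_likelihood_invariant_to_n(self):
        for n in (2, 3, 5):
            space = LabelSpace(tuple(f"l{i}" for i in range(n)))
            assert sequence_likelihood(["l0"], "l0", 1, space) == 1.0
            assert sequence_likelihood(["l0"], "l0", 0, space) == pytest.approx(1 / n)

    def test_empty_sequence_disallowed(self, space3):
        with pytest.raises(ValidationError):
            sequence_likelihood([], "buk", 1, space3)


class TestCorpusValidation:
    def test_counts_distinct_speakers(self, multi_speaker_corpus):
        assert multi_speaker_corpus.m == 7
        assert len(multi_speaker_corpus.events) == 7

    def test_inconsistent_speaker_object_tokens_hard_error(self, space3):
        events = (
            LabelingEvent("s1", "g", "obj", "buk"),
            LabelingEvent("s1", "g", "obj", "puk"),
        )
        with pytest.raises(ZeroProbabilityCorpusError, match="row 2"):
            Corpus(events=events, label_space=space3)

    def test_token_outside_space_rejected(self, space3):
        with pytest.raises(InvalidLabelError):
            Corpus(
                events=(LabelingEvent("s1", "g", "obj", "dog"),),
                label_space=space3,
            )

    def test_undeclared_group_rejected(self, space3):
        with pytest.raises(ValidationError):
            Corpus(
                events=(LabelingEvent("s1", "mystery", "obj", "buk"),),
                label_space=space3,
                groups={"adult": GroupSpec("adult", 0.8)},
            )


def test_label_space_requires_unique_labels():
    with pytest.raises(ValidationError):
        LabelSpace(("buk", "buk"))
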