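"""Knowledgeability posteriors, KL informativeness, exact enumeration."""

import math

import pytest

from epilex import (
    BernoulliBelief,
    Corpus,
    EnumerationCapError,
    GroupSpec,
    ImpossibleObservationError,
    LabelSpace,
    LabelingEvent,
    UndefinedDivergenceError,
    build_switch_corpus,
    event_informativeness,
    interaction_statistic,
    joint_posterior_exact,
    kl_divergence,
    marginal_label_posterior,
    posterior_knowledgeability,
    sweep_interaction,
)


class TestPosteriorKnowledgeability:
    @pytest.mark.parametrize(
        "theta, expected_p1",
        [
            (0.80, 12 / 13),  # 0.8 / (0.8 + 0.2/3), by hand
            (0.15, 9 / 26),  # 0.15 / (0.15 + 0.85/3)
        ],
    )
    def test_correct_token_bayes_update(self, space3, theta, expected_p1):
        post = posterior_knowledgeability(
            "buk", GroupSpec("g", theta), "buk", space3
        )
        assert post.p_knowledgeable == pytest.approx(expected_p1, abs=1e-12)

    def test_incorrect_token_forces_unknowledgeable(self, space3, audio):
        post = posterior_knowledgeability("puk", audio, "buk", space3)
        assert post.p_knowledgeable == 0.0
        assert post.p_unknowledgeable == 1.0

    def test_incorrect_token_from_certain_group_impossible(self, space3):
        with pytest.raises(ImpossibleObservationError):
            posterior_knowledgeability("puk", GroupSpec("g", 1.0), "buk", space3)


class TestKLDivergence:
    def test_incorrect_audio_event_matches_log_prior_mass(self):
        # point mass on K=0 against prior (0.15, 0.85): -log2(0.85)
        p = BernoulliBelief(0.0, 1.0)
        q = BernoulliBelief(0.15, 0.85)
        assert kl_divergence(p, q) == pytest.approx(-math.log2(0.85))
        assert kl_divergence(p, q) == pytest.approx(0.2345, abs=5e-5)

    def test_identical_distributions_give_zero(self):
        q = BernoulliBelief(0.3, 0.7)
        assert kl_divergence(q, q) == 0.0

    def test_correct_adult_update(self):
        p = BernoulliBelief(12 / 13, 1 / 13)
        q = BernoulliBelief(0.8, 0.2)
        assert kl_divergence(p, q) == pytest.approx(0.08453, abs=5e-6)

    def test_undefined_when_posterior_exceeds_prior_support(self):
        with pytest.raises(UndefinedDivergenceError):
            kl_divergence(BernoulliBelief(0.0, 1.0), BernoulliBelief(1.0, 0.0))


class TestEventInformativeness:
    def test_incorrect_audio(self, space3, audio):
        assert event_informativeness(False, audio, space3) == pytest.approx(
            0.2345, abs=5e-5
        )

    def test_correct_audio(self, space3, audio):
        assert event_informativeness(True, audio, space3) == pytest.approx(
            0.1701, abs=5e-5
        )

    def test_vanishes_as_theta_goes_to_zero(self, space3):
        # an incorrect token from a surely-unknowledgeable group is no news
        val = event_informativeness(False, GroupSpec("g", 1e-9), space3)
        assert val == pytest.approx(0.0, abs=1e-7)

    def test_incorrect_event_with_certain_group_undefined(self, space3):
        with pytest.raises((UndefinedDivergenceError, ImpossibleObservationError)):
            event_informativeness(False, GroupSpec("g", 1.0), space3)


class TestInteraction:
    def test_equal_thetas_give_exact_zero(self, space3):
        assert interaction_statistic(0.4, 0.4, space3) == 0.0

    def test_reference_point(self, space3):
        # (2.3219 - 0.0845) - (0.2345 - 0.1701), at full precision
        assert interaction_statistic(0.8, 0.15, space3) == pytest.approx(
            2.1731, abs=5e-4
        )

    def test_antisymmetric_in_arguments(self, space3):
        a = interaction_statistic(0.8, 0.15, space3)
        b = interaction_statistic(0.15, 0.8, space3)
        assert a == pytest.approx(-b)

    def test_sweep_matrix_layout_and_antisymmetry(self, space3):
        grid = [0.1, 0.5, 0.9]
        mat = sweep_interaction(grid, grid, space3)
        assert mat.shape == (3, 3)
        assert all(mat[i, i] == 0.0 for i in range(3))
        assert mat[2, 0] == pytest.approx(-mat[0, 2])
        assert mat[1, 0] == interaction_statistic(0.5, 0.1, space3)


class TestJointPosteriorExact:
    def test_single_speaker_seven_tokens(self, single_speaker_corpus):
        joint = joint_posterior_exact(single_speaker_corpus, k_prior=0.5)
        marg = marginal_label_posterior(joint)
        assert marg["buk"] == pytest.approx(2 / 3, abs=1e-12)
        assert marg["puk"] == pytest.approx(1 / 6, abs=1e-12)
        assert marg["duk"] == pytest.approx(1 / 6, abs=1e-12)

    def test_hypothesis_space_size_n_times_2_to_m(self, multi_speaker_corpus):
        joint = joint_posterior_exact(multi_speaker_corpus)
        assert len(joint.hypotheses) == 3 * 2**7
        assert sum(joint.probs) == pytest.approx(1.0, abs=1e-9)

    def test_seven_agreeing_speakers_closed_form(self, multi_speaker_corpus):
        joint = joint_posterior_exact(multi_speaker_corpus, k_prior=0.5)
        expected = (2 / 3) ** 7 / ((2 / 3) ** 7 + 2 * (1 / 6) ** 7)
        assert joint.label_marginal["buk"] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.999878, abs=5e-7)

    def test_two_disagreeing_speakers_hand_enumeration(self, disagreement_corpus):
        # 12 hypotheses by hand: P(buk) = P(puk) = 4/9, P(duk) = 1/9
        joint = joint_posterior_exact(disagreement_corpus, k_prior=0.5)
        marg = joint.label_marginal
        assert marg["buk"] == pytest.approx(4 / 9, abs=1e-12)
        assert marg["puk"] == pytest.approx(4 / 9, abs=1e-12)
        assert marg["duk"] == pytest.approx(1 / 9, abs=1e-12)

    def test_label_marginal_consistent_with_joint(self, multi_speaker_corpus):
        joint = joint_posterior_exact(multi_speaker_corpus)
        for label in joint.label_marginal.support:
            direct = sum(
                p
                for (cats, _), p in zip(joint.hypotheses, joint.probs)
                if cats[0] == label
            )
            assert joint.label_marginal[label] == pytest.approx(direct, abs=1e-12)

    def test_knowledgeability_marginal(self, single_speaker_corpus):
        # P(K=1 | 7 x buk) = 0.5 / (0.5 + 0.5 * 1/3 * 3) ... via enumeration:
        # C=buk & K=1 weight 1/6; sum over all = 1/4 total -> 0.5 exactly?
        joint = joint_posterior_exact(single_speaker_corpus, k_prior=0.5)
        belief = joint.knowledgeability_marginal("s1")
        # hand enumeration: Z = 1/3*(1/2 + 1/6) + 2*(1/3*1/6) = 1/3;
        # K=1 mass = 1/3 * 1/2 = 1/6 -> posterior 1/2
        assert belief.p_knowledgeable == pytest.approx(0.5, abs=1e-12)

    def test_enumeration_cap_refuses_large_m(self, space3):
        events = tuple(
            LabelingEvent(f"s{i}", "g", "obj", "buk") for i in range(25)
        )
        corpus = Corpus(events=events, label_space=space3)
        with pytest.raises(EnumerationCapError):
            joint_posterior_exact(corpus)

    def test_per_speaker_priors_accepted(self, disagreement_corpus):
        # speaker 'a' certainly knowledgeable: C must be 'buk'
        joint = joint_posterior_exact(
            disagreement_corpus, k_prior={"a": 1.0, "b": 0.5}
        )
        assert joint.label_marginal["buk"] == pytest.approx(1.0, abs=1e-12)

    def test_multi_object_corpus_shared_knowledgeability(self, space3):
        # one speaker labels two objects; K couples them
        events = (
            LabelingEvent("s1", "g", "o1", "buk"),
            LabelingEvent("s1", "g", "o2", "puk"),
        )
        corpus = Corpus(events=events, label_space=space3)
        joint = joint_posterior_exact(corpus, k_prior=0.5)
        assert set(joint.object_ids) == {"o1", "o2"}
        for obj, tok in (("o1", "buk"), ("o2", "puk")):
            marg = joint.label_marginals[obj]
            assert marg.map_value() == tok
            assert sum(p for _, p in marg.items()) == pytest.approx(1.0)
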