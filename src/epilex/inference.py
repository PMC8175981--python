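"""Posterior inference.

Two inference problems are supported:

1. **Knowledgeability from a single labeling event** (word recognition):
   the category ``C`` is known, the speaker's group is observed, and the
   listener updates a Bernoulli belief over the speaker's knowledgeability
   ``K`` after one token. The informativeness of the event is the KL
   divergence (in bits, by default) between posterior and prior — the
   model's ordinal index of looking time.

2. **Joint label + knowledgeability inference** (novel-word learning):
   the category is unknown and the listener infers ``(C, K_vec)`` from a
   corpus of speaker-attributed tokens, either by exact enumeration of the
   ``n x 2^m`` hypothesis space or by Gibbs sampling when ``m`` makes
   enumeration infeasible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    EnumerationCapError,
    ImpossibleObservationError,
    UndefinedDivergenceError,
    ValidationError,
)
from .model import (
    BernoulliBelief,
    CategoricalDistribution,
    Corpus,
    GroupSpec,
    LabelSpace,
    knowledgeability_prior,
    sequence_likelihood,
)

__all__ = [
    "posterior_knowledgeability",
    "kl_divergence",
    "event_informativeness",
    "interaction_statistic",
    "sweep_interaction",
    "JointPosterior",
    "joint_posterior_exact",
    "marginal_label_posterior",
    "GibbsSettings",
    "gibbs_posterior",
    "total_variation",
    "ENUMERATION_CAP",
]

#: Largest speaker count for exact enumeration (n * 2^m hypotheses).
ENUMERATION_CAP = 20


def posterior_knowledgeability(
    token: str, group: GroupSpec, category: str, space: LabelSpace
) -> BernoulliBelief:
    """Posterior over speaker knowledgeability after one token.

    P(K | D, G, C) is proportional to P(D | C, K) * P(K | G). A correct
    token has likelihoods (1, 1/n) under K = (1, 0); an incorrect token
    has (0, 1/n), i.e. a point mass on K = 0. An incorrect token from a
    group with theta = 1 has zero prior probability and raises
    :class:`ImpossibleObservationError`.
    """
    space.require(token)
    space.require(category)
    prior = knowledgeability_prior(group)
    lik_k1 = 1.0 if token == category else 0.0
    lik_k0 = 1.0 / space.n
    w1 = lik_k1 * prior.p_knowledgeable
    w0 = lik_k0 * prior.p_unknowledgeable
    total = w1 + w0
    if total == 0.0:
        raise ImpossibleObservationError(
            f"token {token!r} for category {category!r} has probability zero "
            f"under group {group.name!r} (theta={group.theta})"
        )
    return BernoulliBelief(w1 / total, w0 / total)


def kl_divergence(
    p: BernoulliBelief, q: BernoulliBelief, log_base: float = 2.0
) -> float:
    """Relative entropy D(p || q) over the two knowledgeability states.

    Terms with p = 0 contribute zero. If p puts mass where q has none the
    divergence is undefined and :class:`UndefinedDivergenceError` is
    raised (rather than returning infinity), matching the model's
    treatment of incorrect data under a knowledgeability prior of 1.
    """
    total = 0.0
    for pi, qi in zip(p.as_tuple(), q.as_tuple()):
        if pi == 0.0:
            continue
        if qi == 0.0:
            raise UndefinedDivergenceError(
                "KL divergence undefined: posterior has mass where the prior "
                "has none"
            )
        total += pi * math.log(pi / qi, log_base)
    # tiny negative values can arise from float rounding when p ~ q
    return max(total, 0.0)


def event_informativeness(
    correct: bool, group: GroupSpec, space: LabelSpace, log_base: float = 2.0
) -> float:
    """KL divergence between the knowledgeability posterior after one
    (correct or incorrect) token and the group prior.

    This scalar is the model's looking-time index: more informative
    events predict longer looking. The linkage is ordinal only.
    """
    category = space.labels[0]
    token = category if correct else space.labels[-1] if space.n > 1 else category
    if not correct and space.n < 2:
        raise ValidationError("an incorrect token requires at least two labels")
    posterior = posterior_knowledgeability(token, group, category, space)
    prior = knowledgeability_prior(group)
    return kl_divergence(posterior, prior, log_base)


def interaction_statistic(
    theta_human: float,
    theta_audio: float,
    space: LabelSpace,
    log_base: float = 2.0,
) -> float:
    """Predicted interaction between source group and label accuracy.

    [KL(incorrect | human) - KL(correct | human)]
    - [KL(incorrect | audio) - KL(correct | audio)].

    Positive values mean the human (higher-trust) group gains more
    informativeness from an incorrect label than the audio group does —
    the pattern seen in infant looking. Antisymmetric in its two theta
    arguments; zero when they are equal. Undefined at theta = 1.
    """
    human = GroupSpec("human", theta_human)
    audio = GroupSpec("audio", theta_audio)
    return (
        event_informativeness(False, human, space, log_base)
        - event_informativeness(True, human, space, log_base)
    ) - (
        event_informativeness(False, audio, space, log_base)
        - event_informativeness(True, audio, space, log_base)
    )


def sweep_interaction(
    grid_human: Sequence[float],
    grid_audio: Sequence[float],
    space: LabelSpace,
    log_base: float = 2.0,
) -> np.ndarray:
    """Interaction statistic on a grid: entry (i, j) uses
    (grid_human[i], grid_audio[j])."""
    out = np.empty((len(grid_human), len(grid_audio)))
    for i, th in enumerate(grid_human):
        for j, ta in enumerate(grid_audio):
            out[i, j] = interaction_statistic(th, ta, space, log_base)
    return out


# ---------------------------------------------------------------------------
# Joint inference over (C, K_vec)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class JointPosterior:
    """Posterior over joint hypotheses (label assignment, K vector).

    ``hypotheses`` pairs a per-object category assignment (a tuple aligned
    with ``object_ids``) with a knowledgeability vector aligned with
    ``speaker_ids``. For a single-object corpus there are exactly
    ``n * 2^m`` hypotheses. ``label_marginals`` holds P(C | D) per object;
    ``label_marginal`` is the single-object convenience accessor.
    """

    object_ids: tuple[str, ...]
    speaker_ids: tuple[str, ...]
    hypotheses: tuple[tuple[tuple[str, ...], tuple[int, ...]], ...]
    probs: tuple[float, ...]
    label_marginals: Mapping[str, CategoricalDistribution]
    diagnostics: Mapping[str, object] | None = None

    @property
    def label_marginal(self) -> CategoricalDistribution:
        if len(self.object_ids) != 1:
            raise ValidationError(
                "label_marginal is only defined for single-object corpora; "
                "use label_marginals[object_id]"
            )
        return self.label_marginals[self.object_ids[0]]

    def knowledgeability_marginal(self, speaker_id: str) -> BernoulliBelief:
        idx = self.speaker_ids.index(speaker_id)
        p1 = sum(p for (_, ks), p in zip(self.hypotheses, self.probs) if ks[idx] == 1)
        return BernoulliBelief(p1, 1.0 - p1)


def _normalize_k_prior(
    k_prior: float | Mapping[str, float], speaker_ids: Sequence[str]
) -> dict[str, float]:
    if isinstance(k_prior, Mapping):
        priors = {s: float(k_prior[s]) for s in speaker_ids}
    else:
        priors = {s: float(k_prior) for s in speaker_ids}
    for s, p in priors.items():
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"k_prior for speaker {s!r} outside [0, 1]: {p}")
    return priors


def _resolve_label_prior(
    label_prior: CategoricalDistribution | None, space: LabelSpace
) -> CategoricalDistribution:
    if label_prior is None:
        return CategoricalDistribution.uniform(space.labels)
    if tuple(label_prior.support) != space.labels:
        raise ValidationError("label prior support must match the label space")
    return label_prior


def _pair_likelihood_tables(corpus: Corpus):
    """Per (speaker, object): the single committed token and its count.

    Validation guarantees within-pair consistency, so each pair reduces to
    one token; the count is irrelevant to the likelihood (one intention
    draw) but kept for diagnostics.
    """
    pairs = {}
    for (spk, obj), tokens in corpus.tokens_by_pair().items():
        pairs[(spk, obj)] = tokens[0]
    return pairs


def joint_posterior_exact(
    corpus: Corpus,
    k_prior: float | Mapping[str, float] = 0.5,
    label_prior: CategoricalDistribution | None = None,
    enumeration_cap: int = ENUMERATION_CAP,
) -> JointPosterior:
    """Exact posterior over (C, K_vec) by enumeration.

    Enumerates every combination of a per-object label assignment and a
    per-speaker knowledgeability bit, scores each with the product of
    per-speaker-object sequence likelihoods and the priors, and
    normalizes. For a single object this is the ``n * 2^m`` hypothesis
    space. Refuses (``EnumerationCapError``) above ``enumeration_cap``
    speakers — use :func:`gibbs_posterior` instead.
    """
    space = corpus.label_space
    speakers = corpus.speaker_ids
    objects = corpus.object_ids
    m = len(speakers)
    if m > enumeration_cap:
        raise EnumerationCapError(
            f"{m} speakers gives {space.n ** len(objects)} x 2^{m} hypotheses; "
            f"exact enumeration is capped at {enumeration_cap} speakers — "
            "use gibbs_posterior"
        )
    priors = _normalize_k_prior(k_prior, speakers)
    label_prior = _resolve_label_prior(label_prior, space)
    pair_token = _pair_likelihood_tables(corpus)

    import itertools

    hypotheses: list[tuple[tuple[str, ...], tuple[int, ...]]] = []
    weights: list[float] = []
    for assignment in itertools.product(space.labels, repeat=len(objects)):
        cat_of = dict(zip(objects, assignment))
        prior_c = math.prod(label_prior[c] for c in assignment)
        for ks in itertools.product((0, 1), repeat=m):
            w = prior_c
            for spk, k in zip(speakers, ks):
                w *= priors[spk] if k == 1 else 1.0 - priors[spk]
            if w > 0.0:
                for (spk, obj), token in pair_token.items():
                    k = ks[speakers.index(spk)]
                    w *= sequence_likelihood([token], cat_of[obj], k, space)
                    if w == 0.0:
                        break
            hypotheses.append((assignment, ks))
            weights.append(w)

    expected = space.n ** len(objects) * 2**m
    assert len(hypotheses) == expected, "hypothesis space size mismatch"

    total = sum(weights)
    if total == 0.0:
        raise ImpossibleObservationError(
            "corpus has probability zero under the given priors"
        )
    probs = tuple(w / total for w in weights)
    marginals = {}
    for oi, obj in enumerate(objects):
        mass = {lab: 0.0 for lab in space.labels}
        for (assignment, _), p in zip(hypotheses, probs):
            mass[assignment[oi]] += p
        marginals[obj] = CategoricalDistribution(
            space.labels, tuple(mass[lab] for lab in space.labels)
        )
    return JointPosterior(
        object_ids=objects,
        speaker_ids=speakers,
        hypotheses=tuple(hypotheses),
        probs=probs,
        label_marginals=marginals,
    )


def marginal_label_posterior(joint: JointPosterior) -> CategoricalDistribution:
    """P(C | D): the joint posterior summed over knowledgeability vectors
    (single-object corpora)."""
    return joint.label_marginal


# ---------------------------------------------------------------------------
# Gibbs sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GibbsSettings:
    """Sampler configuration.

    Defaults: 20,000 kept samples after 2,000 burn-in, systematic scan
    (all objects' C, then K_1..K_m), single chain. Estimates are raw
    post-burn-in state frequencies; ``rao_blackwell=True`` switches the
    label marginal to the average of the exact conditional P(C | K, D) at
    each kept sweep, which has lower variance.
    """

    samples: int = 20_000
    burn_in: int = 2_000
    seed: int = 0
    scan: str = "systematic"
    rao_blackwell: bool = False

    def __post_init__(self) -> None:
        if self.samples <= 0:
            raise ValidationError("samples must be positive")
        if self.burn_in < 0:
            raise ValidationError("burn_in must be nonnegative")
        if self.scan != "systematic":
            raise ValidationError(f"unknown scan policy {self.scan!r}")


def _ess_batch_means(indicator: np.ndarray, n_batches: int = 50) -> float:
    """Effective sample size of a 0/1 chain by the batch-means estimator."""
    n = indicator.size
    if n < 2 * n_batches:
        return float(n)
    var = indicator.var()
    if var == 0.0:
        return float(n)
    batch = n // n_batches
    means = indicator[: batch * n_batches].reshape(n_batches, batch).mean(axis=1)
    var_bm = means.var(ddof=1) * batch
    return float(n * var / max(var_bm, 1e-300))


def gibbs_posterior(
    corpus: Corpus,
    k_prior: float | Mapping[str, float] = 0.5,
    label_prior: CategoricalDistribution | None = None,
    settings: GibbsSettings | None = None,
) -> JointPosterior:
    """Approximate the joint posterior by Gibbs sampling.

    Alternates draws from the full conditionals implied by the joint:
    for each object, P(C | K_vec, D) proportional to
    P(C) * prod_m P(D_m | C, K_m); then for each speaker,
    P(K_m | C, D) proportional to P(K_m) * prod_obj P(D_m,obj | C_obj, K_m).
    The chain starts at all K = 0 (always in support) with each object's
    category drawn from its conditional, so no repair step is ever
    needed; the ``support_repairs`` diagnostic records that count (0).

    Deterministic given ``settings.seed``. Returns a :class:`JointPosterior`
    whose hypotheses are the distinct visited states with their empirical
    post-burn-in frequencies, with diagnostics (kept sweeps, effective
    sample size of the modal-label indicator per object).
    """
    settings = settings or GibbsSettings()
    space = corpus.label_space
    speakers = corpus.speaker_ids
    objects = corpus.object_ids
    priors = _normalize_k_prior(k_prior, speakers)
    label_prior = _resolve_label_prior(label_prior, space)
    pair_token = _pair_likelihood_tables(corpus)
    rng = np.random.default_rng(settings.seed)

    spk_index = {s: i for i, s in enumerate(speakers)}
    obj_index = {o: i for i, o in enumerate(objects)}
    # tokens_of_obj[obj] -> list of (speaker index, token)
    tokens_of_obj: dict[str, list[tuple[int, str]]] = {o: [] for o in objects}
    tokens_of_spk: dict[int, list[tuple[str, str]]] = {i: [] for i in range(len(speakers))}
    for (spk, obj), token in pair_token.items():
        tokens_of_obj[obj].append((spk_index[spk], token))
        tokens_of_spk[spk_index[spk]].append((obj, token))

    n = space.n
    m = len(speakers)
    labels = space.labels
    label_prior_arr = np.array([label_prior[lab] for lab in labels])
    prior_k1 = np.array([priors[s] for s in speakers])

    # state: K all 0 (in support for any C), C sampled from its conditional
    k_state = np.zeros(m, dtype=np.int64)
    c_state = [labels[0] for _ in objects]
    support_repairs = 0

    def sample_c(obj: str) -> str:
        w = label_prior_arr.copy()
        for si, token in tokens_of_obj[obj]:
            if k_state[si] == 1:
                # knowledgeable speaker forces C = token
                w *= np.array([1.0 if lab == token else 0.0 for lab in labels])
            else:
                w *= 1.0 / n  # constant in C; kept for clarity
        total = w.sum()
        if total == 0.0:
            raise ImpossibleObservationError(
                "Gibbs conditional for C has empty support"
            )
        return labels[rng.choice(n, p=w / total)]

    def sample_k(si: int) -> int:
        w1 = prior_k1[si]
        w0 = 1.0 - prior_k1[si]
        for obj, token in tokens_of_spk[si]:
            c = c_state[obj_index[obj]]
            w1 *= 1.0 if token == c else 0.0
            w0 *= 1.0 / n
        total = w1 + w0
        if total == 0.0:
            raise ImpossibleObservationError(
                "Gibbs conditional for K has empty support"
            )
        return int(rng.random() < w1 / total)

    n_sweeps = settings.burn_in + settings.samples
    kept_states: dict[tuple[tuple[str, ...], tuple[int, ...]], int] = {}
    label_counts = {o: np.zeros(n) for o in objects}
    rb_mass = {o: np.zeros(n) for o in objects}
    label_trace = {o: np.empty(settings.samples, dtype=np.int64) for o in objects}
    kept = 0
    for sweep in range(n_sweeps):
        for oi, obj in enumerate(objects):
            c_state[oi] = sample_c(obj)
        for si in range(m):
            k_state[si] = sample_k(si)
        if sweep >= settings.burn_in:
            key = (tuple(c_state), tuple(int(k) for k in k_state))
            kept_states[key] = kept_states.get(key, 0) + 1
            for oi, obj in enumerate(objects):
                li = labels.index(c_state[oi])
                label_counts[obj][li] += 1
                label_trace[obj][kept] = li
                if settings.rao_blackwell:
                    w = label_prior_arr.copy()
                    for si, token in tokens_of_obj[obj]:
                        if k_state[si] == 1:
                            w *= np.array(
                                [1.0 if lab == token else 0.0 for lab in labels]
                            )
                        else:
                            w *= 1.0 / n
                    rb_mass[obj] += w / w.sum()
            kept += 1

    marginals = {}
    for obj in objects:
        if settings.rao_blackwell:
            mass = rb_mass[obj] / kept
        else:
            mass = label_counts[obj] / kept
        marginals[obj] = CategoricalDistribution(labels, tuple(mass))

    diagnostics = {
        "kept_samples": kept,
        "burn_in": settings.burn_in,
        "seed": settings.seed,
        "support_repairs": support_repairs,
        "estimator": "rao_blackwell" if settings.rao_blackwell else "frequency",
        "ess_modal_label": {
            obj: _ess_batch_means(
                (label_trace[obj] == int(np.argmax(label_counts[obj]))).astype(float)
            )
            for obj in objects
        },
    }
    hyps = tuple(kept_states.keys())
    probs = tuple(c / kept for c in kept_states.values())
    return JointPosterior(
        object_ids=objects,
        speaker_ids=speakers,
        hypotheses=hyps,
        probs=probs,
        label_marginals=marginals,
        diagnostics=diagnostics,
    )


def total_variation(
    p: CategoricalDistribution, q: CategoricalDistribution
) -> float:
    """Total variation distance between two distributions on one support."""
    if tuple(p.support) != tuple(q.support):
        raise ValidationError("distributions must share a support")
    return 0.5 * sum(abs(a - b) for a, b in zip(p.probs, q.probs))
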