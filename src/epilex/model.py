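"""Domain types and the generative probability model.

The model describes a listener reasoning about labeling events. Each
speaker belongs to a group ``G`` with a characteristic knowledgeability
``theta_g``: the probability that a member of the group is knowledgeable.
A speaker's latent knowledgeability ``K`` is Bernoulli(theta_g).
Knowledgeable speakers (``K = 1``) always intend the correct label ``C``
for an object; unknowledgeable speakers (``K = 0``) commit to one label
drawn uniformly from the ``n`` candidates. Speakers are consistent: the
intention ``I`` is fixed once per speaker-object pair, and every produced
token ``D`` equals the intention (production is noiseless in this release,
but the intention/data stages are kept distinct in the API so a noise
model can be slotted in later without interface changes).

Consistency has a crucial consequence for likelihoods: a speaker
repeating the same token ``t`` times contributes the probability of ONE
intention draw, not ``t`` independent draws. See
:func:`sequence_likelihood`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import InvalidLabelError, ValidationError, ZeroProbabilityCorpusError

__all__ = [
    "LabelSpace",
    "GroupSpec",
    "BernoulliBelief",
    "CategoricalDistribution",
    "SpeakerState",
    "LabelingEvent",
    "Corpus",
    "knowledgeability_prior",
    "intention_distribution",
    "data_distribution",
    "sequence_likelihood",
]

_PROB_ATOL = 1e-9


@dataclass(frozen=True)
class LabelSpace:
    """The finite, ordered set of candidate labels.

    Every category ``C``, intention ``I`` and token ``D`` handled anywhere
    in the package must be a member of this space. Order matters: it is
    the deterministic tie-break for MAP labels.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) < 1:
            raise ValidationError("label space must contain at least one label")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError(f"labels must be unique, got {self.labels!r}")

    @property
    def n(self) -> int:
        return len(self.labels)

    def __contains__(self, label: object) -> bool:
        return label in self.labels

    def __iter__(self):
        return iter(self.labels)

    def require(self, label: str) -> str:
        if label not in self.labels:
            raise InvalidLabelError(
                f"label {label!r} is not in the label space {self.labels!r}"
            )
        return label


@dataclass(frozen=True)
class GroupSpec:
    """A named speaker group with characteristic knowledgeability theta.

    ``theta`` is the probability that a randomly drawn member of the group
    is knowledgeable: p(K = 1 | G) = theta.
    """

    name: str
    theta: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValidationError(
                f"group {self.name!r}: theta must be in [0, 1], got {self.theta}"
            )


@dataclass(frozen=True)
class BernoulliBelief:
    """A belief over binary knowledgeability: (P(K=1), P(K=0))."""

    p_knowledgeable: float
    p_unknowledgeable: float

    def __post_init__(self) -> None:
        for p in (self.p_knowledgeable, self.p_unknowledgeable):
            if not -1e-12 <= p <= 1.0 + 1e-12:
                raise ValidationError(f"probability {p} outside [0, 1]")
        if abs(self.p_knowledgeable + self.p_unknowledgeable - 1.0) > 1e-12:
            raise ValidationError(
                "Bernoulli belief must sum to 1, got "
                f"{self.p_knowledgeable} + {self.p_unknowledgeable}"
            )

    def as_tuple(self) -> tuple[float, float]:
        return (self.p_knowledgeable, self.p_unknowledgeable)


@dataclass(frozen=True)
class CategoricalDistribution:
    """A normalized distribution over an explicit finite support."""

    support: tuple
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "support", tuple(self.support))
        object.__setattr__(self, "probs", tuple(float(p) for p in self.probs))
        if len(self.support) != len(self.probs):
            raise ValidationError("support and probs must have equal length")
        if any(p < -_PROB_ATOL for p in self.probs):
            raise ValidationError(f"negative probability in {self.probs!r}")
        total = sum(self.probs)
        if abs(total - 1.0) > _PROB_ATOL:
            raise ValidationError(f"probabilities sum to {total}, expected 1")

    def __getitem__(self, value) -> float:
        try:
            return self.probs[self.support.index(value)]
        except ValueError:
            raise KeyError(value) from None

    def items(self):
        return zip(self.support, self.probs)

    def map_value(self):
        """Mode of the distribution; ties broken by support order."""
        best = max(self.probs)
        for v, p in self.items():
            if p == best:
                return v
        raise AssertionError("unreachable")

    @classmethod
    def uniform(cls, support: Iterable) -> "CategoricalDistribution":
        support = tuple(support)
        return cls(support, (1.0 / len(support),) * len(support))

    @classmethod
    def point_mass(cls, support: Iterable, value) -> "CategoricalDistribution":
        support = tuple(support)
        return cls(support, tuple(1.0 if v == value else 0.0 for v in support))


@dataclass
class SpeakerState:
    """One speaker's latent state: group, knowledgeability and the fixed
    labeling intention committed to for each object."""

    speaker_id: str
    group: str
    k: int
    intentions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k not in (0, 1):
            raise ValidationError(f"k must be 0 or 1, got {self.k}")


@dataclass(frozen=True)
class LabelingEvent:
    """One observed token: speaker (with group attribution) labels object."""

    speaker_id: str
    group: str
    object_id: str
    token: str


@dataclass(frozen=True)
class Corpus:
    """Speaker-attributed labeling events over one label space.

    Validation enforces the model's support: within one speaker-object
    pair all tokens must be identical (one fixed intention per pair); a
    corpus violating this has probability zero under the model and no
    posterior is defined, so it is a hard error, not a silent zero.
    """

    events: tuple[LabelingEvent, ...]
    label_space: LabelSpace
    groups: Mapping[str, GroupSpec] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        if not self.events:
            raise ValidationError("corpus must contain at least one event")
        self.validate()

    def validate(self) -> None:
        seen: dict[tuple[str, str], tuple[str, int]] = {}
        speaker_group: dict[str, str] = {}
        for row, ev in enumerate(self.events, start=1):
            if ev.token not in self.label_space:
                raise InvalidLabelError(
                    f"row {row}: token {ev.token!r} not in label space "
                    f"{self.label_space.labels!r}"
                )
            if self.groups is not None and ev.group not in self.groups:
                raise ValidationError(
                    f"row {row}: group {ev.group!r} is not declared"
                )
            prev_group = speaker_group.setdefault(ev.speaker_id, ev.group)
            if prev_group != ev.group:
                raise ValidationError(
                    f"row {row}: speaker {ev.speaker_id!r} attributed to both "
                    f"groups {prev_group!r} and {ev.group!r}"
                )
            key = (ev.speaker_id, ev.object_id)
            if key in seen:
                tok, first_row = seen[key]
                if tok != ev.token:
                    raise ZeroProbabilityCorpusError(
                        f"row {row}: speaker {ev.speaker_id!r} labels object "
                        f"{ev.object_id!r} as {ev.token!r} but used "
                        f"{tok!r} at row {first_row}; speakers are consistent, "
                        "so this corpus has probability zero under the model"
                    )
            else:
                seen[key] = (ev.token, row)

    @property
    def m(self) -> int:
        """Number of distinct speakers."""
        return len(self.speaker_ids)

    @property
    def speaker_ids(self) -> tuple[str, ...]:
        out: list[str] = []
        for ev in self.events:
            if ev.speaker_id not in out:
                out.append(ev.speaker_id)
        return tuple(out)

    @property
    def object_ids(self) -> tuple[str, ...]:
        out: list[str] = []
        for ev in self.events:
            if ev.object_id not in out:
                out.append(ev.object_id)
        return tuple(out)

    def speaker_groups(self) -> dict[str, str]:
        return {ev.speaker_id: ev.group for ev in self.events}

    def tokens_by_pair(self) -> dict[tuple[str, str], list[str]]:
        """Tokens grouped by (speaker_id, object_id), in corpus order."""
        out: dict[tuple[str, str], list[str]] = {}
        for ev in self.events:
            out.setdefault((ev.speaker_id, ev.object_id), []).append(ev.token)
        return out


def knowledgeability_prior(group: GroupSpec) -> BernoulliBelief:
    """Prior over a speaker's knowledgeability given group membership:
    p(K | G) = Bernoulli(theta_g)."""
    return BernoulliBelief(group.theta, 1.0 - group.theta)


def intention_distribution(
    category: str, k: int, space: LabelSpace
) -> CategoricalDistribution:
    """Distribution of the labeling intention given the true category.

    A knowledgeable speaker intends the true category (a delta function);
    an unknowledgeable one draws uniformly from the n candidate labels.
    """
    space.require(category)
    if k == 1:
        return CategoricalDistribution.point_mass(space.labels, category)
    return CategoricalDistribution.uniform(space.labels)


def data_distribution(intention: str, space: LabelSpace) -> CategoricalDistribution:
    """Distribution of the produced token given the intention.

    Production is noiseless: D = I with probability 1. Kept as a separate
    stage so a noisy production model can replace it without API change.
    """
    space.require(intention)
    return CategoricalDistribution.point_mass(space.labels, intention)


def sequence_likelihood(
    tokens: Sequence[str], category: str, k: int, space: LabelSpace
) -> float:
    """Likelihood of a token sequence from ONE speaker-object pair.

    Because the speaker's intention is drawn once and then repeated, t
    identical tokens cost exactly one intention draw:

    * ``k = 1``: 1 if every token equals the category, else 0.
    * ``k = 0``: 1/n if all tokens are identical (to any label), else 0.

    Mixed tokens within the pair return 0 for both values of ``k``; a
    caller treating such data as an observed corpus must raise
    :class:`~epilex.errors.ZeroProbabilityCorpusError` (corpus validation
    does this).
    """
    tokens = list(tokens)
    if not tokens:
        raise ValidationError("sequence_likelihood requires at least one token")
    space.require(category)
    for t in tokens:
        space.require(t)
    first = tokens[0]
    if any(t != first for t in tokens):
        return 0.0
    if k == 1:
        return 1.0 if first == category else 0.0
    if k == 0:
        return 1.0 / space.n
    raise ValidationError(f"k must be 0 or 1, got {k}")
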