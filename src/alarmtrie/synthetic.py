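"""Synthetic corpus generator with the statistical structure the analysis assumes.

Each stimulus class draws complete sequences i.i.d. from a finite-support
class-conditional distribution, with exact (non-random) class sizes. Whole
sequences, rather than a positional Markov process, are sampled because the
analysis only ever sees prefix statistics: a finite-support mixture makes
every expected node distribution, entropy, and accuracy available in closed
form (see :func:`expected_conditional_distribution`), so tests can compare
simulated corpora against exact expectations.

:func:`colobus_preset` emulates an olive colobus elicitation corpus — class
sizes N_E = 39, N_T = 79, N_L = 166 (total 284), sequence patterns in which
A-initial sequences indicate eagle, 'BA' then silence indicates leopard, and
'BAA' indicates a falling tree. The support probabilities are invented,
anchored only to those qualitative patterns, not to field percentages.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

import numpy as np

from .corpus import CallSequence, Corpus
from .trie import extended_prefix

__all__ = [
    "GenerativeSpec",
    "SpecError",
    "colobus_preset",
    "simulate_corpus",
    "null_spec",
    "expected_conditional_distribution",
]

_PROB_TOL = 1e-9


class SpecError(Exception):
    pass


@dataclass(frozen=True)
class GenerativeSpec:
    """Class-conditional distribution over complete call sequences.

    ``distributions[y]`` maps a sequence string (compact encoding, one
    character per call) to its probability under class y; probabilities per
    class must sum to one. ``class_sizes[y]`` is the exact number of
    sequences drawn for class y. ``metadata`` carries free-form provenance
    (e.g. per-dataset trial counts for presets emulating a field study).
    """

    class_sizes: Mapping[str, int]
    distributions: Mapping[str, Mapping[str, float]]
    call_alphabet: tuple[str, ...] = ("A", "B")
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "class_sizes", dict(self.class_sizes))
        object.__setattr__(self, "distributions", {y: dict(d) for y, d in self.distributions.items()})
        object.__setattr__(self, "metadata", dict(self.metadata))
        self.validate()

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self.class_sizes)

    @property
    def total_size(self) -> int:
        return sum(self.class_sizes.values())

    def validate(self) -> None:
        if set(self.class_sizes) != set(self.distributions):
            raise SpecError("class_sizes and distributions must declare the same classes")
        for y, n in self.class_sizes.items():
            if n < 1:
                raise SpecError(f"class size must be >= 1, got {n} for {y!r}")
        alpha = set(self.call_alphabet)
        for y, dist in self.distributions.items():
            if not dist:
                raise SpecError(f"class {y!r} has an empty sequence distribution")
            if abs(sum(dist.values()) - 1.0) > _PROB_TOL:
                raise SpecError(f"probabilities for class {y!r} sum to {sum(dist.values())}, not 1")
            for s, p in dist.items():
                if p < 0:
                    raise SpecError(f"negative probability for {s!r} in class {y!r}")
                if not s or set(s) - alpha:
                    raise SpecError(f"sequence {s!r} in class {y!r} not over alphabet {self.call_alphabet}")

    def scaled(self, factor: int) -> "GenerativeSpec":
        """Same distributions with every class size multiplied by ``factor``."""
        if factor < 1:
            raise SpecError(f"scale factor must be >= 1, got {factor}")
        return dataclasses.replace(self, class_sizes={y: n * factor for y, n in self.class_sizes.items()})


def colobus_preset() -> GenerativeSpec:
    """Fixed preset emulating an olive colobus alarm-sequence corpus.

    Class sizes are the elicitation-study totals (eagle 39, falling tree 79,
    leopard 166; 284 sequences from 119 responsive trials across four
    dataset blocks). Sequence supports encode the qualitative grammar:
    eagle sequences are A-initial, leopard sequences are built on 'BA' units,
    and falling-tree sequences carry the 'BAA' pattern.
    """
    return GenerativeSpec(
        class_sizes={"E": 39, "L": 166, "T": 79},
        distributions={
            "E": {"AB": 0.50, "AAB": 0.20, "AAA": 0.20, "BA": 0.10},
            "L": {"BA": 0.60, "BABA": 0.30, "AB": 0.10},
            "T": {"BAA": 0.60, "BAAA": 0.20, "AAA": 0.20},
        },
        metadata={
            # responsive trials per dataset block: (dataset, experimenter, n)
            "responsive_trials": (("1", "KZ", 18), ("2", "QG", 70), ("2", "CD", 21), ("3", "QG", 10)),
        },
    )


def simulate_corpus(spec: GenerativeSpec, seed: int) -> Corpus:
    """Draw a corpus: exactly ``class_sizes[y]`` sequences i.i.d. from class y.

    Deterministic given ``seed``. Classes are sampled in declared order from
    a single generator stream.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    sequences: list[CallSequence] = []
    for y in spec.classes:
        dist = spec.distributions[y]
        support = list(dist)
        probs = np.array([dist[s] for s in support], dtype=float)
        probs = probs / probs.sum()
        draws = rng.choice(len(support), size=spec.class_sizes[y], p=probs)
        sequences.extend(CallSequence(tuple(support[i]), y) for i in draws)
    return Corpus(tuple(sequences), spec.call_alphabet, tuple(sorted(spec.classes)))


def null_spec(spec: GenerativeSpec) -> GenerativeSpec:
    """Null version of a spec: labels independent of tokens.

    Every class receives the same pooled sequence distribution, the
    class-size-weighted mixture of the originals; class sizes are unchanged.
    Idempotent: pooling identical distributions returns them unchanged.
    """
    total = spec.total_size
    pooled: dict[str, float] = {}
    for y, dist in spec.distributions.items():
        share = spec.class_sizes[y] / total
        for s, p in dist.items():
            pooled[s] = pooled.get(s, 0.0) + share * p
    return dataclasses.replace(spec, distributions={y: dict(pooled) for y in spec.classes})


def expected_conditional_distribution(spec: GenerativeSpec, prefix: str | tuple[str, ...]) -> dict[str, float]:
    """Closed-form weighted class distribution at an extended prefix.

    Under inverse-frequency weighting each class has total mass 1/K, so the
    expected weighted mass a class contributes to a trie node is (1/K) times
    the probability that one of its sequences has that extended prefix. The
    prefix may contain the end symbol ``∅``.
    """
    prefix_t = tuple(prefix)
    t = len(prefix_t)
    k = len(spec.classes)
    masses: dict[str, Fraction] = {}
    for y, dist in spec.distributions.items():
        match = sum(
            (Fraction(p).limit_denominator(10**9) for s, p in dist.items() if extended_prefix(tuple(s), t) == prefix_t),
            Fraction(0),
        )
        masses[y] = match / k
    total = sum(masses.values())
    if total == 0:
        raise SpecError(f"prefix {prefix_t!r} has zero probability under the spec")
    return {y: float(m / total) for y, m in masses.items()}
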