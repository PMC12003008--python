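"""Positional information indices on a call-sequence trie.

The stimulus classes are unbalanced in elicitation corpora, so each class y
receives the inverse-frequency weight

    w_y = 1 / (K · N_y),

with K the number of classes and N_y the number of sequences labeled y; the
weights satisfy Σ_y w_y N_y = 1 exactly and give every class prior mass 1/K.

For a trie node s (a distinct extended prefix), the weighted prefix
probability is Pr(s) = Σ_y w_y c_y(s) and the weighted conditional class
distribution is p_y(s) = w_y c_y(s) / Pr(s). From these, per position t:

    H(t) = Σ_s Pr(s) · H(p(s))        normalized entropy, log base K, in [0, 1]
    D(t|t-1) = H(t-1) - H(t)          Kullback-Leibler information gain, >= 0
    J(t) = Σ_s Pr(s) · max_y p_y(s)   prediction gain (expected accuracy of
                                      guessing the maximum-probability class)

Sums run over the depth-t nodes, which partition the corpus because the end
symbol is absorbing; hence H is non-increasing and J non-decreasing in t
(partition refinement), and the D terms telescope to H(0) - H(t). With equal
weighting, H(0) = 1 and J(0) = 1/K before any call is produced.

Node-level arithmetic is done in exact rational arithmetic (class counts are
integers and weights are rationals), converting to float only inside the
logarithm, so the analytic anchors hold to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import Corpus
from .trie import Trie, TrieNode, build_trie

__all__ = [
    "InfoGainError",
    "Weights",
    "InfoProfile",
    "class_weights",
    "prefix_probability",
    "conditional_distribution",
    "entropy_of_distribution",
    "positional_entropy",
    "kl_gain",
    "node_accuracy",
    "positional_accuracy",
    "info_profile",
    "write_profile",
    "read_profile",
]

#: Absolute tolerance used for internal invariant checks on floats.
ATOL = 1e-9

# D(t|t-1) is mathematically >= 0; float round-off this small is clamped to 0.
_CLAMP = 1e-12


class InfoGainError(Exception):
    pass


@dataclass(frozen=True)
class Weights:
    """Inverse-frequency class weights w_y = 1/(K·N_y).

    ``classes`` fixes the ordering used by every array-valued quantity in
    this module. Weights are stored as exact rationals.
    """

    classes: tuple[str, ...]
    counts: tuple[int, ...]
    values: tuple[Fraction, ...]

    @property
    def k(self) -> int:
        return len(self.classes)

    def __getitem__(self, y: str) -> Fraction:
        return self.values[self.classes.index(y)]

    def as_array(self) -> np.ndarray:
        return np.array([float(w) for w in self.values])


def class_weights(corpus: Corpus) -> Weights:
    """Compute w_y = 1/(K·N_y) from corpus class counts.

    Raises :class:`InfoGainError` when a declared class has no sequences
    (its weight would be undefined) or when K < 2.
    """
    counts = corpus.class_counts()
    k = corpus.n_classes
    if k < 2:
        raise InfoGainError(f"need at least 2 classes, got {k}")
    for y, n in counts.items():
        if n == 0:
            raise InfoGainError(f"weights undefined for class with zero sequences: {y!r}")
    classes = corpus.class_alphabet
    values = tuple(Fraction(1, k * counts[y]) for y in classes)
    assert sum(w * counts[y] for w, y in zip(values, classes)) == 1
    return Weights(classes, tuple(counts[y] for y in classes), values)


def _check_match(trie: Trie, weights: Weights) -> None:
    if tuple(trie.class_alphabet) != weights.classes:
        raise InfoGainError("weights and trie come from corpora with different class alphabets")
    root = trie.root.class_counts
    if tuple(root.get(y, 0) for y in weights.classes) != weights.counts:
        raise InfoGainError("weights and trie disagree on class counts; recompute weights")


def _node_masses(node: TrieNode, weights: Weights) -> list[Fraction]:
    return [w * node.class_counts.get(y, 0) for y, w in zip(weights.classes, weights.values)]


def prefix_probability(trie: Trie, node: TrieNode, weights: Weights) -> float:
    """Weighted probability Pr(s) = Σ_y w_y c_y(s) of reaching ``node``.

    Over all nodes of one depth these sum to one.
    """
    _check_match(trie, weights)
    return float(sum(_node_masses(node, weights)))


def conditional_distribution(trie: Trie, node: TrieNode, weights: Weights) -> np.ndarray:
    """Weighted class distribution p_y(s) at a node, ordered like ``weights.classes``."""
    _check_match(trie, weights)
    masses = _node_masses(node, weights)
    total = sum(masses)
    if total == 0:
        raise InfoGainError(f"conditional distribution undefined at zero-mass node {node.prefix}")
    return np.array([float(m / total) for m in masses])


def entropy_of_distribution(dist: Sequence[float] | np.ndarray, k: int | None = None) -> float:
    """Normalized Shannon entropy -Σ p log_k p with the 0·log 0 = 0 convention.

    The base defaults to the number of categories, so the uniform distribution
    has entropy exactly 1 and a point mass entropy 0.
    """
    p = np.asarray(dist, dtype=float)
    if k is None:
        k = p.size
    if k < 2:
        raise InfoGainError(f"entropy base must be >= 2, got {k}")
    if np.any(p < -ATOL) or abs(p.sum() - 1.0) > ATOL:
        raise InfoGainError("not a probability distribution")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / math.log(k))


def positional_entropy(trie: Trie, t: int, weights: Weights) -> float:
    """H(t): weighted entropy of the class given the first t extended symbols."""
    _check_match(trie, weights)
    total = 0.0
    for node in trie.nodes_at_depth(t):
        masses = _node_masses(node, weights)
        pr = sum(masses)
        if pr == 0:
            continue
        dist = [float(m / pr) for m in masses]
        total += float(pr) * entropy_of_distribution(dist, weights.k)
    return total


def kl_gain(h_prev: float, h_curr: float) -> float:
    """Kullback-Leibler information gain D(t|t-1) = H(t-1) - H(t).

    Non-negative because depth-t nodes refine depth-(t-1) nodes; float
    round-off below 1e-12 is clamped to zero.
    """
    d = h_prev - h_curr
    return 0.0 if -_CLAMP < d < _CLAMP else d


def node_accuracy(dist: Sequence[float] | np.ndarray) -> float:
    """Probability of a correct guess at a node: the maximum class probability."""
    p = np.asarray(dist, dtype=float)
    if np.any(p < -ATOL) or abs(p.sum() - 1.0) > ATOL:
        raise InfoGainError("not a probability distribution")
    return float(p.max())


def predicted_class(dist: Sequence[float], classes: Sequence[str]) -> str:
    """The maximum-probability class; ties resolve to the earliest declared class."""
    p = list(dist)
    return classes[p.index(max(p))]


def positional_accuracy(trie: Trie, t: int, weights: Weights) -> float:
    """J(t): expected accuracy of predicting the class from the first t symbols."""
    _check_match(trie, weights)
    total = Fraction(0)
    for node in trie.nodes_at_depth(t):
        masses = _node_masses(node, weights)
        if sum(masses) == 0:
            continue
        total += max(masses)  # Pr(s)·max_y p_y(s) = max_y w_y c_y(s)
    return float(total)


@dataclass
class InfoProfile:
    """Per-position indices H(t), D(t|t-1), J(t) for t = 0..T, plus optional
    permutation-null intervals (NaN where not computed)."""

    t: np.ndarray
    H: np.ndarray
    D: np.ndarray
    J: np.ndarray
    D_lo: np.ndarray = field(default=None)  # type: ignore[assignment]
    D_hi: np.ndarray = field(default=None)  # type: ignore[assignment]
    J_lo: np.ndarray = field(default=None)  # type: ignore[assignment]
    J_hi: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("D_lo", "D_hi", "J_lo", "J_hi"):
            if getattr(self, name) is None:
                setattr(self, name, np.full(n, np.nan))

    @property
    def max_position(self) -> int:
        return int(self.t[-1])

    def significant_D(self) -> np.ndarray:
        """True where the observed D(t|t-1) falls outside its null interval."""
        with np.errstate(invalid="ignore"):
            return (self.D < self.D_lo) | (self.D > self.D_hi)

    def significant_J(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return (self.J < self.J_lo) | (self.J > self.J_hi)

    def to_frame(self) -> pd.DataFrame:
        has_d = ~np.isnan(self.D_lo)
        has_j = ~np.isnan(self.J_lo)
        return pd.DataFrame(
            {
                "t": self.t,
                "H": self.H,
                "D": self.D,
                "J": self.J,
                "D_lo": self.D_lo,
                "D_hi": self.D_hi,
                "J_lo": self.J_lo,
                "J_hi": self.J_hi,
                "significant_D": [bool(s) if h else "" for s, h in zip(self.significant_D(), has_d)],
                "significant_J": [bool(s) if h else "" for s, h in zip(self.significant_J(), has_j)],
            }
        )


def info_profile(corpus: Corpus, max_depth: int | None = None, weights: Weights | None = None) -> InfoProfile:
    """Compute the positional information profile of a corpus.

    ``max_depth`` defaults to the longest sequence length plus one (so the
    final terminator position is included). D(0|0) is 0 by definition.
    """
    trie = build_trie(corpus, max_depth=max_depth)
    if weights is None:
        weights = class_weights(corpus)
    ts = np.arange(trie.depth + 1)
    H = np.array([positional_entropy(trie, int(t), weights) for t in ts])
    J = np.array([positional_accuracy(trie, int(t), weights) for t in ts])
    D = np.zeros_like(H)
    D[1:] = [kl_gain(H[i - 1], H[i]) for i in range(1, len(H))]
    return InfoProfile(t=ts, H=H, D=D, J=J)


def write_profile(profile: InfoProfile, path: str | Path) -> Path:
    """Write a profile to TSV (columns t, H, D, J, D_lo, D_hi, J_lo, J_hi,
    significant_D, significant_J)."""
    path = Path(path)
    profile.to_frame().to_csv(path, sep="\t", index=False)
    return path


def read_profile(path: str | Path) -> InfoProfile:
    """Read back a profile TSV written by :func:`write_profile`."""
    df = pd.read_csv(path, sep="\t")
    return InfoProfile(
        t=df["t"].to_numpy(),
        H=df["H"].to_numpy(float),
        D=df["D"].to_numpy(float),
        J=df["J"].to_numpy(float),
        D_lo=df["D_lo"].to_numpy(float) if "D_lo" in df else None,
        D_hi=df["D_hi"].to_numpy(float) if "D_hi" in df else None,
        J_lo=df["J_lo"].to_numpy(float) if "J_lo" in df else None,
        J_hi=df["J_hi"].to_numpy(float) if "J_hi" in df else None,
    )
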