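"""Prefix trie over the extended call alphabet (calls plus an absorbing end symbol).

Every sequence is represented at *every* position via its extended prefix:
once a sequence has ended, its prefix is padded with the end symbol ``∅``,
which then absorbs (``∅`` is always followed by ``∅``). Consequently the
depth-t nodes of the trie partition the whole corpus for every t, and
per-position statistics are always averages over the full corpus — the
conservation property the positional entropy and accuracy indices rely on.

Each node records per-class sequence counts; transition probabilities between
a node and its children are plain (unweighted) count fractions, the quantity
edge thickness encodes in trie figures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

from .corpus import CallSequence, Corpus

__all__ = ["END", "TrieError", "TrieNode", "Trie", "extended_prefix", "build_trie", "transition_probability"]

#: The absorbing end-of-sequence symbol.
END = "∅"


class TrieError(Exception):
    pass


def extended_prefix(sequence: CallSequence | Sequence[str], t: int) -> tuple[str, ...]:
    """First ``t`` extended symbols of a sequence.

    For t within the sequence this is the plain prefix; beyond its end the
    prefix is padded with the absorbing :data:`END` symbol. ``t = 0`` yields
    the empty prefix (the root).

    >>> extended_prefix(("B", "A"), 3)
    ('B', 'A', '∅')
    """
    if t < 0:
        raise ValueError(f"position must be >= 0, got {t}")
    tokens = sequence.tokens if isinstance(sequence, CallSequence) else tuple(sequence)
    if t <= len(tokens):
        return tuple(tokens[:t])
    return tuple(tokens) + (END,) * (t - len(tokens))


@dataclass
class TrieNode:
    """One node: a distinct extended prefix with per-class sequence counts."""

    prefix: tuple[str, ...]
    class_counts: dict[str, int] = field(default_factory=dict)
    children: dict[str, "TrieNode"] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return len(self.prefix)

    @property
    def symbol(self) -> str | None:
        """The last extended symbol of the prefix (None at the root)."""
        return self.prefix[-1] if self.prefix else None

    def total_count(self) -> int:
        return sum(self.class_counts.values())


@dataclass
class Trie:
    """Prefix trie over extended call prefixes, with class counts at each node."""

    root: TrieNode
    depth: int
    call_alphabet: tuple[str, ...]
    class_alphabet: tuple[str, ...]

    @property
    def extended_alphabet(self) -> tuple[str, ...]:
        return (*self.call_alphabet, END)

    def _child_order(self, node: TrieNode) -> list[str]:
        order = {sym: i for i, sym in enumerate(self.extended_alphabet)}
        return sorted(node.children, key=lambda s: order.get(s, len(order)))

    def iter_nodes(self) -> Iterator[TrieNode]:
        """All nodes in deterministic depth-first, alphabet order."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for sym in reversed(self._child_order(node)):
                stack.append(node.children[sym])

    def nodes_at_depth(self, t: int) -> list[TrieNode]:
        """The depth-t nodes; they partition the corpus (END is absorbing)."""
        if not 0 <= t <= self.depth:
            raise TrieError(f"depth {t} outside built range 0..{self.depth}")
        level = [self.root]
        for _ in range(t):
            level = [node.children[sym] for node in level for sym in self._child_order(node)]
        return level

    def find(self, prefix: Sequence[str]) -> TrieNode | None:
        node = self.root
        for sym in prefix:
            node = node.children.get(sym)
            if node is None:
                return None
        return node

    def truncated(self, depth: int) -> "Trie":
        """A copy of this trie cut at ``depth`` (children below are dropped)."""
        if not 1 <= depth <= self.depth:
            raise TrieError(f"truncation depth {depth} outside 1..{self.depth}")

        def copy(node: TrieNode) -> TrieNode:
            new = TrieNode(node.prefix, dict(node.class_counts))
            if node.depth < depth:
                new.children = {sym: copy(child) for sym, child in node.children.items()}
            return new

        return Trie(copy(self.root), depth, self.call_alphabet, self.class_alphabet)


def build_trie(corpus: Corpus, max_depth: int | None = None) -> Trie:
    """Build the extended-prefix trie of a corpus up to ``max_depth``.

    The default depth is the longest sequence length plus one, so every
    sequence reaches its terminator node. At each depth t, the class counts
    over depth-t nodes sum to the corpus class counts.
    """
    if len(corpus) == 0:
        raise TrieError("cannot build a trie from an empty corpus")
    if max_depth is None:
        max_depth = corpus.max_length() + 1
    if max_depth < 1:
        raise TrieError(f"max_depth must be >= 1, got {max_depth}")

    root = TrieNode(prefix=())
    for seq in corpus.sequences:
        node = root
        node.class_counts[seq.label] = node.class_counts.get(seq.label, 0) + 1
        ext = extended_prefix(seq, max_depth)
        for t in range(1, max_depth + 1):
            sym = ext[t - 1]
            child = node.children.get(sym)
            if child is None:
                child = TrieNode(prefix=node.prefix + (sym,))
                node.children[sym] = child
            child.class_counts[seq.label] = child.class_counts.get(seq.label, 0) + 1
            node = child
    return Trie(root, max_depth, corpus.call_alphabet, corpus.class_alphabet)


def transition_probability(trie: Trie, node: TrieNode, symbol: str) -> float:
    """Unweighted probability that a sequence at ``node`` continues with ``symbol``.

    This is the count fraction (sequences whose next extended symbol is
    ``symbol``) / (sequences at the node); over a node's children, including
    the end symbol, these sum to one. Only defined for nodes above the trie's
    maximum depth (deeper nodes have no recorded children).
    """
    total = node.total_count()
    if total == 0:
        raise TrieError(f"transition probability undefined at zero-count node {node.prefix}")
    if node.depth >= trie.depth:
        raise TrieError(f"node {node.prefix} is at the trie's maximum depth; no transitions recorded")
    child = node.children.get(symbol)
    return (child.total_count() if child is not None else 0) / total
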