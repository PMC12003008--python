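"""Independent brute-force oracles for the positional indices.

These deliberately avoid the package's trie machinery: prefixes are padded
and grouped with plain dictionaries and the indices are computed by direct
enumeration, so agreement with the trie-based implementation is a genuine
two-route check.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

END_PAD = "∅"


def padded_prefix(tokens: tuple[str, ...], t: int) -> tuple[str, ...]:
    if t <= len(tokens):
        return tuple(tokens[:t])
    return tuple(tokens) + (END_PAD,) * (t - len(tokens))


def brute_indices(
    token_lists: list[tuple[str, ...]], labels: list[str], t: int, classes: list[str] | None = None
) -> tuple[float, float]:
    """(H(t), J(t)) by direct enumeration over padded prefixes."""
    if classes is None:
        classes = sorted(set(labels))
    k = len(classes)
    n_y = Counter(labels)
    w = {y: 1.0 / (k * n_y[y]) for y in classes}
    groups: dict[tuple[str, ...], Counter] = {}
    for toks, y in zip(token_lists, labels):
        groups.setdefault(padded_prefix(toks, t), Counter())[y] += 1
    h = j = 0.0
    for cnt in groups.values():
        masses = [w[y] * cnt.get(y, 0) for y in classes]
        pr = sum(masses)
        ps = [m / pr for m in masses]
        h += pr * (-sum(p * math.log(p) for p in ps if p > 0) / math.log(k))
        j += pr * max(ps)
    return h, j


def brute_profile(
    token_lists: list[tuple[str, ...]], labels: list[str], t_max: int
) -> tuple[list[float], list[float], list[float]]:
    """(H, D, J) for t = 0..t_max by direct enumeration."""
    H, J = [], []
    for t in range(t_max + 1):
        h, j = brute_indices(token_lists, labels, t)
        H.append(h)
        J.append(j)
    D = [0.0] + [H[i - 1] - H[i] for i in range(1, t_max + 1)]
    return H, D, J


def exhaustive_null_values(
    token_lists: list[tuple[str, ...]], labels: list[str], t: int, index: str
) -> list[float]:
    """Index value at position t for EVERY within-(t-1)-prefix label arrangement.

    Arrangements are enumerated as the product of full permutations within
    each prefix group (each equally likely under the shuffle), so the returned
    list is the exact, uniform null distribution including multiplicities.
    """
    classes = sorted(set(labels))
    groups: dict[tuple[str, ...], list[int]] = {}
    for i, toks in enumerate(token_lists):
        groups.setdefault(padded_prefix(toks, t - 1), []).append(i)
    h_prev, _ = brute_indices(token_lists, labels, t - 1, classes)

    values = []
    group_items = list(groups.values())
    for arrangement in itertools.product(*(itertools.permutations(idx) for idx in group_items)):
        perm_labels = list(labels)
        for idx, perm in zip(group_items, arrangement):
            for dest, src in zip(idx, perm):
                perm_labels[dest] = labels[src]
        h, j = brute_indices(token_lists, perm_labels, t, classes)
        values.append(h_prev - h if index == "D" else j)
    return values
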