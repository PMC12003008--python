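"""Permutation-null confidence intervals for the positional indices.

The null hypothesis at position t is that the call at position t carries no
information about the stimulus class beyond what the first t-1 calls already
carry. It is simulated by shuffling stimulus labels among sequences that
share the same extended (t-1)-prefix: this is the unique randomization that
leaves every depth-(t-1) statistic exactly invariant while breaking any
association between the class and the position-t symbol. At t = 1 the single
step-0 category is the root, i.e. a global label shuffle.

For each position and index (D = Kullback-Leibler gain, J = prediction gain)
the empirical 2.5% and 97.5% quantiles of the permuted index form a 95%
interval; an observed value outside the interval flags the position as adding
significant information. Quantiles use the order-statistic convention
"k-th smallest with k = ceil(q · n_perm)".

Permutations are computed on per-node count matrices with numpy (the node a
sequence occupies at depth t is fixed; only its label moves), which is
algebraically identical to re-running the trie computation on each permuted
corpus and is validated against exhaustive enumeration in the test suite.
One seed drives everything; the substream for (position t, index) is derived
deterministically, so results are reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .corpus import Corpus
from .infogain import InfoGainError, InfoProfile, Weights, class_weights, info_profile
from .trie import extended_prefix

__all__ = [
    "NullInterval",
    "permute_labels_within_prefix",
    "null_interval",
    "significance_profile",
    "empirical_quantile",
]

_INDEX_CODES = {"D": 0, "J": 1}


@dataclass(frozen=True)
class NullInterval:
    """Permutation interval for one index at one position.

    ``significant`` is True iff the observed value lies strictly outside
    [lo, hi].
    """

    t: int
    index: str
    lo: float
    hi: float
    n_perm: int
    observed: float
    significant: bool


def _group_indices(corpus: Corpus, t: int) -> list[np.ndarray]:
    """Indices of sequences grouped by shared extended (t-1)-prefix."""
    groups: dict[tuple[str, ...], list[int]] = {}
    for i, seq in enumerate(corpus.sequences):
        groups.setdefault(extended_prefix(seq, t - 1), []).append(i)
    return [np.array(idx) for idx in groups.values()]


def permute_labels_within_prefix(corpus: Corpus, t: int, rng: np.random.Generator) -> Corpus:
    """One null draw: reassign labels uniformly within each (t-1)-prefix group.

    Token sequences and the label multiset of every group are preserved, so
    all statistics at positions 0..t-1 are exactly those of the original
    corpus.
    """
    if t < 1:
        raise InfoGainError(f"permutation position must be >= 1, got {t}")
    labels = np.array(corpus.labels(), dtype=object)
    for idx in _group_indices(corpus, t):
        labels[idx] = labels[rng.permutation(idx)]
    new_seqs = [dataclasses.replace(s, label=str(y)) for s, y in zip(corpus.sequences, labels)]
    return corpus.with_sequences(new_seqs)


def empirical_quantile(sorted_values: np.ndarray, q: float) -> float:
    """Order-statistic quantile: the k-th smallest value with k = ceil(q·n)."""
    n = sorted_values.size
    k = min(max(math.ceil(q * n), 1), n)
    return float(sorted_values[k - 1])


def _layout(corpus: Corpus, t: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, Weights]:
    """Integer encodings: labels, depth-(t-1) group ids, depth-t node ids."""
    weights = class_weights(corpus)
    cls_index = {y: i for i, y in enumerate(weights.classes)}
    labels = np.array([cls_index[s.label] for s in corpus.sequences])
    gid_map: dict[tuple[str, ...], int] = {}
    nid_map: dict[tuple[str, ...], int] = {}
    gids = np.empty(len(corpus), dtype=np.int64)
    nids = np.empty(len(corpus), dtype=np.int64)
    for i, seq in enumerate(corpus.sequences):
        g = extended_prefix(seq, t - 1)
        n = extended_prefix(seq, t)
        gids[i] = gid_map.setdefault(g, len(gid_map))
        nids[i] = nid_map.setdefault(n, len(nid_map))
    return labels, gids, nids, weights


def _stats_from_counts(counts: np.ndarray, w: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """H(t) and J(t) from count arrays of shape (..., n_nodes, K).

    Every node has a positive raw count (permutations move labels, not
    sequences), so node masses are strictly positive.
    """
    mass_y = counts * w
    mass = mass_y.sum(axis=-1)
    p = mass_y / mass[..., None]
    h_nodes = -xlogy(p, p).sum(axis=-1) / math.log(k)
    H = (mass * h_nodes).sum(axis=-1)
    J = (mass * p.max(axis=-1)).sum(axis=-1)
    return H, J


def _counts_by_node(nids: np.ndarray, labels: np.ndarray, n_nodes: int, k: int) -> np.ndarray:
    """Count matrix (n_perm, n_nodes, K) for a batch of label rows, or
    (n_nodes, K) for a single label vector."""
    if labels.ndim == 1:
        flat = nids * k + labels
        return np.bincount(flat, minlength=n_nodes * k).reshape(n_nodes, k).astype(float)
    m = labels.shape[0]
    offsets = np.arange(m)[:, None] * (n_nodes * k)
    flat = (offsets + nids * k + labels).ravel()
    return np.bincount(flat, minlength=m * n_nodes * k).reshape(m, n_nodes, k).astype(float)


def null_interval(
    corpus: Corpus,
    t: int,
    index: str = "D",
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    max_chunk: int = 50_000,
) -> NullInterval:
    """Permutation interval for index ``"D"`` or ``"J"`` at position ``t``.

    Returns the empirical alpha/2 and 1-alpha/2 quantiles of the index
    recomputed under ``n_perm`` within-(t-1)-prefix label shuffles, along
    with the observed value and its significance flag. The random substream
    is derived from ``(seed, t, index)``, so D and J intervals at different
    positions are mutually independent and individually reproducible.
    """
    if index not in _INDEX_CODES:
        raise InfoGainError(f"index must be 'D' or 'J', got {index!r}")
    if t < 1:
        raise InfoGainError(f"permutation position must be >= 1, got {t}")
    if not 0 < alpha < 1:
        raise InfoGainError(f"alpha must be in (0, 1), got {alpha}")
    if n_perm < 1:
        raise InfoGainError(f"n_perm must be >= 1, got {n_perm}")

    labels, gids, nids, weights = _layout(corpus, t)
    if len(set(labels.tolist())) < 2:
        raise InfoGainError("permutation null undefined for a corpus with a single class")
    k = weights.k
    w = weights.as_array()
    n_nodes = int(nids.max()) + 1
    n_groups = int(gids.max()) + 1

    # observed value at position t (H at t-1 is invariant under the shuffle)
    h_prev, _ = _stats_from_counts(_counts_by_node(gids, labels, n_groups, k), w, k)
    h_obs, j_obs = _stats_from_counts(_counts_by_node(nids, labels, n_nodes, k), w, k)
    observed = float(h_prev - h_obs) if index == "D" else float(j_obs)

    # sort sequences so prefix groups are contiguous, then shuffle block-wise
    order = np.argsort(gids, kind="stable")
    nids_s, labels_s, gids_s = nids[order], labels[order], gids[order]
    bounds = np.flatnonzero(np.r_[1, np.diff(gids_s), 1])

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(t, _INDEX_CODES[index])))
    # cap the count-matrix footprint at ~max_chunk * 64 doubles per batch
    chunk = int(max(1, min(n_perm, (max_chunk * 64) // max(1, n_nodes * k))))
    values = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perm_labels = np.tile(labels_s, (m, 1))
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b - a > 1:
                perm_labels[:, a:b] = rng.permuted(perm_labels[:, a:b], axis=1)
        counts = _counts_by_node(nids_s, perm_labels, n_nodes, k)
        H, J = _stats_from_counts(counts, w, k)
        values[done : done + m] = (h_prev - H) if index == "D" else J
        done += m

    values.sort()
    lo = empirical_quantile(values, alpha / 2)
    hi = empirical_quantile(values, 1 - alpha / 2)
    return NullInterval(
        t=t, index=index, lo=lo, hi=hi, n_perm=n_perm, observed=observed,
        significant=bool(observed < lo or observed > hi),
    )


def significance_profile(
    corpus: Corpus,
    max_depth: int | None = None,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> InfoProfile:
    """Information profile with permutation intervals for D and J at t = 1..T."""
    profile = info_profile(corpus, max_depth=max_depth)
    for t in profile.t[1:]:
        for index in ("D", "J"):
            ni = null_interval(corpus, int(t), index=index, n_perm=n_perm, alpha=alpha, seed=seed)
            if index == "D":
                profile.D_lo[t], profile.D_hi[t] = ni.lo, ni.hi
            else:
                profile.J_lo[t], profile.J_hi[t] = ni.lo, ni.hi
    return profile
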