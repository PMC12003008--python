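"""Rendering: DOT export of the annotated trie and the positional profile plot.

Node colors follow the three-class RGB convention with channel order
(leopard, falling tree, eagle): a pure leopard node is red (255,0,0), pure
falling tree green (0,255,0), pure eagle blue (0,0,255), and the uniform
distribution maps to gray (153,153,153). Between those anchors each channel
is the power law round(255 · p^γ) with γ = ln 0.6 / ln(1/3) ≈ 0.46497 — the
unique exponent for which both the pure and the uniform anchors hold exactly.
Channels are monotone in their class probability.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np

from .infogain import InfoProfile, Weights, conditional_distribution, node_accuracy
from .trie import END, Trie, transition_probability

__all__ = ["COLOR_GAMMA", "DEFAULT_CHANNEL_ORDER", "VizError", "distribution_color", "render_trie_dot", "plot_profile"]

#: Channel exponent: round(255 · (1/3)^γ) = 153 and 255 · 1^γ = 255.
COLOR_GAMMA = math.log(0.6) / math.log(1 / 3)

#: Class feeding each RGB channel: red = leopard, green = falling tree, blue = eagle.
DEFAULT_CHANNEL_ORDER: tuple[str, str, str] = ("L", "T", "E")


class VizError(Exception):
    pass


def distribution_color(
    dist: Sequence[float] | np.ndarray,
    classes: Sequence[str],
    channel_order: Sequence[str] = DEFAULT_CHANNEL_ORDER,
) -> tuple[int, int, int]:
    """Map a three-class distribution to an RGB triple.

    ``dist`` is ordered like ``classes``; ``channel_order`` names the class
    driving each of (R, G, B). Only defined for exactly three classes.
    """
    dist = np.asarray(dist, dtype=float)
    if len(classes) != 3 or dist.size != 3:
        raise VizError(f"color mixing is defined for exactly 3 classes, got {len(classes)}")
    if set(channel_order) != set(classes):
        raise VizError(f"channel order {tuple(channel_order)} does not cover classes {tuple(classes)}")
    by_class = dict(zip(classes, dist))
    return tuple(int(round(255 * by_class[c] ** COLOR_GAMMA)) for c in channel_order)  # type: ignore[return-value]


def _node_id(prefix: tuple[str, ...]) -> str:
    return "root" if not prefix else "".join("End" if s == END else s for s in prefix)


def _node_shape(symbol: str | None, call_alphabet: tuple[str, ...]) -> str:
    if symbol is None or symbol == END:
        return "plaintext"
    # first call type drawn as a circle, second as a square; extras fall back to ellipse
    shapes = {call_alphabet[0]: "circle"}
    if len(call_alphabet) > 1:
        shapes[call_alphabet[1]] = "box"
    return shapes.get(symbol, "ellipse")


def render_trie_dot(
    trie: Trie,
    weights: Weights | None = None,
    channel_order: Sequence[str] = DEFAULT_CHANNEL_ORDER,
    min_penwidth: float = 0.5,
    max_penwidth: float = 4.5,
) -> str:
    """Emit Graphviz DOT text for a trie.

    Nodes are circles for the first call type, boxes for the second, plain
    labels for the root and the end symbol; edge pen width scales linearly
    with the transition probability. When ``weights`` are given and there are
    three classes, nodes are filled with :func:`distribution_color` and
    labeled with the maximum conditional class probability. Absorbing
    end-symbol chains are collapsed to a single end node per terminated
    prefix. Output is deterministic for a fixed trie.
    """
    colorize = weights is not None and len(trie.class_alphabet) == 3
    lines = [
        "digraph trie {",
        "  rankdir=LR;",
        '  node [style=filled, fillcolor="#ffffff"];',
    ]
    for node in trie.iter_nodes():
        if node.prefix and node.prefix[-1] == END and len(node.prefix) >= 2 and node.prefix[-2] == END:
            continue  # collapse absorbing ∅ chains
        nid = _node_id(node.prefix)
        label = node.symbol or "root"
        if label == END:
            label = END
        attrs = [f'label="{label}"', f"shape={_node_shape(node.symbol, trie.call_alphabet)}"]
        if colorize:
            dist = conditional_distribution(trie, node, weights)
            r, g, b = distribution_color(dist, trie.class_alphabet, channel_order)
            attrs.append(f'fillcolor="#{r:02x}{g:02x}{b:02x}"')
            attrs.append(f'xlabel="{node_accuracy(dist):.2f}"')
        lines.append(f'  {nid} [{", ".join(attrs)}];')
    for node in trie.iter_nodes():
        if node.depth >= trie.depth:
            continue
        if node.prefix and node.prefix[-1] == END:
            continue  # the only child of ∅ is ∅
        for sym in trie._child_order(node):
            p = transition_probability(trie, node, sym)
            width = min_penwidth + (max_penwidth - min_penwidth) * p
            lines.append(
                f'  {_node_id(node.prefix)} -> {_node_id(node.prefix + (sym,))} '
                f'[penwidth={width:.3f}, label="{p:.2f}"];'
            )
    lines.append("}")
    return "\n".join(lines) + "\n"


def plot_profile(profile: InfoProfile, path: str | Path) -> Path:
    """Two-panel plot: prediction gain J(t) and KL gain D(t|t-1) vs position.

    Where permutation intervals are present they are drawn as red vertical
    segments. Writes PNG or SVG according to the file suffix.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    path = Path(path)
    t = np.asarray(profile.t)
    fig, (ax_j, ax_d) = plt.subplots(1, 2, figsize=(9, 3.6), sharex=True)

    ax_j.plot(t, profile.J, "o-", color="black", ms=4)
    has_j = ~np.isnan(profile.J_lo)
    if has_j.any():
        ax_j.vlines(t[has_j], profile.J_lo[has_j], profile.J_hi[has_j], color="red", lw=2, zorder=3)
    ax_j.set_xlabel("call position t")
    ax_j.set_ylabel("prediction accuracy J(t)")
    ax_j.set_title("A  prediction gain")

    ax_d.plot(t[1:], profile.D[1:], "o-", color="black", ms=4)
    has_d = ~np.isnan(profile.D_lo)
    if has_d.any():
        ax_d.vlines(t[has_d], profile.D_lo[has_d], profile.D_hi[has_d], color="red", lw=2, zorder=3)
    ax_d.set_xlabel("call position t")
    ax_d.set_ylabel("KL gain D(t|t−1)")
    ax_d.set_title("B  information gain")

    for ax in (ax_j, ax_d):
        ax.set_xticks(t)
        ax.spines[["top", "right"]].set_visible(False)
    fig.tight_layout()
    try:
        fig.savefig(path, dpi=150)
    finally:
        plt.close(fig)
    return path
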