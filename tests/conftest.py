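from __future__ import annotations

import numpy as np
import pytest

from alarmtrie import CallSequence, Corpus


@pytest.fixture
def tiny_corpus() -> Corpus:
    """Four-sequence corpus whose full profile is known by hand:

    H = (1, log3(2)·2/3, log3(2)·2/3, 0), J = (1/3, 2/3, 2/3, 1) at t = 0..3.
    """
    return Corpus(
        (
            CallSequence(("A", "A"), "E"),
            CallSequence(("A", "B"), "E"),
            CallSequence(("B", "A"), "L"),
            CallSequence(("B", "A", "A"), "T"),
        )
    )


def random_corpus(rng: np.random.Generator, max_seqs: int = 10, max_len: int = 4) -> Corpus:
    """Small random corpus with at least two nonempty classes."""
    while True:
        n = int(rng.integers(2, max_seqs + 1))
        labels = [str(y) for y in rng.choice(["E", "L", "T"], size=n)]
        if len(set(labels)) >= 2:
            break
    seqs = []
    for y in labels:
        length = int(rng.integers(1, max_len + 1))
        tokens = tuple(str(s) for s in rng.choice(["A", "B"], size=length))
        seqs.append(CallSequence(tokens, y))
    return Corpus(tuple(seqs), ("A", "B"), tuple(sorted(set(labels))))
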