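"""Token-level string-edit (Levenshtein) distance and normalized similarity.

The distance between two scan-path sequences is the minimum number of
insertions, deletions and substitutions of *whole tokens* (unit costs)
needed to convert one into the other; the similarity is

    S(a, b) = 1 - d(a, b) / max(|a|, |b|)

i.e. one minus the distance normalized by the longer sequence's length
(Privitera-Stark convention).  With 100 two-digit AOI labels the edit
operations must act at the token level: character-level editing of the
concatenated strings would allow alignments that straddle token
boundaries and is deliberately not supported.
"""

from __future__ import annotations

import warnings
from typing import Collection, Iterable

import numpy as np

__all__ = ["edit_distance", "similarity"]


def _as_tokens(seq: Iterable[str]) -> tuple[str, ...]:
    # ScanPathSequence, list, tuple and generator inputs all accepted.
    tokens = tuple(seq)
    return tuple(str(tok) for tok in tokens)


def _levenshtein(a: tuple[str, ...], b: tuple[str, ...]) -> int:
    """Full-matrix dynamic program, one numpy row per token of ``a``.

    Sequences here are at most a few hundred tokens, so the O(|a||b|)
    matrix is cheap; the inner row is vectorised with a prefix-minimum to
    resolve the left-neighbour (insertion) dependency.
    """
    if not a:
        return len(b)
    if not b:
        return len(a)
    b_arr = np.array(b)
    idx = np.arange(len(b) + 1)
    prev = idx.copy()
    for i, tok in enumerate(a, start=1):
        sub = prev[:-1] + (b_arr != tok)
        cand = np.minimum(prev[1:] + 1, sub)  # deletion vs substitution
        # Insertions: cur[j] = min(cand[j-1], cur[j-1] + 1), resolved via a
        # prefix minimum of (value - position).
        shifted = np.concatenate(([i], cand)) - idx
        prev = np.minimum.accumulate(shifted) + idx
    return int(prev[-1])


def edit_distance(
    a: Iterable[str],
    b: Iterable[str],
    alphabet: Collection[str] | None = None,
) -> int:
    """Minimal whole-token edit count transforming ``a`` into ``b``.

    Symmetric in its arguments.  When ``alphabet`` is given, tokens
    outside it trigger a warning but the computation proceeds.
    """
    ta, tb = _as_tokens(a), _as_tokens(b)
    if alphabet is not None:
        stray = [tok for tok in (*ta, *tb) if tok not in alphabet]
        if stray:
            warnings.warn(
                f"tokens outside the expected alphabet: {sorted(set(stray))}",
                stacklevel=2,
            )
    return _levenshtein(ta, tb)


def similarity(
    a: Iterable[str],
    b: Iterable[str],
    alphabet: Collection[str] | None = None,
) -> float:
    """Normalized string-edit similarity in [0, 1].

    Two empty sequences are identical by convention (the normalization is
    0/0 there, so a warning is emitted).
    """
    ta, tb = _as_tokens(a), _as_tokens(b)
    longest = max(len(ta), len(tb))
    if longest == 0:
        warnings.warn(
            "similarity of two empty sequences is 1 by convention "
            "(normalization is 0/0)",
            stacklevel=2,
        )
        return 1.0
    return 1.0 - edit_distance(ta, tb, alphabet=alphabet) / longest
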