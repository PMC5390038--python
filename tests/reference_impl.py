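"""Independent reference implementations used only as test oracles.

Deliberately naive: plain loops and linear scans, structured differently
from the package code so that agreement is evidence of correctness
rather than shared bugs.
"""

from __future__ import annotations

import math
import random
from typing import Sequence


def brute_force_tau_b(x: Sequence[float], y: Sequence[float]):
    """Tau-b by O(n^2) enumeration of all index pairs.

    Returns (tau, P, Q, X0, Y0); raises ZeroDivisionError-equivalent
    ValueError when a ranking is constant.
    """
    n = len(x)
    p = q = x0 = y0 = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = int(x[i] > x[j]) - int(x[i] < x[j])
            dy = int(y[i] > y[j]) - int(y[i] < y[j])
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                x0 += 1
            elif dy == 0:
                y0 += 1
            elif dx == dy:
                p += 1
            else:
                q += 1
    denom = (p + q + x0) * (p + q + y0)
    if denom == 0:
        raise ValueError("degenerate: constant ranking")
    return (p - q) / math.sqrt(denom), p, q, x0, y0


def naive_chunk_corpus(
    utterances: list[list[str]],
    noise_correction: bool = True,
    mode: str = "cbl",
    attach_prob: float = 0.5,
    seed: int = 0,
    use_chunkatory: bool = True,
) -> list[tuple[str, ...]]:
    """Re-simulation of the incremental chunker with naive data structures.

    Counts are recomputed from an explicit transition log on every
    decision; the chunkatory is a list scanned linearly.  Returns the
    flat sequence of emitted units in emission order.
    """
    transition_log: list[tuple[str, str]] = []  # all (prev, curr) seen so far
    token_log: list[str] = []                   # all tokens counted so far
    btp_log: list[float] = []                   # BTPs in scoring order
    chunkatory: list[tuple[str, ...]] = []
    emitted: list[tuple[str, ...]] = []
    rng = random.Random(seed)

    def freq(w: str) -> int:
        return sum(1 for t in token_log if t == w)

    def left(prev: str, curr: str) -> int:
        return sum(1 for (a, b) in transition_log if a == prev and b == curr)

    def in_chunkatory(prev: str, curr: str) -> bool:
        for unit in chunkatory:
            if len(unit) >= 2:
                for k in range(len(unit) - 1):
                    if unit[k] == prev and unit[k + 1] == curr:
                        return True
        return False

    for utt in utterances:
        token_log.append(utt[0])
        open_unit = [utt[0]]
        for i in range(1, len(utt)):
            prev, curr = utt[i - 1], utt[i]
            token_log.append(curr)
            transition_log.append((prev, curr))
            btp = left(prev, curr) / freq(curr)
            mean_btp = sum(btp_log) / len(btp_log) if btp_log else 0.0
            threshold = mean_btp + (1.0 / freq(curr) if noise_correction else 0.0)
            if mode == "cbl":
                attach = in_chunkatory(prev, curr) or btp > threshold
            else:
                if use_chunkatory and in_chunkatory(prev, curr):
                    attach = True
                else:
                    attach = rng.random() < attach_prob
            if attach:
                open_unit.append(curr)
            else:
                emitted.append(tuple(open_unit))
                chunkatory.append(tuple(open_unit))
                open_unit = [curr]
            btp_log.append(btp)
        emitted.append(tuple(open_unit))
        chunkatory.append(tuple(open_unit))
    return emitted
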