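"""Incremental multi-word-unit chunking by backward transitional probability.

The chunker processes a corpus utterance by utterance and word by word.
For each within-utterance transition from word ``w[i-1]`` to ``w[i]`` it
computes the backward transitional probability (BTP)

    p(w[i-1] | w[i]) = count(w[i-1] immediately before w[i]) / count(w[i])

and attaches ``w[i]`` to the currently open unit when that BTP exceeds a
running-average threshold; otherwise the open unit is closed (emitted)
and a new unit starts at ``w[i]``.  Two refinements:

* **Noise correction** — with ``noise_correction`` on (the default), the
  threshold is the running mean BTP *plus* ``1/count(w[i])``.  Rarely
  seen words therefore attach only when their BTP is much larger than
  average, which suppresses chunking decisions driven by unstable
  small-sample estimates; the penalty decays as exposure accumulates.
* **Chunkatory reuse** — every closed unit is stored in the *chunkatory*
  (set ``M`` of discovered units).  Whenever a transition matches an
  adjacent word pair inside any stored unit of length >= 2, the two words
  are grouped again regardless of the BTP.

A random baseline shares the identical control flow but replaces the BTP
comparison with a Bernoulli coin toss, producing word sequences with no
internal cohesion; by default it keeps the chunkatory stage, so early
random groupings become entrenched.

Per-transition update order (fixed, documented because the running mean
makes results order-sensitive):

1. increment ``count(w[i])`` and ``count(w[i-1] before w[i])``;
2. compute the BTP from the updated counts;
3. form the threshold from the running mean over *prior* transitions
   (0 when none) plus the noise-correction term;
4. attach via the chunkatory override, else via the strict comparison
   ``BTP > threshold`` (ties close the unit);
5. fold this transition's BTP into the running mean (always, including
   overridden transitions).

Counting before scoring means a word's first-ever occurrence has
``count = 1``, threshold >= 1, and BTP <= 1 — so with noise correction a
first exposure can never attach through the probability rule, only
through the chunkatory.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np

from mwulex.corpus_io import Corpus, Utterance

__all__ = [
    "ChunkerConfig",
    "ChunkerState",
    "UnitInventory",
    "backward_tp",
    "attach_decision_cbl",
    "process_utterance",
    "run_cbl",
    "run_baseline",
    "write_inventory",
    "read_inventory",
]

Unit = tuple[str, ...]


@dataclass
class ChunkerConfig:
    """Configuration for a chunker run.

    mode
        ``"cbl"`` for the BTP chunker, ``"baseline"`` for the coin-toss
        baseline.
    threshold_mode
        ``"global_mean"`` (default) compares each BTP against the running
        mean of all transition BTPs scored so far, corpus-wide.
        ``"per_word_mean"`` instead averages the BTPs of the current
        word's distinct attested left neighbours.
    noise_correction
        Add ``1/count(w[i])`` to the threshold (default True).
    baseline_attach_prob
        Coin-toss probability for the baseline (default 0.5).
    baseline_use_chunkatory
        Whether the baseline keeps the chunkatory override stage
        (default True; only the BTP comparison is randomised).
    seed
        RNG seed; required for the baseline, ignored by the CBL.
    """

    mode: Literal["cbl", "baseline"] = "cbl"
    threshold_mode: Literal["global_mean", "per_word_mean"] = "global_mean"
    noise_correction: bool = True
    baseline_attach_prob: float = 0.5
    baseline_use_chunkatory: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("cbl", "baseline"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.threshold_mode not in ("global_mean", "per_word_mean"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if not 0.0 <= self.baseline_attach_prob <= 1.0:
            raise ValueError("baseline_attach_prob must be in [0, 1]")
        if self.mode == "baseline" and self.seed is None:
            raise ValueError("baseline mode requires a seed")


@dataclass
class ChunkerState:
    """Mutable counters and the chunkatory accumulated over a run."""

    word_freq: Counter = field(default_factory=Counter)
    left_count: Counter = field(default_factory=Counter)  # (prev, curr) -> count
    running_btp_sum: float = 0.0
    running_btp_n: int = 0
    chunkatory: set[Unit] = field(default_factory=set)
    # adjacent word pairs inside any stored unit of length >= 2; the O(1)
    # membership structure behind the chunkatory override
    _override_pairs: set[tuple[str, str]] = field(default_factory=set)

    @property
    def mean_btp(self) -> float:
        return self.running_btp_sum / self.running_btp_n if self.running_btp_n else 0.0

    def add_to_chunkatory(self, unit: Unit) -> None:
        self.chunkatory.add(unit)
        if len(unit) >= 2:
            for a, b in zip(unit, unit[1:]):
                self._override_pairs.add((a, b))

    def in_stored_unit(self, prev: str, curr: str) -> bool:
        """True iff (prev, curr) is an adjacent pair inside a stored unit of length >= 2."""
        return (prev, curr) in self._override_pairs


@dataclass
class UnitInventory:
    """Multiset of emitted unit types with their emission (token) counts."""

    counts: Counter = field(default_factory=Counter)
    label: str = ""

    @property
    def n_unit_tokens(self) -> int:
        return sum(self.counts.values())

    @property
    def n_unit_types(self) -> int:
        return len(self.counts)

    def __iter__(self) -> Iterator[Unit]:
        return iter(self.counts)

    def __len__(self) -> int:
        return len(self.counts)

    def add(self, unit: Unit) -> None:
        self.counts[unit] += 1

    def total_word_tokens(self) -> int:
        """Words covered by all emissions: sum of len(unit) * count(unit)."""
        return sum(len(u) * c for u, c in self.counts.items())


def backward_tp(state: ChunkerState, prev: str, curr: str) -> float:
    """Backward transitional probability p(prev | curr) from current counts.

    Requires ``curr`` to have been counted already (the update order
    counts before scoring).
    """
    freq = state.word_freq[curr]
    if freq == 0:
        raise ValueError(
            f"backward_tp called before {curr!r} was counted (contract violation)"
        )
    return state.left_count[(prev, curr)] / freq


class _PerWordThreshold:
    """Per-word running BTP means for threshold_mode='per_word_mean'.

    Keeps, for each current word, the set of distinct left neighbours
    seen so far; the per-word mean BTP is then computed on demand from
    the live counters.  Cost is O(distinct neighbours of curr) per
    lookup, acceptable because natural corpora keep neighbour sets small
    relative to corpus size.
    """

    def __init__(self) -> None:
        self._neighbours: dict[str, set[str]] = {}

    def note(self, prev: str, curr: str) -> None:
        self._neighbours.setdefault(curr, set()).add(prev)

    def mean(self, state: ChunkerState, curr: str) -> float:
        neigh = self._neighbours.get(curr)
        if not neigh:
            return 0.0
        freq = state.word_freq[curr]
        return sum(state.left_count[(p, curr)] for p in neigh) / (freq * len(neigh))


def attach_decision_cbl(
    state: ChunkerState,
    prev: str,
    curr: str,
    config: ChunkerConfig | None = None,
    _per_word: _PerWordThreshold | None = None,
) -> bool:
    """Decide whether ``curr`` joins the open unit (counts already updated).

    Chunkatory override first; otherwise strict comparison of the BTP
    against the running-mean threshold.  Ties close the unit.
    """
    config = config or ChunkerConfig()
    if state.in_stored_unit(prev, curr):
        return True
    btp = backward_tp(state, prev, curr)
    if config.threshold_mode == "global_mean":
        base = state.mean_btp
    else:
        if _per_word is None:
            raise ValueError("per_word_mean requires the per-word tracker")
        base = _per_word.mean(state, curr)
    thr = base + (1.0 / state.word_freq[curr] if config.noise_correction else 0.0)
    return btp > thr


def process_utterance(
    state: ChunkerState,
    u: Utterance,
    config: ChunkerConfig,
    rng: np.random.Generator | None = None,
    _per_word: _PerWordThreshold | None = None,
) -> list[Unit]:
    """Process one utterance incrementally; returns the emitted units in order.

    Emitted units partition the utterance's tokens.  Every closed unit
    (including single words) enters the chunkatory.  The state's
    counters, running mean and chunkatory are updated in place.
    """
    toks = u.tokens
    state.word_freq[toks[0]] += 1
    open_unit: list[str] = [toks[0]]
    emitted: list[Unit] = []

    for i in range(1, len(toks)):
        prev, curr = toks[i - 1], toks[i]
        # (1) count
        state.word_freq[curr] += 1
        state.left_count[(prev, curr)] += 1
        # (2)-(4) score and decide
        if config.mode == "baseline":
            if config.baseline_use_chunkatory and state.in_stored_unit(prev, curr):
                attach = True
            else:
                assert rng is not None
                attach = rng.random() < config.baseline_attach_prob
            btp = backward_tp(state, prev, curr)
        else:
            attach = attach_decision_cbl(state, prev, curr, config, _per_word)
            btp = backward_tp(state, prev, curr)
        if attach:
            open_unit.append(curr)
        else:
            unit = tuple(open_unit)
            emitted.append(unit)
            state.add_to_chunkatory(unit)
            open_unit = [curr]
        # (5) fold this BTP into the running mean, unconditionally
        state.running_btp_sum += btp
        state.running_btp_n += 1
        if _per_word is not None:
            _per_word.note(prev, curr)

    unit = tuple(open_unit)
    emitted.append(unit)
    state.add_to_chunkatory(unit)
    return emitted


def _run(corpus: Corpus, config: ChunkerConfig) -> tuple[UnitInventory, ChunkerState]:
    state = ChunkerState()
    inventory = UnitInventory(label=f"{config.mode}:{corpus.label}")
    rng = (
        np.random.default_rng(config.seed) if config.mode == "baseline" else None
    )
    per_word = (
        _PerWordThreshold() if config.threshold_mode == "per_word_mean" else None
    )
    for u in corpus:
        for unit in process_utterance(state, u, config, rng, per_word):
            inventory.add(unit)
    return inventory, state


def run_cbl(
    corpus: Corpus, config: ChunkerConfig | None = None
) -> tuple[UnitInventory, ChunkerState]:
    """Run the BTP chunker over a corpus; deterministic."""
    config = config or ChunkerConfig(mode="cbl")
    if config.mode != "cbl":
        raise ValueError("run_cbl requires config.mode == 'cbl'")
    return _run(corpus, config)


def run_baseline(
    corpus: Corpus, config: ChunkerConfig
) -> tuple[UnitInventory, ChunkerState]:
    """Run the coin-toss baseline; reproducible given ``config.seed``."""
    if config.mode != "baseline":
        raise ValueError("run_baseline requires config.mode == 'baseline'")
    return _run(corpus, config)


def write_inventory(inventory: UnitInventory, path: str | Path) -> None:
    """Write units as TSV (unit, length, token_count), most frequent first."""
    path = Path(path)
    rows = sorted(inventory.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    with path.open("w", encoding="utf-8") as fh:
        fh.write("unit\tlength\ttoken_count\n")
        for unit, count in rows:
            fh.write(f"{' '.join(unit)}\t{len(unit)}\t{count}\n")


def read_inventory(path: str | Path, label: str = "") -> UnitInventory:
    path = Path(path)
    counts: Counter = Counter()
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("unit\t"):
            raise ValueError(f"{path}: not an inventory TSV")
        for line in fh:
            unit_str, _length, count = line.rstrip("\n").split("\t")
            counts[tuple(unit_str.split(" "))] = int(count)
    return UnitInventory(counts=counts, label=label or path.stem)
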