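"""Per-word predictors and summary statistics over corpora and unit inventories.

The per-word predictors of the correlational analyses:

* ``#Freq`` — raw token frequency of a word in a corpus
  (:func:`word_frequencies`);
* ``#MWUs`` / ``#baseline`` — the number of *distinct* unit types
  (chunker or baseline inventory) of length >= 2 that contain the word
  (:func:`count_units_per_word`).  Types, not tokens: a word contained
  in one very frequent unit still counts 1.

Summaries report token/type counts and the median and interquartile
range of unit (or utterance) lengths; by default unit lengths are
type-weighted (each unit type counted once), with a token-weighted
variant by flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from mwulex.chunker import UnitInventory
from mwulex.corpus_io import Corpus

__all__ = [
    "InventorySummary",
    "CorpusSummary",
    "count_units_per_word",
    "word_frequencies",
    "summarize_inventory",
    "summarize_corpus",
    "select_target_words",
]


@dataclass(frozen=True)
class InventorySummary:
    n_unit_tokens: int
    n_unit_types: int
    median_length: float
    iqr_length: float


@dataclass(frozen=True)
class CorpusSummary:
    n_tokens: int
    n_types: int
    median_utt_length: float
    iqr_utt_length: float
    n_utterances: int


def count_units_per_word(
    inventory: UnitInventory,
    targets: Iterable[str],
    min_length: int = 2,
) -> dict[str, int]:
    """Number of distinct unit types of length >= ``min_length`` containing each target.

    A word repeated inside one unit still contributes one to that unit's
    count; targets absent from every unit map to 0.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    targets = set(targets)
    counts = dict.fromkeys(targets, 0)
    for unit in inventory:
        if len(unit) < min_length:
            continue
        for word in set(unit) & targets:
            counts[word] += 1
    return counts


def word_frequencies(corpus: Corpus, targets: Iterable[str] | None = None) -> dict[str, int]:
    """Raw token counts per target word (all words if ``targets`` is None)."""
    freqs: dict[str, int] = {}
    for u in corpus:
        for tok in u.tokens:
            freqs[tok] = freqs.get(tok, 0) + 1
    if targets is None:
        return freqs
    return {w: freqs.get(w, 0) for w in targets}


def _median_iqr(values: np.ndarray) -> tuple[float, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(med), float(q3 - q1)


def summarize_inventory(
    inventory: UnitInventory, token_weighted: bool = False
) -> InventorySummary:
    """Token/type counts and median/IQR of the unit-length distribution.

    ``token_weighted=True`` weights each unit type's length by its
    emission count instead of counting each type once.
    """
    if inventory.n_unit_types == 0:
        raise ValueError("cannot summarize an empty inventory")
    if token_weighted:
        lengths = np.repeat(
            [len(u) for u in inventory.counts],
            list(inventory.counts.values()),
        )
    else:
        lengths = np.array([len(u) for u in inventory.counts])
    med, iqr = _median_iqr(lengths)
    return InventorySummary(
        n_unit_tokens=inventory.n_unit_tokens,
        n_unit_types=inventory.n_unit_types,
        median_length=med,
        iqr_length=iqr,
    )


def summarize_corpus(corpus: Corpus) -> CorpusSummary:
    if len(corpus) == 0:
        raise ValueError("cannot summarize an empty corpus")
    lengths = np.array([len(u) for u in corpus])
    med, iqr = _median_iqr(lengths)
    return CorpusSummary(
        n_tokens=int(lengths.sum()),
        n_types=len(corpus.vocabulary()),
        median_utt_length=med,
        iqr_utt_length=iqr,
        n_utterances=len(corpus),
    )


def select_target_words(
    cds: Corpus,
    ads: Corpus,
    aofp: Mapping[str, float],
    rt: Mapping[str, float],
) -> set[str]:
    """Words attested in both corpora with both an AoFP and an RT estimate.

    The intersection rule keeps the analyses comparable across predictor
    variants: every correlation is computed on the same word set.
    """
    targets = cds.vocabulary() & ads.vocabulary() & set(aofp) & set(rt)
    if not targets:
        raise ValueError(
            "no target words: the corpora, AoFP and RT sources share no word forms"
        )
    return targets
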