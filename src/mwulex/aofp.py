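"""Age of first production (AoFP) on the mean-length-of-utterance axis.

Child transcripts differ widely in length, so the naive mean utterance
length per transcript is a noisy developmental index.  Each transcript's
MLU is therefore bootstrap-estimated: draw ``reps`` resamples (with
replacement, sample size = the transcript's utterance count) of the
utterance-length sequence and average the resample means.

A word's AoFP is the *minimum* MLU over all transcripts in which any
child produces it — i.e. the earliest developmental stage at which the
word is attested.  Taking the minimum rather than a mean avoids
inflating estimates for words that older children were already using
when their recordings began.  AoFP is thus measured in MLU units
(tokens per utterance), not months.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mwulex.corpus_io import Transcript, TranscriptSet

__all__ = ["MLUEstimate", "bootstrap_mlu", "estimate_mlus", "assign_aofp", "AoFPTable"]


@dataclass(frozen=True)
class MLUEstimate:
    transcript_ref: str
    mlu: float
    n_utterances: int
    reps: int
    seed: int


@dataclass
class AoFPTable:
    """word → smallest MLU among transcripts containing it, with provenance."""

    aofp: dict[str, float]
    source_transcript: dict[str, str]

    def __len__(self) -> int:
        return len(self.aofp)

    def as_mapping(self) -> dict[str, float]:
        return dict(self.aofp)


def bootstrap_mlu(t: Transcript, reps: int = 1000, seed: int = 0) -> MLUEstimate:
    """Bootstrap estimate of a transcript's mean length of utterance.

    The point estimate is the mean of the ``reps`` resample means, which
    converges on the plain sample mean as ``reps`` grows; ``reps=0``
    short-circuits to the sample mean.
    """
    lengths = np.asarray(t.utterance_lengths(), dtype=float)
    if lengths.size == 0:
        raise ValueError(f"transcript {t.transcript_ref or t.child_id}: no utterances")
    if reps == 0:
        mlu = float(lengths.mean())
    else:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, lengths.size, size=(reps, lengths.size))
        mlu = float(lengths[idx].mean(axis=1).mean())
    return MLUEstimate(
        transcript_ref=t.transcript_ref or t.child_id,
        mlu=mlu,
        n_utterances=lengths.size,
        reps=reps,
        seed=seed,
    )


def estimate_mlus(
    ts: TranscriptSet, reps: int = 1000, seed: int = 0
) -> list[MLUEstimate]:
    """Bootstrap MLU for every transcript.

    Per-transcript seeds are derived from ``(seed, index)`` so adding a
    transcript never perturbs earlier estimates.
    """
    estimates = []
    for i, t in enumerate(ts):
        sub = np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31)
        estimates.append(bootstrap_mlu(t, reps=reps, seed=int(sub)))
    return estimates


def assign_aofp(ts: TranscriptSet, mlus: list[MLUEstimate]) -> AoFPTable:
    """AoFP = min transcript MLU over transcripts whose children produce the word.

    Only child utterances are scanned.  ``mlus`` must align one-to-one
    with ``ts.transcripts``.
    """
    if len(mlus) != len(ts):
        raise ValueError(
            f"{len(mlus)} MLU estimates for {len(ts)} transcripts — must align"
        )
    aofp: dict[str, float] = {}
    source: dict[str, str] = {}
    for t, est in zip(ts, mlus):
        for word in t.vocabulary():
            if word not in aofp or est.mlu < aofp[word]:
                aofp[word] = est.mlu
                source[word] = est.transcript_ref
    return AoFPTable(aofp=aofp, source_transcript=source)
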