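"""Synthetic corpora with planted collocations and known response structure.

The generator emulates the shape of the real inputs the analysis
pipeline is designed for, with full ground truth:

* **Utterance corpora** — each utterance either instantiates one of a
  fixed set of planted multi-word *templates* (probability
  ``template_use_prob``), padded with filler words, or consists of
  fillers only.  Fillers are sampled from a Zipf distribution, so filler
  transitions have low backward transitional probability while
  within-template transitions are highly cohesive — the structure the
  chunker is designed to detect.  Two registers differ in utterance
  length: the child-directed-like register is shorter than the
  adult-directed-like one.  Template words occur only inside templates;
  the two registers share one template set.
* **Transcript sets** — transcripts along a simulated developmental
  axis of increasing mean length of utterance, with skewed per-child
  token counts.  A word is introduced earlier (in a lower-MLU
  transcript) the larger ``beta_freq * log(1 + freq) + beta_mwu *
  n_templates`` plus Gaussian noise, so positive betas produce
  facilitation: earlier first production for frequent and
  template-dense words.
* **RT tables** — per-word reaction times
  ``baseline - a*log(1+freq) - b*n_templates + noise`` (milliseconds,
  truncated positive), with ``a`` and ``b`` scaled from the same betas.

Everything is deterministic given the seeds passed in; the config's
``master_seed`` fixes only the template set, so the same planted
structure underlies both registers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from mwulex.corpus_io import Corpus, Transcript, TranscriptSet, Utterance

__all__ = ["SyntheticConfig", "GroundTruth", "generate_corpus",
           "generate_transcripts", "generate_rt_table"]

Register = Literal["cds_like", "ads_like"]


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults define the standard study conditions.

    vocab_size
        Total word types: ``template_pool_size`` reserved for template
        members, the rest fillers.
    n_templates / template_length_range / template_pool_size
        Planted templates: each is a sequence of distinct words drawn
        from a shared pool, so pool words differ in how many templates
        contain them.  The default length range is 3–4: a two-word
        template inside a short utterance keeps its order under a
        within-utterance shuffle with probability about 1/L, so bigram
        templates would partially survive the shuffle controls that
        longer templates do not.
    template_use_prob
        Probability an utterance embeds a template.
    utt_length_range_cds / utt_length_range_ads
        Inclusive uniform ranges of utterance length per register; the
        CDS-like register is shorter, mirroring real child-directed
        speech.
    n_utterances
        Utterances per generated corpus.
    zipf_exponent
        Filler frequencies fall off as rank^-s, mirroring natural
        lexical statistics.
    beta_freq / beta_mwu / noise_sd
        Latent facilitation score per word (see module docstring);
        positive betas mean earlier first production and faster RTs.
    n_transcripts / mlu_range / utterances_per_transcript_median
        Shape of the developmental transcript set.
    rt_baseline_ms / rt_ms_per_unit
        Location and scale mapping the latent score into milliseconds.
    """

    vocab_size: int = 1200
    n_templates: int = 60
    template_length_range: tuple[int, int] = (3, 4)
    template_pool_size: int = 180
    template_use_prob: float = 0.5
    utt_length_range_cds: tuple[int, int] = (1, 8)
    utt_length_range_ads: tuple[int, int] = (1, 12)
    n_utterances: int = 9000
    zipf_exponent: float = 1.0
    beta_freq: float = 0.7
    beta_mwu: float = 1.2
    noise_sd: float = 0.6
    n_transcripts: int = 60
    mlu_range: tuple[float, float] = (1.5, 6.0)
    utterances_per_transcript_median: int = 80
    rt_baseline_ms: float = 750.0
    rt_ms_per_unit: float = 30.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.template_use_prob <= 1.0:
            raise ValueError("template_use_prob must be in [0, 1]")
        if self.template_pool_size > self.vocab_size:
            raise ValueError("template pool exceeds vocab_size")
        lo, hi = self.template_length_range
        if lo < 2 or hi < lo:
            raise ValueError("template_length_range must be [2, L] with L >= 2")
        if hi > self.template_pool_size:
            raise ValueError("templates longer than the template pool")


@dataclass
class GroundTruth:
    """Planted structure underlying a generated corpus."""

    templates: list[tuple[str, ...]]
    true_n_templates: dict[str, int]  # templates containing each word (types)
    true_freq: dict[str, int]         # realized token count in the corpus
    beta_freq: float
    beta_mwu: float

    def vocabulary(self) -> list[str]:
        return sorted(self.true_freq)


def _make_templates(config: SyntheticConfig) -> list[tuple[str, ...]]:
    """The shared template set, a function of the config alone."""
    rng = np.random.default_rng(np.random.SeedSequence([config.master_seed, 17]))
    pool = [f"t{i:03d}" for i in range(config.template_pool_size)]
    lo, hi = config.template_length_range
    templates: list[tuple[str, ...]] = []
    seen: set[tuple[str, ...]] = set()
    while len(templates) < config.n_templates:
        length = int(rng.integers(lo, hi + 1))
        tpl = tuple(rng.choice(pool, size=length, replace=False))
        if tpl not in seen:  # distinct templates; words may repeat across them
            seen.add(tpl)
            templates.append(tpl)
    return templates


def _template_membership(templates: list[tuple[str, ...]]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for tpl in templates:
        for w in set(tpl):
            counts[w] = counts.get(w, 0) + 1
    return counts


def generate_corpus(
    config: SyntheticConfig, register: Register, seed: int
) -> tuple[Corpus, GroundTruth]:
    """Generate one register's corpus plus its ground truth."""
    if register not in ("cds_like", "ads_like"):
        raise ValueError(f"unknown register {register!r}")
    rng = np.random.default_rng(seed)
    templates = _make_templates(config)
    membership = _template_membership(templates)

    n_fillers = config.vocab_size - config.template_pool_size
    fillers = [f"f{i:03d}" for i in range(n_fillers)]
    weights = np.arange(1, n_fillers + 1, dtype=float) ** (-config.zipf_exponent)
    weights /= weights.sum()

    lo, hi = (
        config.utt_length_range_cds
        if register == "cds_like"
        else config.utt_length_range_ads
    )

    freq: dict[str, int] = {}
    utterances: list[Utterance] = []
    for lineno in range(config.n_utterances):
        length = int(rng.integers(lo, hi + 1))
        toks: list[str]
        if rng.random() < config.template_use_prob:
            tpl = templates[int(rng.integers(len(templates)))]
            pad = max(length - len(tpl), 0)
            left = int(rng.integers(pad + 1))
            toks = (
                list(rng.choice(fillers, size=left, p=weights))
                + list(tpl)
                + list(rng.choice(fillers, size=pad - left, p=weights))
            )
        else:
            toks = list(rng.choice(fillers, size=length, p=weights))
        for t in toks:
            freq[t] = freq.get(t, 0) + 1
        utterances.append(Utterance(tokens=tuple(toks), source_line=lineno + 1))

    corpus = Corpus(utterances=utterances, label=register)
    truth = GroundTruth(
        templates=templates,
        true_n_templates={w: membership.get(w, 0) for w in freq},
        true_freq=freq,
        beta_freq=config.beta_freq,
        beta_mwu=config.beta_mwu,
    )
    return corpus, truth


def _facilitation_scores(
    config: SyntheticConfig, truth: GroundTruth, rng: np.random.Generator
) -> tuple[list[str], np.ndarray]:
    """Latent per-word facilitation: beta_freq*log1p(freq) + beta_mwu*n_templates + noise."""
    words = truth.vocabulary()
    freq = np.array([truth.true_freq[w] for w in words], dtype=float)
    ntpl = np.array([truth.true_n_templates[w] for w in words], dtype=float)
    noise = rng.normal(0.0, config.noise_sd, size=len(words))
    # infinitesimal jitter breaks ties deterministically when betas and noise are 0
    jitter = rng.uniform(0, 1e-9, size=len(words))
    scores = config.beta_freq * np.log1p(freq) + config.beta_mwu * ntpl + noise + jitter
    return words, scores


def generate_transcripts(
    config: SyntheticConfig, truth: GroundTruth, seed: int
) -> TranscriptSet:
    """Developmental transcript set consistent with the planted effects.

    Words with higher facilitation scores are introduced in lower-MLU
    transcripts; within a transcript, tokens are drawn
    frequency-weighted from the words introduced so far.  Per-transcript
    utterance counts are lognormal-skewed, mimicking the uneven
    per-child data volumes of real acquisition corpora.
    """
    rng = np.random.default_rng(seed)
    words, scores = _facilitation_scores(config, truth, rng)
    n_words = len(words)
    t_count = config.n_transcripts
    # percentile rank of the score, reversed: best words enter transcript 0
    order = np.argsort(-scores)
    intro = np.empty(n_words, dtype=int)
    intro[order] = (np.arange(n_words) * t_count) // n_words

    freq_w = np.array([truth.true_freq[w] for w in words], dtype=float)
    mlu_lo, mlu_hi = config.mlu_range
    transcripts: list[Transcript] = []
    for t in range(t_count):
        target_mlu = mlu_lo + (mlu_hi - mlu_lo) * t / max(t_count - 1, 1)
        available = np.flatnonzero(intro <= t)
        probs = freq_w[available] / freq_w[available].sum()
        n_utt = int(
            np.clip(
                rng.lognormal(math.log(config.utterances_per_transcript_median), 0.6),
                5,
                400,
            )
        )
        utts = []
        for k in range(n_utt):
            length = 1 + rng.poisson(max(target_mlu - 1.0, 0.0))
            idx = rng.choice(available, size=length, p=probs)
            utts.append(
                Utterance(tokens=tuple(words[i] for i in idx), source_line=k + 1)
            )
        transcripts.append(
            Transcript(
                child_id=f"child{t:03d}",
                child_utterances=utts,
                child_age_months=12.0 + 48.0 * t / max(t_count - 1, 1),
                transcript_ref=f"transcript_{t:03d}.txt",
            )
        )
    return TranscriptSet(transcripts=transcripts)


def generate_rt_table(
    config: SyntheticConfig, truth: GroundTruth, seed: int
) -> dict[str, float]:
    """Per-word lexical-decision RTs with planted frequency and template effects."""
    rng = np.random.default_rng(seed)
    words = truth.vocabulary()
    freq = np.array([truth.true_freq[w] for w in words], dtype=float)
    ntpl = np.array([truth.true_n_templates[w] for w in words], dtype=float)
    a = config.beta_freq * config.rt_ms_per_unit
    b = config.beta_mwu * config.rt_ms_per_unit
    noise = rng.normal(0.0, config.noise_sd * config.rt_ms_per_unit, size=len(words))
    rt = config.rt_baseline_ms - a * np.log1p(freq) - b * ntpl + noise
    rt = np.maximum(rt, 200.0)
    return {w: float(r) for w, r in zip(words, rt)}
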