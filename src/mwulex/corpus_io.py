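"""Reading and writing utterance corpora, transcript sets and word tables.

File formats are deliberately minimal and text-based:

* **Corpus** — UTF-8 plain text, one utterance per line, tokens separated
  by whitespace.  Blank lines are skipped (and counted), not errors.
* **TranscriptSet** — a directory of per-transcript ``.txt`` corpus files
  plus a manifest TSV with columns ``file``, ``child_id``, ``age_months``
  (``age_months`` may be empty; MLU estimation does not need it).
* **RT table** — TSV with header ``word<TAB>rt``, reaction times in
  milliseconds.

No punctuation stripping, stemming, lemmatization or tagging is ever
performed: tokens are raw word forms, and transcribed-speech inputs are
assumed pre-cleaned.  The only normalisation offered is optional case
folding (on by default), so that sentence-case and lower-case renderings
of the same word form count as one type.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

__all__ = [
    "Utterance",
    "Corpus",
    "Transcript",
    "TranscriptSet",
    "tokenize_line",
    "read_corpus",
    "write_corpus",
    "read_transcripts",
    "read_rt_table",
    "read_word_measures",
    "write_word_measures",
]


class EmptyUtteranceError(ValueError):
    """Raised when a line contains no tokens."""


@dataclass(frozen=True)
class Utterance:
    """An ordered sequence of word-form tokens; the unit of incremental processing."""

    tokens: tuple[str, ...]
    source_line: int = 0

    def __post_init__(self) -> None:
        if len(self.tokens) == 0:
            raise EmptyUtteranceError("utterance must contain at least one token")
        for t in self.tokens:
            if not t or any(c.isspace() for c in t):
                raise ValueError(f"invalid token {t!r}: empty or contains whitespace")

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self) -> Iterator[str]:
        return iter(self.tokens)


@dataclass
class Corpus:
    """An ordered collection of utterances.

    Order matters: the chunker processes utterances incrementally, so two
    corpora with the same utterances in different orders are different
    inputs.
    """

    utterances: list[Utterance]
    label: str = ""
    skipped_blank_lines: int = 0

    def __len__(self) -> int:
        return len(self.utterances)

    def __iter__(self) -> Iterator[Utterance]:
        return iter(self.utterances)

    @property
    def n_tokens(self) -> int:
        return sum(len(u) for u in self.utterances)

    def vocabulary(self) -> set[str]:
        return {t for u in self.utterances for t in u.tokens}


@dataclass
class Transcript:
    """Child utterances from one recording session, used for MLU/AoFP.

    ``child_age_months`` is optional metadata; the MLU estimate depends
    only on the utterance lengths.
    """

    child_id: str
    child_utterances: list[Utterance]
    child_age_months: float | None = None
    transcript_ref: str = ""

    @property
    def n_utterances(self) -> int:
        return len(self.child_utterances)

    @property
    def n_tokens(self) -> int:
        return sum(len(u) for u in self.child_utterances)

    def utterance_lengths(self) -> list[int]:
        return [len(u) for u in self.child_utterances]

    def vocabulary(self) -> set[str]:
        return {t for u in self.child_utterances for t in u.tokens}


@dataclass
class TranscriptSet:
    """A collection of transcripts; child_ids may repeat (longitudinal data)."""

    transcripts: list[Transcript] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[Transcript]:
        return iter(self.transcripts)


def tokenize_line(line: str, lowercase: bool = True, source_line: int = 0) -> Utterance:
    """Split a line into a whitespace-tokenized :class:`Utterance`.

    Raises :class:`EmptyUtteranceError` on all-whitespace input; callers
    reading files skip such lines and keep a count.
    """
    toks = line.split()
    if not toks:
        raise EmptyUtteranceError("blank line")
    if lowercase:
        toks = [t.lower() for t in toks]
    return Utterance(tokens=tuple(toks), source_line=source_line)


def read_corpus(path: str | Path, lowercase: bool = True, label: str = "") -> Corpus:
    """Read a one-utterance-per-line text file into a :class:`Corpus`."""
    path = Path(path)
    utterances: list[Utterance] = []
    skipped = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            try:
                utterances.append(tokenize_line(line, lowercase=lowercase, source_line=lineno))
            except EmptyUtteranceError:
                skipped += 1
    if skipped:
        logger.info("read_corpus(%s): skipped %d blank line(s)", path, skipped)
    if not utterances:
        logger.warning("read_corpus(%s): corpus is empty", path)
    return Corpus(utterances=utterances, label=label or path.stem, skipped_blank_lines=skipped)


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as one space-joined utterance per line (round-trips with :func:`read_corpus`)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for u in corpus.utterances:
            fh.write(" ".join(u.tokens) + "\n")


def read_transcripts(
    manifest_path: str | Path, lowercase: bool = True
) -> TranscriptSet:
    """Read a transcript set from a manifest TSV.

    The manifest has columns ``file`` (path relative to the manifest),
    ``child_id`` and ``age_months`` (may be empty).  Transcripts with no
    utterances are excluded with a warning.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    transcripts: list[Transcript] = []
    with manifest_path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"file", "child_id", "age_months"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"manifest {manifest_path} must have columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            corpus = read_corpus(base / row["file"], lowercase=lowercase)
            if len(corpus) == 0:
                logger.warning(
                    "read_transcripts: excluding empty transcript %s", row["file"]
                )
                continue
            age_raw = (row.get("age_months") or "").strip()
            age = float(age_raw) if age_raw else None
            transcripts.append(
                Transcript(
                    child_id=row["child_id"],
                    child_utterances=corpus.utterances,
                    child_age_months=age,
                    transcript_ref=row["file"],
                )
            )
    return TranscriptSet(transcripts=transcripts)


def write_transcripts(ts: TranscriptSet, outdir: str | Path) -> Path:
    """Write per-transcript files plus ``manifest.tsv`` under ``outdir``; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.tsv"
    with manifest.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["file", "child_id", "age_months"])
        for i, t in enumerate(ts):
            fname = t.transcript_ref or f"transcript_{i:04d}.txt"
            if not fname.endswith(".txt"):
                fname = f"{fname}.txt"
            write_corpus(Corpus(utterances=t.child_utterances), outdir / fname)
            age = "" if t.child_age_months is None else repr(t.child_age_months)
            writer.writerow([fname, t.child_id, age])
    return manifest


def read_rt_table(path: str | Path, lowercase: bool = True) -> dict[str, float]:
    """Read a two-column TSV (``word``, ``rt``) into a word → RT(ms) mapping.

    Duplicate words, non-numeric and non-positive RTs are fatal.
    """
    path = Path(path)
    rts: dict[str, float] = {}
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or len(header) < 2:
            raise ValueError(f"RT table {path} must have a 'word<TAB>rt' header")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(row)}")
            word = row[0].lower() if lowercase else row[0]
            try:
                rt = float(row[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric RT {row[1]!r}") from exc
            if rt <= 0:
                raise ValueError(f"{path}:{lineno}: RT must be positive, got {rt}")
            if word in rts:
                raise ValueError(f"{path}:{lineno}: duplicate word {word!r}")
            rts[word] = rt
    return rts


def write_rt_table(rts: dict[str, float], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["word", "rt"])
        for word in sorted(rts):
            writer.writerow([word, repr(float(rts[word]))])


# Word-measure tables (per-target-word predictors and responses) are plain
# pandas DataFrames indexed by word; TSV persistence lives here so the rest
# of the package never touches file paths.

MEASURE_COLUMNS = [
    "freq_cds",
    "freq_ads",
    "n_mwus_cds",
    "n_mwus_ads",
    "n_baseline_cds",
    "n_baseline_ads",
    "aofp",
    "rt",
]


def write_word_measures(df, path: str | Path) -> None:
    """Write a word-measure DataFrame (index = word) as TSV."""
    df.to_csv(Path(path), sep="\t", index_label="word")


def read_word_measures(path: str | Path):
    """Read a word-measure TSV back into a DataFrame indexed by word."""
    import pandas as pd

    return pd.read_csv(Path(path), sep="\t", index_col="word")
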