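"""Text cleaning, vocabulary construction, and line segmentation.

The cleaning pipeline normalises raw pathology-report text into whitespace
tokens while retaining natural line structure, which the hierarchical encoder
needs. Cleaning is applied in a fixed order: XML-tag removal, lowercasing,
tab normalisation, abbreviation-period removal (dr./am./pm.), float and
large-integer replacement with sentinel tokens, unicode-to-ASCII
transliteration, collapsing of repeated punctuation, and padding of
non-alphanumeric characters with spaces. Long lines are re-split at two
successively weaker sets of break characters so no line exceeds 50 tokens
unless it contains no break character at all.
"""

from __future__ import annotations

import re
import unicodedata
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

UNKNOWN = "unknowntoken"
FLOAT = "floattoken"
LARGEINT = "largeinttoken"
PADDING = "paddingtoken"
SEPARATOR = "separatortoken"

#: Strong line-break characters for re-splitting over-long lines.
LINEBREAK_SET_1 = {".", ":", ";", "/", "?", "~", "*", "<", "#"}
#: Weaker break tokens: any standalone single letter except "a" (reports use
#: single letters to itemise lists), plus comma, hyphen, underscore, equals.
LINEBREAK_SET_2_PUNCT = {",", "-", "_", "="}

MAX_LINE_TOKENS = 50

_XML_TAG = re.compile(r"<[^>]*>")
_ABBREV = re.compile(r"\b(dr|am|pm)\.")
_FLOAT = re.compile(r"(?<![a-z0-9])(\d+\.\d+)(?![a-z0-9])")
_INT = re.compile(r"(?<![a-z0-9])(\d+)(?![a-z0-9])")
_REPEAT = re.compile(r"([^a-z0-9\s])\1+")
_NONALNUM = re.compile(r"([^a-z0-9\s])")


def _replace_large_int(match: re.Match) -> str:
    return LARGEINT if int(match.group(1)) > 100 else match.group(1)


def clean_lines(raw: str) -> list[list[str]]:
    """Clean raw text into per-line whitespace tokens (line structure kept)."""
    text = _XML_TAG.sub(" ", raw)
    text = text.lower()
    text = text.replace("\r\n", "\n").replace("\r", "\n").replace("\t", " ")
    text = _ABBREV.sub(r"\1", text)
    text = _FLOAT.sub(f" {FLOAT} ", text)
    text = _INT.sub(_replace_large_int, text)
    text = unicodedata.normalize("NFKD", text).encode("ascii", "ignore").decode("ascii")
    text = _REPEAT.sub(r"\1", text)
    text = _NONALNUM.sub(r" \1 ", text)
    return [line.split() for line in text.split("\n") if line.split()]


def clean_text(raw: str) -> list[str]:
    """Clean raw text into a flat token sequence (total on strings)."""
    return [tok for line in clean_lines(raw) for tok in line]


def _is_set2_break(token: str) -> bool:
    if token in LINEBREAK_SET_2_PUNCT:
        return True
    return len(token) == 1 and token.isalpha() and token != "a"


def _split_at(tokens: Sequence[str], is_break) -> list[list[str]]:
    """Split after every break token; break tokens stay with their segment."""
    segments: list[list[str]] = []
    current: list[str] = []
    for tok in tokens:
        current.append(tok)
        if is_break(tok):
            segments.append(current)
            current = []
    if current:
        segments.append(current)
    return segments


def segment_lines(
    lines: Sequence[Sequence[str]], max_tokens: int = MAX_LINE_TOKENS
) -> list[tuple[int, int]]:
    """Line ranges over the flattened token sequence.

    Natural lines longer than ``max_tokens`` are re-split at set-1 break
    characters, then any still-long segment at set-2 breaks. A segment with no
    break character is kept whole. Ranges are contiguous, non-empty, and
    cover the sequence.
    """
    ranges: list[tuple[int, int]] = []
    offset = 0
    for line in lines:
        segments = [list(line)]
        for is_break in (lambda t: t in LINEBREAK_SET_1, _is_set2_break):
            resplit: list[list[str]] = []
            for seg in segments:
                if len(seg) > max_tokens:
                    resplit.extend(_split_at(seg, is_break))
                else:
                    resplit.append(seg)
            segments = resplit
        for seg in segments:
            if seg:
                ranges.append((offset, offset + len(seg)))
                offset += len(seg)
    return ranges


@dataclass
class TokenizedDoc:
    """A document as vocabulary ids with line boundary ranges."""

    token_ids: np.ndarray
    line_ranges: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.token_ids = np.asarray(self.token_ids, dtype=np.int64)

    def __len__(self) -> int:
        return int(self.token_ids.shape[0])


@dataclass
class Vocab:
    """Token-to-id mapping with frequency-based rare-token collapsing.

    Tokens seen fewer than ``min_count`` times corpus-wide map to the unknown
    token. Ids are dense from 0: special tokens first, then corpus tokens in
    (descending count, lexicographic) order, which makes construction
    deterministic.
    """

    token_to_id: dict[str, int]
    min_count: int = 5

    SPECIALS = (PADDING, UNKNOWN, FLOAT, LARGEINT, SEPARATOR)

    def __len__(self) -> int:
        return len(self.token_to_id)

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PADDING]

    @property
    def unknown_id(self) -> int:
        return self.token_to_id[UNKNOWN]

    @property
    def separator_id(self) -> int:
        return self.token_to_id[SEPARATOR]

    def id_of(self, token: str) -> int:
        return self.token_to_id.get(token, self.unknown_id)

    def encode(self, tokens: Iterable[str]) -> np.ndarray:
        unk = self.unknown_id
        return np.array([self.token_to_id.get(t, unk) for t in tokens], dtype=np.int64)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#min_count\t{self.min_count}\n")
            for tok, idx in sorted(self.token_to_id.items(), key=lambda kv: kv[1]):
                fh.write(f"{tok}\t{idx}\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocab":
        mapping: dict[str, int] = {}
        min_count = 5
        with open(path) as fh:
            for line in fh:
                tok, val = line.rstrip("\n").split("\t")
                if tok == "#min_count":
                    min_count = int(val)
                else:
                    mapping[tok] = int(val)
        return cls(token_to_id=mapping, min_count=min_count)


def build_vocab(corpus: Iterable[Sequence[str]], min_count: int = 5) -> Vocab:
    """Build a vocabulary from tokenized documents.

    Tokens with corpus-wide count below ``min_count`` are not given ids (they
    encode to the unknown token).
    """
    counts: Counter[str] = Counter()
    n_docs = 0
    for doc in corpus:
        n_docs += 1
        counts.update(doc)
    if n_docs == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    mapping = {tok: i for i, tok in enumerate(Vocab.SPECIALS)}
    kept = [
        tok
        for tok, cnt in counts.items()
        if cnt >= min_count and tok not in mapping
    ]
    kept.sort(key=lambda t: (-counts[t], t))
    for tok in kept:
        mapping[tok] = len(mapping)
    return Vocab(token_to_id=mapping, min_count=min_count)


def tokenize_document(raw: str, vocab: Vocab) -> TokenizedDoc:
    """Clean, segment, and encode one document."""
    lines = clean_lines(raw)
    ranges = segment_lines(lines)
    flat = [tok for line in lines for tok in line]
    return TokenizedDoc(token_ids=vocab.encode(flat), line_ranges=ranges)
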