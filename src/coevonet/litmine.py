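"""Mutation-mention mining from article text.

Sentences are the co-occurrence unit: a mutation mention and a keyword
count as related only when they appear in the same sentence.  Three
mention dialects are recognised — compact (S127P), three-letter
(Glu422Lys) and phrase ("Trp58 was mutated to Ala") — and mentions are
validated against the alignment (the stated wild-type letter must match
the sequence) before being mapped to family-wide core positions.  An
annotation is accepted only when the same (position, keyword) pair is
supported by at least ``n_mut`` distinct articles (default 2), which
pools mentions made in different homologs at the same core position.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from Bio.Data.IUPACData import protein_letters_3to1

from .errors import KeywordExpressionError, UnknownSequenceError
from .msa import AMINO_ACIDS, CorePositions, Msa
from . import msa as _msa_mod

_THREE_TO_ONE = {k.upper(): v for k, v in protein_letters_3to1.items()
                 if v in AMINO_ACIDS}
_ONE_TO_THREE = {v: k for k, v in protein_letters_3to1.items() if v in AMINO_ACIDS}

_AA1 = f"[{AMINO_ACIDS}]"
_AA3 = "|".join(_THREE_TO_ONE)  # Ala|Arg|...

_COMPACT = re.compile(rf"\b({_AA1})(\d+)({_AA1})\b")
_THREE = re.compile(rf"\b({_AA3})(\d+)({_AA3})\b", re.IGNORECASE)
_VERBS = "mutated|substituted|replaced|changed"
_CONN = "to|by|with|into"
_PHRASE = re.compile(
    rf"\b({_AA3})(\d+)\s+(?:was|were|is|has\s+been)?\s*(?:{_VERBS})\s+"
    rf"(?:{_CONN})\s+(?:an?\s+)?({_AA3})\b",
    re.IGNORECASE,
)

_ABBREVIATIONS = ("e.g.", "i.e.", "et al.", "fig.", "figs.", "ref.", "cf.", "vs.")
_BOUNDARY = re.compile(r"(?<=[.!?])\s+(?=[A-Z])")


@dataclass(frozen=True)
class MutationMention:
    """One mutation mention found in a sentence."""

    wt_aa: str
    position: int
    mut_aa: str
    article_id: str
    sentence: str
    dialect: str  # compact | threeletter | phrase

    @property
    def silent(self) -> bool:
        return self.wt_aa == self.mut_aa


@dataclass(frozen=True)
class Rejection:
    """A mention that failed validation against the alignment."""

    mention: MutationMention
    reason: str  # wt_mismatch | out_of_range | not_core


@dataclass
class AnnotationTable:
    """(core position, keyword) -> supporting article ids, post-filter."""

    mapping: dict[tuple[int, str], frozenset[str]]
    n_mut: int

    def positions_for(self, keyword: str) -> set[int]:
        return {pos for (pos, kw) in self.mapping if kw == keyword}

    def keywords(self) -> set[str]:
        return {kw for (_, kw) in self.mapping}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (pos, kw, len(arts), ",".join(sorted(arts)))
            for (pos, kw), arts in sorted(self.mapping.items())
        ]
        return pd.DataFrame(
            rows, columns=["position", "keyword", "n_articles", "article_ids"]
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path, n_mut: int = 2) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t")
    mapping = {
        (int(r.position), str(r.keyword)): frozenset(str(r.article_ids).split(","))
        for r in df.itertuples()
    }
    return AnnotationTable(mapping, n_mut)


def split_sentences(text: str) -> list[str]:
    """Deterministic sentence split with a short abbreviation guard."""
    if not text.strip():
        return []
    pieces: list[str] = []
    start = 0
    for m in _BOUNDARY.finditer(text):
        head = text[start:m.start()].strip()
        low = text[:m.start()].lower()
        if any(low.endswith(ab) for ab in _ABBREVIATIONS):
            continue
        if head:
            pieces.append(head)
            start = m.end()
    tail = text[start:].strip()
    if tail:
        pieces.append(tail)
    return pieces


def extract_mentions(sentence: str, article_id: str) -> list[MutationMention]:
    """All mutation mentions in one sentence, deduplicated by (wt, pos, mut)."""
    found: dict[tuple[str, int, str], MutationMention] = {}

    def add(wt: str, pos: str, mut: str, dialect: str) -> None:
        key = (wt, int(pos), mut)
        if key not in found:
            found[key] = MutationMention(
                wt, int(pos), mut, article_id, sentence, dialect
            )

    # phrase first so its three-letter halves win the dialect label
    for m in _PHRASE.finditer(sentence):
        wt = _THREE_TO_ONE[m.group(1).upper()]
        mut = _THREE_TO_ONE[m.group(3).upper()]
        add(wt, m.group(2), mut, "phrase")
    for m in _THREE.finditer(sentence):
        wt = _THREE_TO_ONE[m.group(1).upper()]
        mut = _THREE_TO_ONE[m.group(3).upper()]
        add(wt, m.group(2), mut, "threeletter")
    for m in _COMPACT.finditer(sentence):
        add(m.group(1), m.group(2), m.group(3), "compact")
    return list(found.values())


def _stems(expression: str) -> list[str]:
    parts = [p.strip() for p in re.split(r"\bAND\b", expression)]
    if any(not p for p in parts):
        raise KeywordExpressionError(f"malformed keyword expression {expression!r}")
    for p in parts:
        if not re.fullmatch(r"[A-Za-z][A-Za-z-]*", p):
            raise KeywordExpressionError(
                f"keyword stem {p!r} in {expression!r} is not a single word"
            )
    return [p.lower() for p in parts]


def detect_keywords(sentence: str, keyword_exprs: Iterable[str]) -> set[str]:
    """Keyword expressions matched by the sentence.

    Each stem matches case-insensitively as a word prefix ("increase"
    matches "increased"); a conjunction "a AND b" matches only when every
    stem matches.
    """
    matched = set()
    low = sentence.lower()
    for expr in keyword_exprs:
        stems = _stems(expr)
        if all(re.search(rf"\b{re.escape(s)}\w*", low) for s in stems):
            matched.add(expr)
    return matched


def validate_and_map(
    mention: MutationMention,
    msa: Msa,
    core: CorePositions,
    seq_id: str,
) -> int | Rejection:
    """Check the wild-type letter against the sequence and map to a core position."""
    if seq_id not in msa.ids:
        raise UnknownSequenceError(seq_id)
    try:
        col = _msa_mod._column_of_residue(msa, seq_id, mention.position)
    except _msa_mod.ResidueRangeError:
        return Rejection(mention, "out_of_range")
    aa = msa.row(seq_id)[col - 1]
    if aa != mention.wt_aa:
        return Rejection(mention, "wt_mismatch")
    number = core.number_of(col)
    if number is None:
        return Rejection(mention, "not_core")
    return number


def build_annotation_table(
    records: Iterable[tuple[int, str, str]], n_mut: int = 2
) -> AnnotationTable:
    """Group (position, keyword, article_id) records and apply the article filter.

    A (position, keyword) pair is retained only when supported by at
    least ``n_mut`` *distinct* article ids.
    """
    if n_mut < 1:
        raise ValueError("n_mut must be >= 1")
    groups: dict[tuple[int, str], set[str]] = {}
    for pos, keyword, article_id in records:
        groups.setdefault((int(pos), keyword), set()).add(article_id)
    mapping = {
        key: frozenset(arts)
        for key, arts in groups.items()
        if len(arts) >= n_mut
    }
    return AnnotationTable(mapping, n_mut)


def mine_articles(
    articles: Mapping[str, str],
    article_seq: Mapping[str, str],
    msa: Msa,
    core: CorePositions,
    keyword_exprs: Iterable[str],
    n_mut: int = 2,
    include_silent: bool = False,
) -> tuple[AnnotationTable, list[Rejection]]:
    """Full pipeline: article text -> validated, filtered annotation table.

    ``articles`` maps article id to plain text; ``article_seq`` maps each
    article id to the alignment sequence the article is about.
    """
    keyword_exprs = list(keyword_exprs)
    records: list[tuple[int, str, str]] = []
    rejections: list[Rejection] = []
    for article_id in sorted(articles):
        for sentence in split_sentences(articles[article_id]):
            mentions = extract_mentions(sentence, article_id)
            if not mentions:
                continue
            keywords = detect_keywords(sentence, keyword_exprs)
            if not keywords:
                continue
            for mention in mentions:
                if mention.silent and not include_silent:
                    continue
                outcome = validate_and_map(
                    mention, msa, core, article_seq[article_id]
                )
                if isinstance(outcome, Rejection):
                    rejections.append(outcome)
                    continue
                for kw in keywords:
                    records.append((outcome, kw, article_id))
    return build_annotation_table(records, n_mut), rejections


def one_to_three(aa: str) -> str:
    """Three-letter name of a one-letter amino-acid code (e.g. 'W' -> 'Trp')."""
    return _ONE_TO_THREE[aa]
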