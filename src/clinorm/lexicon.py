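"""Concept lexicon data model, file I/O, and indexing.

A :class:`Lexicon` holds :class:`ConceptEntry` records — one per concept
identifier (CUI) — each carrying a set of semantic-type labels and an
ordered list of synonym strings.  Two indices support the normalization
stages: ``term_index`` maps each preprocessed synonym string to the set of
CUIs listing it (the hash-table behind exact matching), and ``type_index``
maps each semantic-type label to the CUIs carrying it (the grouping behind
per-type pattern learning).

The on-disk format is a UTF-8 TSV with header ``cui  term  sty  source``
(``sty`` and ``source`` optional); pipe-delimited MRCONSO-style extracts
are supported through a dialect flag that maps columns by position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from clinorm.preprocess import PreprocessConfig, DEFAULT_CONFIG, preprocess

#: Reserved gold label for mentions with no corresponding concept.
CUI_LESS = "CUI-less"

#: Reserved gold label for test-time mentions whose annotation is absent.
UNKNOWN_GOLD = "<unknown>"

#: Reserved semantic-type label for concepts of unknown type.
UNKNOWN_TYPE = "unknown"


class LexiconParseError(ValueError):
    """Raised for malformed lexicon or mention files; names the line."""


@dataclass
class ConceptEntry:
    """One concept: identifier, semantic types, and synonym terms.

    ``synonyms`` keeps the raw strings in file order; ``preprocessed``
    holds the corresponding canonical forms with duplicates collapsed
    (order of first occurrence, empty forms dropped).
    """

    cui: str
    semantic_types: set[str]
    synonyms: list[str]
    preprocessed: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.semantic_types:
            self.semantic_types = {UNKNOWN_TYPE}
        if not self.preprocessed:
            self.recompute_preprocessed()

    def recompute_preprocessed(self, cfg: PreprocessConfig = DEFAULT_CONFIG) -> None:
        seen: dict[str, None] = {}
        for raw in self.synonyms:
            p = preprocess(raw, cfg)
            if p:
                seen.setdefault(p, None)
        self.preprocessed = list(seen)


class Lexicon:
    """Indexed collection of :class:`ConceptEntry`, keyed by CUI."""

    def __init__(self, entries: Iterable[ConceptEntry] = (),
                 cfg: PreprocessConfig = DEFAULT_CONFIG) -> None:
        self.cfg = cfg
        self.entries: dict[str, ConceptEntry] = {}
        self.term_index: dict[str, set[str]] = {}
        self.type_index: dict[str, list[str]] = {}
        for e in entries:
            self.add_entry(e)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, cui: str) -> bool:
        return cui in self.entries

    def __getitem__(self, cui: str) -> ConceptEntry:
        return self.entries[cui]

    def add_entry(self, entry: ConceptEntry) -> None:
        if entry.cui in self.entries:
            raise ValueError(f"duplicate CUI {entry.cui!r}")
        entry.recompute_preprocessed(self.cfg)
        self.entries[entry.cui] = entry
        for term in entry.preprocessed:
            self.term_index.setdefault(term, set()).add(entry.cui)
        for sty in sorted(entry.semantic_types):
            self.type_index.setdefault(sty, []).append(entry.cui)

    def add_synonym(self, cui: str, raw_term: str,
                    semantic_types: Iterable[str] = ()) -> None:
        """Attach a synonym to ``cui``, creating the entry if absent."""
        if cui not in self.entries:
            self.add_entry(ConceptEntry(cui, set(semantic_types) or {UNKNOWN_TYPE},
                                        [raw_term]))
            return
        entry = self.entries[cui]
        if raw_term in entry.synonyms:
            return
        entry.synonyms.append(raw_term)
        p = preprocess(raw_term, self.cfg)
        if p and p not in entry.preprocessed:
            entry.preprocessed.append(p)
            self.term_index.setdefault(p, set()).add(cui)

    def lookup(self, preprocessed_term: str) -> set[str]:
        """CUIs whose synonym inventory contains the preprocessed term."""
        return set(self.term_index.get(preprocessed_term, ()))

    def cuis_of_type(self, sty: str) -> list[str]:
        return list(self.type_index.get(sty, ()))

    def semantic_types(self) -> list[str]:
        return sorted(self.type_index)

    def copy(self) -> "Lexicon":
        return Lexicon(
            (ConceptEntry(e.cui, set(e.semantic_types), list(e.synonyms))
             for e in self.entries.values()),
            cfg=self.cfg,
        )


@dataclass(frozen=True)
class AnnotatedMention:
    """A mention string with its gold concept annotation.

    ``gold`` is a CUI, :data:`CUI_LESS`, or :data:`UNKNOWN_GOLD` for
    test-time input whose annotation column is absent.  Multi-span mentions
    are expected pre-concatenated in reading order.
    """

    text: str
    gold: str = UNKNOWN_GOLD

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("mention text must be non-empty")

    @property
    def has_gold(self) -> bool:
        return self.gold != UNKNOWN_GOLD


def _split_row(line: str, delim: str) -> list[str]:
    return [c.strip() for c in line.rstrip("\n").split(delim)]


def read_lexicon(path: str | Path, dialect: str = "tsv",
                 cfg: PreprocessConfig = DEFAULT_CONFIG) -> Lexicon:
    """Read a concept lexicon from a delimited file.

    ``dialect="tsv"`` expects a header line naming at least ``cui`` and
    ``term`` (``sty``, ``source`` and ``lang`` optional; rows with a
    ``lang`` column other than ENG are skipped).  ``dialect="mrconso"``
    reads pipe-delimited rows positionally in MRCONSO column order
    (CUI|LAT|...|STR at index 14, semantic type unavailable).
    Duplicate (cui, term) rows collapse; rows missing required fields
    raise :class:`LexiconParseError` naming the line number.
    """
    path = Path(path)
    rows: list[tuple[str, str, str]] = []  # (cui, term, sty)
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise LexiconParseError(f"{path}: empty lexicon file")

    if dialect == "mrconso":
        for i, line in enumerate(lines, start=1):
            if not line.strip():
                continue
            cols = line.split("|")
            if len(cols) < 15:
                raise LexiconParseError(f"{path}:{i}: expected ≥15 pipe-delimited columns")
            cui, lat, term = cols[0], cols[1], cols[14]
            if not cui or not term:
                raise LexiconParseError(f"{path}:{i}: missing cui or term")
            if lat and lat != "ENG":
                continue
            rows.append((cui, term, ""))
    elif dialect == "tsv":
        header = [h.lower() for h in _split_row(lines[0], "\t")]
        if "cui" not in header or "term" not in header:
            raise LexiconParseError(f"{path}:1: header must name 'cui' and 'term' columns")
        icui, iterm = header.index("cui"), header.index("term")
        isty = header.index("sty") if "sty" in header else None
        ilang = header.index("lang") if "lang" in header else None
        for i, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            cols = _split_row(line, "\t")
            if len(cols) <= max(icui, iterm):
                raise LexiconParseError(f"{path}:{i}: row has too few columns")
            cui, term = cols[icui], cols[iterm]
            if not cui:
                raise LexiconParseError(f"{path}:{i}: missing cui")
            if not term:
                raise LexiconParseError(f"{path}:{i}: missing term")
            if ilang is not None and len(cols) > ilang and cols[ilang] not in ("", "ENG"):
                continue
            sty = cols[isty] if isty is not None and len(cols) > isty else ""
            rows.append((cui, term, sty))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if not rows:
        raise LexiconParseError(f"{path}: no data rows")

    by_cui: dict[str, ConceptEntry] = {}
    for cui, term, sty in rows:
        entry = by_cui.get(cui)
        if entry is None:
            entry = ConceptEntry(cui, set(), [])
            entry.semantic_types = set()
            by_cui[cui] = entry
        if term not in entry.synonyms:
            entry.synonyms.append(term)
        if sty:
            entry.semantic_types.add(sty)
    for entry in by_cui.values():
        if not entry.semantic_types:
            entry.semantic_types = {UNKNOWN_TYPE}
    return Lexicon(by_cui.values(), cfg=cfg)


def write_lexicon(lex: Lexicon, path: str | Path) -> None:
    """Write the lexicon as the documented TSV (cui, term, sty, source)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("cui\tterm\tsty\tsource\n")
        for cui in sorted(lex.entries):
            entry = lex.entries[cui]
            sty = ";".join(sorted(entry.semantic_types))
            for term in entry.synonyms:
                fh.write(f"{cui}\t{term}\t{sty}\t\n")


def read_mentions(path: str | Path) -> list[AnnotatedMention]:
    """Read (text, gold) mention rows from a TSV file.

    The header must name ``text``; a ``gold`` column is optional — when it
    is absent or empty the mention's gold is :data:`UNKNOWN_GOLD`, which is
    distinct from the explicit :data:`CUI_LESS` annotation.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise LexiconParseError(f"{path}: empty mentions file")
    header = [h.lower() for h in _split_row(lines[0], "\t")]
    if "text" not in header:
        raise LexiconParseError(f"{path}:1: header must name a 'text' column")
    itext = header.index("text")
    igold = header.index("gold") if "gold" in header else None
    out: list[AnnotatedMention] = []
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cols = _split_row(line, "\t")
        if len(cols) <= itext or not cols[itext]:
            raise LexiconParseError(f"{path}:{i}: empty mention text")
        gold = UNKNOWN_GOLD
        if igold is not None and len(cols) > igold and cols[igold]:
            gold = cols[igold]
        out.append(AnnotatedMention(cols[itext], gold))
    return out


def write_mentions(mentions: Iterable[AnnotatedMention], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("text\tgold\n")
        for m in mentions:
            fh.write(f"{m.text}\t{m.gold}\n")


def augment_with_training(lex: Lexicon,
                          mentions: Iterable[AnnotatedMention]) -> Lexicon:
    """Return a new lexicon with each mention text added as a synonym of
    its gold concept.

    CUI-less and unannotated mentions are skipped.  Gold CUIs absent from
    the lexicon are added as new entries with the reserved unknown semantic
    type.  The input lexicon is not modified.
    """
    out = lex.copy()
    for m in mentions:
        if m.gold in (CUI_LESS, UNKNOWN_GOLD):
            continue
        out.add_synonym(m.gold, m.text)
    return out
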