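"""Subconcept matching: normalizing a term through the concepts inside it.

A term's *subconcept profile* is built by enumerating all contiguous token
subsequences (n-grams, including single words), keeping those that match a
lexicon synonym, suppressing any matched subterm nested inside a longer
matched subterm, and recording each survivor's candidate CUI set.  A
concept's profile is the union of its synonyms' profiles, except that a
multi-token synonym's trivial self-match (its own full span) is excluded —
it is the parts of a concept's name, not the name itself, that carry the
compositional signal.  Working at the CUI level rather than the string
level is what equates "o2" with "oxygen" when both strings share a concept.

A term matches a concept when the two profiles have the same number of
candidate CUI sets and the sets can be paired off one-to-one such that
every paired couple intersects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from clinorm.lexicon import ConceptEntry, Lexicon


@dataclass(frozen=True)
class SubconceptProfile:
    """Matched subterms of a term (or concept) with their CUI sets.

    ``covered_subterms`` pairs each contributing subterm with its
    candidate CUI set; ``profile`` is the collection of those sets, which
    is what profile comparison operates on.  For a query term the
    collection is a multiset (two maximal subterms with identical CUI sets
    stay distinct and must be paired distinctly); a concept profile is a
    union, deduplicated by CUI set at construction.
    """

    covered_subterms: tuple[tuple[str, frozenset[str]], ...]

    @property
    def profile(self) -> tuple[frozenset[str], ...]:
        return tuple(cuis for _, cuis in self.covered_subterms)

    def __len__(self) -> int:
        return len(self.profile)


def _matched_spans(tokens: Sequence[str], lex: Lexicon,
                   max_ngram: int | None = None) -> list[tuple[int, int, str, frozenset[str]]]:
    """All (start, end, subterm, cuis) whose subterm is a lexicon synonym."""
    n = len(tokens)
    out = []
    for i in range(n):
        top = n if max_ngram is None else min(n, i + max_ngram)
        for j in range(i + 1, top + 1):
            sub = " ".join(tokens[i:j])
            cuis = lex.term_index.get(sub)
            if cuis:
                out.append((i, j, sub, frozenset(cuis)))
    return out


def _maximal(spans: list[tuple[int, int, str, frozenset[str]]]
             ) -> list[tuple[str, frozenset[str]]]:
    """Drop spans strictly contained in another matched span."""
    keep = []
    for i0, j0, sub, cuis in spans:
        contained = any((i1 <= i0 and j0 <= j1) and (i1, j1) != (i0, j0)
                        for i1, j1, _, _ in spans)
        if not contained:
            keep.append((sub, cuis))
    return keep


def term_profile(term: str, lex: Lexicon,
                 max_ngram: int | None = None) -> SubconceptProfile:
    """Profile of a (preprocessed) query term.

    Subterms with no lexicon match are ignored; of the matched subterms
    only the maximal ones contribute.
    """
    spans = _matched_spans(term.split(), lex, max_ngram)
    return SubconceptProfile(tuple(_maximal(spans)))


def concept_profile(entry: ConceptEntry, lex: Lexicon,
                    max_ngram: int | None = None) -> SubconceptProfile:
    """Profile of a concept: union over its synonyms' profiles.

    A multi-token synonym's full-span self-match is excluded before the
    maximal-span suppression, so "oxygen administration by nasal cannula"
    contributes the profiles of "oxygen" and "nasal", not a self-reference.
    A single-token synonym keeps its own match (it has no parts).  The
    union deduplicates by CUI set: two subterms carrying the same
    candidate set contribute one subconcept.
    """
    covered: list[tuple[str, frozenset[str]]] = []
    seen: set[frozenset[str]] = set()
    for syn in entry.preprocessed:
        tokens = syn.split()
        spans = _matched_spans(tokens, lex, max_ngram)
        if len(tokens) > 1:
            spans = [s for s in spans if not (s[0] == 0 and s[1] == len(tokens))]
        for sub, cuis in _maximal(spans):
            if cuis not in seen:
                seen.add(cuis)
                covered.append((sub, cuis))
    return SubconceptProfile(tuple(covered))


def _perfect_pairing(left: Sequence[frozenset[str]],
                     right: Sequence[frozenset[str]]) -> bool:
    """Can the two collections be paired one-to-one with every paired
    couple intersecting?  Backtracking bipartite matching; profiles are
    tiny (a handful of sets), so no need for anything heavier."""
    if len(left) != len(right):
        return False
    used = [False] * len(right)

    def place(i: int) -> bool:
        if i == len(left):
            return True
        for j, r in enumerate(right):
            if not used[j] and left[i] & r:
                used[j] = True
                if place(i + 1):
                    return True
                used[j] = False
        return False

    return place(0)


class SubconceptIndex:
    """Precomputed concept profiles with a CUI-level inverted index.

    Only concepts sharing at least one candidate CUI with the query
    profile are tested, so a lookup touches a small candidate pool rather
    than the whole lexicon.
    """

    def __init__(self, lex: Lexicon, max_ngram: int | None = None) -> None:
        self.lex = lex
        self.max_ngram = max_ngram
        self.profiles: dict[str, SubconceptProfile] = {}
        self.by_cui: dict[str, set[str]] = {}  # candidate CUI -> concepts
        for cui, entry in lex.entries.items():
            prof = concept_profile(entry, lex, max_ngram)
            if len(prof) == 0:
                continue
            self.profiles[cui] = prof
            for cuiset in prof.profile:
                for c in cuiset:
                    self.by_cui.setdefault(c, set()).add(cui)

    def match(self, term: str) -> set[str]:
        qprof = term_profile(term, self.lex, self.max_ngram)
        q = qprof.profile
        if not q:
            return set()
        candidates: set[str] = set()
        for cuiset in q:
            for c in cuiset:
                candidates |= self.by_cui.get(c, set())
        return {cui for cui in candidates
                if _perfect_pairing(q, self.profiles[cui].profile)}


def subconcept_match(term: str, lex: Lexicon,
                     index: SubconceptIndex | None = None,
                     max_ngram: int | None = None) -> set[str]:
    """CUIs of concepts whose subconcept profile matches the term's.

    Builds a :class:`SubconceptIndex` on the fly unless one is supplied;
    callers doing repeated lookups should build the index once.
    """
    if index is None:
        index = SubconceptIndex(lex, max_ngram)
    return index.match(term)
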