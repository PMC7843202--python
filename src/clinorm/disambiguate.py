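"""Semantic-type disambiguation of multi-candidate normalizations.

When a stage returns several candidate concepts, the correct one is often
the one of a particular semantic type given the combination of types in
play.  :func:`learn_rules` mines such combination→winner rules from
training mentions whose candidate sets are ambiguous: a rule is emitted
for a type combination only when, in every covered training mention, one
single winning type selects the gold concept.  :func:`disambiguate`
applies the rules; when none matches, the first candidate in canonical
(lexicographic CUI) order is returned, which makes the documented
"effectively random" default reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from clinorm.lexicon import CUI_LESS, AnnotatedMention, Lexicon


@dataclass(frozen=True)
class DisambiguationRule:
    """A set of semantic types mapped to the winning type among them."""

    type_combination: frozenset[str]
    winner: str
    support: int = 1

    def __post_init__(self) -> None:
        if self.winner not in self.type_combination:
            raise ValueError("winner must belong to the type combination")


def _combination(candidates: Iterable[str], lex: Lexicon) -> frozenset[str]:
    types: set[str] = set()
    for cui in candidates:
        types |= lex.entries[cui].semantic_types
    return frozenset(types)


def _apply_rule(candidates: Sequence[str], winner: str, lex: Lexicon) -> str:
    bearing = sorted(c for c in candidates
                     if winner in lex.entries[c].semantic_types)
    return bearing[0] if bearing else sorted(candidates)[0]


def learn_rules(mentions: Sequence[AnnotatedMention],
                candidate_outputs: Sequence[Iterable[str]],
                lex: Lexicon, min_support: int = 1) -> list[DisambiguationRule]:
    """Mine type-combination rules from ambiguous training mentions.

    ``candidate_outputs[i]`` is the candidate CUI set the normalizer
    produced for ``mentions[i]``.  Mentions with fewer than two candidates,
    CUI-less gold, or gold outside the candidate set are skipped.  For each
    type combination, a rule is emitted only if a single winning type both
    belongs to every covered gold's type set and, applied as a rule,
    selects the gold in every covered mention.
    """
    if len(mentions) != len(candidate_outputs):
        raise ValueError("mentions and candidate outputs must align")
    groups: dict[frozenset[str], list[tuple[list[str], str]]] = {}
    for m, cands in zip(mentions, candidate_outputs):
        cands = sorted(set(cands))
        if len(cands) < 2 or m.gold == CUI_LESS or m.gold not in cands:
            continue
        groups.setdefault(_combination(cands, lex), []).append((cands, m.gold))

    rules: list[DisambiguationRule] = []
    for combo, cases in groups.items():
        if len(cases) < min_support:
            continue
        shared = set.intersection(
            *(set(lex.entries[gold].semantic_types) for _, gold in cases))
        for winner in sorted(shared & combo):
            if all(_apply_rule(cands, winner, lex) == gold
                   for cands, gold in cases):
                rules.append(DisambiguationRule(combo, winner, len(cases)))
                break
    rules.sort(key=lambda r: (sorted(r.type_combination), r.winner))
    return rules


def disambiguate(candidates: Iterable[str],
                 rules: Sequence[DisambiguationRule],
                 lex: Lexicon) -> str:
    """Select a single CUI from a non-empty candidate set.

    A singleton is returned as-is.  Otherwise, if the candidates' combined
    semantic-type set equals some rule's combination, the lexicographically
    first candidate bearing the winning type is returned; with no matching
    rule the lexicographically first candidate wins.
    """
    cands = sorted(set(candidates))
    if not cands:
        raise ValueError("cannot disambiguate an empty candidate set")
    if len(cands) == 1:
        return cands[0]
    combo = _combination(cands, lex)
    for rule in rules:
        if rule.type_combination == combo:
            return _apply_rule(cands, rule.winner, lex)
    return cands[0]


def write_rules(rules: Iterable[DisambiguationRule], path: str | Path) -> None:
    """Serialize rules as TSV: sorted type combination, winner, support."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("types\twinner\tsupport\n")
        for r in rules:
            fh.write(f"{';'.join(sorted(r.type_combination))}\t{r.winner}\t{r.support}\n")


def read_rules(path: str | Path) -> list[DisambiguationRule]:
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        types, winner, support = line.split("\t")
        out.append(DisambiguationRule(frozenset(types.split(";")), winner,
                                      int(support)))
    return out
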