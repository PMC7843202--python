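"""Learning scored, generalized edit patterns from a lexicon's synonymy.

The learner enumerates edit patterns from every ordered pair of distinct
synonyms within each concept, closes the set under pairwise generalization,
and scores each candidate by applying it back to the in-scope synonym
inventory: a rewrite landing on a synonym of the same concept counts as a
positive, one landing on a different concept's term as a negative, and a
rewrite matching nothing counts as neither.  Candidates scoring above a
high threshold (default 0.9 on p/(p+n+1)) are retained.

Two learning regimes mirror how a practitioner would use a terminology plus
an annotated corpus: :func:`learn_by_semantic_type` learns separately
within each semantic type (sampling at most ``max_concepts_per_type``
concepts per type), and :func:`learn_from_training` folds annotated
mentions into the lexicon as extra synonyms and learns over the annotated
concepts plus a sample of random distractor concepts, without a per-type
split.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from clinorm.edit import (
    CHAR,
    WORD,
    EditPattern,
    apply_pattern,
    extract_edit_pattern,
    generalize,
    parse_pattern,
)
from clinorm.lexicon import AnnotatedMention, ConceptEntry, Lexicon, augment_with_training

PROVENANCE_TRAINING = "training"


@dataclass(frozen=True)
class LearnConfig:
    """Knobs of the pattern learner.

    score_threshold : float in (0, 1)
        Minimum retained score; patterns must score strictly above it.
    max_concepts_per_type : int
        Cap on concepts sampled per semantic type.
    extra_random_concepts : int
        Distractor concepts added when learning from training mentions.
    unit_levels : tuple
        Which unit granularities to learn ("char", "word", or both).
    random_seed : int
        Seed for the concept-sampling RNG; recorded in the PatternSet.
    """

    score_threshold: float = 0.9
    max_concepts_per_type: int = 5000
    extra_random_concepts: int = 3000
    unit_levels: tuple[str, ...] = (CHAR, WORD)
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.score_threshold < 1.0):
            raise ValueError("score_threshold must lie in (0, 1)")
        if self.max_concepts_per_type <= 0 or self.extra_random_concepts < 0:
            raise ValueError("concept caps must be positive")
        for lvl in self.unit_levels:
            if lvl not in (CHAR, WORD):
                raise ValueError(f"unknown unit level {lvl!r}")


@dataclass
class PatternSet:
    """Retained patterns plus the configuration that produced them."""

    patterns: list[EditPattern] = field(default_factory=list)
    config: LearnConfig = field(default_factory=LearnConfig)

    def __len__(self) -> int:
        return len(self.patterns)

    def __iter__(self):
        return iter(self.patterns)

    def sorted_by_score(self) -> list[EditPattern]:
        return sorted(self.patterns,
                      key=lambda p: (-p.score, p.render(), p.unit_level))

    def merged_with(self, other: "PatternSet") -> "PatternSet":
        """Union with deduplication, keeping the higher-score copy."""
        best: dict[tuple, EditPattern] = {}
        for p in list(self.patterns) + list(other.patterns):
            k = p.key()
            if k not in best or p.score > best[k].score:
                best[k] = p
        return PatternSet(list(best.values()), self.config)

    def write(self, path: str | Path) -> None:
        """One pattern per line: level, provenance, p, n, score, rendering."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("unit\tprovenance\tp\tn\tscore\tpattern\n")
            for p in self.sorted_by_score():
                fh.write(f"{p.unit_level}\t{p.provenance}\t{p.positives}\t"
                         f"{p.negatives}\t{p.score:.6f}\t{p.render()}\n")

    @classmethod
    def read(cls, path: str | Path,
             config: LearnConfig | None = None) -> "PatternSet":
        patterns = []
        with open(path, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
        for line in lines[1:]:
            if not line.strip():
                continue
            unit, prov, p, n, _score, text = line.split("\t")
            patterns.append(parse_pattern(text, unit, prov, int(p), int(n)))
        return cls(patterns, config or LearnConfig())


def seed_patterns(concepts: Iterable[ConceptEntry],
                  unit_level: str) -> list[EditPattern]:
    """Fully anchored patterns from every ordered pair of distinct
    preprocessed synonyms within each concept.

    Both directions of every pair are used, so the seed set is closed
    under pattern reversal.  Duplicates (across concepts) collapse.
    """
    seen: dict[tuple, EditPattern] = {}
    for entry in concepts:
        terms = entry.preprocessed
        for a in terms:
            for b in terms:
                if a == b:
                    continue
                pat = extract_edit_pattern(a, b, unit_level)
                seen.setdefault(pat.key(), pat)
    return list(seen.values())


def generalize_patterns(seeds: Sequence[EditPattern]) -> list[EditPattern]:
    """Closure of pairwise generalization, to a fixed point.

    Candidates are grouped by their compatibility signature (edit ops and
    inner SAME context); only same-group pairs can generalize.  Within a
    group a worklist generalizes each new pattern against all known ones,
    deduplicating on canonical form.  Termination is guaranteed because
    every generalization is a sub-run of its arguments and a pattern has
    finitely many sub-runs.  The output contains the seeds plus every
    distinct generalization produced.
    """
    groups: dict[tuple, list[EditPattern]] = {}
    for s in seeds:
        groups.setdefault(s.signature(), []).append(s)

    out: dict[tuple, EditPattern] = {}
    for members in groups.values():
        known: dict[tuple, EditPattern] = {}
        agenda = list(members)
        while agenda:
            p = agenda.pop()
            k = p.key()
            if k in known:
                continue
            for q in list(known.values()):
                g = generalize(p, q)
                if g is not None and g.key() not in known:
                    agenda.append(g)
            known[k] = p
        out.update(known)
    return list(out.values())


def score_patterns(candidates: Sequence[EditPattern], lex: Lexicon,
                   scope: Sequence[str]) -> list[EditPattern]:
    """Attach positive/negative counts to each candidate.

    For every in-scope concept, every preprocessed synonym t, and every
    rewrite r of t by candidate P: if r is a synonym of the same concept,
    P's positives increment; if r is a term of some other concept only,
    its negatives increment; a rewrite matching no lexicon term counts as
    neither.  The score is p/(p+n+1).
    """
    scope_entries = [lex.entries[c] for c in scope]
    scored: list[EditPattern] = []
    for P in candidates:
        src = P.source_units()
        needle = "".join(src) if P.unit_level == CHAR else None
        p_count = n_count = 0
        for entry in scope_entries:
            own = set(entry.preprocessed)
            for t in entry.preprocessed:
                if needle is not None and needle and needle not in t:
                    continue  # cheap substring prefilter
                for r in apply_pattern(P, t):
                    if r in own:
                        p_count += 1
                    elif r in lex.term_index:
                        n_count += 1
        scored.append(replace(P, positives=p_count, negatives=n_count))
    return scored


def _learn_over_scope(lex: Lexicon, scope: list[str], cfg: LearnConfig,
                      provenance: str) -> list[EditPattern]:
    entries = [lex.entries[c] for c in scope]
    retained: list[EditPattern] = []
    for level in cfg.unit_levels:
        seeds = seed_patterns(entries, level)
        candidates = generalize_patterns(seeds)
        for P in score_patterns(candidates, lex, scope):
            if P.score > cfg.score_threshold:
                retained.append(replace(P, provenance=provenance))
    return retained


def _sample(cuis: list[str], k: int, rng: random.Random) -> list[str]:
    cuis = sorted(cuis)
    if len(cuis) <= k:
        return cuis
    return sorted(rng.sample(cuis, k))


def learn_by_semantic_type(lex: Lexicon, cfg: LearnConfig | None = None) -> PatternSet:
    """Learn patterns separately within each semantic type of the lexicon.

    Per type: sample up to ``max_concepts_per_type`` concepts (seeded RNG),
    seed, generalize, and score with the sampled concepts as scope, then
    retain patterns above the threshold, tagged with the type as
    provenance.  The per-type results are unioned with deduplication
    keeping the higher-score copy.
    """
    cfg = cfg or LearnConfig()
    rng = random.Random(cfg.random_seed)
    result = PatternSet([], cfg)
    for sty in lex.semantic_types():
        scope = _sample(lex.cuis_of_type(sty), cfg.max_concepts_per_type, rng)
        patterns = _learn_over_scope(lex, scope, cfg, provenance=sty)
        result = result.merged_with(PatternSet(patterns, cfg))
    return result


def learn_from_training(lex: Lexicon, mentions: Sequence[AnnotatedMention],
                        cfg: LearnConfig | None = None) -> PatternSet:
    """Learn patterns from annotated mentions folded into the lexicon.

    Mention texts become extra synonyms of their gold concepts; the
    learning scope is those concepts plus ``extra_random_concepts``
    randomly sampled others that drive generalization and supply negative
    evidence.  No per-type split is made; provenance is "training".
    """
    cfg = cfg or LearnConfig()
    rng = random.Random(cfg.random_seed)
    augmented = augment_with_training(lex, mentions)
    annotated = sorted({m.gold for m in mentions
                        if m.gold in augmented.entries})
    rest = sorted(set(augmented.entries) - set(annotated))
    scope = annotated + _sample(rest, cfg.extra_random_concepts, rng)
    patterns = _learn_over_scope(augmented, scope, cfg,
                                 provenance=PROVENANCE_TRAINING)
    return PatternSet(patterns, cfg)
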