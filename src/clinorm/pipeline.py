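"""The normalization pipeline: exact → edit patterns → subconcepts → CUI-less.

:class:`Normalizer` bundles the resources (lexicon, training-mention
index, learned pattern set, disambiguation rules) and runs the staged
normalization: the first stage returning at least one candidate fixes the
candidate set, and disambiguation selects the single output CUI.
:meth:`Normalizer.evaluate` scores annotated mentions as the percentage
normalized correctly — to the right CUI or correctly to CUI-less — with
ablation switches for each stage and resource, and an oracle mode that
counts a mention correct whenever the gold is anywhere in the candidate
set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from clinorm.disambiguate import DisambiguationRule, disambiguate, learn_rules
from clinorm.edit import EditPattern, apply_pattern
from clinorm.learn import PatternSet
from clinorm.lexicon import (
    CUI_LESS,
    UNKNOWN_GOLD,
    AnnotatedMention,
    Lexicon,
)
from clinorm.preprocess import preprocess
from clinorm.subconcept import SubconceptIndex

STAGE_EXACT = "exact"
STAGE_PATTERN = "pattern"
STAGE_SUBCONCEPT = "subconcept"
STAGE_NONE = "none"


@dataclass(frozen=True)
class NormalizationResult:
    """Outcome of normalizing one term.

    ``stage`` names the first stage that produced candidates ("exact",
    "pattern", "subconcept") or "none" when the output is CUI-less with an
    empty candidate set.  ``candidates`` is the pre-disambiguation CUI
    set; ``matched_patterns`` lists the edit patterns that fired (empty
    outside the pattern stage).
    """

    input_term: str
    output: str
    stage: str
    candidates: frozenset[str]
    matched_patterns: tuple[EditPattern, ...] = ()


def build_training_index(mentions: Iterable[AnnotatedMention]) -> dict[str, set[str]]:
    """Preprocessed mention text → gold CUIs (CUI-less and unannotated
    mentions excluded)."""
    index: dict[str, set[str]] = {}
    for m in mentions:
        if m.gold in (CUI_LESS, UNKNOWN_GOLD):
            continue
        key = preprocess(m.text)
        if key:
            index.setdefault(key, set()).add(m.gold)
    return index


def exact_match(term: str, lex: Lexicon,
                train_index: Mapping[str, set[str]] | None = None) -> set[str]:
    """Union of training-index and lexicon hits for the exact
    preprocessed string (term must already be preprocessed)."""
    out = set(lex.term_index.get(term, ()))
    if train_index:
        out |= set(train_index.get(term, ()))
    return out


def pattern_match(term: str, patterns: PatternSet | Sequence[EditPattern],
                  lex: Lexicon) -> tuple[set[str], list[EditPattern]]:
    """Apply every pattern to the term; rewrites that exact-match a
    lexicon synonym contribute that concept's CUIs.  Patterns of all
    provenances (semantic types and training) are applied; the candidate
    set is the union over all firing patterns."""
    ordered = (patterns.sorted_by_score() if isinstance(patterns, PatternSet)
               else list(patterns))
    cuis: set[str] = set()
    fired: list[EditPattern] = []
    for P in ordered:
        hit = False
        for rewrite in apply_pattern(P, term):
            found = lex.term_index.get(rewrite)
            if found:
                cuis |= found
                hit = True
        if hit:
            fired.append(P)
    return cuis, fired


@dataclass
class EvaluationReport:
    """Accuracy (percent) with per-stage bookkeeping."""

    total: int
    correct: int
    by_stage_total: dict[str, int] = field(default_factory=dict)
    by_stage_correct: dict[str, int] = field(default_factory=dict)
    oracle: bool = False

    @property
    def accuracy(self) -> float:
        return 100.0 * self.correct / self.total if self.total else 0.0

    def summary(self) -> str:
        lines = [f"accuracy: {self.accuracy:.2f}% "
                 f"({self.correct}/{self.total})"
                 + (" [oracle]" if self.oracle else "")]
        for stage in (STAGE_EXACT, STAGE_PATTERN, STAGE_SUBCONCEPT, STAGE_NONE):
            if stage in self.by_stage_total:
                t = self.by_stage_total[stage]
                c = self.by_stage_correct.get(stage, 0)
                lines.append(f"  {stage:<10} {c}/{t}")
        return "\n".join(lines)


class Normalizer:
    """Staged clinical term normalizer.

    Parameters
    ----------
    lexicon : Lexicon
        The concept synonym inventory.
    training_mentions : sequence of AnnotatedMention, optional
        Annotated mentions; used for the exact-match training index.
    patterns : PatternSet, optional
        Learned edit patterns for the rewrite stage.
    rules : sequence of DisambiguationRule, optional
        Semantic-type disambiguation rules.
    use_training, use_patterns, use_subconcept, use_disambiguation : bool
        Ablation switches mirroring the component analyses: disable the
        training index, the pattern stage, the subconcept stage, or rule
        application (falling back to the canonical first candidate).
    """

    def __init__(self, lexicon: Lexicon,
                 training_mentions: Sequence[AnnotatedMention] = (),
                 patterns: PatternSet | None = None,
                 rules: Sequence[DisambiguationRule] = (),
                 *, use_training: bool = True, use_patterns: bool = True,
                 use_subconcept: bool = True,
                 use_disambiguation: bool = True) -> None:
        self.lexicon = lexicon
        self.patterns = patterns or PatternSet()
        self.rules = list(rules)
        self.use_training = use_training
        self.use_patterns = use_patterns
        self.use_subconcept = use_subconcept
        self.use_disambiguation = use_disambiguation
        self.train_index = (build_training_index(training_mentions)
                            if training_mentions else {})
        self._subconcept_index: SubconceptIndex | None = None

    @property
    def subconcept_index(self) -> SubconceptIndex:
        if self._subconcept_index is None:
            self._subconcept_index = SubconceptIndex(self.lexicon)
        return self._subconcept_index

    def candidates(self, term: str) -> tuple[set[str], str, list[EditPattern]]:
        """Run the stages in order; the first non-empty candidate set wins."""
        pre = preprocess(term)
        fired: list[EditPattern] = []
        cands = exact_match(pre, self.lexicon,
                            self.train_index if self.use_training else None)
        if cands:
            return cands, STAGE_EXACT, fired
        if self.use_patterns and len(self.patterns):
            cands, fired = pattern_match(pre, self.patterns, self.lexicon)
            if cands:
                return cands, STAGE_PATTERN, fired
        if self.use_subconcept and pre:
            cands = self.subconcept_index.match(pre)
            if cands:
                return cands, STAGE_SUBCONCEPT, []
        return set(), STAGE_NONE, []

    def normalize(self, term: str) -> NormalizationResult:
        """Normalize one raw term to a CUI or CUI-less."""
        cands, stage, fired = self.candidates(term)
        if not cands:
            return NormalizationResult(term, CUI_LESS, STAGE_NONE,
                                       frozenset())
        rules = self.rules if self.use_disambiguation else ()
        output = disambiguate(cands, rules, self.lexicon)
        return NormalizationResult(term, output, stage, frozenset(cands),
                                   tuple(fired))

    def learn_disambiguation_rules(
            self, mentions: Sequence[AnnotatedMention],
            min_support: int = 1) -> list[DisambiguationRule]:
        """Mine disambiguation rules from the training mentions' own
        candidate sets and install them on this normalizer."""
        outputs = [self.candidates(m.text)[0] for m in mentions]
        self.rules = learn_rules(mentions, outputs, self.lexicon,
                                 min_support=min_support)
        return self.rules

    def evaluate(self, mentions: Sequence[AnnotatedMention],
                 oracle: bool = False) -> EvaluationReport:
        """Accuracy over annotated mentions.

        A mention is correct when the output equals its gold (CUI or
        CUI-less).  In oracle mode it is correct when the gold is among
        the candidates, or the gold is CUI-less and no stage produced
        candidates.
        """
        report = EvaluationReport(total=0, correct=0, oracle=oracle)
        for m in mentions:
            if not m.has_gold:
                raise ValueError(f"mention {m.text!r} has no gold annotation")
            res = self.normalize(m.text)
            if oracle:
                ok = (m.gold in res.candidates if res.candidates
                      else m.gold == CUI_LESS)
            else:
                ok = res.output == m.gold
            report.total += 1
            report.correct += int(ok)
            report.by_stage_total[res.stage] = \
                report.by_stage_total.get(res.stage, 0) + 1
            if ok:
                report.by_stage_correct[res.stage] = \
                    report.by_stage_correct.get(res.stage, 0) + 1
        return report
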