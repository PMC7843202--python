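"""Synthetic lexicons with planted variation structure.

Real terminology resources (UMLS, SNOMED CT, RxNorm) and annotated corpora
are licensed; this generator emulates the statistical structure every
stage of the normalizer depends on, so that learning and normalization are
testable end to end.  It plants, in separate semantic types:

* systematic synonym variations analogous to real ones — suffix
  pluralization ("kafu"/"kafus"), a spelling variant deleting "u" from
  "our" (the "tumour"/"tumor" family), a word substitution pair (the
  "cardiac"/"heart" family), and a trailing "nos" marker deletion — each
  instantiated in a configurable number of concepts so generalization has
  pairs to work on, plus per-rule holdout concepts that carry only one
  form (their other form becomes a pattern-reachable evaluation mention);
* an ambiguous variation whose rewrites land on *other* concepts more
  often than on synonyms, which the score filter must reject;
* ambiguous exact terms shared by two concepts of different semantic
  types, with annotated training instances from which a disambiguation
  rule is learnable and held-out instances to evaluate it;
* compositional concepts whose only synonym is built from other concepts'
  words, reachable solely through subconcept matching;
* a corpus-specific substitution present only in the training mentions
  (the "o/e" / "on examination" analogue), learnable only from
  training-augmented data;
* distractor concepts and CUI-less mentions over a disjoint alphabet.

Vocabulary is built from pronounceable consonant-vowel syllables, so words
never accidentally contain the planted contexts ("our", "nos") and
cross-concept string collisions cannot arise by chance.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from clinorm.lexicon import (
    CUI_LESS,
    AnnotatedMention,
    ConceptEntry,
    Lexicon,
    write_lexicon,
    write_mentions,
)

CONSONANTS = "bcdfglmnprtv"
VOWELS = "aeiou"
CUILESS_CONSONANTS = "hjkwxz"

CLASS_EXACT = "exact"
CLASS_AMBIG = "ambig"
CLASS_PATTERN = "pattern"
CLASS_SUBCONCEPT = "subconcept"
CLASS_CUILESS = "cuiless"


@dataclass(frozen=True)
class VariationRule:
    """A planted systematic variation, described by the term pairs it
    relates.  ``pairs`` are (base, variant) synonym pairs planted inside
    single concepts; ``holdout_pairs`` are (mention, lexicon term) pairs
    where only the lexicon term was planted, so the mention is reachable
    only by applying a learned pattern."""

    name: str
    semantic_type: str
    pairs: tuple[tuple[str, str], ...]
    holdout_pairs: tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class SynthConfig:
    """Shape of the generated data.

    The defaults are sized so that every planted rule clears the score
    threshold on its own evidence (with n positives at zero the m-estimate
    needs more than nine correct applications to exceed 0.9) while the
    whole generation-learning-evaluation cycle stays fast.
    """

    instances_per_rule: int = 10
    holdouts_per_rule: int = 4
    distractors_per_type: int = 14
    ambiguous_rule: bool = True
    ambiguous_collisions: int = 8
    n_ambiguity: int = 8
    ambiguity_train: int = 5
    n_compositional: int = 6
    n_training_rule: int = 10
    training_rule_holdouts: int = 3
    n_exact_eval: int = 20
    n_cuiless_eval: int = 8
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.instances_per_rule < 2:
            raise ValueError("generalization needs at least 2 instances per rule")
        if self.n_training_rule < 2:
            raise ValueError("the training rule needs at least 2 instances")
        if not (0 <= self.ambiguity_train <= self.n_ambiguity):
            raise ValueError("ambiguity_train must not exceed n_ambiguity")
        if self.n_exact_eval > 4 * self.distractors_per_type:
            raise ValueError("not enough distractor concepts for the "
                             "requested exact-class evaluation mentions")
        for name in ("holdouts_per_rule", "ambiguous_collisions",
                     "n_compositional", "training_rule_holdouts",
                     "n_cuiless_eval"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SynthOutput:
    """Generated resources plus the ground-truth manifest.

    ``manifest`` has one record per evaluation mention: its text, gold
    CUI (or CUI-less), reachability class, and the planted rule (if any)
    that makes it reachable.  ``rules`` describes every planted
    systematic variation for planted-rule-recovery checks.
    """

    lexicon: Lexicon
    training_mentions: list[AnnotatedMention]
    eval_mentions: list[AnnotatedMention]
    manifest: list[dict]
    rules: list[VariationRule]
    config: SynthConfig
    #: collision pairs of the planted over-general variation: terms of
    #: *different* concepts that its rewrite relates, so retaining it would
    #: cross concept boundaries.
    ambiguous_pairs: list[tuple[str, str]] = field(default_factory=list)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.manifest:
            counts[rec["class"]] = counts.get(rec["class"], 0) + 1
        return counts

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_lexicon(self.lexicon, out / "lexicon.tsv")
        write_mentions(self.training_mentions, out / "train.tsv")
        write_mentions(self.eval_mentions, out / "eval.tsv")
        with open(out / "manifest.jsonl", "w", encoding="utf-8") as fh:
            for rec in self.manifest:
                fh.write(json.dumps(rec) + "\n")


class _Vocab:
    """Unique pronounceable words over a syllable alphabet."""

    def __init__(self, rng: random.Random, consonants: str = CONSONANTS) -> None:
        self.rng = rng
        self.consonants = consonants
        self.used: set[str] = set()

    def word(self, syllables: int = 2) -> str:
        for _ in range(10000):
            w = "".join(self.rng.choice(self.consonants) + self.rng.choice(VOWELS)
                        for _ in range(syllables))
            if w not in self.used:
                self.used.add(w)
                return w
        raise RuntimeError("vocabulary exhausted")  # pragma: no cover


def generate(cfg: SynthConfig | None = None) -> SynthOutput:
    """Generate a lexicon, training mentions, evaluation mentions, and the
    ground-truth manifest.  Deterministic under ``cfg.random_seed``."""
    cfg = cfg or SynthConfig()
    rng = random.Random(cfg.random_seed)
    vocab = _Vocab(rng)
    cuiless_vocab = _Vocab(random.Random(cfg.random_seed + 1),
                           CUILESS_CONSONANTS)

    counter = [0]

    def new_cui() -> str:
        counter[0] += 1
        return f"C{counter[0]:05d}"

    entries: list[ConceptEntry] = []
    training: list[AnnotatedMention] = []
    manifest: list[dict] = []
    rules: list[VariationRule] = []

    def add_concept(sty: str, synonyms: list[str]) -> str:
        cui = new_cui()
        entries.append(ConceptEntry(cui, {sty}, list(synonyms)))
        return cui

    # --- systematic variation rules, one semantic type each -------------
    def plant_rule(name: str, sty: str, make_pair) -> None:
        pairs, holdouts = [], []
        for _ in range(cfg.instances_per_rule):
            base, variant = make_pair()
            add_concept(sty, [base, variant])
            pairs.append((base, variant))
        for _ in range(cfg.holdouts_per_rule):
            base, variant = make_pair()
            cui = add_concept(sty, [base])
            holdouts.append((variant, base))
            manifest.append({"text": variant, "gold": cui,
                             "class": CLASS_PATTERN, "rule": name})
        rules.append(VariationRule(name, sty, tuple(pairs), tuple(holdouts)))

    plant_rule("plural_s", "plural type",
               lambda: (lambda w: (w, w + "s"))(vocab.word(3)))

    def spelling_pair() -> tuple[str, str]:
        prefix = vocab.word(2)
        vocab.used.add(prefix + "or")
        vocab.used.add(prefix + "our")
        return (prefix + "or", prefix + "our")  # base "or", variant "our"

    plant_rule("spelling_our_or", "spelling type", spelling_pair)

    w_formal, w_informal = vocab.word(3), vocab.word(3)

    def wordsub_pair() -> tuple[str, str]:
        left, right = vocab.word(2), vocab.word(2)
        return (f"{left} {w_formal} {right}", f"{left} {w_informal} {right}")

    plant_rule("word_substitution", "wordsub type", wordsub_pair)

    def nos_pair() -> tuple[str, str]:
        term = f"{vocab.word(2)} {vocab.word(2)}"
        return (term, term + " nos")

    plant_rule("nos_marker", "nos type", nos_pair)

    # --- the ambiguous (over-general) variation -------------------------
    # Seeded by genuine synonym pairs in 2 concepts, but its rewrites land
    # on *different* concepts in the collision pairs, so negatives swamp
    # positives and the score filter must reject every generalization.
    ambiguous_pairs: list[tuple[str, str]] = []
    if cfg.ambiguous_rule:
        sty = "ambiguous rule type"
        for _ in range(2):
            w = vocab.word(2)
            add_concept(sty, [f"{w} bo", f"{w} do"])
        for _ in range(cfg.ambiguous_collisions):
            w = vocab.word(2)
            add_concept(sty, [f"{w} bo"])
            add_concept(sty, [f"{w} do"])
            ambiguous_pairs.append((f"{w} bo", f"{w} do"))

    # --- ambiguous exact terms + disambiguation cases -------------------
    # The shared term is listed under two concepts of different types; the
    # losing concept gets the smaller CUI so the canonical-order fallback
    # picks wrongly and only a learned rule recovers the gold.
    for i in range(cfg.n_ambiguity):
        shared = f"{vocab.word(2)} {vocab.word(2)}"
        lose_cui = add_concept("losing type", [shared, vocab.word(3)])
        win_cui = add_concept("winning type", [shared, vocab.word(3)])
        assert lose_cui < win_cui
        if i < cfg.ambiguity_train:
            training.append(AnnotatedMention(shared, win_cui))
        else:
            manifest.append({"text": shared, "gold": win_cui,
                             "class": CLASS_AMBIG, "rule": None})

    # --- compositional concepts for subconcept matching ------------------
    for _ in range(cfg.n_compositional):
        u1, u2 = vocab.word(3), vocab.word(3)
        v1, v2 = vocab.word(3), vocab.word(3)
        filler = vocab.word(3)  # deliberately not a synonym of anything
        add_concept("component type", [u1, u2])
        add_concept("component type", [v1, v2])
        comp_cui = add_concept("compound type", [f"{u1} {filler} {v1}"])
        manifest.append({"text": f"{u2} {v2}", "gold": comp_cui,
                         "class": CLASS_SUBCONCEPT, "rule": None})

    # --- corpus-specific substitution, learnable only from training -----
    w_corpus, w_standard = vocab.word(3), vocab.word(3)
    training_pairs = []
    for _ in range(cfg.n_training_rule):
        b = vocab.word(2)
        cui = add_concept("training concept type", [f"{w_standard} {b}"])
        training.append(AnnotatedMention(f"{w_corpus} {b}", cui))
        training_pairs.append((f"{w_standard} {b}", f"{w_corpus} {b}"))
    training_holdouts = []
    for _ in range(cfg.training_rule_holdouts):
        b = vocab.word(2)
        cui = add_concept("training concept type", [f"{w_standard} {b}"])
        training_holdouts.append((f"{w_corpus} {b}", f"{w_standard} {b}"))
        manifest.append({"text": f"{w_corpus} {b}", "gold": cui,
                         "class": CLASS_PATTERN, "rule": "training_substitution"})
    # the (standard, corpus) pairs only coexist after training augmentation
    rules.append(VariationRule(
        "training_substitution", "training concept type",
        tuple(training_pairs), tuple(training_holdouts)))

    # --- distractors and exact-class evaluation mentions -----------------
    distractor_cuis: list[str] = []
    for sty in ("plural type", "spelling type", "wordsub type", "nos type"):
        for _ in range(cfg.distractors_per_type):
            n_words = rng.choice((1, 2))
            term = " ".join(vocab.word(rng.choice((2, 3)))
                            for _ in range(n_words))
            distractor_cuis.append(add_concept(sty, [term]))
    exact_cuis = rng.sample(sorted(distractor_cuis), cfg.n_exact_eval)
    lex_preview = {c: e for c, e in ((e.cui, e) for e in entries)}
    for cui in exact_cuis:
        manifest.append({"text": lex_preview[cui].synonyms[0], "gold": cui,
                         "class": CLASS_EXACT, "rule": None})

    # --- CUI-less evaluation mentions ------------------------------------
    for _ in range(cfg.n_cuiless_eval):
        term = " ".join(cuiless_vocab.word(rng.choice((2, 3)))
                        for _ in range(rng.choice((1, 2))))
        manifest.append({"text": term, "gold": CUI_LESS,
                         "class": CLASS_CUILESS, "rule": None})
    # a couple of CUI-less training mentions, to exercise their exclusion
    for _ in range(2):
        training.append(AnnotatedMention(cuiless_vocab.word(3), CUI_LESS))

    lexicon = Lexicon(entries)
    eval_mentions = [AnnotatedMention(rec["text"], rec["gold"])
                     for rec in manifest]
    return SynthOutput(lexicon, training, eval_mentions, manifest, rules, cfg,
                       ambiguous_pairs)
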