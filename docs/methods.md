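# Methods

## Task and scope

`clinorm` normalizes free-text clinical term mentions to concept
identifiers (CUIs) in a synonym lexicon, or to the reserved value
CUI-less. Mention spans are taken as given (multi-span mentions arrive
pre-concatenated in reading order); named-entity recognition, abbreviation
expansion, terminology postcoordination, and context-sensitive
disambiguation are out of scope. The lexicon is any flat extract of
(CUI, term, semantic type) rows — in production a UMLS/SNOMED CT/RxNorm
extract, in development the synthetic generator described below.

## Preprocessing

All matching and learning operates on canonicalized strings: lowercased,
with the character sequences `'s`, `'d`, `'`, `>`, `<` deleted and the
whole-word stopwords *a, an, the, his, her, patient, patient's, any, your,
this, that, these* removed (artifacts of complete-noun-phrase span
annotation). Curly apostrophes normalize to `'` before stripping, and
hyphens/en-/em-dashes are replaced by a space rather than deleted, so
"asthma-cardiac" tokenizes as two words; a config flag switches to
concatenating instead. The order — strip sequences, then stopwords —
means "patient's" reduces to "patient" and is then removed as a stopword.
Preprocessing is idempotent and may produce the empty string (such
synonyms are dropped from indexing).

## Edit patterns

An edit pattern is the full trace of a minimal Levenshtein alignment
between two terms: an ordered sequence of SAME / INSERT / DELETE /
SUBSTITUTE operations over units, with optional BEGIN/END anchors. Units
are either characters or whitespace tokens; both granularities are learned
independently, because character patterns generalize morphology (plural
`INSERT s END`) while word patterns keep lexical swaps
(`SUBSTITUTE cardiac|heart`) that a character-level generalization may
lose.

**Alignment determinism.** Minimal alignments are not unique. The dynamic
programming traceback resolves ties with a fixed policy — diagonal
(SAME/SUBSTITUTE) over DELETE over INSERT, applied right to left — so
extraction is a function, which makes learning reproducible and lets the
test suite freeze expected patterns.

**Generalization.** Two patterns generalize when their edit-operation
subsequences (kinds and units) are identical and the SAME context strictly
between edit operations coincides; the result keeps that core and extends
it with the longest SAME context shared on each side, retaining a
BEGIN/END anchor only when both inputs carry it and the whole context on
that side matched. Under this formulation the generalization of a
compatible pair is unique (no tie-breaking is ever needed), commutative,
and idempotent. The closure is computed per compatibility group with a
worklist and canonical-form deduplication; it terminates because every
generalization is a contiguous sub-run of its arguments and a pattern has
finitely many sub-runs.

**Matching and application.** A pattern's source side — its SAME,
SUBSTITUTE, and DELETE units in order — must occur contiguously in the
term, at position 0 if BEGIN-anchored and ending at the term's end if
END-anchored. Each occurrence is rewritten independently; a pattern whose
source side is empty (pure insertions) matches positionally. Every
pattern is extracted in both directions of each synonym pair, so the
candidate set is closed under reversal.

**Scoring.** A candidate pattern applied to an in-scope concept's synonym
either lands on a synonym of the same concept (a positive), on some other
concept's term (a negative), or on no lexicon term at all (ignored). The
retained score is the m-estimate p/(p+n+1); the +1 makes broadly
applicable clean rules outrank narrow ones and keeps the score strictly
below 1. The retention threshold defaults to 0.9 (strictly exceeded), so
a zero-negative rule needs at least ten positive applications — this is
what rejects over-general rules, whose rewrites cross concept boundaries
and accumulate negatives. Scoring counts ordered synonym pairs once per
direction, on synonym lists deduplicated after preprocessing so repeated
source rows cannot inflate p.

**Learning regimes.** `learn_by_semantic_type` learns separately within
each semantic-type label, sampling up to `max_concepts_per_type`
(default 5000) concepts per type with a seeded RNG and scoring within the
sample; per-type results are unioned, keeping the higher-scoring copy of
duplicates. A concept carrying several types participates in each.
`learn_from_training` folds annotated mentions into the lexicon as extra
synonyms of their gold concepts, then learns — without a type split —
over the annotated concepts plus `extra_random_concepts` (default 3000)
sampled others that drive generalization and supply negative evidence.
Scoring scope is the learning sample, not the full lexicon (configurable).

## Subconcept matching

A query term's profile is the collection of candidate CUI sets of its
maximal dictionary-matching n-grams (a matched subterm nested inside a
longer matched subterm is suppressed; without this, "breast biopsy" would
contribute three subconcepts and profile equality would rarely hold). A
concept's profile is the union over its synonyms' profiles, with one
asymmetry: a multi-token synonym's trivial full-span self-match is
excluded, because the compositional signal of a concept's name lives in
its parts — this is what lets "nasal o2" reach the concept named "oxygen
administration by nasal cannula" through the shared oxygen CUI. A
single-token synonym keeps its self-match (it has no parts). The concept
side deduplicates by CUI set (union semantics); the query side is a
multiset, and matching requires a perfect one-to-one pairing between the
two collections in which every paired couple of CUI sets intersects.
Pairing uses intersection, not equality, so synonymy expressed through
shared CUIs ("o2"/"oxygen") suffices. Candidate concepts are enumerated
through an inverted CUI→concept-profile index, and profiles are tiny, so
a backtracking matcher is ample.

## Disambiguation

When a stage returns several candidates, their combined semantic-type set
is looked up among learned rules mapping a type combination to a winning
type; the lexicographically first candidate bearing the winning type is
returned, and with no matching rule the lexicographically first candidate
overall (a reproducible stand-in for an arbitrary choice). Rules are
mined from training mentions with two or more candidates whose gold is
among them: a combination yields a rule only if one winning type selects
the gold in every covered mention (verified by re-application, which keeps
rules sound on multi-type concepts), with a configurable minimum support
defaulting to 1. Candidate "bearing" of a type means membership in the
candidate's full type set, since concepts may carry several types.

## The synthetic data generator

The generator emulates the structure the method exploits, not real
clinical language. Vocabulary is built from consonant-vowel syllables
(words of 4–6 letters over twelve consonants), so planted contexts like
"our" or the token "nos" cannot arise by chance and cross-concept string
collisions are absent unless planted. It plants, each in its own semantic
type:

* four systematic variations — suffix pluralization, an "our"→"or"
  spelling deletion, a global word-substitution pair, and a trailing
  "nos"-marker deletion — each instantiated as a synonym pair in 10
  concepts (the minimum that clears the 0.9 threshold with zero
  negatives) plus 4 holdout concepts carrying only one form, whose other
  form becomes a pattern-reachable evaluation mention;
* an over-general variation: 2 concepts genuinely carrying both forms
  (seeding the rule) and 8 cross-concept collision pairs (flooding it
  with negatives), which the score filter must reject;
* 8 ambiguous exact terms shared by a "losing type" and a "winning type"
  concept, the loser holding the smaller CUI so the canonical fallback
  errs; 5 instances are annotated for rule learning, 3 held out for
  evaluation;
* 6 compositional concepts whose single synonym combines two component
  concepts' words around an unlisted filler, with evaluation mentions
  using the components' *other* synonyms (reachable only through
  subconcept matching);
* a corpus-specific word substitution present only in training mentions
  (learnable only after training augmentation), 10 instances plus 3
  holdouts;
* 56 single-synonym distractor concepts (negative-evidence pool; 20
  double as unambiguous exact-match evaluation mentions) and 8 CUI-less
  mentions over a disjoint consonant alphabet, unreachable by any stage.

Everything derives from one seed; the manifest records every evaluation
mention's gold, reachability class, and planted rule, so evaluation
accuracies are predictable from construction and the test suite asserts
the staged accuracies exactly. What passing these tests does **not** show:
robustness to typographical noise, morphology beyond the planted rules,
realistic ambiguity rates, or the frequency structure of real
terminologies — headline accuracies on licensed corpora are not
reproduced here.

## Numerical and design choices

* Score threshold 0.9, strict inequality; thresholds are monotone
  (retained sets shrink as the threshold grows).
* Pattern files render a character-level space unit as `_space_`; parser
  and renderer are exact inverses.
* A pattern must contain at least one edit operation; extraction of
  identical terms is an error, and a rewrite that reproduces its input
  (degenerate insert/delete combinations) is discarded.
* Scoring prefilters character patterns by substring containment of the
  source side, the dominant cost at scale.
* Canonical orderings everywhere randomness or dict order could leak:
  concepts sort by CUI before seeded sampling, candidates and rule
  winners break ties lexicographically, evaluation is byte-reproducible
  under fixed seeds.
* The test suite checks the edit-distance implementation against a plain
  recursive oracle exhaustively over all pairs up to length 4 on a
  3-letter alphabet and lengths 5–7 on a 2-letter alphabet, plus seeded
  random pairs — an enumeration sized to run in seconds while still
  covering every alignment topology the implementation distinguishes.

## Known limitations

Edit patterns capture contiguous edits only: word reorderings
("asthma cardiac" vs "cardiac asthma") and non-sequential paraphrases are
out of reach. Disambiguation ignores the mention's document context.
Subconcept matching requires exact profile-size agreement, so a concept
with extra listed parts will not match a shorter mention (a configurable
relaxation point). Pattern learning scales with the square of synonyms
per concept and the closure size within a compatibility group; the
per-type concept cap is the practical control.
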