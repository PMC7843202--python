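# clinorm — clinical term normalization with learned edit patterns

Clinical notes rarely mention clinical terms in the standardized form a
terminology lists: writers pluralize ("tumors"), use spelling variants
("tumour"), swap words ("heart" for "cardiac"), drop markers ("nos"), or
compose concepts from parts ("nasal o2"). Downstream applications — coding,
biosurveillance, decision support — need each mention mapped to a concept
unique identifier (CUI) in a terminology such as SNOMED CT or RxNorm, or
to the reserved answer **CUI-less** when no concept corresponds. `clinorm`
implements an interpretable, pattern-based normalizer for this task, aimed
at clinical NLP practitioners who want a transparent alternative to
end-to-end neural linkers.

## The method

Normalization runs in stages; the first stage that yields candidates wins,
and a disambiguation step picks one CUI when several remain.

1. **Exact matching.** The preprocessed mention is looked up (hash table)
   among all lexicon synonyms and among previously annotated training
   mentions.
2. **Learned edit patterns.** An *edit pattern* is the alignment trace of
   a Levenshtein edit-distance computation between two synonyms — e.g.
   converting "anemic" to "anemias" gives
   `BEGIN SAME a SAME n SAME e SAME m SAME i INSERT a SUBSTITUTE c|s END`.
   Two patterns with the same edit operations generalize to the longest
   contiguous common run of operations containing all edits; iterated over
   a lexicon's synonym pairs this discovers rules like
   `SAME m SAME i INSERT a SUBSTITUTE c|s END` ("rewrite trailing *mic* to
   *mias*"). Each candidate pattern is scored by applying it back to the
   lexicon: *p* counts rewrites landing on a synonym of the same concept,
   *n* rewrites landing on a different concept, and the retained score is
   the m-estimate *p/(p+n+1)*, thresholded at 0.9. Patterns are learned
   over characters and over whitespace words, separately per semantic type
   of the lexicon, and additionally from annotated training mentions folded
   in as extra synonyms. A mention is rewritten by every retained pattern;
   rewrites that exact-match the lexicon contribute their CUIs.
3. **Subconcept matching.** The mention's maximal dictionary-matching
   n-grams define its *subconcept profile* (a collection of candidate CUI
   sets); a concept's profile is the union over its synonyms' parts. A
   mention maps to a concept when the two profiles pair off one-to-one
   with every paired couple of CUI sets intersecting — which is how
   "nasal o2" reaches *oxygen administration by nasal cannula* even though
   the strings "o2" and "oxygen" differ.
4. **Disambiguation.** From training mentions with multiple candidates the
   system learns rules of the form *type combination → winning semantic
   type* (kept only when the winner is consistent across all covered
   mentions); without a matching rule the canonically first candidate is
   returned.

Licensed resources (UMLS, the MCN corpus) are not required: the package
ships a synthetic-lexicon generator that plants the same kinds of
systematic variation, ambiguity, and compositionality, so every stage is
learnable and measurable from scratch.

## Worked example

```python
from clinorm import (ConceptEntry, Lexicon, LearnConfig, Normalizer,
                     learn_by_semantic_type)

lex = Lexicon([
    ConceptEntry("C001", {"disease or syndrome"}, ["anemic", "anemias"]),
    ConceptEntry("C002", {"disease or syndrome"}, ["glycemic", "glycemias"]),
    ConceptEntry("C003", {"disease or syndrome"}, ["thmic", "thmias"]),
    ConceptEntry("C004", {"disease or syndrome"}, ["arrhythmias"]),
])
patterns = learn_by_semantic_type(lex, LearnConfig(score_threshold=0.5,
                                                   unit_levels=("char",)))
for p in patterns.sorted_by_score():
    print(f"p={p.positives} n={p.negatives} score={p.score:.2f}  {p.render()}")

nm = Normalizer(lex, patterns=patterns)
res = nm.normalize("Arrhythmic")
print(res.output, res.stage, sorted(res.candidates))
```

prints

```
p=3 n=0 score=0.75  SAME m SAME i DELETE a SUBSTITUTE s|c END
p=3 n=0 score=0.75  SAME m SAME i INSERT a SUBSTITUTE c|s END
p=2 n=0 score=0.67  SAME e SAME m SAME i DELETE a SUBSTITUTE s|c END
p=2 n=0 score=0.67  SAME e SAME m SAME i INSERT a SUBSTITUTE c|s END
C004 pattern ['C004']
```

The learner found the suffix rule (and its reverse — every pattern's
reverse is also generated) in both a general and a more context-bound
form, each with three resp. two positive applications and no negatives.
"Arrhythmic" matches no synonym exactly, but the retained rule rewrites it
to "arrhythmias", a synonym of `C004`, so the pattern stage normalizes it
there. On this toy lexicon each rule has at most three positives, so the
retention threshold was lowered to 0.5; at the default 0.9 a rule needs
more than nine clean applications — deliberately demanding, since an
over-general rule (e.g. "change every *c* to *s*") accumulates negatives
and is filtered out.

The same workflow is available from the shell:

```sh
clinorm synth --seed 7 --out data/
clinorm learn --lexicon data/lexicon.tsv --train data/train.tsv \
              --out data/patterns.tsv --seed 7
clinorm evaluate --lexicon data/lexicon.tsv --patterns data/patterns.tsv \
                 --train data/train.tsv --in data/eval.tsv
```

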