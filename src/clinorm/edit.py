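"""Edit patterns: extraction, generalization, matching, and application.

An *edit pattern* is the alignment trace of a Levenshtein edit-distance
computation between two synonymous terms: the ordered sequence of SAME,
INSERT, DELETE, and SUBSTITUTE operations over units (characters, or
whitespace-separated word tokens), optionally anchored to the beginning
(BEGIN) and/or end (END) of a term.  A freshly extracted pattern is fully
anchored and rewrites exactly its source synonym into its target; the
generalization of two patterns is the longest contiguous run of operations
common to both that still contains every edit operation, which is what lets
a pattern learned from "anemic"/"anemias" and "glycemic"/"glycemias" fire on
"arrhythmic".

Rendering uses the field notation ``BEGIN SAME g ... INSERT a SUBSTITUTE c|s
END``; at the character level a space unit renders as ``_space_``.  The
parser and renderer are exact inverses.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

CHAR = "char"
WORD = "word"

_SPACE_TOKEN = "_space_"


class OpKind(str, enum.Enum):
    SAME = "SAME"
    INSERT = "INSERT"
    DELETE = "DELETE"
    SUBSTITUTE = "SUBSTITUTE"


@dataclass(frozen=True)
class EditOp:
    """One alignment step.

    SAME and DELETE carry only ``source`` (for SAME the unit is stored
    once, as the source); INSERT carries only ``target``; SUBSTITUTE
    carries both with ``source != target``.
    """

    kind: OpKind
    source: Optional[str] = None
    target: Optional[str] = None

    def __post_init__(self) -> None:
        k = self.kind
        if k is OpKind.SAME and (self.source is None or self.target is not None):
            raise ValueError("SAME stores its unit once, as source")
        if k is OpKind.INSERT and (self.source is not None or self.target is None):
            raise ValueError("INSERT has only a target unit")
        if k is OpKind.DELETE and (self.source is None or self.target is not None):
            raise ValueError("DELETE has only a source unit")
        if k is OpKind.SUBSTITUTE:
            if self.source is None or self.target is None:
                raise ValueError("SUBSTITUTE needs source and target")
            if self.source == self.target:
                raise ValueError("SUBSTITUTE requires source != target")

    @property
    def is_edit(self) -> bool:
        return self.kind is not OpKind.SAME

    def source_unit(self) -> Optional[str]:
        """Unit this op consumes from the term being rewritten."""
        return self.source

    def target_unit(self) -> Optional[str]:
        """Unit this op emits into the rewritten term."""
        return self.source if self.kind is OpKind.SAME else self.target


def same(u: str) -> EditOp:
    return EditOp(OpKind.SAME, source=u)


def insert(u: str) -> EditOp:
    return EditOp(OpKind.INSERT, target=u)


def delete(u: str) -> EditOp:
    return EditOp(OpKind.DELETE, source=u)


def substitute(a: str, b: str) -> EditOp:
    return EditOp(OpKind.SUBSTITUTE, source=a, target=b)


@dataclass(frozen=True)
class EditPattern:
    """An anchored sequence of edit operations with quality counts.

    ``positives`` (p) counts applications that rewrite a term into a
    synonym of the same concept, ``negatives`` (n) applications that land
    on a different concept's term; the score p/(p+n+1) — an m-estimate —
    rewards patterns that are both accurate and broadly applicable.
    """

    unit_level: str
    ops: tuple[EditOp, ...]
    anchored_begin: bool = False
    anchored_end: bool = False
    provenance: str = ""
    positives: int = 0
    negatives: int = 0

    def __post_init__(self) -> None:
        if self.unit_level not in (CHAR, WORD):
            raise ValueError(f"unknown unit level {self.unit_level!r}")
        if not any(op.is_edit for op in self.ops):
            raise ValueError("an edit pattern needs at least one edit operation")

    @property
    def score(self) -> float:
        return self.positives / (self.positives + self.negatives + 1)

    @property
    def edit_ops(self) -> tuple[EditOp, ...]:
        return tuple(op for op in self.ops if op.is_edit)

    def signature(self) -> tuple:
        """Generalization-compatibility key: the edit ops (kinds and units)
        plus the SAME context between consecutive edit ops.

        Two patterns generalize iff their signatures are equal: the common
        run must span from the first to the last edit op, so everything
        strictly between them has to coincide.
        """
        sig: list = [self.unit_level]
        run: list[str] = []
        started = False
        for op in self.ops:
            if op.is_edit:
                if started:
                    sig.append(tuple(run))
                run = []
                started = True
                sig.append((op.kind.value, op.source, op.target))
            elif started:
                run.append(op.source)  # type: ignore[arg-type]
        return tuple(sig)

    def key(self) -> tuple:
        """Identity for deduplication: level, anchors, full op sequence."""
        return (self.unit_level, self.anchored_begin, self.anchored_end,
                tuple((op.kind.value, op.source, op.target) for op in self.ops))

    def source_units(self) -> tuple[str, ...]:
        """Concatenated units the pattern requires in the matched term."""
        return tuple(u for op in self.ops
                     if (u := op.source_unit()) is not None)

    def target_units(self) -> tuple[str, ...]:
        return tuple(u for op in self.ops
                     if (u := op.target_unit()) is not None)

    def render(self) -> str:
        parts: list[str] = []
        if self.anchored_begin:
            parts.append("BEGIN")
        esc = _escape_unit if self.unit_level == CHAR else (lambda u: u)
        for op in self.ops:
            if op.kind is OpKind.SAME:
                parts.append(f"SAME {esc(op.source)}")
            elif op.kind is OpKind.INSERT:
                parts.append(f"INSERT {esc(op.target)}")
            elif op.kind is OpKind.DELETE:
                parts.append(f"DELETE {esc(op.source)}")
            else:
                parts.append(f"SUBSTITUTE {esc(op.source)}|{esc(op.target)}")
        if self.anchored_end:
            parts.append("END")
        return " ".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def _escape_unit(u: str) -> str:
    return _SPACE_TOKEN if u == " " else u


def _unescape_unit(u: str) -> str:
    return " " if u == _SPACE_TOKEN else u


def parse_pattern(text: str, unit_level: str, provenance: str = "",
                  positives: int = 0, negatives: int = 0) -> EditPattern:
    """Parse the rendered notation back into an :class:`EditPattern`."""
    tokens = text.split()
    anchored_begin = anchored_end = False
    if tokens and tokens[0] == "BEGIN":
        anchored_begin = True
        tokens = tokens[1:]
    if tokens and tokens[-1] == "END":
        anchored_end = True
        tokens = tokens[:-1]
    unesc = _unescape_unit if unit_level == CHAR else (lambda u: u)
    ops: list[EditOp] = []
    i = 0
    while i < len(tokens):
        kw = tokens[i]
        if i + 1 >= len(tokens):
            raise ValueError(f"dangling operator {kw!r} in pattern {text!r}")
        arg = tokens[i + 1]
        if kw == "SAME":
            ops.append(same(unesc(arg)))
        elif kw == "INSERT":
            ops.append(insert(unesc(arg)))
        elif kw == "DELETE":
            ops.append(delete(unesc(arg)))
        elif kw == "SUBSTITUTE":
            src, sep, tgt = arg.partition("|")
            if not sep:
                raise ValueError(f"SUBSTITUTE needs 'a|b' argument in {text!r}")
            ops.append(substitute(unesc(src), unesc(tgt)))
        else:
            raise ValueError(f"unknown operator {kw!r} in pattern {text!r}")
        i += 2
    return EditPattern(unit_level, tuple(ops), anchored_begin, anchored_end,
                       provenance, positives, negatives)


def _units(term: str, unit_level: str) -> list[str]:
    return list(term) if unit_level == CHAR else term.split()


def _join(units: Iterable[str], unit_level: str) -> str:
    return "".join(units) if unit_level == CHAR else " ".join(units)


def _dp_table(a: list[str], b: list[str]) -> list[list[int]]:
    la, lb = len(a), len(b)
    dp = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(la + 1):
        dp[i][0] = i
    for j in range(lb + 1):
        dp[0][j] = j
    for i in range(1, la + 1):
        ai = a[i - 1]
        row, prev = dp[i], dp[i - 1]
        for j in range(1, lb + 1):
            cost = 0 if ai == b[j - 1] else 1
            row[j] = min(prev[j - 1] + cost, prev[j] + 1, row[j - 1] + 1)
    return dp


def edit_distance(a: str, b: str, unit_level: str = CHAR) -> int:
    """Levenshtein distance between two terms over the chosen units.

    >>> edit_distance("glycemic", "glycemias")
    2
    """
    ua, ub = _units(a, unit_level), _units(b, unit_level)
    return _dp_table(ua, ub)[len(ua)][len(ub)]


def extract_edit_pattern(a: str, b: str, unit_level: str = CHAR) -> EditPattern:
    """Fully anchored pattern spelling a minimal alignment of ``a`` to ``b``.

    Minimal alignments are not unique; the traceback resolves ties by a
    fixed policy — prefer the diagonal move (SAME/SUBSTITUTE), then DELETE,
    then INSERT — so extraction is deterministic.  ``apply_pattern`` on the
    result rewrites ``a`` into exactly ``b``.
    """
    ua, ub = _units(a, unit_level), _units(b, unit_level)
    if ua == ub:
        raise ValueError("terms are identical after preprocessing; no edits")
    dp = _dp_table(ua, ub)
    ops: list[EditOp] = []
    i, j = len(ua), len(ub)
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            cost = 0 if ua[i - 1] == ub[j - 1] else 1
            if dp[i][j] == dp[i - 1][j - 1] + cost:
                ops.append(same(ua[i - 1]) if cost == 0
                           else substitute(ua[i - 1], ub[j - 1]))
                i, j = i - 1, j - 1
                continue
        if i > 0 and dp[i][j] == dp[i - 1][j] + 1:
            ops.append(delete(ua[i - 1]))
            i -= 1
            continue
        ops.append(insert(ub[j - 1]))
        j -= 1
    ops.reverse()
    return EditPattern(unit_level, tuple(ops), anchored_begin=True,
                       anchored_end=True)


def generalize(p1: EditPattern, p2: EditPattern) -> Optional[EditPattern]:
    """Longest contiguous common run of ops containing every edit op.

    Returns None when the patterns are incompatible: different unit levels,
    different edit-op sequences, or differing SAME context between edit
    ops.  When compatible, the run spans from the first to the last edit
    op, extended outward by the longest shared SAME context on each side;
    a BEGIN/END anchor survives only when both patterns carry it and the
    full context on that side matched.

    Generalization is commutative, and ``generalize(P, P) == P`` up to
    counts and provenance.
    """
    if p1.unit_level != p2.unit_level:
        return None
    if p1.signature() != p2.signature():
        return None

    def split(p: EditPattern) -> tuple[list[str], list[EditOp], list[str]]:
        first = next(k for k, op in enumerate(p.ops) if op.is_edit)
        last = max(k for k, op in enumerate(p.ops) if op.is_edit)
        prefix = [op.source for op in p.ops[:first]]  # all SAME
        core = list(p.ops[first:last + 1])
        suffix = [op.source for op in p.ops[last + 1:]]
        return prefix, core, suffix  # type: ignore[return-value]

    pre1, core, suf1 = split(p1)
    pre2, _, suf2 = split(p2)

    # longest common suffix of the two SAME prefixes
    k = 0
    while k < len(pre1) and k < len(pre2) and pre1[-1 - k] == pre2[-1 - k]:
        k += 1
    shared_pre = pre1[len(pre1) - k:]
    begin = (p1.anchored_begin and p2.anchored_begin
             and k == len(pre1) == len(pre2))

    # longest common prefix of the two SAME suffixes
    m = 0
    while m < len(suf1) and m < len(suf2) and suf1[m] == suf2[m]:
        m += 1
    shared_suf = suf1[:m]
    end = (p1.anchored_end and p2.anchored_end
           and m == len(suf1) == len(suf2))

    ops = tuple([same(u) for u in shared_pre] + core
                + [same(u) for u in shared_suf])
    return EditPattern(p1.unit_level, ops, begin, end)


def match_pattern(P: EditPattern, term: str) -> list[int]:
    """Unit offsets in ``term`` where the pattern's source side occurs.

    The source side is the contiguous sequence of SAME, SUBSTITUTE, and
    DELETE units; BEGIN pins an occurrence to offset 0, END to the end of
    the term.  A pattern with an empty source side (pure insertions)
    matches positionally: at every boundary, or only at the anchored one.
    """
    units = _units(term, P.unit_level)
    src = list(P.source_units())
    n, m = len(units), len(src)
    if m == 0:
        starts: Iterable[int] = range(n + 1)
    else:
        starts = (i for i in range(n - m + 1) if units[i:i + m] == src)
    out = []
    for i in starts:
        if P.anchored_begin and i != 0:
            continue
        if P.anchored_end and i + m != n:
            continue
        out.append(i)
    return out


def apply_pattern(P: EditPattern, term: str) -> list[str]:
    """Rewrite ``term`` at every match location, one result per location.

    Returns the empty list when the pattern does not match.  A rewrite
    that reproduces the input (possible only for degenerate delete/insert
    combinations) is dropped.
    """
    units = _units(term, P.unit_level)
    m = len(P.source_units())
    tgt = list(P.target_units())
    out: list[str] = []
    for i in match_pattern(P, term):
        rewritten = _join(units[:i] + tgt + units[i + m:], P.unit_level)
        if rewritten != term:
            out.append(rewritten)
    return out


def reverse_pattern(P: EditPattern) -> EditPattern:
    """The pattern performing the inverse rewrite: INSERT and DELETE swap,
    SUBSTITUTE flips its units, SAME ops and anchors are preserved.
    An involution: ``reverse_pattern(reverse_pattern(P)) == P``.
    """
    ops = []
    for op in P.ops:
        if op.kind is OpKind.SAME:
            ops.append(op)
        elif op.kind is OpKind.INSERT:
            ops.append(delete(op.target))
        elif op.kind is OpKind.DELETE:
            ops.append(insert(op.source))
        else:
            ops.append(substitute(op.target, op.source))
    return replace(P, ops=tuple(ops))
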