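"""Canonicalization of mention and synonym strings.

Every string that enters matching, learning, or indexing goes through
:func:`preprocess` first.  The transform lowercases, strips a small set of
character sequences (possessives, quotes, comparison signs), removes a fixed
list of determiner-like stopwords that leak into mention spans from
noun-phrase annotation policies, and collapses whitespace.  Hyphens and
en/em dashes are replaced by a space rather than deleted so that word-level
tokenization is preserved ("asthma-cardiac" becomes two tokens, not one).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

DEFAULT_STOPWORDS: tuple[str, ...] = (
    "a", "an", "the", "his", "her", "patient", "patient's", "any",
    "your", "this", "that", "these",
)

# "-" is handled separately (replaced by a space); the rest are deleted.
DEFAULT_STRIP_STRINGS: tuple[str, ...] = ("'s", "'d", "'", ">", "<")

_APOSTROPHES = str.maketrans({"’": "'", "‘": "'"})
_DASH_RE = re.compile(r"[-‐‑‒–—]")
_WS_RE = re.compile(r"\s+")


@dataclass(frozen=True)
class PreprocessConfig:
    """Stopword and strip-string configuration for term canonicalization.

    ``hyphen_splits`` controls whether hyphen removal joins the neighbours
    with a space (default) or concatenates them.
    """

    stopwords: tuple[str, ...] = DEFAULT_STOPWORDS
    strip_strings: tuple[str, ...] = DEFAULT_STRIP_STRINGS
    hyphen_splits: bool = True

    @classmethod
    def from_file(cls, path: str | Path) -> "PreprocessConfig":
        """Load overrides from a YAML (or JSON — YAML superset) config file."""
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        kwargs = {}
        if "stopwords" in data:
            kwargs["stopwords"] = tuple(data["stopwords"])
        if "strip_strings" in data:
            kwargs["strip_strings"] = tuple(data["strip_strings"])
        if "hyphen_splits" in data:
            kwargs["hyphen_splits"] = bool(data["hyphen_splits"])
        return cls(**kwargs)


DEFAULT_CONFIG = PreprocessConfig()


def preprocess(term: str, cfg: PreprocessConfig = DEFAULT_CONFIG) -> str:
    """Canonicalize a raw term string.

    Order of operations: lowercase, normalize apostrophe and dash variants,
    replace hyphens with a space (or nothing if ``hyphen_splits`` is False),
    delete strip strings, drop stopword tokens by whole-word match, collapse
    whitespace.  The result may be the empty string.

    >>> preprocess("The patient's anemia")
    'anemia'
    """
    s = term.lower().translate(_APOSTROPHES)
    s = _DASH_RE.sub(" " if cfg.hyphen_splits else "", s)
    for frag in cfg.strip_strings:
        if frag and frag != "-":
            s = s.replace(frag, "")
    stop = set(cfg.stopwords)
    tokens = [t for t in s.split() if t not in stop]
    return _WS_RE.sub(" ", " ".join(tokens)).strip()
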