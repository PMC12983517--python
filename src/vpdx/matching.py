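"""Free-text normalization and lexicon matching.

Learners enter diagnoses and test names as free text.  Scoring resolves
those entries against curated synonym lexicons: the case's diagnosis
lexicon (canonical label -> synonyms) and each test's name/synonym list.
Matching is exact on a normalized form by default; a bounded Levenshtein
fallback (distance <= 2) can be enabled for typo tolerance.
"""

from __future__ import annotations

import re
from typing import Mapping, Sequence

try:
    import edlib

    _HAVE_EDLIB = True
except ImportError:  # pragma: no cover
    _HAVE_EDLIB = False

_WS = re.compile(r"\s+")
_PUNCT = re.compile(r"[^\w\s]")

__all__ = ["normalize_text", "levenshtein", "LexiconMatcher", "match_free_text"]


def normalize_text(s: str) -> str:
    """Case-fold, strip punctuation, trim and collapse whitespace."""
    s = _PUNCT.sub(" ", s.casefold())
    return _WS.sub(" ", s).strip()


def levenshtein(a: str, b: str) -> int:
    """Edit distance between two strings (edlib if available, else DP)."""
    if _HAVE_EDLIB:
        return edlib.align(a, b)["editDistance"]
    # O(len(a)*len(b)) fallback
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


class LexiconMatcher:
    """Resolve free-text entries to canonical labels.

    Parameters
    ----------
    lexicon
        Mapping of canonical label -> synonym list.  The canonical label
        itself is always accepted as a synonym.
    max_edit_distance
        0 (default) for exact normalized matching only; a positive value
        enables a bounded Levenshtein fallback for unmatched entries.
    """

    def __init__(
        self,
        lexicon: Mapping[str, Sequence[str]],
        max_edit_distance: int = 0,
    ) -> None:
        if not lexicon:
            raise ValueError("lexicon must be non-empty")
        self.max_edit_distance = int(max_edit_distance)
        self._index: dict[str, str] = {}
        # insertion order of the lexicon fixes tie-breaks -> deterministic
        self._entries: list[tuple[str, str]] = []
        for canonical, synonyms in lexicon.items():
            for syn in [canonical, *synonyms]:
                norm = normalize_text(syn)
                if norm and norm not in self._index:
                    self._index[norm] = canonical
                    self._entries.append((norm, canonical))
        self.unmatched: list[str] = []

    def match(self, entry: str) -> str | None:
        """Return the canonical label for ``entry``, or None.

        Unmatched entries are appended to :attr:`unmatched` so callers can
        log them to a side channel.
        """
        norm = normalize_text(entry)
        hit = self._index.get(norm)
        if hit is not None:
            return hit
        if self.max_edit_distance > 0 and norm:
            best: tuple[int, int] | None = None  # (distance, entry index)
            for i, (syn, _) in enumerate(self._entries):
                d = levenshtein(norm, syn)
                if d <= self.max_edit_distance and (best is None or d < best[0]):
                    best = (d, i)
            if best is not None:
                return self._entries[best[1]][1]
        self.unmatched.append(entry)
        return None


def match_free_text(
    entry: str,
    lexicon: Mapping[str, Sequence[str]],
    max_edit_distance: int = 0,
) -> str | None:
    """One-shot convenience wrapper around :class:`LexiconMatcher`."""
    return LexiconMatcher(lexicon, max_edit_distance).match(entry)
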