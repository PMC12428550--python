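"""Diagnosis text normalization and similarity scoring.

The diagnosis-similarity factor of the trust score compares the AI-generated
diagnosis (AIDx) against the clinician-documented reference (hDx).  Raw
strings first pass through a standard clinical-text normalization pipeline —
lowercasing, punctuation removal, whitespace tokenization, English stopword
filtering and suffix-stripping (Porter) stemming — and are then scored by a
pluggable similarity backend.  An exact match of the normalized surfaces
short-circuits to 1.0 before any backend is consulted.

The default backend is a deterministic term-frequency cosine over the union
vocabulary of both token sequences.  A sentence-embedding backend can be
registered under its own name and satisfies the same contract: symmetric,
deterministic for fixed inputs, and scores clamped into [0, 1].

The stopword list and stemmer are fixed in this module so that similarity
scores are bit-stable across installations.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Dict, Sequence

__all__ = [
    "NormalizedText",
    "SimilarityBackend",
    "normalize_text",
    "diagnosis_similarity",
    "token_cosine",
    "porter_stem",
    "get_backend",
    "register_backend",
    "available_backends",
    "STOPWORDS",
]

# ---------------------------------------------------------------------------
# Stopwords — the standard English list, frozen here for reproducibility.
# ---------------------------------------------------------------------------

STOPWORDS: frozenset = frozenset("""
a about above after again against all am an and any are aren't as at be
because been before being below between both but by can't cannot could
couldn't did didn't do does doesn't doing don't down during each few for from
further had hadn't has hasn't have haven't having he he'd he'll he's her here
here's hers herself him himself his how how's i i'd i'll i'm i've if in into
is isn't it it's its itself let's me more most mustn't my myself no nor not
of off on once only or other ought our ours ourselves out over own same
shan't she she'd she'll she's should shouldn't so some such than that that's
the their theirs them themselves then there there's these they they'd they'll
they're they've this those through to too under until up very was wasn't we
we'd we'll we're we've were weren't what what's when when's where where's
which while who who's whom why why's with won't would wouldn't you you'd
you'll you're you've your yours yourself yourselves
""".split())


# ---------------------------------------------------------------------------
# Porter stemmer
# ---------------------------------------------------------------------------

_VOWELS = set("aeiou")


def _is_consonant(word: str, i: int) -> bool:
    ch = word[i]
    if ch in _VOWELS:
        return False
    if ch == "y":
        return i == 0 or not _is_consonant(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of VC sequences ("measure" m) in the stem."""
    m = 0
    prev_vowel = False
    for i in range(len(stem)):
        if _is_consonant(stem, i):
            if prev_vowel:
                m += 1
            prev_vowel = False
        else:
            prev_vowel = True
    return m


def _contains_vowel(stem: str) -> bool:
    return any(not _is_consonant(stem, i) for i in range(len(stem)))


def _ends_double_consonant(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_consonant(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    if not (
        _is_consonant(word, len(word) - 3)
        and not _is_consonant(word, len(word) - 2)
        and _is_consonant(word, len(word) - 1)
    ):
        return False
    return word[-1] not in "wxy"


_STEP2_SUFFIXES = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
]

_STEP3_SUFFIXES = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]

_STEP4_SUFFIXES = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement", "ment",
    "ent", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]


def porter_stem(word: str) -> str:
    """Reduce an English word to its stem via the classic Porter algorithm."""
    if len(word) <= 2:
        return word
    w = word

    # Step 1a — plurals
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif w.endswith("ss"):
        pass
    elif w.endswith("s"):
        w = w[:-1]

    # Step 1b — -ed / -ing
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            w = w[:-1]
    else:
        flag = False
        if w.endswith("ed") and _contains_vowel(w[:-2]):
            w, flag = w[:-2], True
        elif w.endswith("ing") and _contains_vowel(w[:-3]):
            w, flag = w[:-3], True
        if flag:
            if w.endswith(("at", "bl", "iz")):
                w += "e"
            elif _ends_double_consonant(w) and not w.endswith(("l", "s", "z")):
                w = w[:-1]
            elif _measure(w) == 1 and _ends_cvc(w):
                w += "e"

    # Step 1c — -y → -i
    if w.endswith("y") and _contains_vowel(w[:-1]):
        w = w[:-1] + "i"

    # Step 2
    for suffix, repl in _STEP2_SUFFIXES:
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if _measure(stem) > 0:
                w = stem + repl
            break

    # Step 3
    for suffix, repl in _STEP3_SUFFIXES:
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if _measure(stem) > 0:
                w = stem + repl
            break

    # Step 4
    for suffix in _STEP4_SUFFIXES:
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if _measure(stem) > 1:
                w = stem
            break
    else:
        if w.endswith("ion") and len(w) > 3 and w[-4] in "st":
            stem = w[:-3]
            if _measure(stem) > 1:
                w = stem

    # Step 5a — final -e
    if w.endswith("e"):
        stem = w[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            w = stem

    # Step 5b — -ll → -l
    if _measure(w) > 1 and _ends_double_consonant(w) and w.endswith("l"):
        w = w[:-1]

    return w


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

_PUNCT_RE = re.compile(r"[^\w\s]|_", re.UNICODE)
_WS_RE = re.compile(r"\s+")


@dataclass(frozen=True)
class NormalizedText:
    """Normalized diagnosis text: stemmed content tokens plus a surface form."""

    tokens: tuple
    surface: str

    def __bool__(self) -> bool:
        return bool(self.tokens)


def normalize_text(raw: str) -> NormalizedText:
    """Run the normalization pipeline on one diagnosis string.

    Lowercase, strip punctuation, tokenize on whitespace, remove English
    stopwords and stem the remainder.  An input that is empty or consists
    entirely of stopwords/punctuation yields an empty token sequence.
    """
    lowered = _PUNCT_RE.sub(" ", raw.lower())
    words = [t for t in _WS_RE.split(lowered) if t]
    tokens = tuple(porter_stem(t) for t in words if t not in STOPWORDS)
    return NormalizedText(tokens=tokens, surface=" ".join(tokens))


# ---------------------------------------------------------------------------
# Backends
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimilarityBackend:
    """Named scoring function over a pair of normalized texts.

    The contract: symmetric, deterministic, and (after clamping by the
    caller) valued in [0, 1]; any nonempty text scores 1.0 against itself.
    """

    name: str
    score: Callable[[NormalizedText, NormalizedText], float] = field(repr=False)


def token_cosine(a: NormalizedText, b: NormalizedText) -> float:
    """Cosine of term-frequency vectors over the union vocabulary.

    Returns 0.0 when either side has no tokens.  Counts are nonnegative, so
    the score is always within [0, 1].
    """
    if not a.tokens or not b.tokens:
        return 0.0
    ca, cb = Counter(a.tokens), Counter(b.tokens)
    dot = sum(ca[t] * cb[t] for t in ca.keys() & cb.keys())
    norm = math.sqrt(sum(v * v for v in ca.values())) * math.sqrt(
        sum(v * v for v in cb.values())
    )
    return dot / norm if norm else 0.0


_BACKENDS: Dict[str, SimilarityBackend] = {}


def register_backend(backend: SimilarityBackend) -> None:
    _BACKENDS[backend.name] = backend


def get_backend(name: str) -> SimilarityBackend:
    try:
        return _BACKENDS[name]
    except KeyError:
        raise KeyError(
            f"unknown similarity backend {name!r}; available: "
            f"{sorted(_BACKENDS)}"
        ) from None


def available_backends() -> Sequence[str]:
    return sorted(_BACKENDS)


register_backend(SimilarityBackend(name="token-cosine", score=token_cosine))


# ---------------------------------------------------------------------------
# Top-level similarity
# ---------------------------------------------------------------------------

def diagnosis_similarity(
    a: str,
    b: str,
    backend: SimilarityBackend | str = "token-cosine",
) -> float:
    """Similarity in [0, 1] between two diagnosis strings.

    Exact match of the nonempty normalized surfaces short-circuits to 1.0;
    otherwise the backend score is clamped into [0, 1] (embedding cosines can
    be negative; the trust score assumes a nonnegative similarity).
    """
    if isinstance(backend, str):
        backend = get_backend(backend)
    na, nb = normalize_text(a), normalize_text(b)
    if not na.tokens and not nb.tokens:
        raise ValueError("cannot score similarity of two empty diagnoses")
    if na.surface == nb.surface and na.tokens:
        return 1.0
    return min(1.0, max(0.0, float(backend.score(na, nb))))
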