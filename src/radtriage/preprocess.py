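"""Text preprocessing: from impression text to a bag-of-words feature set.

The pipeline order is fixed and load-bearing:

    lowercase -> merge common phrases -> remove negated scopes ->
    tokenize -> drop stop words -> deduplicate to a set

Phrase merging MUST precede negation removal: stock normal phrases such
as "no acute cardiopulmonary process" carry their own negation, and
collapsing them to a single whitespace-free token first ("noacute...")
protects them from the scope remover.  A normal report whose impression
is nothing but negated findings then reduces to an empty bag, which is a
valid (and for low-priority reports, typical) input to the classifier.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "PhraseList",
    "TokenBag",
    "PreprocessConfig",
    "merge_common_phrases",
    "remove_negated",
    "remove_stop_words",
    "tokenize",
    "to_token_bag",
    "load_default_phrases",
    "load_default_stop_words",
    "load_default_triggers",
]

#: Sentence-ending punctuation that terminates a negation scope.
SENTENCE_TERMINATORS: frozenset[str] = frozenset({".", ";", ":"})

#: Conjunctions that break a negation scope without ending the sentence.
DEFAULT_SCOPE_BREAKERS: frozenset[str] = frozenset({"but", "however", "although"})


def _read_data_lines(name: str) -> list[str]:
    text = resources.files("radtriage").joinpath(f"data/{name}").read_text("utf-8")
    return [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]


def _read_lines(path: str | Path) -> list[str]:
    return [
        line.strip()
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]


@dataclass(frozen=True)
class PhraseList:
    """Ordered multi-word phrases to be collapsed into single tokens.

    Ordering is longest-match-first (enforced at construction): no phrase
    may be a prefix of an earlier phrase after lowercasing, so at an
    overlapping match the longest phrase wins.
    """

    phrases: tuple[str, ...]

    def __post_init__(self) -> None:
        ordered = tuple(
            sorted(self.phrases, key=lambda p: (-len(p.lower().split()), -len(p), p.lower()))
        )
        object.__setattr__(self, "phrases", ordered)
        seen: list[str] = []
        for p in self.phrases:
            pl = " ".join(p.lower().split())
            for earlier in seen:
                if earlier.startswith(pl) and earlier != pl:
                    # longer phrase is earlier by construction; fine
                    pass
                if pl.startswith(earlier) and pl != earlier:
                    raise ValueError(
                        f"phrase ordering violated: {p!r} extends earlier phrase"
                    )
            seen.append(pl)

    @classmethod
    def from_file(cls, path: str | Path) -> "PhraseList":
        return cls(phrases=tuple(_read_lines(path)))

    def __iter__(self):
        return iter(self.phrases)

    def __len__(self) -> int:
        return len(self.phrases)


def load_default_phrases() -> PhraseList:
    return PhraseList(phrases=tuple(_read_data_lines("common_phrases.txt")))


def load_default_stop_words() -> frozenset[str]:
    return frozenset(_read_data_lines("stop_words.txt"))


def load_default_triggers() -> tuple[str, ...]:
    return tuple(_read_data_lines("negation_triggers.txt"))


@dataclass(frozen=True)
class TokenBag:
    """Unordered unique-token feature set for one report.

    Tokens are lowercase, whitespace-free, and exclude stop words —
    presence/absence only, no counts.
    """

    features: frozenset[str]
    source_report_id: str = ""

    def __post_init__(self) -> None:
        for t in self.features:
            if t != t.lower() or any(c.isspace() for c in t):
                raise ValueError(f"malformed token {t!r}")

    def __contains__(self, token: str) -> bool:
        return token in self.features

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(sorted(self.features))


@dataclass(frozen=True)
class PreprocessConfig:
    """Resources and knobs for the preprocessing pipeline."""

    phrases: PhraseList = field(default_factory=load_default_phrases)
    stop_words: frozenset[str] = field(default_factory=load_default_stop_words)
    negation_triggers: tuple[str, ...] = field(default_factory=load_default_triggers)
    scope_breakers: frozenset[str] = DEFAULT_SCOPE_BREAKERS
    min_token_len: int = 2
    max_scope_len: int | None = None  # tokens removed per scope; None = to terminator


def merge_common_phrases(text: str, phrases: PhraseList | Iterable[str] | None = None) -> str:
    """Delete internal whitespace of each listed phrase occurrence.

    Matching is case-insensitive and whitespace-normalized (any run of
    whitespace in the text matches the single spaces of the phrase);
    surrounding text is untouched.  Longest phrase wins at overlaps
    because phrases are applied in longest-first order.
    """
    if phrases is None:
        phrases = load_default_phrases()
    if not isinstance(phrases, PhraseList):
        phrases = PhraseList(phrases=tuple(phrases))
    out = text
    for phrase in phrases:
        words = [re.escape(w) for w in phrase.split()]
        if len(words) < 2:
            continue
        rx = re.compile(
            r"(?<![A-Za-z0-9])" + r"\s+".join(words) + r"(?![A-Za-z0-9])",
            re.IGNORECASE,
        )
        out = rx.sub(lambda m: re.sub(r"\s+", "", m.group(0)), out)
    return out


_TOKEN_STREAM_RE = re.compile(r"[A-Za-z0-9']+|[.;:]|\S")


def remove_negated(
    text: str,
    triggers: Sequence[str] | None = None,
    terminators: Iterable[str] | None = None,
    max_scope_len: int | None = None,
) -> str:
    """Delete each negation trigger and its scope from the text.

    A scope runs from the trigger to (exclusive) the first terminator: a
    sentence-ending punctuation mark (. ; :), a scope-breaking
    conjunction ("but", "however", "although"), or end of text.
    Multi-word triggers ("negative for", "ruled out") are matched before
    single-word ones.  Text outside negation scopes is unchanged up to
    whitespace normalization.
    """
    if triggers is None:
        triggers = load_default_triggers()
    breakers = DEFAULT_SCOPE_BREAKERS if terminators is None else frozenset(
        t for t in terminators if t not in SENTENCE_TERMINATORS
    )
    punct = SENTENCE_TERMINATORS if terminators is None else frozenset(
        t for t in terminators if t in SENTENCE_TERMINATORS
    ) or SENTENCE_TERMINATORS

    multi = [tuple(t.lower().split()) for t in triggers if " " in t]
    multi.sort(key=len, reverse=True)
    single = {t.lower() for t in triggers if " " not in t}

    tokens = _TOKEN_STREAM_RE.findall(text)
    lowered = [t.lower() for t in tokens]
    out: list[str] = []
    i = 0
    n = len(tokens)
    while i < n:
        matched_len = 0
        for mt in multi:
            if tuple(lowered[i : i + len(mt)]) == mt:
                matched_len = len(mt)
                break
        if matched_len == 0 and lowered[i] in single:
            matched_len = 1
        if matched_len:
            i += matched_len
            removed = 0
            while i < n:
                tok = lowered[i]
                if tok in punct or tok in breakers:
                    break
                if max_scope_len is not None and removed >= max_scope_len:
                    break
                i += 1
                removed += 1
            continue
        out.append(tokens[i])
        i += 1
    return " ".join(out)


def remove_stop_words(
    tokens: Sequence[str], stop_words: Iterable[str] | None = None
) -> list[str]:
    """Drop every stop word, preserving order of the rest."""
    if stop_words is None:
        stop_words = load_default_stop_words()
    stop = set(stop_words)
    return [t for t in tokens if t not in stop]


def tokenize(text: str, min_token_len: int = 2) -> list[str]:
    """Split on any non-alphanumeric character; drop pure digits and
    tokens shorter than ``min_token_len`` (keeps PHI-ish numerics and
    stray single letters out of the vocabulary)."""
    raw = re.findall(r"[a-z0-9]+", text.lower())
    return [t for t in raw if len(t) >= min_token_len and not t.isdigit()]


def to_token_bag(
    text: str, config: PreprocessConfig | None = None, source_report_id: str = ""
) -> TokenBag:
    """Run the full pipeline and return the unique-token feature set.

    An empty bag is a valid result — it is exactly what a fully negated
    normal report should produce.
    """
    if config is None:
        config = PreprocessConfig()
    lowered = text.lower()
    merged = merge_common_phrases(lowered, config.phrases)
    unnegated = remove_negated(
        merged,
        triggers=config.negation_triggers,
        terminators=SENTENCE_TERMINATORS | config.scope_breakers,
        max_scope_len=config.max_scope_len,
    )
    tokens = tokenize(unnegated, min_token_len=config.min_token_len)
    kept = remove_stop_words(tokens, config.stop_words)
    return TokenBag(features=frozenset(kept), source_report_id=source_report_id)
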