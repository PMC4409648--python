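"""Impression-section extraction and PHI scrubbing.

Radiology reports conventionally end with an Impression section — the
radiologist's own summary and prioritization of the findings.  The
classifier operates on that section alone; when no recognized header is
present the whole report body is used instead.  Extracted text is then
scrubbed of residual PHI-like strings (dates, phone numbers, long digit
runs, and a configurable name/facility lexicon).  The scrubber is a
simplified stand-in, NOT a certified de-identifier.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

from .corpus_io import ClinicalReport

logger = logging.getLogger("radtriage")

#: Default section headers, in priority order.  The first pattern that
#: matches anywhere in the report wins.
DEFAULT_HEADERS: tuple[str, ...] = (
    "IMPRESSION",
    "CONCLUSION",
    "IMPRESSIONS",
    "FINDINGS AND IMPRESSION",
)

#: A line that starts a new all-caps section, e.g. "SIGNED:" — ends the
#: extracted impression.
_SECTION_END_RE = re.compile(r"^[A-Z][A-Z /]{2,}:")

#: Labeled default PHI patterns.  Order matters only for readability;
#: every pattern is applied at every pass.
DEFAULT_PHI_PATTERNS: tuple[tuple[str, str], ...] = (
    ("date_slash", r"\b\d{1,2}[/-]\d{1,2}[/-]\d{2,4}\b"),
    ("date_iso", r"\b\d{4}-\d{2}-\d{2}\b"),
    (
        "date_month",
        r"\b(?:jan|feb|mar|apr|may|jun|jul|aug|sep|oct|nov|dec)[a-z]*\.?\s+"
        r"\d{1,2}(?:\s*,)?\s+\d{4}\b",
    ),
    ("phone", r"\(?\b\d{3}\)?[-. ]\d{3}[-. ]\d{4}\b"),
    ("mrn_digit_run", r"\b\d{5,}\b"),
)


def load_phi_lexicon() -> frozenset[str]:
    """Names/facilities shipped with the package (synthetic entries)."""
    text = (
        resources.files("radtriage").joinpath("data/phi_lexicon.txt").read_text("utf-8")
    )
    return frozenset(
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


@dataclass(frozen=True)
class ImpressionSection:
    """Extracted impression text, scrubbed of PHI-like strings."""

    text: str
    header_found: bool
    header_matched: Optional[str] = None


def _compile_header(header: str) -> re.Pattern[str]:
    # Header at start of a line, case-insensitive, optionally followed by
    # a colon.  \b keeps "IMPRESSION" from matching "IMPRESSIONS:".
    words = re.escape(header).replace("\\ ", r"\s+")
    return re.compile(rf"^[ \t]*({words})\b[ \t]*:?", re.IGNORECASE | re.MULTILINE)


def scrub_phi(
    text: str,
    patterns: Sequence[tuple[str, str]] | None = None,
    lexicon: Iterable[str] | None = None,
) -> str:
    """Replace every PHI-pattern match with a single space.

    Applied to a fixpoint so the operation is idempotent even when a
    removal abuts two fragments into a new match.  Never introduces
    alphanumeric characters.
    """
    if patterns is None:
        patterns = DEFAULT_PHI_PATTERNS
    if lexicon is None:
        lexicon = load_phi_lexicon()
    compiled = [re.compile(rx, re.IGNORECASE) for _label, rx in patterns]
    for entry in sorted(lexicon, key=len, reverse=True):
        entry = entry.strip()
        if entry:
            compiled.append(
                re.compile(
                    r"(?<![A-Za-z0-9])"
                    + re.escape(entry).replace("\\ ", r"\s+")
                    + r"(?![A-Za-z0-9])",
                    re.IGNORECASE,
                )
            )
    prev = None
    current = text
    while current != prev:
        prev = current
        for rx in compiled:
            current = rx.sub(" ", current)
    return current


def extract_impression(
    report: ClinicalReport,
    headers: Sequence[str] | None = None,
    scrub: bool = True,
    phi_patterns: Sequence[tuple[str, str]] | None = None,
    phi_lexicon: Iterable[str] | None = None,
) -> ImpressionSection:
    """Extract the impression section, falling back to the whole body.

    The first header pattern (in priority order) matching at the start of
    a line wins; the section runs from the end of the matched header to
    the next all-caps section header line or end of document.  By default
    the extracted text is PHI-scrubbed before being returned.
    """
    raw = report.raw_text
    if not raw.strip():
        raise ValueError(f"report {report.report_id!r} has empty text")
    if headers is None:
        headers = DEFAULT_HEADERS

    header_found = False
    header_matched: Optional[str] = None
    text = raw
    for header in headers:
        m = _compile_header(header).search(raw)
        if m is None:
            continue
        header_found = True
        header_matched = m.group(1)
        tail = raw[m.end():]
        # Section runs to the next all-caps header line (tail starts
        # mid-line, right after the matched header, so a position-0 match
        # can only be a header jammed against ours and still ends us).
        m_end = re.search(_SECTION_END_RE.pattern, tail, re.MULTILINE)
        text = tail[: m_end.start()] if m_end else tail
        break

    text = text.strip()
    if scrub:
        text = scrub_phi(text, patterns=phi_patterns, lexicon=phi_lexicon)
    if header_found and not text.strip():
        logger.warning(
            "report %s: impression header %r with no following text",
            report.report_id,
            header_matched,
        )
    return ImpressionSection(
        text=text, header_found=header_found, header_matched=header_matched
    )
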