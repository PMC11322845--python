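"""Substring matching of library terms and conflict resolution.

Each narrative is normalized and scanned for every library surface as a
plain substring — deliberately without word boundaries, because the
library contains sub-word and symbol surfaces (",helmet,", "whelmet",
"+helmemt") that only work as raw substrings.  Substring collisions
(e.g. "helmeted" inside "unhelmeted" firing both the wearing and
not-wearing indicators) are absorbed by deterministic precedence rules,
not by the matcher.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from helmetcoder.term_library import (
    CATEGORY_ORDER,
    HelmetStatus,
    TermLibrary,
    normalize_text,
)

logger = logging.getLogger(__name__)


class DuplicateCaseError(ValueError):
    """Raised when a corpus contains a repeated case identifier."""


@dataclass(frozen=True)
class NarrativeRecord:
    """One ED visit: case id, free-text narrative, optional extras."""

    case_id: str
    narrative: str
    product_codes: tuple[int, ...] | None = None
    status: HelmetStatus | None = None


@dataclass(frozen=True)
class TermMatch:
    """A single phrase hit: which phrase, its category, where it starts."""

    surface: str
    category: HelmetStatus
    offset: int  # character offset in the normalized narrative


@dataclass(frozen=True)
class MatchResult:
    """All library hits for one record plus per-category indicators."""

    case_id: str
    fired: Mapping[HelmetStatus, bool]
    matches: tuple[TermMatch, ...]


def match_terms(record: NarrativeRecord, library: TermLibrary) -> MatchResult:
    """Scan a narrative for every library surface as a plain substring.

    All matches across all categories are kept, including overlapping
    and nested hits; repeated hits of one phrase are recorded once per
    start offset.  The per-category indicator ``fired[c]`` is true iff
    at least one phrase of category ``c`` matched.
    """
    text = normalize_text(record.narrative)
    matches: list[TermMatch] = []
    for entry in library.entries:
        start = text.find(entry.surface)
        while start != -1:
            matches.append(TermMatch(entry.surface, entry.category, start))
            start = text.find(entry.surface, start + 1)
    fired = {
        category: any(m.category is category for m in matches)
        for category in CATEGORY_ORDER
    }
    return MatchResult(record.case_id, fired, tuple(matches))


def resolve(fired: Mapping[HelmetStatus, bool]) -> HelmetStatus:
    """Collapse co-firing category indicators into one helmet status.

    Deterministic truth table over the three indicators:

    ========  ===========  =======  ===========
    wearing   not wearing  unknown  result
    ========  ===========  =======  ===========
    no        no           no       UNKNOWN
    yes       no           no       WEARING
    no        yes          no       NOT_WEARING
    no        no           yes      UNKNOWN
    yes       no           yes      UNKNOWN
    yes       yes          no       NOT_WEARING
    no        yes          yes      NOT_WEARING
    yes       yes          yes      NOT_WEARING
    ========  ===========  =======  ===========

    The affirmation+unknown conflict is coded unknown; any conflict
    involving a negation is coded not wearing (negations like
    "unhelmeted" and "not wearing helmet" contain affirmation surfaces
    as substrings, so this precedence is what makes raw substring
    matching sound).  The all-three case composes the two pairwise
    negation rules and is likewise coded not wearing.  No indicator at
    all means the narrative never mentions a helmet: unknown.
    """
    wearing = bool(fired[HelmetStatus.WEARING])
    not_wearing = bool(fired[HelmetStatus.NOT_WEARING])
    unknown = bool(fired[HelmetStatus.UNKNOWN])
    if not_wearing:
        return HelmetStatus.NOT_WEARING
    if unknown:
        return HelmetStatus.UNKNOWN
    if wearing:
        return HelmetStatus.WEARING
    return HelmetStatus.UNKNOWN


@dataclass(frozen=True)
class ClassificationResult:
    """Labeled corpus plus full audit trail of every phrase hit."""

    records: tuple[NarrativeRecord, ...]  # input order, status filled in
    audit: pd.DataFrame  # columns: case_id, phrase, category, offset
    counts: Mapping[HelmetStatus, int]

    @property
    def labels(self) -> tuple[HelmetStatus, ...]:
        return tuple(r.status for r in self.records)


def classify_batch(
    records: Sequence[NarrativeRecord], library: TermLibrary
) -> ClassificationResult:
    """Assign exactly one helmet status to every record.

    Input order is preserved; duplicate case ids abort with an error
    naming the first offending id; category counts sum to the corpus
    size.  The audit table has one row per phrase hit.
    """
    seen: set[str] = set()
    for record in records:
        if record.case_id in seen:
            raise DuplicateCaseError(
                f"duplicate case id in corpus: {record.case_id!r}"
            )
        seen.add(record.case_id)

    labeled: list[NarrativeRecord] = []
    audit_rows: list[tuple[str, str, str, int]] = []
    counts = {category: 0 for category in CATEGORY_ORDER}
    conflicts = 0
    for record in records:
        result = match_terms(record, library)
        status = resolve(result.fired)
        if sum(result.fired.values()) > 1:
            conflicts += 1
            logger.info(
                "conflict resolution for %s: fired=%s -> %s",
                record.case_id,
                [c.name for c in CATEGORY_ORDER if result.fired[c]],
                status.name,
            )
        counts[status] += 1
        labeled.append(replace(record, status=status))
        for m in result.matches:
            audit_rows.append((record.case_id, m.surface, m.category.name, m.offset))
    audit = pd.DataFrame(
        audit_rows, columns=["case_id", "phrase", "category", "offset"]
    )
    logger.info(
        "classified %d records (%d with conflicting indicators): %s",
        len(labeled),
        conflicts,
        {c.name: n for c, n in counts.items()},
    )
    return ClassificationResult(tuple(labeled), audit, counts)


def filter_micromobility(
    records: Sequence[NarrativeRecord],
    code_map: Mapping[int, str],
) -> tuple[list[NarrativeRecord], int]:
    """Drop records whose product codes map to more than one mode.

    ``code_map`` maps product codes to micromobility mode labels
    (e.g. bicycle, e-bike, scooter, hoverboard); codes absent from the
    map are ignored.  A record whose mapped codes resolve to more than
    one distinct mode is excluded, so each kept record is attributable
    to the single mode of its first mapped product code.  Returns the
    kept records and the exclusion count.
    """
    if not code_map:
        logger.warning("empty product-code map: micromobility filter is a no-op")
        return list(records), 0
    kept: list[NarrativeRecord] = []
    excluded = 0
    for record in records:
        if record.product_codes is None:
            raise ValueError(
                f"record {record.case_id!r} has no product codes but "
                "micromobility filtering was requested"
            )
        modes = {
            code_map[code]
            for code in record.product_codes
            if code in code_map
        }
        if len(modes) > 1:
            excluded += 1
        else:
            kept.append(record)
    logger.info(
        "micromobility filter: kept %d, excluded %d multi-mode records",
        len(kept),
        excluded,
    )
    return kept, excluded


# ---------------------------------------------------------------------------
# DataFrame front end (NEISS-shaped CSV corpora)

ID_COLUMN = "cpsc_case_number"
NARRATIVE_COLUMN = "narrative_1"
STATUS_COLUMN = "helmet_status"


def records_from_frame(
    frame: pd.DataFrame,
    id_column: str = ID_COLUMN,
    narrative_column: str = NARRATIVE_COLUMN,
) -> list[NarrativeRecord]:
    """Build a record corpus from a NEISS-shaped DataFrame."""
    for column in (id_column, narrative_column):
        if column not in frame.columns:
            raise KeyError(f"input is missing required column {column!r}")
    return [
        NarrativeRecord(str(case_id), "" if pd.isna(narrative) else str(narrative))
        for case_id, narrative in zip(frame[id_column], frame[narrative_column])
    ]


def classify_frame(
    frame: pd.DataFrame,
    library: TermLibrary,
    id_column: str = ID_COLUMN,
    narrative_column: str = NARRATIVE_COLUMN,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify a DataFrame corpus; return (labeled frame, audit frame).

    The labeled frame is the input plus a ``helmet_status`` column;
    all other columns pass through untouched.
    """
    records = records_from_frame(frame, id_column, narrative_column)
    result = classify_batch(records, library)
    labeled = frame.copy()
    labeled[STATUS_COLUMN] = [status.label for status in result.labels]
    return labeled, result.audit
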