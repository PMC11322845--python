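"""Categorized phrase library driving helmet-status classification.

A term library is three ordered lists of surface phrases, one per
helmet-status level.  Phrases are matched later as raw substrings, so
they are stored exactly as written apart from a minimal normalization
(lower-casing and whitespace collapsing).  Symbol tokens such as
``"+helmet"``, ``"?helmet"`` or ``",helmet,"`` are legitimate surfaces
and survive normalization untouched.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

logger = logging.getLogger(__name__)

_WS_RUN = re.compile(r"\s+")

#: YAML keys of the library config schema, in fixed category order.
_CONFIG_KEYS = ("wearing", "not_wearing", "unknown")


class LibraryError(ValueError):
    """Raised when a term-library file violates the schema or its invariants."""


class HelmetStatus(enum.Enum):
    """Three-level helmet-status outcome assigned to each ED visit."""

    WEARING = "wearing helmet"
    NOT_WEARING = "not wearing helmet"
    UNKNOWN = "helmet not mentioned/unknown"

    @property
    def label(self) -> str:
        """Serialized label used in CSV output."""
        return self.value

    @classmethod
    def from_label(cls, label: str) -> "HelmetStatus":
        for status in cls:
            if status.value == label:
                return status
        raise ValueError(f"unknown helmet-status label: {label!r}")

    def __repr__(self) -> str:  # keep audit tables compact
        return self.name


#: Fixed category order used for contingency tables and reports.
CATEGORY_ORDER: tuple[HelmetStatus, ...] = (
    HelmetStatus.WEARING,
    HelmetStatus.NOT_WEARING,
    HelmetStatus.UNKNOWN,
)


def normalize_text(raw: str) -> str:
    """Normalize text for matching: lower-case, collapse whitespace runs.

    Punctuation and symbols are preserved — library surfaces include
    tokens like ``"+helmet"`` and ``"w/o helmet"`` whose punctuation is
    the signal.  Total function: any string in, normalized string out.
    """
    return _WS_RUN.sub(" ", raw.strip()).lower()


@dataclass(frozen=True)
class TermEntry:
    """One surface phrase assigned to one helmet-status category."""

    surface: str
    category: HelmetStatus

    def __post_init__(self) -> None:
        if not self.surface.strip():
            raise LibraryError("term surface is empty after trimming")
        if self.surface != normalize_text(self.surface):
            raise LibraryError(
                f"term surface not normalized: {self.surface!r}"
            )


@dataclass(frozen=True)
class TermLibrary:
    """Validated, normalized collection of categorized term entries.

    Invariants enforced at construction: no duplicate (surface,
    category) pair, and no surface listed under two categories —
    conflicts between categories are the classifier's job to resolve
    via co-firing indicators, never the library's.
    """

    entries: tuple[TermEntry, ...]

    def __post_init__(self) -> None:
        seen: dict[str, HelmetStatus] = {}
        for entry in self.entries:
            prior = seen.get(entry.surface)
            if prior is not None and prior != entry.category:
                raise LibraryError(
                    f"phrase {entry.surface!r} listed under both "
                    f"{prior.name} and {entry.category.name}"
                )
            seen[entry.surface] = entry.category
        if len({(e.surface, e.category) for e in self.entries}) != len(self.entries):
            raise LibraryError("duplicate (surface, category) pair in library")

    @classmethod
    def from_lists(
        cls,
        wearing: Iterable[str] = (),
        not_wearing: Iterable[str] = (),
        unknown: Iterable[str] = (),
    ) -> "TermLibrary":
        """Build a library from three phrase lists.

        Phrases are normalized; repeats within a category are dropped
        with a logged warning.
        """
        entries: list[TermEntry] = []
        for category, phrases in zip(
            CATEGORY_ORDER, (wearing, not_wearing, unknown)
        ):
            seen: set[str] = set()
            for phrase in phrases:
                surface = normalize_text(phrase)
                if not surface:
                    raise LibraryError(
                        f"empty phrase in {category.name} list"
                    )
                if surface in seen:
                    logger.warning(
                        "duplicate phrase %r in %s list; keeping first",
                        surface,
                        category.name,
                    )
                    continue
                seen.add(surface)
                entries.append(TermEntry(surface, category))
        return cls(tuple(entries))

    def surfaces(self, category: HelmetStatus) -> tuple[str, ...]:
        """Ordered phrase list for one category."""
        return tuple(e.surface for e in self.entries if e.category is category)

    @property
    def by_category(self) -> dict[HelmetStatus, tuple[str, ...]]:
        return {c: self.surfaces(c) for c in CATEGORY_ORDER}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, item: tuple[str, HelmetStatus]) -> bool:
        surface, category = item
        return TermEntry(normalize_text(surface), category) in self.entries


def _library_from_mapping(config: Mapping[str, object], origin: str) -> TermLibrary:
    if not isinstance(config, Mapping):
        raise LibraryError(f"{origin}: config root must be a mapping")
    unknown_keys = set(config) - set(_CONFIG_KEYS)
    if unknown_keys:
        raise LibraryError(f"{origin}: unexpected keys {sorted(unknown_keys)}")
    lists: dict[str, list[str]] = {}
    for key in _CONFIG_KEYS:
        value = config.get(key, [])
        if value is None:
            value = []
        if not isinstance(value, list) or not all(
            isinstance(p, str) for p in value
        ):
            raise LibraryError(f"{origin}: {key!r} must be a list of phrases")
        lists[key] = value
    return TermLibrary.from_lists(
        wearing=lists["wearing"],
        not_wearing=lists["not_wearing"],
        unknown=lists["unknown"],
    )


def load_library(path: str | Path) -> TermLibrary:
    """Load and validate a term library from a YAML (or JSON) config file.

    The schema is a mapping with keys ``wearing``, ``not_wearing`` and
    ``unknown``, each a list of phrases.  Phrases are normalized on
    load; within-category repeats are deduplicated with a warning; a
    phrase under two categories is a hard error naming the phrase.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"term-library file not found: {path}")
    with path.open("r", encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    return _library_from_mapping(config, str(path))


def save_library(library: TermLibrary, path: str | Path) -> None:
    """Serialize a library to the YAML config schema (round-trip stable)."""
    payload = {
        "wearing": list(library.surfaces(HelmetStatus.WEARING)),
        "not_wearing": list(library.surfaces(HelmetStatus.NOT_WEARING)),
        "unknown": list(library.surfaces(HelmetStatus.UNKNOWN)),
    }
    Path(path).write_text(
        yaml.safe_dump(payload, sort_keys=False, allow_unicode=True),
        encoding="utf-8",
    )


def load_default_library() -> TermLibrary:
    """Load the packaged default term library.

    The default library is the curated phrase list developed by
    iterative review of micromobility-injury narratives: affirmation
    phrases ("helmeted", "w/ helmet", "+helmet", ...), negations
    ("no helmet", "unhelmeted", "w/o helmet", ...), and explicit
    unknown markers ("?helmet", "helmet ns", "unk helmet", ...),
    including observed misspellings.  Deterministic: repeated calls
    yield element-wise identical libraries.
    """
    ref = resources.files("helmetcoder.data").joinpath("default_terms.yaml")
    config = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return _library_from_mapping(config, "default_terms.yaml")
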