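"""Synthetic NEISS-style narratives with known truth, and imperfect raters.

The generator emulates the shape of real ED surveillance narratives —
short, upper-case, telegraphic strings like

    "23YOM FELL OFF BICYCLE NO HELMET DX: CLOSED HEAD INJURY"

— by filling a fixed template with distractor incident fragments and,
depending on the drawn truth category, a helmet phrase sampled from the
term library.  Records drawn as UNMENTIONED carry no helmet phrase at
all and their truth is unknown, mirroring the dominant category of real
corpora.  An optional single-character corruption of the inserted
phrase produces out-of-library variants ("was not wearig a helmet",
"+helmemt" style) that a strict substring matcher must miss.

The rater error model reproduces the characteristic failure modes of a
generative-model rater: flipping negations to affirmations
("unhelmeted" read as wearing), labeling explicit unknown markers as
wearing, and residual symmetric noise.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from helmetcoder.term_library import (
    HelmetStatus,
    TermLibrary,
    load_default_library,
    normalize_text,
)


class GenClass(enum.Enum):
    """Generation stratum: what the narrative says about the helmet."""

    WEARING = "wearing"
    NOT_WEARING = "not_wearing"
    UNKNOWN_MENTIONED = "unknown_mentioned"  # explicit unknown marker
    UNMENTIONED = "unmentioned"  # helmet never mentioned

    @property
    def truth(self) -> HelmetStatus:
        if self is GenClass.WEARING:
            return HelmetStatus.WEARING
        if self is GenClass.NOT_WEARING:
            return HelmetStatus.NOT_WEARING
        return HelmetStatus.UNKNOWN


#: Default truth mixture.  Shares follow the marginal composition of a
#: 54,569-record micromobility corpus coded by string search: ~9.3%
#: wearing, ~11.0% not wearing, ~79.7% unknown, of which roughly 1.8
#: points carry an explicit unknown marker and the rest never mention a
#: helmet.
DEFAULT_MIXTURE: dict[GenClass, float] = {
    GenClass.WEARING: 0.093,
    GenClass.NOT_WEARING: 0.110,
    GenClass.UNKNOWN_MENTIONED: 0.018,
    GenClass.UNMENTIONED: 0.779,
}

#: Distractor fragments.  None contains "helmet" or any library
#: surface, so only the inserted phrase can fire an indicator.
DEFAULT_ACTIONS = (
    "FELL OFF",
    "FELL FROM",
    "LOST CONTROL OF",
    "STRUCK CURB RIDING",
    "COLLIDED WITH CAR ON",
    "THROWN FROM",
    "CRASHED",
)
DEFAULT_PRODUCTS = (
    "BICYCLE",
    "BIKE",
    "EBIKE",
    "E-SCOOTER",
    "SCOOTER",
    "HOVERBOARD",
)
DEFAULT_DIAGNOSES = (
    "CLOSED HEAD INJURY",
    "CONCUSSION",
    "WRIST FX",
    "CLAVICLE FX",
    "FACIAL ABRASIONS",
    "SHOULDER CONTUSION",
    "SCALP LACERATION",
)

#: Product codes paired 1:1 with DEFAULT_PRODUCTS, and the mode map a
#: config file would supply for micromobility filtering.
DEFAULT_PRODUCT_CODES = (5040, 5040, 5042, 1329, 1329, 5044)
DEFAULT_CODE_MAP = {5040: "bicycle", 5042: "e-bike", 1329: "scooter", 5044: "hoverboard"}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic corpus generator.

    ``mixture`` gives the probability of each generation stratum and
    must sum to 1.  ``misspelling_rate`` is the probability that an
    inserted helmet phrase is corrupted by one random character edit,
    taking it out of the library.  All randomness flows from ``seed``.
    """

    n: int
    mixture: Mapping[GenClass, float] = field(
        default_factory=lambda: dict(DEFAULT_MIXTURE)
    )
    phrase_source: TermLibrary | None = None  # None -> default library
    misspelling_rate: float = 0.0
    seed: int = 0
    actions: Sequence[str] = DEFAULT_ACTIONS
    products: Sequence[str] = DEFAULT_PRODUCTS
    diagnoses: Sequence[str] = DEFAULT_DIAGNOSES

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("corpus size must be non-negative")
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture must sum to 1, got {total}")
        if any(p < 0 for p in self.mixture.values()):
            raise ValueError("mixture probabilities must be non-negative")
        if not 0.0 <= self.misspelling_rate <= 1.0:
            raise ValueError("misspelling_rate must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticRecord:
    """Generated narrative with its ground truth and provenance."""

    case_id: str
    narrative: str  # upper-case telegraphic text
    truth: HelmetStatus
    inserted_phrase: str  # normalized phrase, or "" for UNMENTIONED
    corrupted: bool
    product_code: int


def _corrupt_phrase(phrase: str, rng: np.random.Generator) -> str:
    """One random character edit: substitution, deletion or transposition.

    Mirrors the single-edit misspellings seen in real narratives
    ("wearig", "helmemt").  Guaranteed to return a string different
    from the input.
    """
    chars = list(phrase)
    for _ in range(100):
        edited = list(chars)
        op = rng.integers(3)
        if op == 0:  # substitution
            i = int(rng.integers(len(edited)))
            edited[i] = chr(ord("a") + int(rng.integers(26)))
        elif op == 1 and len(edited) > 1:  # deletion
            i = int(rng.integers(len(edited)))
            del edited[i]
        elif len(edited) > 1:  # transposition
            i = int(rng.integers(len(edited) - 1))
            edited[i], edited[i + 1] = edited[i + 1], edited[i]
        candidate = "".join(edited)
        if candidate != phrase and candidate.strip():
            return candidate
    raise RuntimeError(f"could not corrupt phrase {phrase!r}")  # pragma: no cover


def generate_corpus(config: GeneratorConfig) -> list[SyntheticRecord]:
    """Generate ``config.n`` synthetic records; pure function of the seed.

    Each narrative follows the template
    ``<AGE><SEX> <ACTION> <PRODUCT> [<PHRASE>] DX: <DIAGNOSIS>``,
    upper-cased.  The phrase is drawn uniformly from the library list
    of the drawn stratum; UNMENTIONED inserts nothing.  With
    probability ``misspelling_rate`` the phrase is corrupted by one
    character edit and the record is flagged ``corrupted``.
    """
    library = config.phrase_source or load_default_library()
    rng = np.random.default_rng(config.seed)
    strata = list(config.mixture)
    probs = np.array([config.mixture[s] for s in strata], dtype=float)
    phrase_lists = {
        GenClass.WEARING: library.surfaces(HelmetStatus.WEARING),
        GenClass.NOT_WEARING: library.surfaces(HelmetStatus.NOT_WEARING),
        GenClass.UNKNOWN_MENTIONED: library.surfaces(HelmetStatus.UNKNOWN),
    }

    records: list[SyntheticRecord] = []
    for i in range(config.n):
        stratum = strata[int(rng.choice(len(strata), p=probs))]
        age = int(rng.integers(5, 86))
        sex = "M" if rng.random() < 0.5 else "F"
        action = config.actions[int(rng.integers(len(config.actions)))]
        product_idx = int(rng.integers(len(config.products)))
        product = config.products[product_idx]
        diagnosis = config.diagnoses[int(rng.integers(len(config.diagnoses)))]

        phrase = ""
        corrupted = False
        if stratum is not GenClass.UNMENTIONED:
            pool = phrase_lists[stratum]
            if not pool:
                raise ValueError(
                    f"phrase requested from empty {stratum.truth.name} list"
                )
            phrase = pool[int(rng.integers(len(pool)))]
            inserted = phrase
            if rng.random() < config.misspelling_rate:
                inserted = _corrupt_phrase(phrase, rng)
                corrupted = True
            parts = [f"{age}YO{sex}", action, product, inserted.upper(),
                     "DX:", diagnosis]
        else:
            parts = [f"{age}YO{sex}", action, product, "DX:", diagnosis]

        narrative = " ".join(parts)
        records.append(
            SyntheticRecord(
                case_id=f"{200000000 + i}",
                narrative=narrative,
                truth=stratum.truth,
                inserted_phrase=phrase,
                corrupted=corrupted,
                product_code=DEFAULT_PRODUCT_CODES[product_idx]
                if product_idx < len(DEFAULT_PRODUCT_CODES)
                else 0,
            )
        )
    return records


@dataclass(frozen=True)
class RaterErrorModel:
    """Stochastic label corruption emulating an imperfect rater.

    Transitions are applied at most once per record, in fixed order:

    1. ``negation_flip`` — a true not-wearing record is labeled wearing
       (a negation like "w/o helmet" read as an affirmation);
    2. ``unknown_miss`` — a record whose narrative carries an explicit
       unknown marker is labeled wearing ("?helmet" read as wearing);
    3. ``random_noise`` — the label is replaced by one of the other two
       categories, uniformly.
    """

    negation_flip: float = 0.0
    unknown_miss: float = 0.0
    random_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("negation_flip", "unknown_miss", "random_noise"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")


_OTHER = {
    HelmetStatus.WEARING: (HelmetStatus.NOT_WEARING, HelmetStatus.UNKNOWN),
    HelmetStatus.NOT_WEARING: (HelmetStatus.WEARING, HelmetStatus.UNKNOWN),
    HelmetStatus.UNKNOWN: (HelmetStatus.WEARING, HelmetStatus.NOT_WEARING),
}


def simulate_rater(
    corpus: Sequence[SyntheticRecord], model: RaterErrorModel
) -> list[HelmetStatus]:
    """Draw one label per record from the error model; pure in ``model.seed``."""
    rng = np.random.default_rng(model.seed)
    labels: list[HelmetStatus] = []
    for record in corpus:
        label = record.truth
        if (
            record.truth is HelmetStatus.NOT_WEARING
            and rng.random() < model.negation_flip
        ):
            label = HelmetStatus.WEARING
        elif (
            record.truth is HelmetStatus.UNKNOWN
            and record.inserted_phrase
            and rng.random() < model.unknown_miss
        ):
            label = HelmetStatus.WEARING
        elif rng.random() < model.random_noise:
            label = _OTHER[label][int(rng.integers(2))]
        labels.append(label)
    return labels


def transition_matrix(model: RaterErrorModel) -> dict[GenClass, dict[HelmetStatus, float]]:
    """Per-stratum label distribution implied by the error model."""
    f, u, r = model.negation_flip, model.unknown_miss, model.random_noise
    w, n, unk = HelmetStatus.WEARING, HelmetStatus.NOT_WEARING, HelmetStatus.UNKNOWN

    def noisy(truth: HelmetStatus, keep: float) -> dict[HelmetStatus, float]:
        other = _OTHER[truth]
        row = {truth: keep * (1 - r)}
        for category in other:
            row[category] = row.get(category, 0.0) + keep * r / 2
        return row

    rows: dict[GenClass, dict[HelmetStatus, float]] = {}
    # wearing: noise only
    rows[GenClass.WEARING] = noisy(w, 1.0)
    # not wearing: flip to wearing, else noise
    row = noisy(n, 1 - f)
    row[w] = row.get(w, 0.0) + f
    rows[GenClass.NOT_WEARING] = row
    # unknown with explicit marker: miss to wearing, else noise
    row = noisy(unk, 1 - u)
    row[w] = row.get(w, 0.0) + u
    rows[GenClass.UNKNOWN_MENTIONED] = row
    # unmentioned: noise only
    rows[GenClass.UNMENTIONED] = noisy(unk, 1.0)
    for row in rows.values():
        for category in (w, n, unk):
            row.setdefault(category, 0.0)
    return rows


def expected_kappa(
    mixture: Mapping[GenClass, float], model: RaterErrorModel
) -> float:
    """Exact large-sample Cohen kappa between truth and the modeled rater.

    Builds the 3x3 joint distribution (truth marginal x transition
    matrix), collapsing both unknown strata onto the unknown truth
    level, and evaluates kappa in closed form.
    """
    order = (HelmetStatus.WEARING, HelmetStatus.NOT_WEARING, HelmetStatus.UNKNOWN)
    index = {category: i for i, category in enumerate(order)}
    rows = transition_matrix(model)
    joint = np.zeros((3, 3))
    for stratum, pi in mixture.items():
        i = index[stratum.truth]
        for category, prob in rows[stratum].items():
            joint[i, index[category]] += pi * prob
    joint /= joint.sum()
    po = float(np.trace(joint))
    pe = float(joint.sum(axis=1) @ joint.sum(axis=0))
    if pe >= 1.0 - 1e-15:
        raise ZeroDivisionError("degenerate joint distribution: pe = 1")
    return (po - pe) / (1 - pe)


def corpus_to_frame(corpus: Sequence[SyntheticRecord]):
    """Synthetic corpus as a NEISS-shaped DataFrame (classifier dialect)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "cpsc_case_number": [r.case_id for r in corpus],
            "narrative_1": [r.narrative for r in corpus],
            "product_code": [r.product_code for r in corpus],
            "truth": [r.truth.label for r in corpus],
            "corrupted": [r.corrupted for r in corpus],
        }
    )
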