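"""Agreement and validity statistics for categorical helmet-status labels.

Implements the evaluation layer: K×K contingency tables, Cohen kappa
with an asymptotic 95% CI, Fleiss kappa with a large-sample z test for
multi-session test-retest reliability, qualitative kappa bands,
one-vs-rest precision/recall/F1 against a criterion standard, and the
stratified validation sampler.

Cohen kappa is chance-corrected agreement between two raters,

    kappa = (p_o - p_e) / (1 - p_e),

with p_o the observed agreement proportion and p_e the agreement
expected from the raters' marginals.  The standard error follows the
asymptotic variance of Fleiss, Cohen & Everitt (1969); a simpler
classical SE is available behind a flag.  Fleiss kappa generalizes to
m raters per item, with the large-sample null SE of Fleiss (1971).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import precision_recall_fscore_support

logger = logging.getLogger(__name__)


class UndefinedKappaError(ZeroDivisionError):
    """Expected agreement is 1 (both raters constant on one category)."""


@dataclass(frozen=True)
class ContingencyTable:
    """K×K cross-classification of two label sequences.

    Rows are rater A, columns rater B, in the fixed ``labels`` order.
    """

    labels: tuple[Hashable, ...]
    counts: np.ndarray  # (K, K) non-negative integers

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        k = len(self.labels)
        if counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("contingency counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.labels, self.counts.T)


def build_contingency(
    labels_a: Sequence[Hashable],
    labels_b: Sequence[Hashable],
    category_order: Sequence[Hashable],
) -> ContingencyTable:
    """Cross-tabulate two equal-length label sequences.

    Cell (i, j) counts records labeled ``category_order[i]`` by A and
    ``category_order[j]`` by B.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError(
            f"label sequences differ in length: {len(labels_a)} vs {len(labels_b)}"
        )
    index = {category: i for i, category in enumerate(category_order)}
    counts = np.zeros((len(index), len(index)), dtype=np.int64)
    for a, b in zip(labels_a, labels_b):
        if a not in index:
            raise ValueError(f"label {a!r} not in category order")
        if b not in index:
            raise ValueError(f"label {b!r} not in category order")
        counts[index[a], index[b]] += 1
    return ContingencyTable(tuple(category_order), counts)


@dataclass(frozen=True)
class KappaResult:
    """Cohen kappa point estimate with its 95% CI and components."""

    kappa: float
    se: float
    ci_low: float
    ci_high: float
    po: float
    pe: float


def cohen_kappa(table: ContingencyTable, se_method: str = "fce") -> KappaResult:
    """Cohen kappa with an asymptotic 95% CI from a contingency table.

    ``se_method="fce"`` (default) uses the full asymptotic variance of
    Fleiss, Cohen & Everitt (1969); ``se_method="simple"`` uses the
    classical sqrt(po(1-po)) / ((1-pe) sqrt(n)) approximation.  A table
    where both raters are constant on the same category has expected
    agreement 1 and kappa is undefined — that raises rather than
    silently returning 0 or 1.
    """
    n = table.n
    if n == 0:
        raise ValueError("empty contingency table")
    p = table.counts / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = float(np.trace(p))
    pe = float(row @ col)
    if pe >= 1.0 - 1e-15:
        raise UndefinedKappaError(
            "expected agreement is 1 (both raters constant on one "
            "category); kappa is undefined"
        )
    kappa = (po - pe) / (1 - pe)

    if se_method == "fce":
        diag = np.diag(p)
        a = float(
            np.sum(diag * ((1 - pe) - (row + col) * (1 - po)) ** 2)
        )
        # off-diagonal term: cell (i, j) weighted by (col_i + row_j)^2
        w = (col[:, None] + row[None, :]) ** 2
        off = p * w
        np.fill_diagonal(off, 0.0)
        b = float((1 - po) ** 2 * off.sum())
        c = float((po * pe - 2 * pe + po) ** 2)
        var = (a + b - c) / (n * (1 - pe) ** 4)
        se = math.sqrt(max(var, 0.0))
    elif se_method == "simple":
        se = math.sqrt(po * (1 - po) / n) / (1 - pe)
    else:
        raise ValueError(f"unknown se_method {se_method!r}")

    z = stats.norm.ppf(0.975)
    ci_low = max(kappa - z * se, -1.0)
    ci_high = min(kappa + z * se, 1.0)
    return KappaResult(kappa, se, ci_low, ci_high, po, pe)


@dataclass(frozen=True)
class RatingMatrix:
    """Items × raters categorical grid with no missing cells."""

    items: tuple[Hashable, ...]
    raters: tuple[Hashable, ...]
    ratings: np.ndarray  # (N, m) object array of category labels
    categories: tuple[Hashable, ...]

    def __post_init__(self) -> None:
        ratings = np.asarray(self.ratings, dtype=object)
        if ratings.shape != (len(self.items), len(self.raters)):
            raise ValueError(
                f"ratings must be {len(self.items)}x{len(self.raters)}, "
                f"got {ratings.shape}"
            )
        allowed = set(self.categories)
        for value in ratings.flat:
            if value not in allowed:
                raise ValueError(f"rating {value!r} not in categories")
        object.__setattr__(self, "ratings", ratings)

    @classmethod
    def from_columns(
        cls,
        columns: Mapping[Hashable, Sequence[Hashable]],
        categories: Sequence[Hashable],
        items: Sequence[Hashable] | None = None,
    ) -> "RatingMatrix":
        """Build from one label sequence per rater (aligned by position)."""
        raters = tuple(columns)
        lengths = {len(v) for v in columns.values()}
        if len(lengths) != 1:
            raise ValueError("rater label sequences differ in length")
        (n,) = lengths
        if items is None:
            items = tuple(range(n))
        ratings = np.empty((n, len(raters)), dtype=object)
        for j, rater in enumerate(raters):
            ratings[:, j] = list(columns[rater])
        return cls(tuple(items), raters, ratings, tuple(categories))

    def category_counts(self) -> np.ndarray:
        """(N, K) table: how many raters put each item in each category."""
        index = {category: j for j, category in enumerate(self.categories)}
        counts = np.zeros((len(self.items), len(self.categories)), dtype=np.int64)
        for i in range(self.ratings.shape[0]):
            for value in self.ratings[i]:
                counts[i, index[value]] += 1
        return counts


@dataclass(frozen=True)
class FleissResult:
    """Fleiss kappa with its large-sample null z test."""

    kappa: float
    z: float
    p_value: float
    p_bar: float  # mean per-item agreement
    p_bar_e: float  # chance agreement from pooled category shares


def fleiss_kappa(matrix: RatingMatrix) -> FleissResult:
    """Fleiss kappa over m >= 2 raters with complete ratings.

    Per-item agreement P_i = sum_j n_ij (n_ij - 1) / (m (m - 1)); the
    chance term is sum_j p_j^2 over the pooled category shares.  The z
    statistic uses the large-sample SE under the null of chance-only
    agreement (Fleiss 1971), with a two-sided normal p-value.
    """
    counts = matrix.category_counts()
    n_items, _ = counts.shape
    m = len(matrix.raters)
    if m < 2:
        raise ValueError("fleiss_kappa needs at least 2 raters")
    if n_items < 1:
        raise ValueError("fleiss_kappa needs at least 1 item")
    p_j = counts.sum(axis=0) / (n_items * m)
    p_i = (counts * (counts - 1)).sum(axis=1) / (m * (m - 1))
    p_bar = float(p_i.mean())
    p_bar_e = float((p_j**2).sum())
    if p_bar_e >= 1.0 - 1e-15:
        raise UndefinedKappaError(
            "all ratings fall in a single category; kappa is undefined"
        )
    kappa = (p_bar - p_bar_e) / (1 - p_bar_e)

    q_j = p_j * (1 - p_j)
    var0 = (
        2.0
        / (n_items * m * (m - 1))
        * (q_j.sum() ** 2 - float((q_j * (1 - 2 * p_j)).sum()))
        / q_j.sum() ** 2
    )
    se0 = math.sqrt(max(var0, 0.0))
    z = kappa / se0 if se0 > 0 else math.inf
    p_value = float(2 * stats.norm.sf(abs(z)))
    return FleissResult(kappa, z, p_value, p_bar, p_bar_e)


#: Qualitative agreement bands, lower-edge inclusive except as printed:
#: kappa > 0.90 is "almost perfect"; exactly 0.90 falls in "strong".
_KAPPA_BANDS = (
    (0.90, "almost perfect"),  # exclusive lower edge, handled below
    (0.80, "strong"),
    (0.60, "moderate"),
    (0.40, "weak"),
    (0.21, "minimal"),
    (0.0, "none"),
)


def interpret_kappa(kappa: float) -> str:
    """Map a kappa value to its qualitative agreement band.

    Bands: almost perfect (>0.90), strong (0.80-0.90), moderate
    (0.60-0.79), weak (0.40-0.59), minimal (0.21-0.39), none (0-0.20).
    A boundary value of exactly 0.90 is "strong".  Negative values
    (worse-than-chance agreement) map to "none" with a logged flag.
    """
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa out of range [-1, 1]: {kappa}")
    if kappa < 0:
        logger.warning("negative kappa %.3f: worse-than-chance agreement", kappa)
        return "none"
    if kappa > 0.90:
        return "almost perfect"
    for cut, band in _KAPPA_BANDS[1:]:
        if kappa >= cut:
            return band
    return "none"


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest precision/recall/F1 per category, plus supports."""

    categories: tuple[Hashable, ...]
    precision: Mapping[Hashable, float]
    recall: Mapping[Hashable, float]
    f1: Mapping[Hashable, float]
    support: Mapping[Hashable, int]
    zero_division_flags: tuple[Hashable, ...]  # categories where a denominator was 0


def per_class_prf(
    truth: Sequence[Hashable],
    predicted: Sequence[Hashable],
    category_order: Sequence[Hashable],
) -> ClassMetrics:
    """Per-category precision, recall and F1 against a criterion standard.

    Zero-denominator cases (a category never predicted, or absent from
    the truth) return 0 for the affected metric and are flagged.
    """
    if len(truth) != len(predicted):
        raise ValueError(
            f"label sequences differ in length: {len(truth)} vs {len(predicted)}"
        )
    order = list(category_order)
    for value in (*truth, *predicted):
        if value not in order:
            raise ValueError(f"label {value!r} not in category order")
    # encode as integers: category objects may be enums sklearn rejects
    code = {category: i for i, category in enumerate(order)}
    precision, recall, f1, support = precision_recall_fscore_support(
        [code[v] for v in truth],
        [code[v] for v in predicted],
        labels=list(range(len(order))),
        zero_division=0,
    )
    predicted_counts = {c: 0 for c in order}
    for value in predicted:
        predicted_counts[value] += 1
    flags = tuple(
        category
        for category, sup in zip(order, support)
        if sup == 0 or predicted_counts[category] == 0
    )
    return ClassMetrics(
        tuple(order),
        dict(zip(order, map(float, precision))),
        dict(zip(order, map(float, recall))),
        dict(zip(order, map(float, f1))),
        dict(zip(order, map(int, support))),
        flags,
    )


def draw_validation_sample(
    labeled: pd.DataFrame,
    strata_sizes: Mapping[Hashable, int],
    seed: int,
    status_column: str = "helmet_status",
) -> pd.DataFrame:
    """Stratified without-replacement sample from a labeled corpus.

    Strata are defined by the assigned label column; within each
    stratum the draw is uniform without replacement and reproducible
    for a given seed.  The returned frame carries a ``stratum`` column
    and preserves the input's column set.
    """
    if status_column not in labeled.columns:
        raise KeyError(f"labeled corpus is missing column {status_column!r}")
    rng = np.random.default_rng(seed)
    pieces: list[pd.DataFrame] = []
    for stratum, size in strata_sizes.items():
        label = getattr(stratum, "label", stratum)
        pool = labeled.index[labeled[status_column] == label]
        if len(pool) < size:
            raise ValueError(
                f"stratum {label!r} has only {len(pool)} records; "
                f"{size} requested"
            )
        chosen = rng.choice(pool.to_numpy(), size=size, replace=False)
        piece = labeled.loc[chosen].copy()
        piece["stratum"] = label
        pieces.append(piece)
    return pd.concat(pieces, axis=0)
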