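"""Contingency tables, kappa statistics and criterion-standard metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from statsmodels.stats import inter_rater

from helmetcoder.agreement import (
    ContingencyTable,
    RatingMatrix,
    UndefinedKappaError,
    build_contingency,
    cohen_kappa,
    draw_validation_sample,
    fleiss_kappa,
    interpret_kappa,
    per_class_prf,
)

# random 3x3 contingency grids; degenerate ones are skipped inside tests
grids = arrays(np.int64, (3, 3), elements=st.integers(0, 40)).filter(
    lambda g: g.sum() > 0
)


def _nondegenerate(grid) -> bool:
    table = ContingencyTable(("a", "b", "c"), grid)
    n = table.n
    if n == 0:
        return False
    pe = (table.row_totals / n) @ (table.col_totals / n)
    return pe < 1 - 1e-12


class TestBuildContingency:
    def test_perfect_agreement_diagonal(self):
        t = build_contingency(["w", "n", "u"], ["w", "n", "u"], ["w", "n", "u"])
        assert np.array_equal(t.counts, np.eye(3, dtype=int))
        assert t.n == 3

    def test_single_off_diagonal_cell(self):
        t = build_contingency(["w"], ["n"], ["w", "n", "u"])
        assert t.counts[0, 1] == 1 and t.counts.sum() == 1

    def test_published_grid_marginals(self):
        # 3x3 grid of a low-detail LLM session vs string search: the
        # row/column totals of the printed table must be recovered.
        t = ContingencyTable(
            ("w", "n", "u"),
            np.array([[5081, 4072, 995], [0, 1908, 0], [1, 0, 42512]]),
        )
        assert list(t.row_totals) == [10148, 1908, 42513]
        assert list(t.col_totals) == [5082, 5980, 43507]
        assert t.n == 54569

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            build_contingency(["w"], ["w", "n"], ["w", "n"])

    def test_label_outside_order(self):
        with pytest.raises(ValueError, match="not in category order"):
            build_contingency(["x"], ["w"], ["w", "n"])


class TestCohenKappa:
    def test_diagonal_table_gives_one(self):
        t = ContingencyTable(("a", "b", "c"), np.diag([7, 2, 5]))
        assert cohen_kappa(t).kappa == pytest.approx(1.0)

    def test_constant_raters_undefined(self):
        t = ContingencyTable(("a", "b"), np.array([[9, 0], [0, 0]]))
        with pytest.raises(UndefinedKappaError):
            cohen_kappa(t)

    def test_empty_table_rejected(self):
        t = ContingencyTable(("a", "b"), np.zeros((2, 2), dtype=int))
        with pytest.raises(ValueError):
            cohen_kappa(t)

    @given(grids)
    def test_symmetry_under_transpose(self, grid):
        if not _nondegenerate(grid):
            return
        t = ContingencyTable(("a", "b", "c"), grid)
        k1 = cohen_kappa(t)
        k2 = cohen_kappa(t.transpose())
        assert k1.kappa == pytest.approx(k2.kappa, abs=1e-12)
        assert k1.se == pytest.approx(k2.se, abs=1e-12)

    @given(grids)
    def test_matches_statsmodels_estimate_and_variance(self, grid):
        if not _nondegenerate(grid):
            return
        result = cohen_kappa(ContingencyTable(("a", "b", "c"), grid))
        reference = inter_rater.cohens_kappa(grid, return_results=True)
        assert result.kappa == pytest.approx(reference.kappa, abs=1e-10)
        assert result.se**2 == pytest.approx(reference.var_kappa, abs=1e-10)

    def test_identity_kappa_formula(self):
        t = ContingencyTable(
            ("a", "b", "c"),
            np.array([[10, 2, 1], [3, 20, 2], [0, 4, 30]]),
        )
        r = cohen_kappa(t)
        assert r.kappa == pytest.approx((r.po - r.pe) / (1 - r.pe))
        assert r.ci_low <= r.kappa <= r.ci_high
        assert -1 <= r.kappa <= 1

    def test_simple_se_flag(self):
        t = ContingencyTable(
            ("a", "b"), np.array([[40, 10], [5, 45]])
        )
        fce = cohen_kappa(t, se_method="fce")
        simple = cohen_kappa(t, se_method="simple")
        n, po, pe = t.n, fce.po, fce.pe
        assert simple.se == pytest.approx(
            np.sqrt(po * (1 - po) / n) / (1 - pe)
        )
        with pytest.raises(ValueError):
            cohen_kappa(t, se_method="bogus")


def fleiss_oracle(counts: np.ndarray) -> float:
    """Direct transcription of the published multi-rater kappa formula."""
    n_items, _ = counts.shape
    m = counts[0].sum()
    p_j = counts.sum(axis=0) / (n_items * m)
    p_i = ((counts**2).sum(axis=1) - m) / (m * (m - 1))
    p_bar = p_i.mean()
    p_e = (p_j**2).sum()
    return (p_bar - p_e) / (1 - p_e)


class TestFleissKappa:
    def test_unanimous_raters_give_one(self):
        matrix = RatingMatrix.from_columns(
            {f"s{i}": ["a", "b", "a", "c"] for i in range(5)}, ["a", "b", "c"]
        )
        result = fleiss_kappa(matrix)
        assert result.kappa == pytest.approx(1.0)
        assert result.p_value < 0.001

    def test_single_category_undefined(self):
        matrix = RatingMatrix.from_columns(
            {"s1": ["a", "a"], "s2": ["a", "a"]}, ["a", "b"]
        )
        with pytest.raises(UndefinedKappaError):
            fleiss_kappa(matrix)

    def test_needs_two_raters(self):
        matrix = RatingMatrix.from_columns({"s1": ["a", "b"]}, ["a", "b"])
        with pytest.raises(ValueError, match="at least 2 raters"):
            fleiss_kappa(matrix)

    def test_rejects_rating_outside_categories(self):
        with pytest.raises(ValueError, match="not in categories"):
            RatingMatrix.from_columns({"s1": ["a"], "s2": ["z"]}, ["a", "b"])

    @pytest.mark.parametrize("n_raters", [2, 3, 5])
    def test_matches_direct_formula_oracle(self, n_raters):
        rng = np.random.default_rng(202)
        categories = ["w", "n", "u"]
        for _ in range(20):
            n_items = int(rng.integers(4, 30))
            ratings = rng.integers(0, 3, size=(n_items, n_raters))
            if len(np.unique(ratings)) < 2:
                continue
            matrix = RatingMatrix.from_columns(
                {
                    f"s{j}": [categories[v] for v in ratings[:, j]]
                    for j in range(n_raters)
                },
                categories,
            )
            counts = matrix.category_counts()
            assert fleiss_kappa(matrix).kappa == pytest.approx(
                fleiss_oracle(counts), abs=1e-12
            )
            assert fleiss_kappa(matrix).kappa == pytest.approx(
                inter_rater.fleiss_kappa(counts), abs=1e-10
            )


@pytest.mark.parametrize(
    ("kappa", "band"),
    [
        (0.95, "almost perfect"),
        (0.91, "almost perfect"),
        (0.90, "strong"),
        (0.80, "strong"),
        (0.74, "moderate"),
        (0.60, "moderate"),
        (0.53, "weak"),
        (0.40, "weak"),
        (0.30, "minimal"),
        (0.21, "minimal"),
        (0.10, "none"),
        (0.0, "none"),
        (-0.2, "none"),
    ],
)
def test_interpret_kappa_bands(kappa, band):
    assert interpret_kappa(kappa) == band


def test_interpret_kappa_range_check():
    with pytest.raises(ValueError):
        interpret_kappa(1.5)


class TestPerClassPrf:
    def test_perfect_prediction(self):
        labels = ["w", "n", "u", "w"]
        metrics = per_class_prf(labels, labels, ["w", "n", "u"])
        for category in ("w", "n"):
            assert metrics.precision[category] == 1.0
            assert metrics.recall[category] == 1.0
            assert metrics.f1[category] == 1.0

    def test_single_class_truth_with_one_error(self):
        truth = ["w"] * 10
        predicted = ["w"] * 9 + ["n"]
        metrics = per_class_prf(truth, predicted, ["w", "n"])
        assert metrics.recall["w"] == pytest.approx(0.9)
        assert metrics.precision["w"] == 1.0

    def test_hand_count_oracle_on_random_labels(self):
        rng = np.random.default_rng(31)
        categories = ["w", "n", "u"]
        truth = [categories[i] for i in rng.integers(0, 3, 200)]
        predicted = [categories[i] for i in rng.integers(0, 3, 200)]
        metrics = per_class_prf(truth, predicted, categories)
        for c in categories:
            tp = sum(1 for t, p in zip(truth, predicted) if t == c and p == c)
            fp = sum(1 for t, p in zip(truth, predicted) if t != c and p == c)
            fn = sum(1 for t, p in zip(truth, predicted) if t == c and p != c)
            assert metrics.precision[c] == pytest.approx(tp / (tp + fp))
            assert metrics.recall[c] == pytest.approx(tp / (tp + fn))
            assert metrics.support[c] == tp + fn

    def test_micro_recall_equals_accuracy(self):
        rng = np.random.default_rng(7)
        categories = ["w", "n", "u"]
        truth = [categories[i] for i in rng.integers(0, 3, 500)]
        predicted = [categories[i] for i in rng.integers(0, 3, 500)]
        metrics = per_class_prf(truth, predicted, categories)
        micro = sum(
            metrics.recall[c] * metrics.support[c] for c in categories
        ) / len(truth)
        accuracy = np.mean([t == p for t, p in zip(truth, predicted)])
        assert micro == pytest.approx(accuracy)

    def test_zero_denominator_flagged(self):
        metrics = per_class_prf(["w", "w"], ["w", "w"], ["w", "n"])
        assert "n" in metrics.zero_division_flags
        assert metrics.precision["n"] == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            per_class_prf(["w"], ["w", "n"], ["w", "n"])


class TestDrawValidationSample:
    @pytest.fixture()
    def corpus(self):
        rng = np.random.default_rng(3)
        labels = ["wearing helmet"] * 300 + ["not wearing helmet"] * 300 + [
            "helmet not mentioned/unknown"
        ] * 600
        rng.shuffle(labels)
        return pd.DataFrame(
            {
                "cpsc_case_number": [str(i) for i in range(len(labels))],
                "helmet_status": labels,
            }
        )

    STRATA = {
        "wearing helmet": 100,
        "not wearing helmet": 100,
        "helmet not mentioned/unknown": 200,
    }

    def test_composition(self, corpus):
        sample = draw_validation_sample(corpus, self.STRATA, seed=9)
        assert len(sample) == 400
        assert sample["stratum"].value_counts().to_dict() == self.STRATA
        # sampled rows really belong to their stratum
        assert (sample["helmet_status"] == sample["stratum"]).all()

    def test_deterministic_given_seed(self, corpus):
        a = draw_validation_sample(corpus, self.STRATA, seed=9)
        b = draw_validation_sample(corpus, self.STRATA, seed=9)
        pd.testing.assert_frame_equal(a, b)
        c = draw_validation_sample(corpus, self.STRATA, seed=10)
        assert list(a["cpsc_case_number"]) != list(c["cpsc_case_number"])

    def test_without_replacement(self, corpus):
        sample = draw_validation_sample(corpus, self.STRATA, seed=9)
        assert sample["cpsc_case_number"].is_unique

    def test_stratum_shortfall_names_stratum(self, corpus):
        strata = dict(self.STRATA, **{"wearing helmet": 301})
        with pytest.raises(ValueError, match="wearing helmet.*300"):
            draw_validation_sample(corpus, strata, seed=9)
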