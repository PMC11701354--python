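"""Kappa statistics and specific agreement against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.inter_rater import aggregate_raters
from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss_kappa

from scs_triage.agreement import (
    RELIABILITY_THRESHOLD,
    agreement_report,
    cohen_kappa,
    fleiss_kappa,
    intra_rater,
    pair_counts,
    specific_agreement,
)
from scs_triage.cohort import RaterModel, simulate_ratings
from scs_triage.markers import UNDEFINED
from scs_triage.records import RatingMatrix


def matrix_from_array(arr) -> RatingMatrix:
    arr = np.asarray(arr)
    return RatingMatrix(
        pd.DataFrame(
            arr,
            index=[f"S{i}" for i in range(arr.shape[0])],
            columns=[f"r{j}" for j in range(arr.shape[1])],
        )
    )


def expected_cohen_kappa(prevalence, rater_a, rater_b):
    """Closed-form population kappa from the 2x2 cell probabilities."""
    se1, sp1 = rater_a.p_correct_positive, rater_a.p_correct_negative
    se2, sp2 = rater_b.p_correct_positive, rater_b.p_correct_negative
    pi = prevalence
    p11 = pi * se1 * se2 + (1 - pi) * (1 - sp1) * (1 - sp2)
    p10 = pi * se1 * (1 - se2) + (1 - pi) * (1 - sp1) * sp2
    p01 = pi * (1 - se1) * se2 + (1 - pi) * sp1 * (1 - sp2)
    p00 = pi * (1 - se1) * (1 - se2) + (1 - pi) * sp1 * sp2
    p_o = p11 + p00
    row = p11 + p10
    col = p11 + p01
    p_e = row * col + (1 - row) * (1 - col)
    return (p_o - p_e) / (1 - p_e)


class TestCohenKappa:
    def test_identical_vectors(self):
        v = [1, 0, 1, 1, 0]
        assert cohen_kappa(v, v) == pytest.approx(1.0)

    def test_independence_gives_zero(self):
        # 2x2 cross-counts a=b=c=d=25: p_o = p_e = 0.5
        a = [1] * 50 + [0] * 50
        b = [1] * 25 + [0] * 25 + [1] * 25 + [0] * 25
        assert cohen_kappa(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_same_category(self):
        assert cohen_kappa([1, 1, 1], [1, 1, 1]) == 1.0
        assert cohen_kappa([0, 0], [0, 0]) == 1.0

    def test_matches_sklearn_oracle_on_random_pairs(self):
        rng = np.random.default_rng(10)
        checked = 0
        while checked < 500:
            n = int(rng.integers(5, 60))
            a = rng.integers(0, 2, n)
            b = rng.integers(0, 2, n)
            # sklearn returns nan for degenerate marginals; skip those
            if len(np.unique(a)) < 2 and len(np.unique(b)) < 2:
                continue
            expected = cohen_kappa_score(a, b)
            if np.isnan(expected):
                continue
            assert cohen_kappa(a, b) == pytest.approx(expected, abs=1e-12)
            checked += 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            cohen_kappa([1, 0], [1])

    def test_simulated_raters_recover_closed_form(self):
        """Empirical kappa at n=50000 matches the analytic cell-probability value."""
        ra = RaterModel(rater_id="a", p_correct_positive=0.9, p_correct_negative=0.85)
        rb = RaterModel(rater_id="b", p_correct_positive=0.8, p_correct_negative=0.95)
        labels = np.random.default_rng(11).random(50_000) < 0.4
        matrix = simulate_ratings(labels, [ra, rb], seed=12)
        empirical = cohen_kappa(matrix.column("a"), matrix.column("b"))
        analytic = expected_cohen_kappa(0.4, ra, rb)
        assert empirical == pytest.approx(analytic, abs=0.02)


class TestFleissKappa:
    def test_unanimous_raters(self):
        m = matrix_from_array([[1, 1, 1], [0, 0, 0], [1, 1, 1]])
        assert fleiss_kappa(m) == pytest.approx(1.0)

    def test_single_category_degenerate(self):
        m = matrix_from_array([[1, 1], [1, 1]])
        assert fleiss_kappa(m) == 1.0

    def test_two_raters_equals_scotts_pi(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            n = int(rng.integers(4, 50))
            arr = rng.integers(0, 2, (n, 2))
            if len(np.unique(arr)) < 2:
                continue
            # Scott's pi oracle: chance agreement from pooled marginals
            a, b = arr[:, 0], arr[:, 1]
            p_o = (a == b).mean()
            p_bar = (a.mean() + b.mean()) / 2
            p_e = p_bar**2 + (1 - p_bar) ** 2
            pi = (p_o - p_e) / (1 - p_e)
            assert fleiss_kappa(matrix_from_array(arr)) == pytest.approx(
                pi, abs=1e-12
            )

    def test_matches_statsmodels_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(100):
            n = int(rng.integers(4, 40))
            r = int(rng.integers(2, 6))
            arr = rng.integers(0, 2, (n, r))
            if len(np.unique(arr)) < 2:
                continue
            table, _ = aggregate_raters(arr, n_cat=2)
            assert fleiss_kappa(matrix_from_array(arr)) == pytest.approx(
                sm_fleiss_kappa(table), abs=1e-12
            )

    def test_identical_raters_give_one(self):
        rng = np.random.default_rng(15)
        col = rng.integers(0, 2, 30)
        m = matrix_from_array(np.tile(col[:, None], (1, 4)))
        assert fleiss_kappa(m) == pytest.approx(1.0)

    def test_four_simulated_raters_recover_closed_form(self):
        """Four identical raters, n=50000: kappa matches its analytic expectation."""
        se, sp, pi = 0.88, 0.92, 0.5
        raters = [
            RaterModel(rater_id=f"r{i}", p_correct_positive=se, p_correct_negative=sp)
            for i in range(4)
        ]
        labels = np.random.default_rng(16).random(50_000) < pi
        matrix = simulate_ratings(labels, raters, seed=17)
        # analytic: P_o from within-class binomial pair agreement, P_e from
        # the pooled positive-call probability
        p_pos = pi * se + (1 - pi) * (1 - sp)
        p_o = pi * (se**2 + (1 - se) ** 2) + (1 - pi) * (sp**2 + (1 - sp) ** 2)
        p_e = p_pos**2 + (1 - p_pos) ** 2
        analytic = (p_o - p_e) / (1 - p_e)
        assert fleiss_kappa(matrix) == pytest.approx(analytic, abs=0.02)

    def test_incomplete_matrix_rejected(self):
        frame = pd.DataFrame({"a": [1, 0, None], "b": [1, 0, 1]})
        with pytest.raises(ValueError, match="pairwise"):
            RatingMatrix(frame)


class TestSpecificAgreement:
    def test_perfect_agreement(self):
        s = specific_agreement([1, 0, 1], [1, 0, 1])
        assert (s.overall, s.positive, s.negative) == (1.0, 1.0, 1.0)

    def test_pure_disagreement(self):
        s = specific_agreement([1, 0], [0, 1])
        assert s.overall == 0.0
        assert s.positive == 0.0
        assert s.negative == 0.0

    def test_undefined_components(self):
        s = specific_agreement([0, 0], [0, 0])
        assert s.positive is UNDEFINED
        assert s.negative == 1.0

    def test_matches_direct_count_oracle(self):
        rng = np.random.default_rng(18)
        for _ in range(300):
            n = int(rng.integers(2, 50))
            x = rng.integers(0, 2, n)
            y = rng.integers(0, 2, n)
            a = int(((x == 1) & (y == 1)).sum())
            b = int(((x == 1) & (y == 0)).sum())
            c = int(((x == 0) & (y == 1)).sum())
            d = int(((x == 0) & (y == 0)).sum())
            s = specific_agreement(x, y)
            assert s.overall == pytest.approx((a + d) / n, abs=1e-12)
            if 2 * a + b + c:
                assert s.positive == pytest.approx(
                    2 * a / (2 * a + b + c), abs=1e-12
                )
            if 2 * d + b + c:
                assert s.negative == pytest.approx(
                    2 * d / (2 * d + b + c), abs=1e-12
                )


class TestInvariances:
    def test_subject_permutation_invariance(self):
        rng = np.random.default_rng(19)
        arr = rng.integers(0, 2, (30, 3))
        perm = rng.permutation(30)
        m1, m2 = matrix_from_array(arr), matrix_from_array(arr[perm])
        assert fleiss_kappa(m1) == pytest.approx(fleiss_kappa(m2), abs=1e-12)
        assert cohen_kappa(arr[:, 0], arr[:, 1]) == pytest.approx(
            cohen_kappa(arr[perm, 0], arr[perm, 1]), abs=1e-12
        )

    def test_category_relabelling(self):
        rng = np.random.default_rng(20)
        arr = rng.integers(0, 2, (40, 4))
        flipped = 1 - arr
        assert fleiss_kappa(matrix_from_array(arr)) == pytest.approx(
            fleiss_kappa(matrix_from_array(flipped)), abs=1e-12
        )
        assert cohen_kappa(arr[:, 0], arr[:, 1]) == pytest.approx(
            cohen_kappa(flipped[:, 0], flipped[:, 1]), abs=1e-12
        )
        s, sf = (
            specific_agreement(arr[:, 0], arr[:, 1]),
            specific_agreement(flipped[:, 0], flipped[:, 1]),
        )
        assert s.overall == pytest.approx(sf.overall, abs=1e-12)
        assert s.positive == pytest.approx(sf.negative, abs=1e-12)
        assert s.negative == pytest.approx(sf.positive, abs=1e-12)


class TestReports:
    def test_reliability_verdict_threshold(self):
        rng = np.random.default_rng(21)
        labels = rng.random(300) < 0.5
        raters = [
            RaterModel(rater_id="good1", p_correct_positive=0.98, p_correct_negative=0.98),
            RaterModel(rater_id="good2", p_correct_positive=0.97, p_correct_negative=0.97),
            RaterModel(rater_id="noisy", p_correct_positive=0.6, p_correct_negative=0.6),
        ]
        report = agreement_report(simulate_ratings(labels, raters, seed=22))
        verdicts = {
            (p.rater_a, p.rater_b): p.reliable for p in report.pairwise
        }
        assert verdicts[("good1", "good2")]
        assert not verdicts[("good1", "noisy")]
        for p in report.pairwise:
            assert p.reliable == (p.kappa >= RELIABILITY_THRESHOLD)
        assert -1 <= report.fleiss <= 1
        mat = report.cohen_matrix
        assert mat.loc["good1", "good2"] == mat.loc["good2", "good1"]

    def test_intra_rater_test_retest(self):
        v = [1, 0, 1, 1, 0, 0]
        result = intra_rater(v, v, rater_id="ps1")
        assert result["cohen_kappa"] == pytest.approx(1.0)
        assert result["agreement"]["overall"] == 1.0
        assert result["reliable"]

        flipped = [0, 1, 0, 0, 1, 1]
        result = intra_rater(v, flipped)
        assert result["agreement"]["overall"] == 0.0

    def test_intra_rater_flip_probability_closed_form(self):
        """Retest flips with prob f: kappa of two noisy looks at the same truth."""
        rater = RaterModel(rater_id="a", p_correct_positive=0.93, p_correct_negative=0.93)
        labels = np.random.default_rng(23).random(50_000) < 0.5
        test = simulate_ratings(labels, [rater], seed=24).column("a")
        retest = simulate_ratings(labels, [rater], seed=25).column("a")
        analytic = expected_cohen_kappa(0.5, rater, rater)
        assert cohen_kappa(test, retest) == pytest.approx(analytic, abs=0.02)


def test_pair_counts_totals():
    counts = pair_counts([1, 1, 0, 0], [1, 0, 1, 0])
    assert (counts.a, counts.b, counts.c, counts.d) == (1, 1, 1, 1)
    assert counts.n == 4
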