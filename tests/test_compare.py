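"""Friedman omnibus test and Bayesian correlated t-test comparisons."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from rrespstate.compare import bc_ttest, build_matrix, friedman
from rrespstate.ml_harness import CVResult


class TestFriedman:
    def test_all_tied_blocks(self):
        m = np.tile([[0.8, 0.8, 0.8]], (20, 1))
        stat, p = friedman(m)
        assert stat == 0.0 and p == 1.0

    def test_strict_ordering_closed_form(self):
        """Three algorithms ranked 3>2>1 in every one of 100 blocks give the
        closed-form statistic 12*100/12 * ((1)^2+0+(-1)^2) = 200."""
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, (100, 1))
        m = np.hstack([base + 3, base + 2, base + 1])
        stat, p = friedman(m)
        assert stat == pytest.approx(200.0)
        assert p < 1e-10

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(3)
        m = np.round(rng.normal(0, 1, (40, 5)), 1)  # rounding forces ties
        stat, p = friedman(m)
        ref = stats.friedmanchisquare(*(m[:, j] for j in range(5)))
        assert stat == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_two_algorithms_sign_test_reduction(self):
        """For k = 2 without ties the statistic equals (n_plus - n_minus)^2/n,
        the squared standardized sign statistic."""
        rng = np.random.default_rng(4)
        d = rng.normal(0.2, 1.0, 60)
        d = d[d != 0]
        m = np.column_stack([np.zeros_like(d), d])
        stat, _ = friedman(m)
        n_plus = int(np.sum(d > 0))
        n_minus = int(np.sum(d < 0))
        expected = (n_plus - n_minus) ** 2 / d.size
        assert stat == pytest.approx(expected, rel=1e-12)

    def test_needs_two_algorithms(self):
        with pytest.raises(ValueError):
            friedman(np.ones((10, 1)))


class TestBCTTest:
    def test_all_zero_differences(self):
        r = bc_ttest(np.zeros(100))
        assert r.p_rope == 1.0 and r.verdict == "equivalent"

    def test_location_far_right_of_rope(self):
        x = np.full(100, 0.05) + 1e-12 * np.arange(100)
        r = bc_ttest(x)
        assert r.p_right == pytest.approx(1.0, abs=1e-6)
        assert r.verdict == "row_better"

    def test_masses_match_quadrature(self):
        """Closed-form region masses equal numerical integration of the
        posterior Student-t density to 1e-6."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            x = rng.normal(0.005, 0.03, 100)
            r = bc_ttest(x)
            pdf = lambda v: stats.t.pdf(v, df=r.dof, loc=r.mu_hat, scale=r.scale)
            q_left = quad(pdf, -np.inf, -r.rope)[0]
            q_rope = quad(pdf, -r.rope, r.rope)[0]
            q_right = quad(pdf, r.rope, np.inf)[0]
            assert r.p_left == pytest.approx(q_left, abs=1e-6)
            assert r.p_rope == pytest.approx(q_rope, abs=1e-6)
            assert r.p_right == pytest.approx(q_right, abs=1e-6)
            assert r.p_left + r.p_rope + r.p_right == pytest.approx(1.0, abs=1e-9)

    def test_swapping_order_mirrors_result(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0.02, 0.05, 100)
        fwd, rev = bc_ttest(x), bc_ttest(-x)
        assert rev.mu_hat == pytest.approx(-fwd.mu_hat)
        assert rev.p_left == pytest.approx(fwd.p_right, abs=1e-12)
        assert rev.p_right == pytest.approx(fwd.p_left, abs=1e-12)

    def test_location_shift(self):
        rng = np.random.default_rng(13)
        x = rng.normal(0, 0.02, 50)
        c = 0.004
        assert bc_ttest(x + c).mu_hat == pytest.approx(bc_ttest(x).mu_hat + c)

    def test_rho_to_zero_recovers_standard_t(self):
        """As the fold correlation vanishes the posterior scale approaches the
        ordinary one-sample s/sqrt(n)."""
        rng = np.random.default_rng(14)
        x = rng.normal(0.01, 0.05, 100)
        s = np.std(x, ddof=1)
        r = bc_ttest(x, rho=1e-9)
        assert r.scale == pytest.approx(s / np.sqrt(x.size), rel=1e-6)

    def test_correlation_widens_posterior(self):
        rng = np.random.default_rng(15)
        x = rng.normal(0.01, 0.05, 100)
        assert bc_ttest(x, rho=0.1).scale > bc_ttest(x, rho=0.01).scale

    @pytest.mark.parametrize("bad_rho", [0.0, 1.0, -0.5])
    def test_rho_domain(self, bad_rho):
        with pytest.raises(ValueError, match="rho"):
            bc_ttest(np.zeros(10), rho=bad_rho)


def fake_cv(name, accuracy, runs=2, folds=5):
    accuracy = np.asarray(accuracy, dtype=float)
    k = 3
    return CVResult(
        algorithm=name,
        classes=np.array(["a", "b", "c"]),
        accuracy=accuracy,
        f1=accuracy,
        auc=accuracy,
        confusions=np.zeros((runs, k, k)),
        runs=runs,
        folds=folds,
    )


class TestBuildMatrix:
    def test_self_copy_is_equivalent(self):
        rng = np.random.default_rng(20)
        acc = rng.uniform(0.7, 0.9, 10)
        matrix = build_matrix([fake_cv("A", acc), fake_cv("B", acc.copy())])
        assert matrix.cells[("A", "B")].verdict == "equivalent"
        assert matrix.cells[("A", "B")].p_rope == 1.0

    def test_clear_winner_gets_probability_one(self):
        rng = np.random.default_rng(21)
        good = rng.uniform(0.93, 0.99, 10)
        bad = rng.uniform(0.30, 0.36, 10)
        matrix = build_matrix([fake_cv("good", good), fake_cv("bad", bad)])
        cell = matrix.cells[("good", "bad")]
        assert cell.verdict == "row_better"
        assert cell.p_right == pytest.approx(1.0, abs=1e-4)

    def test_antisymmetry(self):
        rng = np.random.default_rng(22)
        a = rng.uniform(0.7, 0.9, 10)
        b = a + rng.normal(0.01, 0.02, 10)
        matrix = build_matrix([fake_cv("A", a), fake_cv("B", b)])
        ab, ba = matrix.cells[("A", "B")], matrix.cells[("B", "A")]
        assert ab.p_right == pytest.approx(ba.p_left, abs=1e-12)
        assert ab.p_left == pytest.approx(ba.p_right, abs=1e-12)
        assert ab.mu_hat == pytest.approx(-ba.mu_hat)

    def test_unpaired_results_rejected(self):
        a = fake_cv("A", np.full(10, 0.8))
        b = fake_cv("B", np.full(8, 0.8), runs=2, folds=4)
        with pytest.raises(ValueError, match="unpaired"):
            build_matrix([a, b])

    def test_frames_have_blank_diagonal(self):
        rng = np.random.default_rng(23)
        results = [fake_cv(n, rng.uniform(0.7, 0.9, 10)) for n in "ABC"]
        matrix = build_matrix(results)
        frame = matrix.probability_frame()
        assert list(frame.index) == ["A", "B", "C"]
        assert all(np.isnan(frame.iloc[i, i]) for i in range(3))
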