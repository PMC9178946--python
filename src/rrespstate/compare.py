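"""Statistical comparison of cross-validated classifiers.

Two stages, matching standard practice for comparing learners on one dataset:

1. A Friedman rank test across all algorithms, with the runs x folds paired
   measurements as blocks, asking whether the algorithms perform equivalently
   at all (alpha = 0.05).

2. Pairwise Bayesian correlated t-tests.  Cross-validated metric differences
   are not independent observations — test sets overlap across folds — so the
   ordinary t-test is miscalibrated.  The correlated variant models the
   difference vector as x = 1*mu + noise with equicorrelated noise and yields
   a Student-t posterior for mu with

       dof   = n - 1
       loc   = mean(x)
       scale^2 = (1/n + rho / (1 - rho)) * var(x)

   where rho is the fold-overlap correlation, heuristically the test-set
   fraction 1/folds.  The posterior mass is split over three regions:
   below, inside and above a region of practical equivalence (ROPE,
   default +/- 0.01 on the accuracy scale); the region holding the most
   mass decides the verdict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ml_harness import CVResult

__all__ = ["BCTestResult", "ComparisonMatrix", "friedman", "bc_ttest", "build_matrix"]


def friedman(metric_matrix: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square over a blocks x algorithms metric matrix.

    Blocks are the paired runs x folds measurements; ties within a block get
    average ranks.  Returns ``(statistic, p_value)``; the null of equivalent
    algorithms is conventionally rejected at p < 0.05.
    """
    m = np.asarray(metric_matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 algorithm columns")
    if m.shape[0] < 2:
        raise ValueError("need >= 2 blocks")
    n, k = m.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, m)
    # tie correction, as in the standard chi-square approximation
    ties = 0.0
    for row in m:
        _, t = np.unique(row, return_counts=True)
        ties += float(np.sum(t**3 - t))
    c = 1.0 - ties / (k * (k * k - 1) * n)
    if c == 0.0:
        return 0.0, 1.0  # every block fully tied
    ssbn = float(np.sum(ranks.sum(axis=0) ** 2))
    statistic = (12.0 / (n * k * (k + 1)) * ssbn - 3.0 * n * (k + 1)) / c
    p = float(stats.chi2.sf(statistic, k - 1))
    return float(statistic), p


@dataclass(frozen=True)
class BCTestResult:
    """Posterior of the mean metric difference between two algorithms."""

    x: np.ndarray
    mu_hat: float  # posterior location (mean difference, row - column)
    scale: float  # posterior scale
    dof: int
    rho: float
    rope: float
    p_left: float  # P(mu < -rope): column better
    p_rope: float  # P(-rope <= mu <= rope): practically equivalent
    p_right: float  # P(mu > rope): row better
    verdict: str  # 'row_better' | 'column_better' | 'equivalent'

    @property
    def p_winner(self) -> float:
        """Mass of the winning region (the number a comparison cell shows)."""
        return {"row_better": self.p_right,
                "column_better": self.p_left,
                "equivalent": self.p_rope}[self.verdict]


def bc_ttest(
    x: np.ndarray, rope: float = 0.01, rho: float = 0.1
) -> BCTestResult:
    """Bayesian correlated t-test on a vector of paired metric differences.

    ``rho`` defaults to 0.1 = 1/folds for tenfold designs (the test-set
    fraction heuristic).  With zero sample variance the posterior degenerates
    to a point mass at the sample mean and the region containing it gets all
    the probability (a mean exactly on a ROPE edge counts as inside, the
    closed-interval convention).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need >= 2 paired differences")
    if not 0.0 < rho < 1.0:
        raise ValueError(f"rho must be in (0, 1), got {rho}")
    mu = float(np.mean(x))
    var = float(np.var(x, ddof=1))
    scale = float(np.sqrt((1.0 / n + rho / (1.0 - rho)) * var))
    dof = n - 1
    if scale == 0.0:
        p_left = 1.0 if mu < -rope else 0.0
        p_right = 1.0 if mu > rope else 0.0
        p_rope = 1.0 - p_left - p_right
    else:
        dist = stats.t(df=dof, loc=mu, scale=scale)
        p_left = float(dist.cdf(-rope))
        p_rope = float(dist.cdf(rope) - dist.cdf(-rope))
        p_right = float(1.0 - dist.cdf(rope))
    masses = {"column_better": p_left, "equivalent": p_rope, "row_better": p_right}
    verdict = max(masses, key=masses.get)  # type: ignore[arg-type]
    return BCTestResult(
        x=x, mu_hat=mu, scale=scale, dof=dof, rho=rho, rope=rope,
        p_left=p_left, p_rope=p_rope, p_right=p_right, verdict=verdict,
    )


@dataclass
class ComparisonMatrix:
    """All ordered pairwise comparisons over an algorithm roster."""

    algorithms: list[str]
    cells: dict[tuple[str, str], BCTestResult]

    def verdict_frame(self) -> pd.DataFrame:
        """Row-vs-column verdicts ('row_better'/'column_better'/'equivalent')."""
        return self._frame(lambda r: r.verdict, fill="")

    def probability_frame(self) -> pd.DataFrame:
        """Winning-region probability per cell (the rendered matrix numbers)."""
        return self._frame(lambda r: r.p_winner, fill=np.nan)

    def _frame(self, getter, fill) -> pd.DataFrame:
        k = len(self.algorithms)
        data = np.full((k, k), fill, dtype=object)
        for (row, col), res in self.cells.items():
            i, j = self.algorithms.index(row), self.algorithms.index(col)
            data[i, j] = getter(res)
        return pd.DataFrame(data, index=self.algorithms, columns=self.algorithms)


def build_matrix(
    cv_results: list[CVResult],
    metric: str = "accuracy",
    rope: float = 0.01,
    rho: float | None = None,
) -> ComparisonMatrix:
    """Pairwise comparison matrix from a shared-fold CV evaluation.

    All results must come from the same :func:`~rrespstate.ml_harness.run_cv`
    call (identical fold partitions) so that per-fold differences are paired;
    the runs are pooled into one length runs*folds difference vector.
    ``rho`` defaults to 1/folds.
    """
    if len(cv_results) < 2:
        raise ValueError("need >= 2 algorithms to compare")
    n = cv_results[0].accuracy.size
    folds = cv_results[0].folds
    for r in cv_results:
        if getattr(r, metric).size != n or r.folds != folds:
            raise ValueError("unpaired results: fold designs differ")
    if rho is None:
        rho = 1.0 / folds
    cells: dict[tuple[str, str], BCTestResult] = {}
    for a in cv_results:
        for b in cv_results:
            if a.algorithm == b.algorithm:
                continue
            x = getattr(a, metric) - getattr(b, metric)
            cells[(a.algorithm, b.algorithm)] = bc_ttest(x, rope=rope, rho=rho)
    return ComparisonMatrix(
        algorithms=[r.algorithm for r in cv_results], cells=cells
    )
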