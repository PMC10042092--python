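"""Trial analysis statistics.

Covers the primary-outcome arithmetic of a two-arm cessation trial —
per-arm abstinence rates from the 2x2 table, the odds ratio with a
Woolf (log-normal) confidence interval, the Pearson chi-square
comparison — plus longitudinal mean/SD summaries of the protection
motivation theory construct scores and a plain maximum-likelihood
logistic fitter (IRLS) used as the parameter-recovery oracle for
simulated data.  Repeated-measures modelling with a working
correlation structure is intentionally out of scope; the long-format
export feeds such tools directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class TwoByTwo:
    """Outcome table: (a, b) intervention abstinent / not, (c, d)
    control abstinent / not."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n_intervention(self) -> int:
        return self.a + self.b

    @property
    def n_control(self) -> int:
        return self.c + self.d


@dataclass(frozen=True)
class EffectEstimate:
    odds_ratio: float
    ci_low: float
    ci_high: float
    alpha: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("confidence limits must bracket the odds ratio")


class ZeroCellError(ValueError):
    """A 2x2 cell is zero; the Woolf interval is undefined.  Re-run
    with ``haldane=True`` to add 0.5 to every cell."""


def abstinence_rates(table: TwoByTwo) -> tuple[float, float]:
    """(intervention, control) abstinence proportions."""
    if table.n_intervention == 0 or table.n_control == 0:
        raise ValueError("both arms must have a positive denominator")
    return table.a / table.n_intervention, table.c / table.n_control


def odds_ratio_ci(
    table: TwoByTwo, alpha: float = 0.05, haldane: bool = False
) -> EffectEstimate:
    """Odds ratio with the Woolf log-normal confidence interval.

    ``OR = ad/bc``; ``CI = exp(ln OR +/- z_{1-a/2} sqrt(1/a+1/b+1/c+1/d))``.
    Zero cells raise :class:`ZeroCellError` unless the Haldane-Anscombe
    +0.5 correction is explicitly requested.
    """
    cells = np.array([table.a, table.b, table.c, table.d], dtype=float)
    if np.any(cells == 0):
        if not haldane:
            raise ZeroCellError(
                "zero cell in the 2x2 table; pass haldane=True to apply the "
                "+0.5 Haldane-Anscombe correction"
            )
        cells = cells + 0.5
    a, b, c, d = cells
    or_ = (a * d) / (b * c)
    se = np.sqrt((1 / cells).sum())
    z = sps.norm.ppf(1 - alpha / 2)
    lo, hi = np.exp(np.log(or_) + np.array([-1, 1]) * z * se)
    return EffectEstimate(odds_ratio=float(or_), ci_low=float(lo), ci_high=float(hi), alpha=alpha)


def chi_square(table: TwoByTwo, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square (1 df) comparing the two arms; Yates
    continuity correction optional.  Warns if an expected cell < 1."""
    obs = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    expected = sps.contingency.expected_freq(obs)
    if np.any(expected < 1):
        import warnings

        warnings.warn(
            "an expected cell count is below 1; consider an exact test",
            stacklevel=2,
        )
    stat, p, _, _ = sps.chi2_contingency(obs, correction=yates)
    return float(stat), float(p)


def summarize_longitudinal(records: pd.DataFrame) -> pd.DataFrame:
    """Per (arm, visit, construct) n / mean / SD summary.

    ``records`` is long-format with columns ``participant_id, arm,
    visit_month, construct, score`` (scores in [1, 7]).  Cells with a
    single observation report SD as NA.
    """
    required = {"participant_id", "arm", "visit_month", "construct", "score"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"long-format records lack columns: {sorted(missing)}")
    scores = records["score"].to_numpy(dtype=float)
    if np.any((scores < 1) | (scores > 7)):
        raise ValueError("scores must lie in [1, 7]")
    out = (
        records.groupby(["arm", "visit_month", "construct"], observed=True)["score"]
        .agg(n="count", mean="mean", sd=lambda s: s.std(ddof=1))
        .reset_index()
    )
    return out


def fit_logistic_irls(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood logistic regression by iteratively
    reweighted least squares.

    Returns ``(beta, standard_errors)``.  Raises on rank-deficient
    designs and on non-convergence (e.g. separation), naming the
    coefficient that diverged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcomes must be binary 0/1")
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1 / (1 + np.exp(-eta))
        w = mu * (1 - mu)
        w = np.maximum(w, 1e-12)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol:
            info = X.T @ (X * (mu * (1 - mu))[:, None])
            se = np.sqrt(np.diag(np.linalg.inv(info)))
            return beta, se
    worst = int(np.argmax(np.abs(beta)))
    raise RuntimeError(
        f"IRLS did not converge in {max_iter} iterations; coefficient "
        f"{worst} is at {beta[worst]:.3g} (possible separation)"
    )


def long_format_export(records: pd.DataFrame, path) -> None:
    """Write the long-format table (one row per participant x visit x
    construct, with the running abstinence flag) for external
    repeated-measures tools."""
    cols = ["participant_id", "arm", "visit_month", "construct", "score", "abstinent_so_far"]
    missing = set(cols) - set(records.columns)
    if missing:
        raise ValueError(f"export lacks columns: {sorted(missing)}")
    records[cols].to_csv(path, index=False)
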