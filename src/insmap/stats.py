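"""Significance machinery for observed-vs-control comparisons.

Three test families cover every comparison in the pipeline: exact binomial
tests with the success probability estimated from pooled in-silico control
sets, Fisher's exact test for between-dataset 2x2 contrasts, and bootstrap
p-values computed by ranking an observed statistic against the per-set
statistics of the control collection.  Benjamini-Hochberg FDR is applied
whenever a batch of features is tested together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "binomial_enrichment_test",
    "fisher_2x2",
    "bootstrap_pvalue",
    "bh_fdr",
]

SIGNIFICANCE_THRESHOLD = 0.05


@dataclass
class TestResult:
    name: str
    observed: float
    null_value: float
    p: float
    side: str
    q: float | None = None
    n_controls: int | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        val = self.q if self.q is not None else self.p
        return val < SIGNIFICANCE_THRESHOLD

    def p_text(self) -> str:
        """Bootstrap zeros are reported as a bound, e.g. 'P < 0.001'."""
        if self.p == 0 and self.n_controls:
            return f"P < {1.0 / self.n_controls:g}"
        return f"P = {self.p:g}"


def binomial_enrichment_test(
    k: int, n: int, control_k: int, control_n: int, side: str = "auto", name: str = "binomial"
) -> TestResult:
    """Exact binomial tail test of k/n successes against the control rate.

    The success probability is estimated as ``control_k / control_n`` with
    successes and totals pooled over all control sets.  ``side`` is
    'enrichment' (P(X >= k)), 'depletion' (P(X <= k)), or 'auto' (the
    direction of the observed deviation).
    """
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    if control_n <= 0:
        raise ValueError("control_n must be positive")
    p_hat = control_k / control_n
    flags: list[str] = []
    if side == "auto":
        side = "enrichment" if k / n >= p_hat else "depletion"
    if p_hat in (0.0, 1.0):
        flags.append("degenerate_null")
        discordant = (p_hat == 0.0 and k > 0) or (p_hat == 1.0 and k < n)
        p = 0.0 if discordant else 1.0
    elif side == "enrichment":
        p = float(sps.binom.sf(k - 1, n, p_hat))
    elif side == "depletion":
        p = float(sps.binom.cdf(k, n, p_hat))
    else:
        raise ValueError(f"unknown side {side!r}")
    return TestResult(
        name=name,
        observed=k / n,
        null_value=p_hat,
        p=p,
        side=side,
        flags=flags,
    )


def fisher_2x2(a: int, b: int, c: int, d: int, name: str = "fisher") -> TestResult:
    """Two-sided Fisher's exact test on the 2x2 table [[a, b], [c, d]]."""
    table = np.array([[a, b], [c, d]])
    if (table < 0).any():
        raise ValueError("cell counts must be non-negative")
    if table.sum() == 0:
        raise ValueError("all-zero contingency table")
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return TestResult(
        name=name,
        observed=float(odds) if np.isfinite(odds) else float("inf"),
        null_value=1.0,
        p=float(p),
        side="two-sided",
    )


def bootstrap_pvalue(
    observed_stat: float,
    control_stats,
    side: str = "auto",
    plus_one: bool = False,
    name: str = "bootstrap",
) -> TestResult:
    """Rank-based p-value against a collection of per-control-set statistics.

    ``p = (#control sets at least as extreme as the observed value) / N``,
    one-sided in the direction of the observed deviation by default
    ('auto'); 'two-sided' doubles the one-sided p, capped at 1.
    ``plus_one`` uses the (count+1)/(N+1) convention instead of the literal
    count/N.
    """
    control_stats = np.asarray(control_stats, dtype=float)
    if control_stats.size < 1:
        raise ValueError("need at least one control statistic")
    if not np.isfinite(observed_stat):
        raise ValueError("observed statistic must be finite")
    n = control_stats.size
    mean = float(control_stats.mean())
    resolved = side
    if side in ("auto", "two-sided"):
        resolved = "enrichment" if observed_stat >= mean else "depletion"
    if resolved == "enrichment":
        count = int((control_stats >= observed_stat).sum())
    elif resolved == "depletion":
        count = int((control_stats <= observed_stat).sum())
    else:
        raise ValueError(f"unknown side {side!r}")
    p = (count + 1) / (n + 1) if plus_one else count / n
    if side == "two-sided":
        p = min(1.0, 2 * p)
        resolved = "two-sided"
    return TestResult(
        name=name,
        observed=float(observed_stat),
        null_value=mean,
        p=float(p),
        side=resolved,
        n_controls=n,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def attach_fdr(results: list[TestResult]) -> list[TestResult]:
    """Fill ``q`` across a batch of results tested together."""
    qs = bh_fdr([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return results
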