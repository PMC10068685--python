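"""Correlation of imaging response with PSA response.

Each compartment's signed percent change is correlated with the signed
PSA percent change across patients (Pearson product-moment r), using
pairwise-complete deletion: a patient enters a compartment's
correlation only if both that compartment's change and the PSA change
are known.  Significance is the two-tailed t test

    t = r * sqrt((n - 2) / (1 - r^2)),   p = 2 * (1 - F_t(|t|; n - 2))

A compartment whose correlation cannot be computed (fewer than two
complete pairs, or zero variance) is *suppressed* rather than reported;
a column that is nearly constant (the prostate/bed column of a cohort
of near-complete responders) gets its r and p computed but is flagged
low-variance, because a correlation against an almost-degenerate
predictor is not meaningfully interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .response import PCT_COLUMNS, CohortTable

#: A column whose modal value exceeds this share of entries is flagged
#: low-variance.
LOW_VARIANCE_MODAL_SHARE = 0.75


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r of one compartment's response vs PSA response."""

    compartment: str
    r: float | None
    n: int
    p_two_tailed: float | None
    suppressed: bool = False
    low_variance: bool = False
    perfect: bool = False  # |r| = 1: p reported as 0 with this flag set

    def as_dict(self) -> dict:
        return {
            "compartment": self.compartment,
            "r": None if self.r is None else float(self.r),
            "n": int(self.n),
            "p_two_tailed": None if self.p_two_tailed is None else float(self.p_two_tailed),
            "suppressed": bool(self.suppressed),
            "low_variance": bool(self.low_variance),
        }


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation; inputs must be same-length, n >= 2,
    with nonzero variance in both."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1D vectors of equal length")
    if len(x) < 2:
        raise ValueError(f"need at least 2 pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    return float(sps.pearsonr(x, y).statistic)


def r_significance(r: float, n: int) -> float:
    """Two-tailed p-value of a Pearson r via the t distribution with n-2 df.

    For |r| = 1 the t statistic diverges; p is reported as exactly 0
    (callers flag this case).
    """
    if n < 3:
        raise ValueError(f"need n >= 3 for a t test, got {n}")
    if abs(r) > 1:
        raise ValueError(f"|r| must be <= 1, got {r}")
    if abs(r) == 1:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def _modal_share(v: np.ndarray) -> float:
    _, counts = np.unique(v, return_counts=True)
    return counts.max() / len(v)


def correlate_columns(x: np.ndarray, y: np.ndarray, compartment: str) -> CorrelationResult:
    """Correlate one complete pair of columns, with suppression semantics."""
    n = len(x)
    try:
        r = pearson_r(x, y)
    except ValueError:
        return CorrelationResult(compartment, None, n, None, suppressed=True)
    perfect = abs(r) >= 1.0 - 1e-15
    p = r_significance(r, n) if n >= 3 else None
    return CorrelationResult(
        compartment,
        r,
        n,
        p,
        low_variance=bool(_modal_share(x) > LOW_VARIANCE_MODAL_SHARE),
        perfect=perfect,
    )


def correlate_table(table: CohortTable) -> list[CorrelationResult]:
    """One Pearson result per compartment column vs the PSA column.

    Pairwise-complete per column; new-disease rows are excluded.  Order:
    nodal, osseous, prostate_bed, composite.
    """
    results = []
    for col, comp in PCT_COLUMNS.items():
        pairs = table.column_pairs(col)
        results.append(
            correlate_columns(
                pairs[col].to_numpy(), pairs["psa_pct"].to_numpy(), comp
            )
        )
    return results
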