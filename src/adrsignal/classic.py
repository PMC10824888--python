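"""Traditional disproportionality measures: PRR, ROR and the O/E ratio.

For a 2x2 table with cells a = n_ij, b = n_i. - n_ij, c = n_.j - n_ij,
d = n - n_i. - n_.j + n_ij:

* PRR  = (n_ij / n_i.) / ((n_.j - n_ij) / (n - n_i.))   -- reporting-rate ratio
* ROR  = a d / (b c)                                     -- reporting odds ratio
* RRR  = n_ij / E_ij,  E_ij = n_i. n_.j / n              -- observed / expected

Confidence intervals are the standard log-scale Wald forms
``exp(log m +/- z * se)`` with

* ``se^2(log PRR) = 1/a - 1/n_i. + 1/c - 1/(n - n_i.)``
* ``se^2(log ROR) = 1/a + 1/b + 1/c + 1/d``

and a pair is flagged as a signal when the lower 95% limit exceeds 1.  When a
required cell is zero the CI (and hence the signal) is undefined; this is the
well-known failure mode of the traditional measures that the mixed model
avoids.  An optional Haldane correction (adding 0.5 to every cell) is
available but off by default so that the zero-cell behaviour is faithful.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .tabulate import ContingencyTable

__all__ = ["SignalRow", "prr", "ror", "rrr"]


@dataclass(frozen=True)
class SignalRow:
    """One disproportionality estimate with its 95% CI and signal flag."""

    drug: str
    adr: str
    measure: str          # "PRR" | "ROR" | "RRR"
    estimate: float
    ci_lower: float       # NaN when undefined
    ci_upper: float
    signal: bool
    method: str = "traditional"


def _z(alpha: float) -> float:
    return float(norm.ppf(1.0 - alpha / 2.0))


def prr(table: ContingencyTable, alpha: float = 0.05, *,
        haldane: bool = False, drug: str = "drug", adr: str = "adr") -> SignalRow:
    """Proportional reporting ratio with a log-scale Wald CI."""
    a, b, c, d = (x + 0.5 for x in table.cells) if haldane else table.cells
    n_drug, n_other = a + b, c + d
    if n_drug <= 0 or n_other <= 0:
        raise ValueError("PRR needs exposed and unexposed reports (n_i. > 0, n - n_i. > 0)")
    est = (a / n_drug) / (c / n_other) if c > 0 else (0.0 if a == 0 else np.inf)
    if a > 0 and c > 0:
        se = np.sqrt(1 / a - 1 / n_drug + 1 / c - 1 / n_other)
        lo, hi = np.exp(np.log(est) + np.array([-1, 1]) * _z(alpha) * se)
    else:
        lo = hi = np.nan
    return SignalRow(drug, adr, "PRR", float(est), float(lo), float(hi),
                     signal=bool(np.isfinite(lo) and lo > 1.0))


def ror(table: ContingencyTable, alpha: float = 0.05, *,
        haldane: bool = False, drug: str = "drug", adr: str = "adr") -> SignalRow:
    """Reporting odds ratio with a log-scale Wald CI."""
    a, b, c, d = (x + 0.5 for x in table.cells) if haldane else table.cells
    if a + b <= 0 or c + d <= 0:
        raise ValueError("ROR needs exposed and unexposed reports")
    with np.errstate(divide="ignore", invalid="ignore"):
        est = (a * d) / (b * c) if b * c > 0 else (0.0 if a * d == 0 else np.inf)
    if min(a, b, c, d) > 0:
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        lo, hi = np.exp(np.log(est) + np.array([-1, 1]) * _z(alpha) * se)
    else:
        lo = hi = np.nan
    return SignalRow(drug, adr, "ROR", float(est), float(lo), float(hi),
                     signal=bool(np.isfinite(lo) and lo > 1.0))


def rrr(table: ContingencyTable, *, drug: str = "drug", adr: str = "adr") -> SignalRow:
    """Relative reporting ratio n_ij / E_ij (reported without a CI)."""
    if table.n_drug <= 0 or table.n_adr <= 0:
        raise ValueError("RRR needs non-zero margins n_i. and n_.j")
    expected = table.n_drug * table.n_adr / table.n_total
    est = table.n_joint / expected
    return SignalRow(drug, adr, "RRR", float(est), np.nan, np.nan, signal=False)


# ---------------------------------------------------------------------------
# vectorised forms used by the screening/simulation layers


def prr_arrays(a, n_drug, c, n_other, alpha: float = 0.05):
    """Vectorised PRR: returns (estimate, ci_lower, ci_upper) arrays.

    Entries with a == 0 or c == 0 get estimate 0/inf and NaN limits.
    """
    a = np.asarray(a, float)
    c = np.asarray(c, float)
    z = _z(alpha)
    with np.errstate(divide="ignore", invalid="ignore"):
        est = (a / n_drug) / (c / n_other)
        se = np.sqrt(1 / a - 1 / n_drug + 1 / c - 1 / n_other)
        lo = np.exp(np.log(est) - z * se)
        hi = np.exp(np.log(est) + z * se)
    bad = (a <= 0) | (c <= 0)
    est = np.where(a <= 0, 0.0, np.where(c <= 0, np.inf, est))
    lo, hi = (np.where(bad, np.nan, v) for v in (lo, hi))
    return est, lo, hi


def ror_arrays(a, b, c, d, alpha: float = 0.05):
    """Vectorised ROR on the four cells; NaN limits when any cell is 0."""
    a, b, c, d = (np.asarray(x, float) for x in (a, b, c, d))
    z = _z(alpha)
    with np.errstate(divide="ignore", invalid="ignore"):
        est = (a * d) / (b * c)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        lo = np.exp(np.log(est) - z * se)
        hi = np.exp(np.log(est) + z * se)
    bad = (np.minimum(np.minimum(a, b), np.minimum(c, d)) <= 0)
    est = np.where((a == 0) | (d == 0), 0.0, np.where(bad, np.where(est > 0, est, np.inf), est))
    lo, hi = (np.where(bad, np.nan, v) for v in (lo, hi))
    return est, lo, hi
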