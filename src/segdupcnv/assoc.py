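"""Exact case/control association from 2x2 carrier counts.

The two-sided Fisher p-value uses the point-probability rule (sum the
hypergeometric probabilities of all tables with fixed margins whose
probability does not exceed the observed table's), the convention of the
standard R implementation. The confidence interval is the exact conditional
interval obtained by inverting the noncentral (Fisher) hypergeometric
distribution, and the reported conditional maximum-likelihood odds ratio
solves E[X | psi] = x under that distribution. The sample cross-product
odds ratio is reported alongside, with a Haldane-Anscombe 0.5 correction
when a cell is empty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import fisher_exact as _scipy_fisher
from scipy.stats import nchypergeom_fisher


@dataclass(frozen=True)
class ContingencyTable:
    """Carrier counts: rows carrier/noncarrier, columns case/control."""

    case_carriers: int
    control_carriers: int
    case_noncarriers: int
    control_noncarriers: int

    def __post_init__(self) -> None:
        cells = (
            self.case_carriers,
            self.control_carriers,
            self.case_noncarriers,
            self.control_noncarriers,
        )
        if any(c < 0 for c in cells):
            raise ValueError("counts must be non-negative")
        if sum(cells) == 0:
            raise ValueError("table is empty")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                [self.case_carriers, self.control_carriers],
                [self.case_noncarriers, self.control_noncarriers],
            ]
        )


@dataclass(frozen=True)
class AssociationResult:
    or_sample: float
    or_cmle: float
    p_two_sided: float
    ci: tuple[float, float]
    level: float
    haldane_corrected: bool = False
    one_sided_ci: bool = False


def odds_ratio(table: ContingencyTable) -> tuple[float, bool]:
    """Sample cross-product odds ratio; (value, Haldane-corrected flag)."""
    a, b = table.case_carriers, table.control_carriers
    c, d = table.case_noncarriers, table.control_noncarriers
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
        return (a * d) / (b * c), True
    return (a * d) / (b * c), False


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided exact p by the point-probability rule (log-space safe)."""
    _, p = _scipy_fisher(table.as_array(), alternative="two-sided")
    return float(p)


def _support_and_margins(table: ContingencyTable):
    a = table.case_carriers
    n_carrier = table.case_carriers + table.control_carriers
    n_case = table.case_carriers + table.case_noncarriers
    total = int(table.as_array().sum())
    lo = max(0, n_case + n_carrier - total)
    hi = min(n_case, n_carrier)
    return a, total, n_carrier, n_case, lo, hi


def _solve_logpsi(func, lo=-50.0, hi=50.0) -> float:
    return float(brentq(func, lo, hi, xtol=1e-12, rtol=1e-12))


def conditional_mle_or(table: ContingencyTable) -> float:
    """Odds ratio maximizing the conditional likelihood: E[X | psi] = x."""
    x, total, n_carrier, n_case, lo, hi = _support_and_margins(table)
    if x == lo:
        return 0.0
    if x == hi:
        return float("inf")

    def mean_gap(logpsi: float) -> float:
        dist = nchypergeom_fisher(total, n_carrier, n_case, np.exp(logpsi))
        return float(dist.mean()) - x

    return float(np.exp(_solve_logpsi(mean_gap)))


def exact_ci(
    table: ContingencyTable, level: float = 0.95
) -> tuple[tuple[float, float], float, bool]:
    """Exact conditional CI by tail inversion; returns (ci, cmle, one_sided).

    The lower bound solves P(X >= x | psi) = (1-level)/2, the upper bound
    P(X <= x | psi) = (1-level)/2. When the observed count sits at an edge
    of the conditional support, the corresponding bound is degenerate (0 or
    infinity) and the interval is flagged one-sided.
    """
    if not (0 < level < 1):
        raise ValueError("level must lie in (0, 1)")
    alpha = (1.0 - level) / 2.0
    x, total, n_carrier, n_case, lo, hi = _support_and_margins(table)

    def upper_tail(logpsi: float) -> float:
        dist = nchypergeom_fisher(total, n_carrier, n_case, np.exp(logpsi))
        return float(dist.sf(x - 1)) - alpha

    def lower_tail(logpsi: float) -> float:
        dist = nchypergeom_fisher(total, n_carrier, n_case, np.exp(logpsi))
        return float(dist.cdf(x)) - alpha

    one_sided = False
    if x == lo:
        low = 0.0
        one_sided = True
    else:
        low = float(np.exp(_solve_logpsi(upper_tail)))
    if x == hi:
        high = float("inf")
        one_sided = True
    else:
        high = float(np.exp(_solve_logpsi(lower_tail)))
    return (low, high), conditional_mle_or(table), one_sided


def associate(table: ContingencyTable, level: float = 0.95) -> AssociationResult:
    """Full exact association summary for one 2x2 table."""
    or_sample, corrected = odds_ratio(table)
    p = fisher_exact(table)
    ci, or_cmle, one_sided = exact_ci(table, level)
    return AssociationResult(
        or_sample=or_sample,
        or_cmle=or_cmle,
        p_two_sided=p,
        ci=ci,
        level=level,
        haldane_corrected=corrected,
        one_sided_ci=one_sided,
    )
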