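"""Closed-form descriptors of the target compartment and the analytic
errors made by a closed-compartment fit.

At equilibrium the target compartment of the precursor/target model is
summarised by three rates and one dimensionless ratio:

* proliferation p_E,
* turnover T = r 2^k C/E + p_E (total inflow = outflow d_E),
* production by division P = r (2^k - 1) C/E + p_E,
* influx ratio X = r 2^k C/E / d_E = (d_E - p_E) / d_E, the fraction of
  target turnover supplied by precursor differentiation.

A one-compartment fit to target data estimates P. Equating that estimate
with proliferation or turnover incurs relative errors that depend only
on X and k:

    100 (P - p_E) / p_E = 100 X (2^k - 1) / ((1 - X) 2^k)
    100 (T - P) / T     = 100 X / 2^k

Four qualitative regimes (cases) follow from whether k is zero and
whether X is appreciable: A (k > 0, large X: proliferation overestimated),
B (k > 0, X ~ 0), C (k = 0, large X: turnover underestimated) and
D (k = 0, X ~ 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import PrecursorTargetParams

__all__ = [
    "TargetDescriptors",
    "descriptors",
    "proliferation_error_theory",
    "turnover_error_theory",
    "classify_case",
    "upstream_bound",
]

#: X below this is treated as "close to zero" when labelling cases.
DEFAULT_X_THRESHOLD = 0.1


@dataclass(frozen=True)
class TargetDescriptors:
    proliferation: float
    turnover: float
    production_by_division: float
    influx_ratio: float
    case_label: str

    def __post_init__(self) -> None:
        if not self.proliferation <= self.production_by_division + 1e-12:
            raise ValueError("production by division cannot be below proliferation")
        if not self.production_by_division <= self.turnover + 1e-12:
            raise ValueError("turnover cannot be below production by division")
        if not 0.0 <= self.influx_ratio < 1.0 + 1e-12:
            raise ValueError("influx ratio must lie in [0, 1)")


def descriptors(
    params: PrecursorTargetParams, x_threshold: float = DEFAULT_X_THRESHOLD
) -> TargetDescriptors:
    """Compute (p_E, T, P, X) and the case label for a parameter set."""
    two_k = 2.0**params.k
    influx = params.r * two_k * params.ratio_CE
    turnover = influx + params.p_E
    production = params.r * (two_k - 1.0) * params.ratio_CE + params.p_E
    x = influx / turnover if turnover > 0 else 0.0
    return TargetDescriptors(
        proliferation=params.p_E,
        turnover=turnover,
        production_by_division=production,
        influx_ratio=x,
        case_label=classify_case(x, params.k, x_threshold),
    )


def proliferation_error_theory(x, k):
    """Percent error from equating production by division with proliferation.

    100 (P - p_E) / p_E = 100 X (2^k - 1) / ((1 - X) 2^k); non-decreasing
    in both X and k, and identically zero for k = 0 (influx unlabelled).
    """
    x = np.asarray(x, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any(x < 0) or np.any(x >= 1):
        raise ValueError("influx ratio X must lie in [0, 1)")
    if np.any(k < 0):
        raise ValueError("k must be non-negative")
    two_k = 2.0**k
    out = 100.0 * x * (two_k - 1.0) / ((1.0 - x) * two_k)
    return out if out.ndim else float(out)


def turnover_error_theory(x, k):
    """Percent error from equating production by division with turnover.

    100 (T - P) / T = 100 X / 2^k; increases with X, decreases with k.
    """
    x = np.asarray(x, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any(x < 0) or np.any(x >= 1):
        raise ValueError("influx ratio X must lie in [0, 1)")
    if np.any(k < 0):
        raise ValueError("k must be non-negative")
    out = 100.0 * x / 2.0**k
    return out if out.ndim else float(out)


def classify_case(x, k, x_threshold: float = DEFAULT_X_THRESHOLD) -> str:
    """Label the (X, k) regime: A, B (k > 0) or C, D (k = 0).

    A and C have appreciable precursor influx (X >= ``x_threshold``);
    B and D have X close to zero. k is compared exactly with zero: any
    positive (possibly fractional) k counts as division-linked.
    """
    if not 0.0 <= x < 1.0:
        raise ValueError("influx ratio X must lie in [0, 1)")
    if k < 0:
        raise ValueError("k must be non-negative")
    large_influx = x >= x_threshold
    if k > 0:
        return "A" if large_influx else "B"
    return "C" if large_influx else "D"


def upstream_bound(p_C: float, ratio_CE: float) -> float:
    """Upper bound p_C * C/E on the turnover / production-by-division gap.

    T - P = r C/E and r <= p_C, so the bound holds for any admissible
    differentiation rate and is attained at r = p_C.
    """
    if p_C < 0 or ratio_CE < 0:
        raise ValueError("p_C and ratio_CE must be non-negative")
    return p_C * ratio_CE
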