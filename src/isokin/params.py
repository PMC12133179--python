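"""Parameter containers for the compartmental labelling models.

All rates are day^-1 and all compartments are assumed to be at population
equilibrium, which ties some rates together:

* precursor/target: p_C = d_C + r and d_E = r 2^k C/E + p_E, so the
  precursor-to-target size ratio C/E is (d_E - p_E) / (r 2^k);
* explicit kinetic heterogeneity: each subpopulation has d_i = p_i;
* blood/lymph: d = p and g = f_recirc * B/A.

Kinetic heterogeneity within a compartment is approximated implicitly by
giving labelled cells their own disappearance rate (d_C*, d_E*, d*),
expected to be at least the population-average rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OneCompartmentParams",
    "PrecursorTargetParams",
    "ExplicitHeterogeneityParams",
    "RealisticTargetParams",
    "BloodLymphParams",
]


@dataclass(frozen=True)
class OneCompartmentParams:
    """Closed single-compartment model: dF/dt = p b_w U(t) - d* F.

    ``p`` is production by division; ``d_star`` the disappearance rate of
    labelled cells. The kinetically homogeneous special case is
    ``d_star == p``.
    """

    p: float
    d_star: float

    def __post_init__(self) -> None:
        if self.p < 0:
            raise ValueError(f"p must be non-negative, got {self.p}")
        if self.d_star < 0:
            raise ValueError(f"d_star must be non-negative, got {self.d_star}")


@dataclass(frozen=True)
class PrecursorTargetParams:
    """Two-compartment precursor (C) -> target (E) model.

    Precursor cells proliferate at ``p_C``, die at ``d_C`` and
    differentiate at ``r``; each differentiating cell divides ``k`` times
    (k = 0 means differentiation without division). Target cells
    proliferate at ``p_E`` and disappear at ``d_E``. ``d_C_star`` and
    ``d_E_star`` are the disappearance rates of *labelled* cells, which
    absorb within-compartment kinetic heterogeneity.

    Equilibrium fixes d_C = p_C - r and the size ratio
    ``ratio_CE`` = C/E = (d_E - p_E) / (r 2^k).
    """

    p_C: float
    r: float
    k: float
    d_C_star: float
    p_E: float
    d_E: float
    d_E_star: float

    def __post_init__(self) -> None:
        for name in ("p_C", "r", "k", "d_C_star", "p_E", "d_E", "d_E_star"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.r > self.p_C:
            raise ValueError("differentiation rate r must not exceed p_C")
        if self.d_C_star < self.d_C - 1e-12:
            raise ValueError("d_C_star must be >= d_C (labelled cells disappear at least as fast)")
        if self.d_E_star < self.d_E - 1e-12:
            raise ValueError("d_E_star must be >= d_E")
        if self.d_E < self.p_E:
            raise ValueError("equilibrium requires d_E >= p_E (influx term non-negative)")
        if self.r == 0 and self.d_E > self.p_E:
            raise ValueError("r = 0 with d_E > p_E leaves the C/E size ratio undefined")

    @property
    def d_C(self) -> float:
        """Population-average precursor disappearance rate, p_C - r."""
        return self.p_C - self.r

    @property
    def ratio_CE(self) -> float:
        """Equilibrium size ratio C/E = (d_E - p_E) / (r 2^k)."""
        if self.r == 0:
            return 0.0
        return (self.d_E - self.p_E) / (self.r * 2.0**self.k)


@dataclass(frozen=True)
class ExplicitHeterogeneityParams:
    """N unconnected subpopulations, each at equilibrium (d_i = p_i).

    ``p`` are the subpopulation proliferation rates and ``alpha`` their
    relative sizes (summing to 1). The total labelled fraction is the
    alpha-weighted mixture of the subpopulation curves. The fitted
    parameter count is 2N - 1.
    """

    p: np.ndarray
    alpha: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "p", np.atleast_1d(np.asarray(self.p, dtype=float)))
        object.__setattr__(self, "alpha", np.atleast_1d(np.asarray(self.alpha, dtype=float)))
        if self.p.size == 0:
            raise ValueError("at least one subpopulation is required")
        if self.p.shape != self.alpha.shape:
            raise ValueError("p and alpha must have the same length")
        if np.any(self.p < 0):
            raise ValueError("proliferation rates must be non-negative")
        if np.any(self.alpha <= 0) or np.any(self.alpha >= 1 + 1e-12):
            if self.alpha.size > 1 or not np.isclose(self.alpha[0], 1.0):
                raise ValueError("each alpha_i must lie in (0, 1)")
        if not np.isclose(self.alpha.sum(), 1.0, atol=1e-8):
            raise ValueError(f"alpha must sum to 1, got {self.alpha.sum()}")

    @property
    def n_subpopulations(self) -> int:
        return int(self.p.size)

    @property
    def mean_proliferation(self) -> float:
        """Size-weighted mean proliferation rate, sum_i alpha_i p_i."""
        return float(np.dot(self.alpha, self.p))

    def sorted_by_alpha(self) -> "ExplicitHeterogeneityParams":
        """Return an equivalent parameter set with alpha non-decreasing.

        The mixture is invariant under relabelling; ordering by weight is
        the convention used to resolve label switching when fitting.
        """
        order = np.argsort(self.alpha, kind="stable")
        return ExplicitHeterogeneityParams(p=self.p[order], alpha=self.alpha[order])


@dataclass(frozen=True)
class RealisticTargetParams:
    """Precursor feeding a kinetically heterogeneous, two-part target.

    Differentiating precursor output is split: a fraction ``gamma`` of
    cells enters target subpopulation E1 and the remainder E2. Each
    subpopulation proliferates (p1, p2) and disappears (d1, d2)
    independently and is independently at equilibrium, which fixes the
    size ratios C/E1 and C/E2. The observable is the size-weighted
    labelled fraction of E1 and E2 combined.
    """

    p_C: float
    r: float
    k: float
    d_C_star: float
    gamma: float
    p1: float
    d1: float
    p2: float
    d2: float

    def __post_init__(self) -> None:
        for name in ("p_C", "r", "k", "d_C_star", "p1", "d1", "p2", "d2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must lie in [0, 1], got {self.gamma}")
        if self.r > self.p_C:
            raise ValueError("differentiation rate r must not exceed p_C")
        if self.d1 < self.p1 or self.d2 < self.p2:
            raise ValueError("equilibrium requires d_i >= p_i in each target subpopulation")
        for g, d, p, lab in ((self.gamma, self.d1, self.p1, "E1"), (1 - self.gamma, self.d2, self.p2, "E2")):
            if g * self.r == 0 and d > p + 1e-15:
                raise ValueError(f"no influx into {lab} but d > p: size ratio undefined")

    @property
    def ratio_CE1(self) -> float:
        """C/E1 from E1 equilibrium: d1 = gamma r 2^k (C/E1) + p1."""
        if self.gamma * self.r == 0:
            return 0.0
        return (self.d1 - self.p1) / (self.gamma * self.r * 2.0**self.k)

    @property
    def ratio_CE2(self) -> float:
        if (1.0 - self.gamma) * self.r == 0:
            return 0.0
        return (self.d2 - self.p2) / ((1.0 - self.gamma) * self.r * 2.0**self.k)

    @property
    def target_weights(self) -> tuple[float, float]:
        """Relative equilibrium sizes (w1, w2) of E1 and E2, w1 + w2 = 1."""
        # E_i proportional to 1 / (C/E_i); a zero ratio means influx-free
        # subpopulation whose size is not pinned by the precursor -- in that
        # case fall back to gamma as the size split.
        r1, r2 = self.ratio_CE1, self.ratio_CE2
        if r1 > 0 and r2 > 0:
            e1, e2 = 1.0 / r1, 1.0 / r2
            return e1 / (e1 + e2), e2 / (e1 + e2)
        return self.gamma, 1.0 - self.gamma


@dataclass(frozen=True)
class BloodLymphParams:
    """Lymphoid-tissue (A) / blood (B) exchange model.

    Cells proliferate (p) and disappear (d) in tissue only, enter blood
    at rate g and return to tissue at rate f_recirc. Equilibrium imposes
    d = p and g = f_recirc * B/A, with the blood-to-tissue size ratio
    ``ratio_BA`` about 2/98 for lymphocytes. Only blood label F_B is
    observable.
    """

    p: float
    f_recirc: float
    ratio_BA: float = 2.0 / 98.0

    def __post_init__(self) -> None:
        if self.p < 0:
            raise ValueError(f"p must be non-negative, got {self.p}")
        if self.f_recirc <= 0:
            raise ValueError(f"f_recirc must be positive, got {self.f_recirc}")
        if self.ratio_BA <= 0:
            raise ValueError(f"ratio_BA must be positive, got {self.ratio_BA}")

    @property
    def d(self) -> float:
        """Tissue disappearance rate, equal to p at equilibrium."""
        return self.p

    @property
    def g(self) -> float:
        """Tissue-to-blood exit rate, f_recirc * B/A at equilibrium."""
        return self.f_recirc * self.ratio_BA
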