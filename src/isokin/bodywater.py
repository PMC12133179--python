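"""Deuterium enrichment of body water during and after label administration.

During a labelling phase of length ``tau`` (days) the fraction of deuterium
in body water rises towards a plateau ``f_plateau`` at rate ``delta``
(day^-1, the turnover rate of body water); after label withdrawal the
enrichment decays exponentially at the same rate:

    U(t) = f * (1 - exp(-delta * t))          for 0 <= t <= tau
    U(t) = U(tau) * exp(-delta * (t - tau))   for t > tau

U(t) is the forcing function of every labelling model in this package:
dividing cells incorporate label in proportion to ``b_w * U(t)`` where
``b_w`` is the amplification (normalisation) factor for water.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BodyWaterCurve", "PerfectLabelCurve", "body_water_fraction"]


@dataclass(frozen=True)
class BodyWaterCurve:
    """Empirical body-water enrichment curve.

    Parameters
    ----------
    f_plateau : float
        Plateau enrichment, the expected fraction of D2O in daily water
        intake. Dimensionless, in (0, 1).
    delta : float
        Rate (day^-1) at which the plateau is approached and at which
        enrichment decays after label withdrawal.
    tau : float
        Length of the labelling phase in days.
    b_w : float
        Amplification factor for water, multiplying U(t) wherever label
        is incorporated. Default 4.18.
    """

    f_plateau: float = 0.032
    delta: float = 0.07
    tau: float = 49.0
    b_w: float = 4.18

    def __post_init__(self) -> None:
        if not 0.0 < self.f_plateau < 1.0:
            raise ValueError(f"f_plateau must be in (0, 1), got {self.f_plateau}")
        if self.delta <= 0:
            raise ValueError(f"delta must be positive, got {self.delta}")
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.b_w <= 0:
            raise ValueError(f"b_w must be positive, got {self.b_w}")

    def __call__(self, t):
        return body_water_fraction(self, t)


@dataclass(frozen=True)
class PerfectLabelCurve:
    """Idealised label availability: U(t) = 1 during labelling, 0 after.

    Used to emulate experiments analysed with the assumption of
    instantaneous, complete precursor labelling. ``b_w`` defaults to 1
    so that the incorporation term is exactly the on/off indicator.
    """

    tau: float = 49.0
    b_w: float = 1.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("t must be non-negative")
        out = np.where(t <= self.tau, 1.0, 0.0)
        return out if out.ndim else float(out)


def body_water_fraction(curve: BodyWaterCurve, t):
    """Evaluate the body-water enrichment U(t).

    Parameters
    ----------
    curve : BodyWaterCurve
    t : float or array-like
        Time(s) in days, non-negative.

    Returns
    -------
    float or ndarray
        Enrichment fraction(s); scalar in, scalar out.
    """
    if isinstance(curve, PerfectLabelCurve):
        return curve(t)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    f, delta, tau = curve.f_plateau, curve.delta, curve.tau
    u_tau = f * (1.0 - np.exp(-delta * tau))
    rising = f * (1.0 - np.exp(-delta * np.minimum(t, tau)))
    decaying = u_tau * np.exp(-delta * np.clip(t - tau, 0.0, None))
    out = np.where(t <= tau, rising, decaying)
    return out if out.ndim else float(out)
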