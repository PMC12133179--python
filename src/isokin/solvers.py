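"""Forward solvers for the labelling models.

Every model here is a linear, constant-coefficient compartmental ODE
system forced by the body-water enrichment U(t), which is itself a sum of
exponentials on each phase (labelling / delabelling). All solutions are
therefore exponential sums and are evaluated in closed form; iterated
convolutions are computed with cancellation-free ``expm1``-based kernels.

Parameter sets that bring two decay rates closer than ``DEGENERATE_TOL``
(where the partial-fraction closed form loses accuracy) are routed to an
adaptive numerical integrator instead. The numerical path is also exposed
directly (``*_numeric``) and serves as an independent cross-check of the
closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .bodywater import BodyWaterCurve, PerfectLabelCurve, body_water_fraction
from .params import (
    BloodLymphParams,
    ExplicitHeterogeneityParams,
    OneCompartmentParams,
    PrecursorTargetParams,
    RealisticTargetParams,
)

__all__ = [
    "LabelCurve",
    "solve_one_compartment",
    "solve_precursor_target",
    "solve_explicit_heterogeneity",
    "solve_realistic_target",
    "solve_blood_lymph",
    "one_compartment_label",
    "solve_one_compartment_numeric",
    "solve_precursor_target_numeric",
    "solve_explicit_heterogeneity_numeric",
    "solve_realistic_target_numeric",
    "solve_blood_lymph_numeric",
]

# Below this absolute separation of decay rates (day^-1) the closed form's
# partial fractions are abandoned for the numerical path.
DEGENERATE_TOL = 1e-9


@dataclass
class LabelCurve:
    """Labelled fractions over time for one or more compartments."""

    times: np.ndarray
    fractions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for name, values in self.fractions.items():
            values = np.asarray(values, dtype=float)
            if values.shape != self.times.shape:
                raise ValueError(f"compartment {name!r} has mismatched length")
            if not np.all(np.isfinite(values)):
                raise ValueError(f"compartment {name!r} contains non-finite values")
            self.fractions[name] = values

    def __getitem__(self, compartment: str) -> np.ndarray:
        return self.fractions[compartment]

    @property
    def compartments(self) -> list[str]:
        return list(self.fractions)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns time_days, compartment, fraction_labelled."""
        rows = [
            pd.DataFrame(
                {"time_days": self.times, "compartment": name, "fraction_labelled": values}
            )
            for name, values in self.fractions.items()
        ]
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LabelCurve":
        df = pd.read_csv(path)
        fractions = {}
        times = None
        for name, group in df.groupby("compartment", sort=False):
            group = group.sort_values("time_days")
            t = group["time_days"].to_numpy(dtype=float)
            if times is None:
                times = t
            elif not np.array_equal(times, t):
                raise ValueError("compartments have inconsistent time grids")
            fractions[str(name)] = group["fraction_labelled"].to_numpy(dtype=float)
        if times is None:
            raise ValueError("no rows found")
        return cls(times=times, fractions=fractions)


# ---------------------------------------------------------------------------
# exponential-sum kernels


def _conv(a, b, t):
    """Convolution integral int_0^t exp(-a (t-s)) exp(-b s) ds.

    Equals (exp(-b t) - exp(-a t)) / (a - b) for a != b and t exp(-a t)
    in the limit a -> b. Near-coincident rates are evaluated through the
    cancellation-free expm1 form; well-separated rates through the direct
    difference (which cannot overflow). Broadcasts over all arguments.
    _conv(a, 0, t) = (1 - exp(-a t)) / a.
    """
    a, b, t = np.broadcast_arrays(
        np.asarray(a, dtype=float), np.asarray(b, dtype=float), np.asarray(t, dtype=float)
    )
    x = (a - b) * t
    small = np.abs(x) < 1e-3
    xs = np.where(small, x, 1.0)
    h = np.where(xs == 0.0, 1.0, np.expm1(xs) / np.where(xs == 0.0, 1.0, xs))
    near = np.exp(-a * t) * t * h
    denom = np.where(small, 1.0, a - b)
    apart = (np.exp(-b * t) - np.exp(-a * t)) / denom
    return np.where(small, near, apart)


def _dconv(d, a, b, t):
    """Iterated convolution int_0^t exp(-d (t-s)) _conv(a, b, s) ds.

    Partial-fraction form; requires |a - b| above DEGENERATE_TOL.
    """
    return (_conv(d, b, t) - _conv(d, a, t)) / (a - b)


def _phase_forcing(curve, which: int):
    """Forcing terms of b_w^-1 * input on phase 0 (labelling) or 1 (after).

    Returns a list of (coefficient, decay-rate) pairs such that the label
    availability on the phase is sum_j c_j exp(-rho_j * u) with u the time
    since phase start.
    """
    if isinstance(curve, PerfectLabelCurve):
        return [(1.0, 0.0)] if which == 0 else []
    f, delta, tau = curve.f_plateau, curve.delta, curve.tau
    if which == 0:
        return [(f, 0.0), (-f, delta)]
    u_tau = f * (1.0 - np.exp(-delta * tau))
    return [(u_tau, delta)]


def _split_times(times, tau):
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    in_label = times <= tau
    return times, in_label


# ---------------------------------------------------------------------------
# one-compartment model


def one_compartment_label(p, d_star, curve, times):
    """Labelled fraction of a closed compartment, dF/dt = p b_w U(t) - d* F.

    ``p`` and ``d_star`` may be arrays (broadcast against each other);
    the result has shape ``broadcast(p, d_star).shape + times.shape``.
    This is the low-level kernel used by the likelihoods; the limit
    d* -> delta (resonant forcing) is handled analytically.
    """
    p = np.asarray(p, dtype=float)
    d_star = np.asarray(d_star, dtype=float)
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    scalar_params = p.ndim == 0 and d_star.ndim == 0
    q = p[..., None] * curve.b_w
    d = d_star[..., None]
    tau = curve.tau

    t_label = np.minimum(times, tau)
    u = np.clip(times - tau, 0.0, None)
    f_label = 0.0
    f_tau = 0.0
    for c, rho in _phase_forcing(curve, 0):
        f_label = f_label + q * c * _conv(d, rho, t_label)
        f_tau = f_tau + q * c * _conv(d, rho, tau)
    f_after = f_tau * np.exp(-d * u)
    for c, rho in _phase_forcing(curve, 1):
        f_after = f_after + q * c * _conv(d, rho, u)

    out = np.where(times <= tau, f_label, f_after)
    return out.reshape(times.shape) if scalar_params else out


def solve_one_compartment(params: OneCompartmentParams, curve, times) -> LabelCurve:
    """Closed-form labelling curve of the one-compartment model."""
    times = np.asarray(times, dtype=float)
    f = one_compartment_label(params.p, params.d_star, curve, times)
    return LabelCurve(times=times, fractions={"E": np.asarray(f, dtype=float)})


def solve_one_compartment_numeric(params: OneCompartmentParams, curve, times) -> LabelCurve:
    """Adaptive-integrator solution; independent check of the closed form."""
    def rhs(t, y):
        u = body_water_fraction(curve, t)
        return [params.p * curve.b_w * u - params.d_star * y[0]]

    f = _integrate(rhs, 1, curve, times)
    return LabelCurve(times=times, fractions={"E": f[0]})


# ---------------------------------------------------------------------------
# precursor/target model


def _precursor_target_rates(params: PrecursorTargetParams, heterogeneous: bool):
    d_C_eff = params.d_C_star if heterogeneous else params.d_C
    d_E_eff = params.d_E_star if heterogeneous else params.d_E
    a = d_C_eff + params.r  # precursor label decay rate
    ratio = params.ratio_CE
    s_r = params.r * ratio  # source rate into target label
    q_C = params.p_C * 1.0
    q_E = (2.0**params.k - 1.0) * params.r * ratio + params.p_E
    return a, d_E_eff, q_C, q_E, s_r


def _pt_closed_form_ok(a, d, curve) -> bool:
    rates = [0.0, a, d]
    if isinstance(curve, BodyWaterCurve):
        rates.append(curve.delta)
    rates = np.sort(np.asarray(rates))
    return bool(np.all(np.diff(rates) > DEGENERATE_TOL))


def _cascade_label(a, d, q_C, q_E, s_r, curve, times):
    """Closed form for a target fed by one precursor.

    dF_C/dt = q_C b_w U - a F_C;  dF_E/dt = q_E b_w U + s_r F_C - d F_E.
    Returns (F_C, F_E) on ``times``.
    """
    times = np.asarray(times, dtype=float)
    tau = curve.tau
    b_w = curve.b_w
    qc, qe = q_C * b_w, q_E * b_w

    def phase_values(forcing, fc0, fe0, u):
        fc = fc0 * np.exp(-a * u)
        fe = fe0 * np.exp(-d * u) + s_r * fc0 * _conv(d, a, u)
        for c, rho in forcing:
            fc = fc + qc * c * _conv(a, rho, u)
            fe = fe + qe * c * _conv(d, rho, u) + s_r * qc * c * _dconv(d, a, rho, u)
        return fc, fe

    forcing0 = _phase_forcing(curve, 0)
    forcing1 = _phase_forcing(curve, 1)
    t_label = np.minimum(times, tau)
    fc_label, fe_label = phase_values(forcing0, 0.0, 0.0, t_label)
    fc_tau, fe_tau = phase_values(forcing0, 0.0, 0.0, np.asarray([tau]))
    u = np.clip(times - tau, 0.0, None)
    fc_after, fe_after = phase_values(forcing1, fc_tau, fe_tau, u)
    in_label = times <= tau
    fc = np.where(in_label, fc_label, fc_after)
    fe = np.where(in_label, fe_label, fe_after)
    return fc, fe


def solve_precursor_target(
    params: PrecursorTargetParams, curve, times, heterogeneous: bool = True
) -> LabelCurve:
    """Labelled fractions (F_C, F_E) of the precursor/target model.

    With ``heterogeneous=True`` (default) the labelled-cell disappearance
    rates d_C*, d_E* govern label loss; otherwise the population-average
    rates d_C, d_E are used (kinetically homogeneous compartments).
    """
    times = np.asarray(times, dtype=float)
    a, d, q_C, q_E, s_r = _precursor_target_rates(params, heterogeneous)
    if not _pt_closed_form_ok(a, d, curve):
        return solve_precursor_target_numeric(params, curve, times, heterogeneous)
    fc, fe = _cascade_label(a, d, q_C, q_E, s_r, curve, times)
    return LabelCurve(times=times, fractions={"C": fc, "E": fe})


def solve_precursor_target_numeric(
    params: PrecursorTargetParams, curve, times, heterogeneous: bool = True
) -> LabelCurve:
    a, d, q_C, q_E, s_r = _precursor_target_rates(params, heterogeneous)

    def rhs(t, y):
        u = body_water_fraction(curve, t) * curve.b_w
        return [q_C * u - a * y[0], q_E * u + s_r * y[0] - d * y[1]]

    f = _integrate(rhs, 2, curve, times)
    return LabelCurve(times=times, fractions={"C": f[0], "E": f[1]})


# ---------------------------------------------------------------------------
# explicit kinetic heterogeneity


def explicit_heterogeneity_label(p, alpha, curve, times):
    """Mixture labelled fraction sum_i alpha_i F_i with d_i = p_i.

    ``p`` and ``alpha`` have shape (..., N); broadcasting over leading
    axes supports vectorised likelihood evaluation. Returns an array of
    shape (..., len(times)).
    """
    p = np.asarray(p, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    per_sub = one_compartment_label(p, p, curve, times)  # (..., N, T)
    return np.einsum("...n,...nt->...t", alpha, per_sub)


def solve_explicit_heterogeneity(
    params: ExplicitHeterogeneityParams, curve, times
) -> LabelCurve:
    """Total labelled fraction of N unconnected subpopulations (d_i = p_i)."""
    times = np.asarray(times, dtype=float)
    total = explicit_heterogeneity_label(params.p, params.alpha, curve, times)
    fractions = {"E": np.asarray(total, dtype=float)}
    for i in range(params.n_subpopulations):
        fractions[f"E{i + 1}"] = one_compartment_label(
            params.p[i], params.p[i], curve, times
        )
    return LabelCurve(times=times, fractions=fractions)


def solve_explicit_heterogeneity_numeric(
    params: ExplicitHeterogeneityParams, curve, times
) -> LabelCurve:
    n = params.n_subpopulations

    def rhs(t, y):
        u = body_water_fraction(curve, t) * curve.b_w
        return params.p * u - params.p * y

    f = _integrate(rhs, n, curve, times)
    total = params.alpha @ f
    fractions = {"E": total}
    for i in range(n):
        fractions[f"E{i + 1}"] = f[i]
    return LabelCurve(times=times, fractions=fractions)


# ---------------------------------------------------------------------------
# heterogeneous-target (realistic) model


def solve_realistic_target(params: RealisticTargetParams, curve, times) -> LabelCurve:
    """Precursor feeding two independent target subpopulations.

    Returns the precursor curve, each subpopulation curve, and the
    observable "E": the size-weighted mixture of E1 and E2.
    """
    times = np.asarray(times, dtype=float)
    a = params.d_C_star + params.r
    two_k = 2.0**params.k
    w1, w2 = params.target_weights
    fractions: dict[str, np.ndarray] = {}
    fc_ref = None
    for label, g, p_i, d_i, ratio in (
        ("E1", params.gamma, params.p1, params.d1, params.ratio_CE1),
        ("E2", 1.0 - params.gamma, params.p2, params.d2, params.ratio_CE2),
    ):
        s_r = g * params.r * ratio
        q_E = g * (two_k - 1.0) * params.r * ratio + p_i
        if not _pt_closed_form_ok(a, d_i, curve):
            return solve_realistic_target_numeric(params, curve, times)
        fc, fe = _cascade_label(a, d_i, params.p_C, q_E, s_r, curve, times)
        fractions[label] = fe
        fc_ref = fc
    fractions["C"] = fc_ref
    fractions["E"] = w1 * fractions["E1"] + w2 * fractions["E2"]
    return LabelCurve(times=times, fractions=fractions)


def solve_realistic_target_numeric(params: RealisticTargetParams, curve, times) -> LabelCurve:
    a = params.d_C_star + params.r
    two_k = 2.0**params.k
    g1, g2 = params.gamma, 1.0 - params.gamma
    r1, r2 = params.ratio_CE1, params.ratio_CE2

    def rhs(t, y):
        u = body_water_fraction(curve, t) * curve.b_w
        fc, fe1, fe2 = y
        dfc = params.p_C * u - a * fc
        dfe1 = g1 * (two_k - 1.0) * u * params.r * r1 + g1 * params.r * r1 * fc + params.p1 * u - params.d1 * fe1
        dfe2 = g2 * (two_k - 1.0) * u * params.r * r2 + g2 * params.r * r2 * fc + params.p2 * u - params.d2 * fe2
        return [dfc, dfe1, dfe2]

    f = _integrate(rhs, 3, curve, times)
    w1, w2 = params.target_weights
    return LabelCurve(
        times=np.asarray(times, dtype=float),
        fractions={"C": f[0], "E1": f[1], "E2": f[2], "E": w1 * f[1] + w2 * f[2]},
    )


# ---------------------------------------------------------------------------
# blood / lymphoid-tissue exchange


def _blood_lymph_matrix(params: BloodLymphParams):
    R = params.ratio_BA
    f = params.f_recirc
    g = params.g
    M = np.array([[-(params.d + g), f * R], [g / R, -f]])
    v = np.array([params.p, 0.0])
    return M, v


def solve_blood_lymph(params: BloodLymphParams, curve, times) -> LabelCurve:
    """Labelled fractions in lymphoid tissue (A) and blood (B).

    Coupled 2x2 linear system solved by eigendecomposition; falls back
    to the numerical integrator for (near-)defective configurations.
    """
    times = np.asarray(times, dtype=float)
    M, v = _blood_lymph_matrix(params)
    mu, V = np.linalg.eig(M)
    rates = [0.0, -mu[0].real, -mu[1].real]
    if isinstance(curve, BodyWaterCurve):
        rates.append(curve.delta)
    if np.min(np.abs(np.diff(np.sort(rates)))) <= DEGENERATE_TOL or np.abs(mu[0].imag) > 0:
        return solve_blood_lymph_numeric(params, curve, times)
    mu = mu.real
    V = V.real
    Vinv = np.linalg.inv(V)
    w = Vinv @ v

    def phase_values(forcing, x0, u):
        # homogeneous part: V diag(e^{mu u}) V^-1 x0
        modes = np.exp(np.outer(u, mu))  # (n_times, 2)
        x = (modes * (Vinv @ x0)) @ V.T
        for c, rho in forcing:
            # forcing c b_w e^{-rho u} v: mode m contributes w_m conv(-mu_m, rho, u)
            contrib = _conv(-mu[None, :], rho, u[:, None]) * w
            x = x + curve.b_w * c * (contrib @ V.T)
        return x

    tau = curve.tau
    t_label = np.minimum(times, tau)
    x_label = phase_values(_phase_forcing(curve, 0), np.zeros(2), t_label)
    x_tau = phase_values(_phase_forcing(curve, 0), np.zeros(2), np.asarray([tau]))[0]
    u = np.clip(times - tau, 0.0, None)
    x_after = phase_values(_phase_forcing(curve, 1), x_tau, u)
    in_label = (times <= tau)[:, None]
    x = np.where(in_label, x_label.real, x_after.real)
    return LabelCurve(times=times, fractions={"A": x[:, 0], "B": x[:, 1]})


def solve_blood_lymph_numeric(params: BloodLymphParams, curve, times) -> LabelCurve:
    M, v = _blood_lymph_matrix(params)

    def rhs(t, y):
        u = body_water_fraction(curve, t) * curve.b_w
        return M @ y + v * u

    f = _integrate(rhs, 2, curve, times)
    return LabelCurve(
        times=np.asarray(times, dtype=float), fractions={"A": f[0], "B": f[1]}
    )


# ---------------------------------------------------------------------------
# shared numerical integrator


def _integrate(rhs, n_states, curve, times, rtol=1e-10, atol=1e-13):
    """Integrate ``rhs`` from zero initial conditions over ``times``.

    The integration is split at the end of the labelling phase where the
    forcing has a kink, so the adaptive stepper never straddles it.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    tau = curve.tau
    t_end = max(times[-1], tau) if times.size else tau
    out = np.zeros((n_states, times.size))
    y = np.zeros(n_states)
    segments = [(0.0, min(tau, t_end))]
    if t_end > tau:
        segments.append((tau, t_end))
    for lo, hi in segments:
        mask = (times >= lo) & (times <= hi) if lo == 0.0 else (times > lo) & (times <= hi)
        eval_ts = times[mask]
        sol = solve_ivp(
            rhs,
            (lo, hi),
            y,
            method="LSODA",
            t_eval=np.unique(np.concatenate([eval_ts, [hi]])),
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        lookup = {t: i for i, t in enumerate(sol.t)}
        for j, t in zip(np.nonzero(mask)[0], eval_ts):
            out[:, j] = sol.y[:, lookup[t]]
        y = sol.y[:, -1]
    return out
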