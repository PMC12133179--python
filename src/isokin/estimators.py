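"""Model fitting: maximum likelihood, bootstrap intervals and posterior
sampling, presented as scikit-learn style estimators.

All estimators share the convention ``fit(X, y)`` where ``X`` holds the
sampling times in days (shape (n,) or (n, 1)) and ``y`` the measured
labelled fractions. The measurement-noise family and scale are treated
as known and supplied through a :class:`~isokin.datasets.NoiseSpec`.

* :class:`OneCompartmentFit` - maximum likelihood for the closed
  one-compartment model dF/dt = p b_w U(t) - d* F (implicit kinetic
  heterogeneity; the homogeneous special case ties d* = p).
* :class:`PrecursorTargetFit` - maximum likelihood for the two-compartment
  precursor/target model fitted to target data only, on the transformed
  (log/interpolated) parameter scale with physiological box constraints;
  optionally with the precursor-to-target size ratio frozen.
* :class:`BayesianHeterogeneityFit` - affine-invariant ensemble MCMC for
  the homogeneous, implicit and explicit N-subpopulation heterogeneity
  models, retaining pointwise log-likelihood draws for LOO comparison.

Point estimates from maximum likelihood are deterministic given ``seed``
(which controls the pseudo-random multi-start search).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import emcee
import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .bodywater import BodyWaterCurve
from .datasets import LabellingDataset, NoiseSpec, SamplingBounds
from .solvers import (
    _cascade_label,
    explicit_heterogeneity_label,
    one_compartment_label,
)

__all__ = [
    "FitResult",
    "OneCompartmentFit",
    "PrecursorTargetFit",
    "BayesianHeterogeneityFit",
    "fit_ml",
    "fit_ml_with_ratio",
    "fit_bayes",
    "bootstrap_ci",
    "percentage_error",
    "abs_percentage_error",
    "coverage",
]


# ---------------------------------------------------------------------------
# likelihoods


def pointwise_loglik(model, y, noise_family: str, noise_sd: float):
    """Per-observation log-likelihood under the known noise model.

    ``model`` may carry leading batch axes; the observation axis is last.
    Lognormal noise is undefined at an exactly-zero observation (the
    anchoring t = 0 point, which carries no information); such points
    contribute zero. A non-positive model value against a positive
    observation yields -inf.
    """
    y = np.asarray(y, dtype=float)
    model = np.asarray(model, dtype=float)
    if noise_family == "gaussian":
        return (
            -0.5 * np.log(2.0 * np.pi * noise_sd**2)
            - 0.5 * ((y - model) / noise_sd) ** 2
        )
    if noise_family != "lognormal":
        raise ValueError(f"unsupported noise family {noise_family!r}")
    zero_obs = y == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        log_m = np.log(np.where(model > 0, model, np.nan))
        log_y = np.log(np.where(zero_obs, 1.0, y))
        ll = (
            -0.5 * np.log(2.0 * np.pi * noise_sd**2)
            - log_y
            - 0.5 * ((log_y - log_m) / noise_sd) ** 2
        )
    ll = np.where(np.broadcast_to(zero_obs, ll.shape), 0.0, ll)
    return np.where(np.isnan(ll), -np.inf, ll)


@dataclass
class FitResult:
    """Outcome of a model fit.

    ``estimates`` are point estimates (posterior medians for Bayesian
    fits); ``intervals`` are (lo, hi) pairs tagged by ``interval_method``
    ("bootstrap_percentile" or "posterior_credible"); ``pointwise_loglik``
    has one entry per observation (at the point estimate for ML fits,
    or draws x observations for Bayesian fits, see ``loglik_draws``).
    """

    model_id: str
    estimates: dict[str, float]
    intervals: dict[str, tuple[float, float]] = field(default_factory=dict)
    interval_method: str = ""
    pointwise_loglik: np.ndarray | None = None
    loglik_draws: np.ndarray | None = None
    posterior_draws: dict[str, np.ndarray] | None = None
    diagnostics: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", True))

    @property
    def identifiable(self) -> bool:
        return bool(self.diagnostics.get("identifiable", True))

    def interval_contains(self, name: str, value: float) -> bool:
        lo, hi = self.intervals[name]
        return lo <= value <= hi

    def to_json(self, path=None):
        payload = {
            "model_id": self.model_id,
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "intervals": {k: [float(a), float(b)] for k, (a, b) in self.intervals.items()},
            "interval_method": self.interval_method,
            "diagnostics": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.diagnostics.items()
            },
            "seed": self.seed,
        }
        if path is None:
            return json.dumps(payload, indent=2)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# shared ML machinery


def _multistart_minimize(nll, bounds, n_starts, rng, x0_extra=()):
    """Pseudo-random global search + local refinement.

    Starts are drawn uniformly inside the box ``bounds`` (plus any
    caller-supplied warm starts) and refined with L-BFGS-B; the best
    finite optimum wins. Returns (x_best, nll_best, n_failed).
    """
    bounds = np.asarray(bounds, dtype=float)
    starts = list(x0_extra) + [
        rng.uniform(bounds[:, 0], bounds[:, 1]) for _ in range(n_starts)
    ]
    best_x, best_f, failed = None, np.inf, 0
    for x0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        except (ValueError, FloatingPointError):
            failed += 1
            continue
        if np.isfinite(res.fun) and res.fun < best_f:
            best_x, best_f = res.x, res.fun
    return best_x, best_f, failed


def _identifiability(nll, x, bounds, f0):
    """Finite-difference Hessian conditioning check at the optimum.

    Returns False when the numerical information matrix is singular or
    near-singular (collinear parameters), mirroring the covariance-matrix
    diagnostic of standard NLS machinery.
    """
    n = x.size
    h = 1e-4 * np.maximum(np.abs(x), 1e-3)
    H = np.zeros((n, n))
    fs = {}

    def f(v):
        key = tuple(np.round(v, 12))
        if key not in fs:
            fs[key] = nll(v)
        return fs[key]

    try:
        for i in range(n):
            ei = np.zeros(n); ei[i] = h[i]
            for j in range(i, n):
                ej = np.zeros(n); ej[j] = h[j]
                fpp = f(x + ei + ej)
                fpm = f(x + ei - ej)
                fmp = f(x - ei + ej)
                fmm = f(x - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        if not np.all(np.isfinite(H)):
            return False
        eig = np.linalg.eigvalsh(H)
        if np.min(eig) <= 0:
            return False
        return bool(np.max(eig) / np.min(eig) < 1e10)
    except (np.linalg.LinAlgError, ValueError):
        return False


def _validate_xy(X, y):
    X = np.asarray(X, dtype=float)
    if X.ndim == 2 and X.shape[1] == 1:
        X = X[:, 0]
    if X.ndim != 1:
        raise ValueError("X must be a 1-d array of times (or a single column)")
    y = np.asarray(y, dtype=float)
    if y.shape != X.shape:
        raise ValueError("X and y must have matching lengths")
    if np.any(X < 0):
        raise ValueError("times must be non-negative")
    return X, y


# ---------------------------------------------------------------------------
# one-compartment maximum likelihood


class OneCompartmentFit(BaseEstimator):
    """Maximum-likelihood fit of the closed one-compartment model.

    Parameters
    ----------
    curve : BodyWaterCurve or PerfectLabelCurve
        Known body-water enrichment forcing.
    noise : NoiseSpec
        Known measurement-noise model (family and scale).
    homogeneous : bool
        If True, tie d* = p (kinetically homogeneous population).
    p_max : float or None
        Upper box bound for p; default 5 / b_w.
    d_star_max : float
        Upper box bound for d*.
    n_starts : int
        Pseudo-random starts for the global search.
    seed : int or None
        Seed for the start sampler (determinism contract).

    Attributes
    ----------
    p_, d_star_ : fitted rates (day^-1)
    result_ : FitResult with diagnostics and pointwise log-likelihoods
    """

    def __init__(
        self,
        curve=None,
        noise=None,
        homogeneous: bool = False,
        p_max: float | None = None,
        d_star_max: float = 1.0,
        n_starts: int = 50,
        seed: int | None = 0,
    ):
        self.curve = curve
        self.noise = noise
        self.homogeneous = homogeneous
        self.p_max = p_max
        self.d_star_max = d_star_max
        self.n_starts = n_starts
        self.seed = seed

    def _resolve(self):
        curve = self.curve or BodyWaterCurve()
        noise = self.noise or NoiseSpec()
        p_max = self.p_max if self.p_max is not None else 5.0 / curve.b_w
        return curve, noise, p_max

    def _model(self, theta, times, curve):
        # theta holds log10 rates: the optimisation runs on log scale,
        # where the likelihood surface is far better conditioned.
        p = 10.0 ** theta[0]
        d = p if self.homogeneous else 10.0 ** theta[1]
        return one_compartment_label(p, d, curve, times)

    def fit(self, X, y, noise_sd: float | None = None):
        X, y = _validate_xy(X, y)
        curve, noise, p_max = self._resolve()
        sd = noise.scale if noise_sd is None else noise_sd

        def nll(theta):
            ll = pointwise_loglik(self._model(theta, X, curve), y, noise.family, sd)
            return -np.sum(ll)

        lo = -8.0  # 1e-8/day lower box: numerically zero on a 100-day study
        bounds = [(lo, np.log10(p_max))]
        if not self.homogeneous:
            bounds.append((lo, np.log10(self.d_star_max)))
        rng = np.random.default_rng(self.seed)
        extra = [self._warm_x0] if getattr(self, "_warm_x0", None) is not None else []
        x, f, n_failed = _multistart_minimize(nll, bounds, self.n_starts, rng, x0_extra=extra)
        if x is None:
            self.p_ = self.d_star_ = np.nan
            self.result_ = FitResult(
                model_id="homogeneous" if self.homogeneous else "one_compartment",
                estimates={}, diagnostics={"converged": False, "n_failed_starts": n_failed},
                seed=self.seed,
            )
            return self
        self.theta_ = x
        self.p_ = float(10.0 ** x[0])
        self.d_star_ = float(self.p_ if self.homogeneous else 10.0 ** x[1])
        pw = pointwise_loglik(self._model(x, X, curve), y, noise.family, sd)
        self.nll_ = float(f)
        self.identifiable_ = _identifiability(nll, x, bounds, f)
        self.result_ = FitResult(
            model_id="homogeneous" if self.homogeneous else "one_compartment",
            estimates={"p": self.p_, "d_star": self.d_star_},
            pointwise_loglik=np.asarray(pw, dtype=float),
            diagnostics={
                "converged": True,
                "identifiable": self.identifiable_,
                "nll": self.nll_,
                "n_failed_starts": n_failed,
            },
            seed=self.seed,
        )
        self._fit_X_, self._fit_y_ = X, y
        self._fit_sd_ = sd
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float).reshape(-1)
        curve, _, _ = self._resolve()
        return self._model(self.theta_, X, curve)


# ---------------------------------------------------------------------------
# precursor/target maximum likelihood


class PrecursorTargetFit(BaseEstimator):
    """Maximum-likelihood fit of the precursor/target model to target data.

    The model is fitted on the transformed parameter scale
    (log10 p_C, log10 p_E, log10 r/p_C, k, log10 d_C*/d_C, and the
    log-interpolation coordinates of d_E and d_E* between p_E and delta),
    with the physiological sampling bounds as box constraints. With
    ``ratio_CE`` given, the precursor-to-target size ratio is frozen at
    that value instead of being derived from d_E (one fewer parameter).

    The fitted labelled-cell dynamics use the kinetically heterogeneous
    form (d_C*, d_E* governing label loss). Parameters of this model are
    known to be poorly identifiable from target data alone; the
    ``identifiable_`` flag reports the Hessian-conditioning diagnostic
    and point estimates are retained regardless.
    """

    def __init__(
        self,
        curve=None,
        noise=None,
        ratio_CE: float | None = None,
        bounds: SamplingBounds | None = None,
        n_starts: int = 20,
        seed: int | None = 0,
    ):
        self.curve = curve
        self.noise = noise
        self.ratio_CE = ratio_CE
        self.bounds = bounds
        self.n_starts = n_starts
        self.seed = seed

    def _resolve(self):
        return self.curve or BodyWaterCurve(), self.noise or NoiseSpec(), self.bounds or SamplingBounds()

    def _unpack(self, theta, delta):
        """Transformed vector -> physical rates of the label ODEs."""
        log_p_C, log_p_E = theta[0], theta[1]
        p_C = 10.0 ** log_p_C
        p_E = 10.0 ** log_p_E
        r = p_C * 10.0 ** theta[2]
        k = theta[3]
        d_C_star = (p_C - r) * 10.0 ** theta[4]
        span = np.log10(delta) - log_p_E
        two_k = 2.0 ** k
        if self.ratio_CE is None:
            d_E = 10.0 ** (log_p_E + theta[5] * span)
            d_E_star = 10.0 ** (log_p_E + theta[6] * span)
            ratio = (d_E - p_E) / (r * two_k)
        else:
            ratio = self.ratio_CE
            d_E_star = 10.0 ** (log_p_E + theta[5] * span)
        a = d_C_star + r
        s_r = r * ratio
        q_E = (two_k - 1.0) * r * ratio + p_E
        return p_C, p_E, a, d_E_star, q_E, s_r

    def _model(self, theta, times, curve, delta):
        p_C, p_E, a, d_E_star, q_E, s_r = self._unpack(theta, delta)
        _, fe = _cascade_label(a, d_E_star, p_C, q_E, s_r, curve, times)
        return fe

    def _box(self, bounds: SamplingBounds):
        rows = [
            bounds.log10_p_C,
            bounds.log10_p_E,
            bounds.log10_r_over_p_C,
            bounds.k,
            bounds.log10_d_C_star_over_d_C,
        ]
        if self.ratio_CE is None:
            rows += [bounds.z_d_E, bounds.z_d_E_star]
        else:
            rows += [bounds.z_d_E_star]
        return rows

    def fit(self, X, y, noise_sd: float | None = None):
        X, y = _validate_xy(X, y)
        curve, noise, bounds = self._resolve()
        delta = bounds.delta
        sd = noise.scale if noise_sd is None else noise_sd

        def nll(theta):
            ll = pointwise_loglik(self._model(theta, X, curve, delta), y, noise.family, sd)
            return -np.sum(ll)

        box = self._box(bounds)
        rng = np.random.default_rng(self.seed)
        extra = [self._warm_x0] if getattr(self, "_warm_x0", None) is not None else []
        x, f, n_failed = _multistart_minimize(nll, box, self.n_starts, rng, x0_extra=extra)
        model_id = "precursor_target_ratio" if self.ratio_CE is not None else "precursor_target"
        if x is None:
            self.p_E_ = np.nan
            self.result_ = FitResult(
                model_id=model_id, estimates={},
                diagnostics={"converged": False, "n_failed_starts": n_failed},
                seed=self.seed,
            )
            return self
        self.theta_ = x
        self.p_C_ = float(10.0 ** x[0])
        self.p_E_ = float(10.0 ** x[1])
        self.r_ = float(self.p_C_ * 10.0 ** x[2])
        self.k_ = float(x[3])
        span = np.log10(delta) - x[1]
        if self.ratio_CE is None:
            self.d_E_ = float(10.0 ** (x[1] + x[5] * span))
            self.d_E_star_ = float(10.0 ** (x[1] + x[6] * span))
            self.ratio_CE_ = float((self.d_E_ - self.p_E_) / (self.r_ * 2.0 ** self.k_))
        else:
            self.d_E_star_ = float(10.0 ** (x[1] + x[5] * span))
            self.ratio_CE_ = float(self.ratio_CE)
        pw = pointwise_loglik(self._model(x, X, curve, delta), y, noise.family, sd)
        self.nll_ = float(f)
        self.identifiable_ = _identifiability(nll, x, box, f)
        self.result_ = FitResult(
            model_id=model_id,
            estimates={
                "p_E": self.p_E_, "p_C": self.p_C_, "r": self.r_, "k": self.k_,
                "d_E_star": self.d_E_star_, "ratio_CE": self.ratio_CE_,
            },
            pointwise_loglik=np.asarray(pw, dtype=float),
            diagnostics={
                "converged": True,
                "identifiable": self.identifiable_,
                "nll": self.nll_,
                "n_failed_starts": n_failed,
            },
            seed=self.seed,
        )
        self._fit_X_, self._fit_y_ = X, y
        self._fit_sd_ = sd
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float).reshape(-1)
        curve, _, bounds = self._resolve()
        return self._model(self.theta_, X, curve, bounds.delta)


# ---------------------------------------------------------------------------
# Bayesian heterogeneity fits


class BayesianHeterogeneityFit(BaseEstimator):
    """Posterior sampling for the kinetic-heterogeneity model family.

    Parameters
    ----------
    model : {"homogeneous", "implicit", "explicit"}
        homogeneous: single rate p (= d*); implicit: (p, d*); explicit:
        N subpopulations with rates p_i and weights alpha (2N - 1
        parameters).
    n_compartments : int
        N for the explicit model (ignored otherwise).
    prior_upper : float
        Upper bound of the uniform priors on rates (p, d*, p_i).
    p_prior_upper : float or None
        Separate upper bound for p (the one-compartment Bayesian fit of
        the upstream study uses 5 / b_w for p and 1 for d*).

    The weight vector has a symmetric Dirichlet(1) prior restricted to
    non-decreasing order (resolving label switching); for N = 2 this is
    uniform alpha_1 in (0, 0.5]. Sampling uses the emcee ensemble
    sampler on log10-rate coordinates (with the Jacobian keeping the
    prior uniform on the rate scale), in two stages: an exploratory run
    from a prior-wide start, then a production run re-initialised around
    the best exploratory point. Convergence is flagged via split-chain
    R-hat of the mean proliferation rate across walker halves.

    Attributes (after fit): ``samples_`` (draws x params, rate scale),
    ``mean_proliferation_draws_``, ``estimates_``, ``ci_``,
    ``loglik_draws_`` (draws x observations), ``result_``.
    """

    #: log10-rate lower sampling bound: 1e-8/day is numerically zero on
    #: a 100-day study; the prior mass below it is negligible.
    LOG_RATE_FLOOR = -8.0

    def __init__(
        self,
        model: str = "implicit",
        n_compartments: int = 2,
        curve=None,
        noise=None,
        prior_upper: float = 1.0,
        p_prior_upper: float | None = None,
        n_walkers: int = 32,
        n_explore: int = 800,
        n_steps: int = 3000,
        n_burn: int = 1000,
        thin: int = 2,
        seed: int | None = 0,
    ):
        self.model = model
        self.n_compartments = n_compartments
        self.curve = curve
        self.noise = noise
        self.prior_upper = prior_upper
        self.p_prior_upper = p_prior_upper
        self.n_walkers = n_walkers
        self.n_explore = n_explore
        self.n_steps = n_steps
        self.n_burn = n_burn
        self.thin = thin
        self.seed = seed

    # -- parameterisation ---------------------------------------------------
    # Sampling space: the first m coordinates are log10 rates (m = 1 for
    # homogeneous, 2 for implicit, N for explicit); the remaining N - 1
    # (explicit only) are the free mixture weights.

    def _n_rates(self):
        if self.model == "homogeneous":
            return 1
        if self.model == "implicit":
            return 2
        if self.model == "explicit":
            return self.n_compartments
        raise ValueError(f"unknown model {self.model!r}")

    def _n_params(self):
        m = self._n_rates()
        return m if self.model != "explicit" else 2 * self.n_compartments - 1

    def _param_names(self):
        if self.model == "homogeneous":
            return ["p"]
        if self.model == "implicit":
            return ["p", "d_star"]
        n = self.n_compartments
        return [f"p{i + 1}" for i in range(n)] + [f"alpha{i + 1}" for i in range(n - 1)]

    def _rate_uppers(self):
        p_up = self.p_prior_upper if self.p_prior_upper is not None else self.prior_upper
        if self.model == "homogeneous":
            return np.array([p_up])
        if self.model == "implicit":
            return np.array([p_up, self.prior_upper])
        return np.full(self.n_compartments, self.prior_upper)

    def _log_prior(self, theta):
        """Vectorised log-prior in sampling space; theta shape (W, D).

        Uniform priors on the rate scale pick up a log-Jacobian
        ln(10) sum_i x_i under the log10 transform.
        """
        m = self._n_rates()
        x = theta[:, :m]
        log_up = np.log10(self._rate_uppers())
        ok = np.all((x >= self.LOG_RATE_FLOOR) & (x <= log_up), axis=1)
        if self.model == "explicit" and self.n_compartments > 1:
            alpha = self._alphas(theta)
            ok &= np.all(alpha > 0, axis=1)
            ok &= np.all(np.diff(alpha, axis=1) >= 0, axis=1)  # non-decreasing
        jac = np.log(10.0) * x.sum(axis=1)
        return np.where(ok, jac, -np.inf)

    def _alphas(self, theta):
        """Full weight vector (W, N) from the free (N-1) coordinates."""
        n = self.n_compartments
        if n == 1:
            return np.ones((theta.shape[0], 1))
        a_free = theta[:, n: 2 * n - 1]
        a_last = 1.0 - a_free.sum(axis=1, keepdims=True)
        return np.concatenate([a_free, a_last], axis=1)

    def _model_curve(self, theta, times, curve):
        m = self._n_rates()
        rates = 10.0 ** theta[:, :m]
        if self.model == "homogeneous":
            return one_compartment_label(rates[:, 0], rates[:, 0], curve, times)
        if self.model == "implicit":
            return one_compartment_label(rates[:, 0], rates[:, 1], curve, times)
        return explicit_heterogeneity_label(rates, self._alphas(theta), curve, times)

    def _mean_proliferation(self, theta):
        rates = 10.0 ** theta[:, : self._n_rates()]
        if self.model in ("homogeneous", "implicit"):
            return rates[:, 0]
        return np.einsum("wn,wn->w", rates, self._alphas(theta))

    def _initial(self, rng):
        W = self.n_walkers
        m = self._n_rates()
        x = rng.uniform(self.LOG_RATE_FLOOR, np.log10(self._rate_uppers()), (W, m))
        if self.model != "explicit" or self.n_compartments == 1:
            return x
        n = self.n_compartments
        alpha = np.sort(rng.dirichlet(np.ones(n), W), axis=1)
        return np.concatenate([x, alpha[:, : n - 1]], axis=1)

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y, noise_sd: float | None = None):
        X, y = _validate_xy(X, y)
        curve = self.curve or BodyWaterCurve()
        noise = self.noise or NoiseSpec()
        sd = noise.scale if noise_sd is None else noise_sd
        ndim = self._n_params()
        if self.n_walkers < 2 * ndim:
            raise ValueError("n_walkers must be at least twice the parameter count")

        def log_prob(theta):
            theta = np.atleast_2d(theta)
            lp = self._log_prior(theta)
            out = np.full(theta.shape[0], -np.inf)
            ok = np.isfinite(lp)
            if np.any(ok):
                curves = self._model_curve(theta[ok], X, curve)
                ll = pointwise_loglik(curves, y, noise.family, sd).sum(axis=-1)
                out[ok] = lp[ok] + ll
            return out

        rng = np.random.default_rng(self.seed)
        moves = [
            (emcee.moves.StretchMove(), 0.5),
            (emcee.moves.DEMove(), 0.3),
            (emcee.moves.DESnookerMove(), 0.2),
        ]
        sampler = emcee.EnsembleSampler(
            self.n_walkers, ndim, log_prob, vectorize=True, moves=moves
        )
        sampler._random = np.random.RandomState(int(rng.integers(0, 2**31 - 1)))

        # stage 1: explore from a prior-wide start, then collapse the
        # ensemble around the best point found (burn-in acceleration for
        # posteriors that occupy a tiny corner of the prior box)
        p0 = self._initial(rng)
        sampler.run_mcmc(p0, self.n_explore, progress=False)
        best = sampler.get_chain(flat=True)[np.argmax(sampler.get_log_prob(flat=True))]
        m = self._n_rates()
        scale = np.concatenate([np.full(m, 0.05), np.full(ndim - m, 0.01)])
        p1 = best + rng.normal(0.0, scale, (self.n_walkers, ndim))
        p1[:, :m] = np.clip(p1[:, :m], self.LOG_RATE_FLOOR, np.log10(self._rate_uppers()))
        if ndim > m:
            p1[:, m:] = np.clip(p1[:, m:], 1e-4, 0.5)
        sampler.reset()
        sampler.run_mcmc(p1, self.n_steps, progress=False)

        chain = sampler.get_chain(discard=self.n_burn, thin=self.thin)  # (S, W, D)
        self.chain_ = chain
        flat = chain.reshape(-1, ndim)
        self.sampling_draws_ = flat
        samples = flat.copy()
        samples[:, :m] = 10.0 ** samples[:, :m]
        self.samples_ = samples

        mp_chain = np.stack(
            [self._mean_proliferation(chain[:, w, :]) for w in range(chain.shape[1])],
            axis=1,
        )[:, :, None]
        self.rhat_ = _split_rhat(chain)
        self.rhat_mean_proliferation_ = float(_split_rhat(mp_chain)[0])
        converged = bool(self.rhat_mean_proliferation_ < 1.1)

        mp = self._mean_proliferation(flat)
        self.mean_proliferation_draws_ = mp
        self.mean_proliferation_ = float(np.median(mp))
        lo, hi = np.percentile(mp, [2.5, 97.5])
        self.ci_ = (float(lo), float(hi))

        names = self._param_names()
        estimates = {nm: float(np.median(samples[:, i])) for i, nm in enumerate(names)}
        estimates["mean_proliferation"] = self.mean_proliferation_
        intervals = {
            nm: tuple(np.percentile(samples[:, i], [2.5, 97.5])) for i, nm in enumerate(names)
        }
        intervals["mean_proliferation"] = self.ci_

        curves = self._model_curve(flat, X, curve)
        self.loglik_draws_ = pointwise_loglik(curves, y, noise.family, sd)
        self.n_chains_ = chain.shape[1]

        model_id = self.model if self.model != "explicit" else f"explicit_{self.n_compartments}"
        self.result_ = FitResult(
            model_id=model_id,
            estimates=estimates,
            intervals={k: (float(a), float(b)) for k, (a, b) in intervals.items()},
            interval_method="posterior_credible",
            pointwise_loglik=self.loglik_draws_.mean(axis=0),
            loglik_draws=self.loglik_draws_,
            posterior_draws={nm: samples[:, i] for i, nm in enumerate(names)},
            diagnostics={
                "converged": converged,
                "rhat": self.rhat_,
                "rhat_mean_proliferation": self.rhat_mean_proliferation_,
                "n_draws": flat.shape[0],
                "n_chains": self.n_chains_,
            },
            seed=self.seed,
        )
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float).reshape(-1)
        curve = self.curve or BodyWaterCurve()
        med = np.median(self.sampling_draws_, axis=0)[None, :]
        return self._model_curve(med, X, curve)[0]


def _split_rhat(chain):
    """Split-chain potential scale reduction factor per parameter.

    ``chain`` has shape (steps, walkers, params); each walker half counts
    as a chain.
    """
    s, w, d = chain.shape
    half = s // 2
    sub = np.concatenate([chain[:half], chain[half: 2 * half]], axis=1)  # (half, 2w, d)
    m = sub.shape[1]
    means = sub.mean(axis=0)  # (2w, d)
    vars_ = sub.var(axis=0, ddof=1)
    W = vars_.mean(axis=0)
    B = half * means.var(axis=0, ddof=1)
    var_hat = (half - 1) / half * W + B / half
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / W)
    return np.where(np.isfinite(rhat), rhat, np.inf)


# ---------------------------------------------------------------------------
# functional surface


def _estimator_for(model_id: str, dataset: LabellingDataset, config: dict):
    cfg = dict(config or {})
    curve = cfg.pop("curve", dataset.curve) or BodyWaterCurve()
    common = dict(curve=curve, noise=dataset.noise)
    if model_id in ("one_compartment", "homogeneous_ml"):
        return OneCompartmentFit(
            homogeneous=(model_id == "homogeneous_ml"), **common, **cfg
        )
    if model_id == "precursor_target":
        return PrecursorTargetFit(**common, **cfg)
    raise ValueError(f"unknown ML model {model_id!r}")


def fit_ml(model_id: str, dataset: LabellingDataset, config: dict | None = None) -> FitResult:
    """Maximum-likelihood fit of ``model_id`` to a dataset.

    ``model_id`` is "one_compartment", "homogeneous_ml" or
    "precursor_target". The likelihood family and scale follow the
    dataset's noise specification (sigma known).
    """
    est = _estimator_for(model_id, dataset, config)
    est.fit(dataset.times, dataset.observations, noise_sd=dataset.noise_sd)
    return est.result_


def fit_ml_with_ratio(
    dataset: LabellingDataset, ratio_CE: float, config: dict | None = None
) -> FitResult:
    """Precursor/target fit with the size ratio C/E frozen at ``ratio_CE``."""
    cfg = dict(config or {})
    curve = cfg.pop("curve", dataset.curve) or BodyWaterCurve()
    est = PrecursorTargetFit(curve=curve, noise=dataset.noise, ratio_CE=ratio_CE, **cfg)
    est.fit(dataset.times, dataset.observations, noise_sd=dataset.noise_sd)
    return est.result_


def fit_bayes(
    model_id: str, dataset: LabellingDataset, priors: dict | None = None,
    config: dict | None = None,
) -> FitResult:
    """Posterior sampling fit. ``model_id`` is "homogeneous", "implicit"
    or "explicit_N" (e.g. "explicit_2"); ``priors`` may set
    ``prior_upper`` / ``p_prior_upper``."""
    cfg = dict(config or {})
    curve = cfg.pop("curve", dataset.curve) or BodyWaterCurve()
    priors = priors or {}
    if model_id.startswith("explicit"):
        n = int(model_id.split("_")[1]) if "_" in model_id else cfg.pop("n_compartments", 2)
        est = BayesianHeterogeneityFit(
            model="explicit", n_compartments=n, curve=curve, noise=dataset.noise,
            **priors, **cfg,
        )
    else:
        est = BayesianHeterogeneityFit(
            model=model_id, curve=curve, noise=dataset.noise, **priors, **cfg
        )
    est.fit(dataset.times, dataset.observations, noise_sd=dataset.noise_sd)
    return est.result_


def bootstrap_ci(
    estimator, X, y, n_boot: int = 500, seed: int | None = 0,
    noise_sd: float | None = None, params: list[str] | None = None,
):
    """Percentile bootstrap confidence intervals for an ML estimator.

    (time, observation) pairs are resampled with replacement ``n_boot``
    times; each resample is refitted (warm-started at the original
    optimum) and the 2.5/97.5 percentiles of the estimates form the 95%
    CI. Failed resample fits are dropped and counted.

    Returns (intervals, n_failed): a dict name -> (lo, hi).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    X, y = _validate_xy(X, y)
    if not hasattr(estimator, "result_"):
        estimator.fit(X, y, noise_sd=noise_sd)
    names = params or list(estimator.result_.estimates)
    rng = np.random.default_rng(seed)
    warm = clone_with_warm_start(estimator)
    draws = {nm: [] for nm in names}
    n_failed = 0
    n = X.size
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            warm.fit(X[idx], y[idx], noise_sd=noise_sd)
            res = warm.result_
        except (ValueError, RuntimeError):
            n_failed += 1
            continue
        if not res.converged or not res.estimates:
            n_failed += 1
            continue
        for nm in names:
            draws[nm].append(res.estimates[nm])
    intervals = {}
    for nm in names:
        vals = np.asarray(draws[nm])
        if vals.size < 2:
            intervals[nm] = (np.nan, np.nan)
        else:
            lo, hi = np.percentile(vals, [2.5, 97.5])
            intervals[nm] = (float(lo), float(hi))
    return intervals, n_failed


def clone_with_warm_start(estimator):
    """Copy of a fitted ML estimator whose search starts at the parent's
    optimum (plus a couple of fresh random starts)."""
    params = estimator.get_params()
    params["n_starts"] = min(params.get("n_starts", 3), 3)
    warm = type(estimator)(**params)
    x0 = getattr(estimator, "theta_", None)
    if x0 is not None and np.all(np.isfinite(x0)):
        warm._warm_x0 = np.asarray(x0, dtype=float)
    return warm


def percentage_error(estimate: float, truth: float) -> float:
    """Signed percent error 100 (estimate - truth) / truth."""
    if truth == 0:
        raise ValueError("percentage error undefined for zero truth")
    return 100.0 * (estimate - truth) / truth


def abs_percentage_error(estimate: float, truth: float) -> float:
    """Absolute percent error |100 (estimate - truth) / truth|."""
    return abs(percentage_error(estimate, truth))


def coverage(intervals, truths):
    """Fraction of (lo, hi) intervals containing the matching truth.

    Returns (proportion, n_usable); intervals with non-finite bounds are
    excluded from both counts.
    """
    intervals = list(intervals)
    truths = np.asarray(list(truths), dtype=float)
    if len(intervals) != truths.size:
        raise ValueError("intervals and truths must have matching lengths")
    if len(intervals) == 0:
        raise ValueError("empty input")
    hits = 0
    usable = 0
    for (lo, hi), t in zip(intervals, truths):
        if np.isnan(lo) or np.isnan(hi):
            continue
        usable += 1
        if lo <= t <= hi:
            hits += 1
    if usable == 0:
        raise ValueError("no usable intervals")
    return hits / usable, usable
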