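"""Predictive model comparison and sequential complexity selection.

Models are compared by their expected log pointwise predictive density
estimated with Pareto-smoothed importance-sampling leave-one-out
cross-validation (PSIS-LOO). For models i and j,

    delta_elpd = elpd_loo_i - elpd_loo_j

with standard error sqrt(n * var(pointwise differences)). Model i is
supported over model j when delta_elpd is positive and exceeds its
standard error; the two models are tied when the standard error exceeds
|delta_elpd| (the conservative reading: ties go to the simpler model).

The sequential procedure starts from the two simplest models of a
complexity ladder (homogeneous = one subpopulation, then explicit
mixtures with growing N) and keeps adding the next model while the most
complex one is supported, selecting the second most complex model once
support runs out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datasets import LabellingDataset
from .estimators import BayesianHeterogeneityFit, FitResult

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import arviz as az

__all__ = [
    "LooResult",
    "ModelComparison",
    "SelectionResult",
    "elpd_loo",
    "compare_models",
    "sequential_selection",
    "default_ladder",
]


@dataclass(frozen=True)
class LooResult:
    """PSIS-LOO estimate of the expected log predictive density."""

    estimate: float
    se: float
    pointwise: np.ndarray
    pareto_k: np.ndarray
    n_high_k: int

    @property
    def reliable(self) -> bool:
        return self.n_high_k == 0


def _loglik_chains(fit: FitResult) -> np.ndarray:
    """Pointwise log-likelihood draws as (chain, draw, observation)."""
    if fit.loglik_draws is None:
        raise ValueError("fit carries no pointwise log-likelihood draws")
    ll = np.asarray(fit.loglik_draws)
    n_chains = int(fit.diagnostics.get("n_chains", 1))
    n_total, n_obs = ll.shape
    if n_total % n_chains:
        n_chains = 1
    n_draw = n_total // n_chains
    # flat index is draw-major (s * n_chains + w)
    return ll.reshape(n_draw, n_chains, n_obs).transpose(1, 0, 2)


def elpd_loo(fit: FitResult) -> LooResult:
    """PSIS-LOO elpd and its standard error for a Bayesian fit.

    Observations with Pareto shape k > 0.7 (unreliable importance
    weights) are counted in ``n_high_k``.
    """
    ll = _loglik_chains(fit)
    n_chain, n_draw, _ = ll.shape
    posterior = {}
    if fit.posterior_draws:
        posterior = {
            k: np.asarray(v).reshape(n_draw, n_chain).T
            for k, v in fit.posterior_draws.items()
            if np.asarray(v).size == n_chain * n_draw
        }
    if not posterior:  # fall back to a neutral reff of 1
        posterior = {"lp": ll.sum(axis=2)}
    idata = az.from_dict(posterior=posterior, log_likelihood={"y": ll})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = az.loo(idata, pointwise=True)
    pareto_k = np.asarray(res.pareto_k)
    return LooResult(
        estimate=float(res.elpd_loo),
        se=float(res.se),
        pointwise=np.asarray(res.loo_i),
        pareto_k=pareto_k,
        n_high_k=int(np.sum(pareto_k > 0.7)),
    )


@dataclass(frozen=True)
class ModelComparison:
    """Pairwise LOO comparison of model i (more complex) vs model j."""

    model_i: str
    model_j: str
    elpd_i: float
    elpd_j: float
    delta: float
    se: float
    decision: str  # "select_i" | "select_j" | "tie"

    def supports(self, which: str) -> bool:
        return self.decision == f"select_{which}"


def compare_models(
    fit_i: FitResult | LooResult,
    fit_j: FitResult | LooResult,
    names: tuple[str, str] = ("i", "j"),
    stringency: float = 1.0,
) -> ModelComparison:
    """Compare two fits of the same data by delta elpd_loo.

    ``stringency`` multiplies the standard error in the support rule
    (1.0 reproduces the plain delta > SE criterion). A tie (SE >=
    |delta| at the given stringency) selects neither model; sequential
    selection then keeps the simpler one.
    """
    loo_i = fit_i if isinstance(fit_i, LooResult) else elpd_loo(fit_i)
    loo_j = fit_j if isinstance(fit_j, LooResult) else elpd_loo(fit_j)
    diff = loo_i.pointwise - loo_j.pointwise
    if diff.shape != loo_i.pointwise.shape or loo_i.pointwise.size != loo_j.pointwise.size:
        raise ValueError("fits were evaluated on different observation sets")
    n = diff.size
    delta = float(np.sum(diff))
    se = float(np.sqrt(n * np.var(diff, ddof=1))) if n > 1 else 0.0
    threshold = stringency * se
    if delta > threshold:
        decision = "select_i"
    elif -delta > threshold:
        decision = "select_j"
    else:
        decision = "tie"
    return ModelComparison(
        model_i=names[0], model_j=names[1],
        elpd_i=loo_i.estimate, elpd_j=loo_j.estimate,
        delta=delta, se=se, decision=decision,
    )


@dataclass
class SelectionResult:
    selected_id: str
    selected_index: int
    trace: list[ModelComparison] = field(default_factory=list)
    fits: dict[str, FitResult] = field(default_factory=dict)

    @property
    def selected_fit(self) -> FitResult:
        return self.fits[self.selected_id]


def default_ladder(
    curve=None, noise=None, max_compartments: int = 4, seed: int | None = 0, **kwargs
) -> list[BayesianHeterogeneityFit]:
    """Complexity ladder: homogeneous, then explicit N = 2, 3, ..."""
    ladder = [
        BayesianHeterogeneityFit(model="homogeneous", curve=curve, noise=noise, seed=seed, **kwargs)
    ]
    for n in range(2, max_compartments + 1):
        ladder.append(
            BayesianHeterogeneityFit(
                model="explicit", n_compartments=n, curve=curve, noise=noise,
                seed=None if seed is None else seed + n, **kwargs,
            )
        )
    return ladder


def sequential_selection(
    dataset: LabellingDataset,
    ladder: list[BayesianHeterogeneityFit] | None = None,
    stringency: float = 1.0,
    **ladder_kwargs,
) -> SelectionResult:
    """Grow model complexity until predictive fit stops improving.

    Starting from the two simplest models, the more complex one must be
    supported (delta elpd_loo positive and above its standard error) to
    stay in the race; each win admits the next model on the ladder. The
    procedure stops at the first non-win, selecting the simpler model of
    the final comparison. A single-model ladder returns that model.
    """
    if ladder is None:
        ladder = default_ladder(
            curve=dataset.curve, noise=dataset.noise, **ladder_kwargs
        )
    if not ladder:
        raise ValueError("model ladder must be non-empty")

    def model_id(est, idx):
        if est.model == "explicit":
            return f"explicit_{est.n_compartments}"
        return est.model

    fits: dict[str, FitResult] = {}
    loos: dict[str, LooResult] = {}

    def fit_model(idx):
        est = ladder[idx]
        mid = model_id(est, idx)
        if mid not in fits:
            est.fit(dataset.times, dataset.observations, noise_sd=dataset.noise_sd)
            fits[mid] = est.result_
            loos[mid] = elpd_loo(est.result_)
        return mid

    trace: list[ModelComparison] = []
    current = fit_model(0)
    current_idx = 0
    if len(ladder) == 1:
        return SelectionResult(selected_id=current, selected_index=0, trace=trace, fits=fits)

    for idx in range(1, len(ladder)):
        challenger = fit_model(idx)
        comp = compare_models(
            loos[challenger], loos[current], names=(challenger, current),
            stringency=stringency,
        )
        trace.append(comp)
        if comp.decision == "select_i":
            current, current_idx = challenger, idx
        else:
            break
    return SelectionResult(
        selected_id=current, selected_index=current_idx, trace=trace, fits=fits
    )
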