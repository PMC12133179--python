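"""Synthetic labelling datasets.

Three study designs are generated here:

* "optimal" precursor/target time courses: daily sampling to day 100
  with small lognormal noise (sigma = 0.005), generating parameters drawn
  by Latin-hypercube sampling of physiologically transformed rates;
* "realistic" time courses: weekly sampling (15 points), Gaussian noise
  with sd 0.1 x the maximum of the true curve, and an explicitly
  heterogeneous (two-subpopulation) target compartment;
* the explicit kinetic-heterogeneity grid: 125 combinations of
  (p1, p2, alpha1) for the two-subpopulation mixture model, sampled
  weekly with lognormal noise.

All generators are deterministic given a seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .bodywater import BodyWaterCurve
from .params import (
    ExplicitHeterogeneityParams,
    PrecursorTargetParams,
    RealisticTargetParams,
)
from .solvers import (
    solve_explicit_heterogeneity,
    solve_precursor_target,
    solve_realistic_target,
)

__all__ = [
    "SamplingBounds",
    "NoiseSpec",
    "LabellingDataset",
    "sample_precursor_target_params",
    "sample_realistic_target_params",
    "generate_optimal_dataset",
    "generate_realistic_dataset",
    "heterogeneity_grid",
    "generate_heterogeneity_dataset",
    "OPTIMAL_TIMES",
    "WEEKLY_TIMES",
]

#: Daily sampling, day 0 through day 100 inclusive (101 points).
OPTIMAL_TIMES = np.arange(0.0, 101.0)

#: Weekly sampling, day 0 through day 98 inclusive (15 points).
WEEKLY_TIMES = np.arange(0.0, 99.0, 7.0)


@dataclass(frozen=True)
class SamplingBounds:
    """Bounds of the uniform distribution over transformed parameters.

    The transforms keep every draw physiological: proliferation rates
    between 10^-4 and 10^-2 day^-1, differentiation slower than precursor
    proliferation, labelled-cell disappearance in the precursor at most
    100x the average, and target disappearance rates between p_E and the
    body-water turnover delta (label must outlive the cells of interest).
    """

    log10_p_C: tuple[float, float] = (-4.0, -2.0)
    log10_p_E: tuple[float, float] = (-4.0, -2.0)
    log10_r_over_p_C: tuple[float, float] = (-2.0, 0.0)
    k: tuple[float, float] = (0.0, 20.0)
    log10_d_C_star_over_d_C: tuple[float, float] = (0.0, 2.0)
    z_d_E: tuple[float, float] = (0.0, 1.0)
    z_d_E_star: tuple[float, float] = (0.0, 1.0)
    delta: float = 0.07

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.log10_p_C,
                self.log10_p_E,
                self.log10_r_over_p_C,
                self.k,
                self.log10_d_C_star_over_d_C,
                self.z_d_E,
                self.z_d_E_star,
            ]
        )


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model for a dataset.

    family "lognormal": observation = truth * exp(sigma * Z) with
    ``scale`` = sigma (an exactly-zero truth stays zero).
    family "gaussian": observation = truth + sd * Z. With
    ``reference`` = "max_fraction" the sd is ``scale`` x max(truth) of
    the dataset; with "absolute" it is ``scale`` itself.
    """

    family: str = "lognormal"
    scale: float = 0.005
    reference: str = "absolute"

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "gaussian", "none"):
            raise ValueError(f"unknown noise family {self.family!r}")
        if self.family != "none" and self.scale < 0:
            raise ValueError("noise scale must be non-negative")
        if self.reference not in ("absolute", "max_fraction"):
            raise ValueError(f"unknown scale reference {self.reference!r}")

    def sd_for(self, truth: np.ndarray) -> float:
        if self.reference == "max_fraction":
            return self.scale * float(np.max(truth))
        return self.scale

    def apply(self, truth: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        truth = np.asarray(truth, dtype=float)
        if self.family == "none" or self.scale == 0:
            return truth.copy()
        z = rng.standard_normal(truth.shape)
        if self.family == "lognormal":
            return truth * np.exp(self.scale * z)
        return truth + self.sd_for(truth) * z


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


@dataclass
class LabellingDataset:
    """A simulated time/labelled-fraction series with known provenance."""

    times: np.ndarray
    observations: np.ndarray
    noise: NoiseSpec
    truth_params: object = None
    truth_curve: np.ndarray | None = None
    model_id: str = ""
    seed: int | None = None
    curve: BodyWaterCurve | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.observations = np.asarray(self.observations, dtype=float)
        if self.times.shape != self.observations.shape:
            raise ValueError("times and observations must have the same length")
        if self.truth_curve is not None:
            self.truth_curve = np.asarray(self.truth_curve, dtype=float)

    def __len__(self) -> int:
        return self.times.size

    @property
    def noise_sd(self) -> float:
        """The (known) noise scale used by the likelihood."""
        if self.noise.family == "gaussian" and self.noise.reference == "max_fraction":
            ref = self.truth_curve if self.truth_curve is not None else self.observations
            return self.noise.sd_for(ref)
        return self.noise.scale

    def to_csv(self, path, sidecar: bool = True) -> None:
        pd.DataFrame(
            {"time_days": self.times, "fraction_labelled": self.observations}
        ).to_csv(path, index=False)
        if sidecar:
            meta = {
                "model_id": self.model_id,
                "seed": self.seed,
                "noise": _to_jsonable(self.noise),
                "truth_params": _to_jsonable(self.truth_params),
                "curve": _to_jsonable(self.curve),
            }
            with open(str(path) + ".json", "w") as fh:
                json.dump(meta, fh, indent=2)

    @classmethod
    def from_csv(cls, path) -> "LabellingDataset":
        df = pd.read_csv(path)
        noise = NoiseSpec(family="none", scale=0.0)
        meta_path = str(path) + ".json"
        model_id, seed, curve = "", None, None
        try:
            with open(meta_path) as fh:
                meta = json.load(fh)
            noise = NoiseSpec(**meta.get("noise", {}))
            model_id = meta.get("model_id", "")
            seed = meta.get("seed")
            if meta.get("curve"):
                curve = BodyWaterCurve(**meta["curve"])
        except FileNotFoundError:
            pass
        return cls(
            times=df["time_days"].to_numpy(),
            observations=df["fraction_labelled"].to_numpy(),
            noise=noise,
            model_id=model_id,
            seed=seed,
            curve=curve,
        )


# ---------------------------------------------------------------------------
# Latin-hypercube parameter sampling


def _back_transform(z: np.ndarray, bounds: SamplingBounds) -> PrecursorTargetParams:
    delta = bounds.delta
    p_C = 10.0 ** z[0]
    p_E = 10.0 ** z[1]
    r = p_C * 10.0 ** z[2]
    k = z[3]
    d_C = p_C - r
    d_C_star = d_C * 10.0 ** z[4]
    span = np.log10(delta) - np.log10(p_E)
    d_E = 10.0 ** (np.log10(p_E) + z[5] * span)
    d_E_star = 10.0 ** (np.log10(p_E) + z[6] * span)
    return PrecursorTargetParams(
        p_C=p_C, r=r, k=k, d_C_star=d_C_star, p_E=p_E, d_E=d_E, d_E_star=d_E_star
    )


def sample_precursor_target_params(
    n: int,
    bounds: SamplingBounds | None = None,
    k_mode: str = "sampled",
    seed: int | np.random.Generator | None = None,
) -> list[PrecursorTargetParams]:
    """Draw precursor/target parameter sets by Latin-hypercube sampling.

    Transformed parameters are sampled uniformly within ``bounds`` and
    back-transformed; draws violating the kinetic-heterogeneity ordering
    d_E* > d_E are rejected, with whole hypercubes re-drawn until ``n``
    survivors accumulate (approximately preserving stratification).
    ``k_mode`` is "sampled" (k uniform on its bounds) or "zero".
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if k_mode not in ("sampled", "zero"):
        raise ValueError(f"unknown k_mode {k_mode!r}")
    bounds = bounds or SamplingBounds()
    arr = bounds.as_array()
    if np.any(arr[:, 1] < arr[:, 0]):
        raise ValueError("infeasible sampling bounds (upper < lower)")
    rng = np.random.default_rng(seed)
    sampler = qmc.LatinHypercube(d=7, rng=rng)
    out: list[PrecursorTargetParams] = []
    while len(out) < n:
        unit = sampler.random(n)
        z = qmc.scale(unit, arr[:, 0], arr[:, 1])
        if k_mode == "zero":
            z[:, 3] = 0.0
        keep = z[:, 6] > z[:, 5]  # d_E* > d_E
        for row in z[keep]:
            out.append(_back_transform(row, bounds))
            if len(out) == n:
                break
    return out


def sample_realistic_target_params(
    n: int,
    bounds: SamplingBounds | None = None,
    seed: int | np.random.Generator | None = None,
) -> list[RealisticTargetParams]:
    """Draw parameter sets for the heterogeneous-target design.

    The upstream block follows the same transformed scheme as
    :func:`sample_precursor_target_params`; the routing fraction gamma is
    uniform on (0, 1) and each target subpopulation's (p_i, d_i) follows
    the target-rate scheme (p_i log-uniform, d_i log-interpolated between
    p_i and delta), keeping both subpopulations in equilibrium.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    bounds = bounds or SamplingBounds()
    delta = bounds.delta
    lows = [
        bounds.log10_p_C[0], bounds.log10_r_over_p_C[0], bounds.k[0],
        bounds.log10_d_C_star_over_d_C[0], 0.0,
        bounds.log10_p_E[0], bounds.z_d_E[0],
        bounds.log10_p_E[0], bounds.z_d_E[0],
    ]
    highs = [
        bounds.log10_p_C[1], bounds.log10_r_over_p_C[1], bounds.k[1],
        bounds.log10_d_C_star_over_d_C[1], 1.0,
        bounds.log10_p_E[1], bounds.z_d_E[1],
        bounds.log10_p_E[1], bounds.z_d_E[1],
    ]
    rng = np.random.default_rng(seed)
    sampler = qmc.LatinHypercube(d=9, rng=rng)
    z = qmc.scale(sampler.random(n), lows, highs)
    out = []
    for row in z:
        p_C = 10.0 ** row[0]
        r = p_C * 10.0 ** row[1]
        d_C_star = (p_C - r) * 10.0 ** row[3]
        gamma = row[4]
        subs = []
        for base, zd in ((row[5], row[6]), (row[7], row[8])):
            p_i = 10.0 ** base
            d_i = 10.0 ** (base + zd * (np.log10(delta) - base))
            subs.append((p_i, d_i))
        out.append(
            RealisticTargetParams(
                p_C=p_C, r=r, k=row[2], d_C_star=d_C_star, gamma=gamma,
                p1=subs[0][0], d1=subs[0][1], p2=subs[1][0], d2=subs[1][1],
            )
        )
    return out


# ---------------------------------------------------------------------------
# dataset generators


def generate_optimal_dataset(
    params: PrecursorTargetParams,
    curve: BodyWaterCurve | None = None,
    seed: int | np.random.Generator | None = None,
    sigma: float = 0.005,
    times: np.ndarray | None = None,
) -> LabellingDataset:
    """Target-compartment series on the dense design: daily sampling to
    day 100, multiplicative lognormal noise with sigma = 0.005."""
    curve = curve or BodyWaterCurve()
    times = OPTIMAL_TIMES if times is None else np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    truth = solve_precursor_target(params, curve, times, heterogeneous=True)["E"]
    noise = NoiseSpec(family="lognormal" if sigma > 0 else "none", scale=sigma)
    obs = noise.apply(truth, rng)
    return LabellingDataset(
        times=times, observations=obs, noise=noise, truth_params=params,
        truth_curve=truth, model_id="precursor_target",
        seed=seed if isinstance(seed, int) else None, curve=curve,
    )


def generate_realistic_dataset(
    params: RealisticTargetParams,
    curve: BodyWaterCurve | None = None,
    seed: int | np.random.Generator | None = None,
    noise_fraction: float = 0.1,
    times: np.ndarray | None = None,
) -> LabellingDataset:
    """Observed-target series on the sparse design: weekly sampling
    (15 points over 100 days), additive Gaussian noise with sd equal to
    ``noise_fraction`` x the maximum of the true curve, and an explicitly
    heterogeneous two-subpopulation target."""
    curve = curve or BodyWaterCurve()
    times = WEEKLY_TIMES if times is None else np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    truth = solve_realistic_target(params, curve, times)["E"]
    noise = NoiseSpec(
        family="gaussian" if noise_fraction > 0 else "none",
        scale=noise_fraction,
        reference="max_fraction",
    )
    obs = noise.apply(truth, rng)
    return LabellingDataset(
        times=times, observations=obs, noise=noise, truth_params=params,
        truth_curve=truth, model_id="realistic_target",
        seed=seed if isinstance(seed, int) else None, curve=curve,
    )


#: Grid values for the two-subpopulation simulation study.
GRID_P1 = (0.0072, 0.018, 0.036, 0.12, 0.24, 0.36, 0.72)
GRID_P2 = (0.0036, 0.0072, 0.0108, 0.016)
GRID_ALPHA1 = (0.1, 0.3, 0.5, 0.7, 0.9)


def heterogeneity_grid() -> list[ExplicitHeterogeneityParams]:
    """All (p1, p2, alpha1) combinations with p1 > p2: 125 in total."""
    out = []
    for p1, p2, a1 in product(GRID_P1, GRID_P2, GRID_ALPHA1):
        if p1 > p2:
            out.append(ExplicitHeterogeneityParams(p=[p1, p2], alpha=[a1, 1.0 - a1]))
    return out


def generate_heterogeneity_dataset(
    params: ExplicitHeterogeneityParams,
    curve: BodyWaterCurve | None = None,
    seed: int | np.random.Generator | None = None,
    sigma: float = 0.005,
    times: np.ndarray | None = None,
) -> LabellingDataset:
    """Mixture-model series: weekly sampling to day 98, lognormal noise."""
    curve = curve or BodyWaterCurve()
    times = WEEKLY_TIMES if times is None else np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    truth = solve_explicit_heterogeneity(params, curve, times)["E"]
    noise = NoiseSpec(family="lognormal" if sigma > 0 else "none", scale=sigma)
    obs = noise.apply(truth, rng)
    return LabellingDataset(
        times=times, observations=obs, noise=noise, truth_params=params,
        truth_curve=truth, model_id="explicit_heterogeneity",
        seed=seed if isinstance(seed, int) else None, curve=curve,
    )
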