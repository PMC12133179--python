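# isokin

Compartmental models and inference for stable-isotope (deuterated water)
cell-labelling kinetics.

Stable isotope labelling is the standard way to measure cell turnover in
humans in vivo: volunteers drink heavy water for a labelling period of
length τ, dividing cells incorporate deuterium into DNA, and the
labelled-nucleotide fraction F(t) of a sorted cell population is tracked
through the labelling and delabelling phases. Kinetic rates are obtained
by fitting linear compartmental ODE models forced by the body-water
enrichment

    U(t) = f (1 − e^{−δt})        for t ≤ τ,
    U(t) = U(τ) e^{−δ(t−τ)}       for t > τ,

with amplification factor b_w. `isokin` implements the model family used
to study how three ubiquitous simplifying assumptions bias the resulting
rate estimates:

1. **Closed population.** A target population E fed by an unsampled
   precursor C (proliferation p_C, differentiation r with k
   division-linked expansions, target proliferation p_E, disappearance
   d_E) versus the closed one-compartment fit dF/dt = p b_w U(t) − d*F.
   The closed fit estimates the *production by division*
   P = r(2^k−1)C̄/Ē + p_E — not the proliferation rate p_E and not the
   turnover T = r2^k C̄/Ē + p_E. The conflation errors depend only on the
   influx ratio X = (d_E − p_E)/d_E and k:
   100·X(2^k−1)/((1−X)2^k) against proliferation and 100·X/2^k against
   turnover.
2. **Kinetic homogeneity.** Mixtures of N unconnected subpopulations
   (p_i, weights α_i) versus the implicit summary with a single
   labelled-cell disappearance rate d* ≥ p, fitted by MCMC with
   PSIS-LOO–based sequential model selection.
3. **Spatial homogeneity.** A lymphoid-tissue/blood exchange model
   quantifying the maximum relative discrepancy
   D = max (F_A − F_B)/F_A between tissue and blood label as a function
   of the recirculation rate f.

The synthetic-data module reproduces the study designs end to end:
Latin-hypercube parameter ensembles on physiological transformed scales,
a dense low-noise "optimal" design (daily sampling to day 100, lognormal
σ = 0.005), a sparse noisy "realistic" design (weekly sampling, Gaussian
sd = 0.1 × max label, explicitly heterogeneous target) and the
125-combination two-subpopulation grid.

## Worked example

```python
import numpy as np
from isokin import (
    BodyWaterCurve, PrecursorTargetParams, descriptors,
    generate_optimal_dataset, OneCompartmentFit, PrecursorTargetFit,
)

curve = BodyWaterCurve(f_plateau=0.032, delta=0.07, tau=49.0, b_w=4.18)
truth = PrecursorTargetParams(
    p_C=0.005, r=0.002, k=3.0, d_C_star=0.01,
    p_E=0.001, d_E=0.02, d_E_star=0.03,
)
d = descriptors(truth)
print(f"influx ratio X = {d.influx_ratio:.3f}, case {d.case_label}")
print(f"turnover T = {d.turnover:.5f}/day, production by division P = {d.production_by_division:.5f}/day")

ds = generate_optimal_dataset(truth, curve, seed=7)
one = OneCompartmentFit(curve=curve, noise=ds.noise, seed=0).fit(ds.times, ds.observations)
two = PrecursorTargetFit(curve=curve, noise=ds.noise, seed=0).fit(ds.times, ds.observations)
print(f"one-compartment p-hat = {one.p_:.5f}/day   (tracks P, not p_E)")
print(f"precursor/target p_E-hat = {two.p_E_:.5f}/day  (true p_E = {truth.p_E})")
```

prints

```
influx ratio X = 0.950, case A
turnover T = 0.02000/day, production by division P = 0.01763/day
one-compartment p-hat = 0.01754/day   (tracks P, not p_E)
precursor/target p_E-hat = 0.00135/day  (true p_E = 0.001)
```

With 95% of target turnover supplied by the precursor (case A), the
closed-model estimate 0.0175/day is an excellent estimate of production
by division and turnover but overestimates the true proliferation rate
(0.001/day) seventeen-fold; fitting the two-compartment model to the
same target-only data recovers p_E to within ~35% despite its
colinearity (the fit is flagged as non-identifiable and its point
estimate retained).

Estimators follow scikit-learn conventions (`fit(X, y)`, `get_params`,
fitted attributes with trailing underscores), so they compose with
sklearn tooling; `fit_ml`, `fit_bayes` and friends are thin functional
wrappers. A CLI is included: `isokin simulate`, `isokin fit`,
`isokin upstream-experiment`, `isokin heterogeneity-experiment`,
`isokin prior-sensitivity`, `isokin select`, `isokin spatial-grid`,
`isokin report`.

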