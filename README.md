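# npil

Spike deconvolution and neuropil analysis for two-photon calcium imaging.

`npil` is aimed at labs analysing population calcium imaging of cortex
(e.g. layer 2/3 of mouse V1 imaged at 7–10 Hz with OGB or GCaMP6s): it
infers spike rates from somatic ΔF/F, corrects somatic traces for neuropil
contamination, and quantifies how the surrounding neuropil behaves —
evoked-response reliability (Fano factors), distance-resolved noise
correlations, and linear population decoding of grating direction.

## The model

A cell's fluorescence is modelled with linear calcium dynamics: a spike in
frame *t* adds an instantaneous ΔF/F increment that decays geometrically,

```
c_t = r c_{t-1} + n_t,        r = 1 − Δ/τ,   n ≥ 0
```

(Δ the frame period, τ the indicator decay constant, ~1 s for OGB).
In matrix form `c = P n` with `P = M⁻¹` and `M` lower-bidiagonal.  For a
multi-pixel ROI the data are `C ≈ P n aᵀ` with a non-negative per-pixel
spatial filter **a**, and estimation alternates two convex subproblems

```
J(n) = ‖C − P n aᵀ‖²_F + k₁‖n‖₁     s.t. n ≥ 0
J(a) = ‖C − P n aᵀ‖²_F + k₂‖a‖₁     s.t. a ≥ 0
```

solved by a log-barrier interior-point method with duality-gap control.
Under the Bayesian reading (Gaussian noise of scale λ₀, exponential priors
on **n** and **a**), `k₁ = λ₀λ₁` and `k₂ = λ₀`, with λ₀ re-estimated at its
stationary point `2R/N` each sweep.  Each subproblem then has a single
free parameter, so the alternation is coordinate ascent on the
log-posterior and the learning curve is provably monotone — the stability
property that distinguishes this scheme from alternating methods whose
noise and prior scales interact inside one objective.

Downstream statistics follow the field's standard definitions: outlier-
excluding F₀ for ΔF/F, `F_corr = F − S·F_np` contamination correction
(S ≈ 0.6, estimated from blood-vessel lumina), Fano = var/mean of trial
responses, noise correlations as Pearson coefficients of within-condition
residuals, optimal linear (Fisher) decoding with 10-fold cross-validation,
and `d′ = (μ_h − μ_v)/√(½(σ²_h + σ²_v))`.

## Worked example

Deconvolve a synthetic 300-s, 3-pixel OGB-like trace with known ground
truth (2 Hz Poisson spiking, τ = 1 s, 8 Hz frames, noise SD = 0.25 × the
single-spike amplitude):

```python
import numpy as np
from npil import SpikeDeconvolution
from npil.dynamics import CalciumDynamicsParams
from npil.synth import simulate_spike_train, simulate_calcium_trace

rng = np.random.default_rng(42)
params = CalciumDynamicsParams.from_frame_rate(8.0, 1.0)
counts = simulate_spike_train(2.0, 8.0, 2400, rng)
trace, n_true = simulate_calcium_trace(
    counts, params, noise_sd=0.025, rng=rng, amplitude=0.1,
    true_filter=np.array([0.5, 0.3, 0.2]),
)
result = SpikeDeconvolution(trace).fit()
print(result.summary())
print("corr(est, true):", round(float(np.corrcoef(result.rates, n_true)[0, 1]), 3))
```

prints

```
Spike deconvolution results
===========================
frames               2400
pixels               3
frame rate (Hz)      8
decay factor r       0.8750
status               converged
sweeps               4
noise scale lambda0  0.001085
penalty k1           0.0001357
penalty k2           0.001085
active spike frames  730
log-posterior        9357.38
corr(est, true): 0.823
```

The fit converged in 4 alternating sweeps; the recovered noise scale λ₀
matches the injected noise variance (2·0.025² ≈ 1.25e−3 over the residual
degrees of freedom), and the estimated spike train correlates 0.82 with
the ground truth at frame resolution.  `result.spatial_filter` holds the
unit-sum pixel weights, `result.dff()` the filter-weighted ΔF/F trace, and
`result.state.objective_history` the (monotone) learning curve.

A full synthetic experiment — contaminated somata, coherent neuropil
field, 6-condition trial structure — is one call away
(`npil.synth.simulate_fov_dataset`), and the `npil` CLI exposes
`simulate`, `deconvolve`, `analyze`, `decode` and `report` verbs over the
same machinery.

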