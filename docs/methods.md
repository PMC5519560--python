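# Methods

## Calcium dynamics and the deconvolution model

Somatic fluorescence is modelled as linear, time-invariant calcium
dynamics: a spike in frame *t* adds an instantaneous ΔF/F increment that
decays geometrically with per-frame retention `r = 1 − Δ/τ`, where Δ is the
frame period (s) and τ the indicator decay constant (s).  The model
assumes τ is constant over the recording and that transients superpose
linearly — adequate for OGB and an approximation for GCaMP6s, whose
nonlinearity is treated only as a gain/τ change.

The per-frame spike signal **n** carries ΔF/F units (amplitude × spike
count), not physical spike counts; correlation-based comparisons with
ground truth are therefore scale-free.

The discrete map between calcium and spikes is encoded by a square T×T
lower-bidiagonal matrix `M` (diagonal 1, subdiagonal −r) whose first row is
`[1, 0, …]`, i.e. calcium is taken to be zero before the first frame.  This
square convention makes `M` invertible, `P = M⁻¹ = (r^{i−j})_{i≥j}`, and both
operators are applied as O(T) recursions (`scipy.signal.lfilter`), never as
dense matrices, in the hot paths.

## Joint estimation of spike rates and the spatial filter

For a multi-pixel ROI, `C ≈ P n aᵀ` with `n ≥ 0` (length T) and a
non-negative spatial filter `a ≥ 0` (length Npix).  The two subproblems

- `J(n) = ‖C − P n aᵀ‖²_F + k₁‖n‖₁`, solved by a log-barrier interior-point
  method.  With `a` fixed the Frobenius objective collapses to a single
  least-squares problem with design `‖a‖P`; the Newton systems factor as
  `Pᵀ(2t‖a‖²I + MᵀDM)P` with the middle matrix tridiagonal, so each Newton
  step costs O(T).
- `J(a) = ‖C − P n aᵀ‖²_F + k₂‖a‖₁`, separable per pixel with the closed
  form `a_j = max(0, ((Pn)·C_j − k₂/2)/‖Pn‖²)`.

The Bayesian reading — Gaussian likelihood with variance scale λ₀ (ΔF/F²),
exponential priors `p(n) ∝ exp(−λ₁n)` and `p(a) ∝ exp(−a)` — fixes the
penalty weights as `k₁ = λ₀λ₁` and `k₂ = λ₀` after multiplying the negative
log-posterior through by λ₀.  λ₁ is set to the imaging frame period in
seconds (an interpretable prior: the expected per-frame spike signal scales
with the frame duration); it is exposed as an option because "frame period"
could also be read in frame units.  λ₀ is re-estimated each sweep at the
stationary point of the log-posterior, `λ₀ = 2R/N`, where R is the squared
Frobenius residual and N the total entry count of C, floored at 1e−12.

Each sweep is exact (filter step, λ₀ step) or guarded (spike step: the
interior-point iterate is accepted only if it does not increase the
subproblem objective) coordinate ascent on the log-posterior, so the
learning curve is monotone non-decreasing up to floating-point error.  This
monotonicity is the method's central robustness property: because each
subproblem has a single free parameter (k₁ or k₂, both driven by λ₀ alone),
there are no interacting scale parameters that could make the objective
oscillate between sweeps.

The bilinear product `n aᵀ` is scale-ambiguous; the two L1 penalties pin the
scale during optimization, and after convergence the filter is renormalized
to unit sum (`a ← a/Σa`, `n ← n·Σa`), so the filter-weighted mean ΔF/F
(`C·a/Σa`) needs no further scaling.

Numerical choices: uniform filter initialization (1/Npix); spike
initialization `max(0, M·(mean pixel trace))`; λ₀ initialized to the
variance of C; convergence when the relative log-posterior change falls
below 1e−6 or after 50 sweeps; interior-point duality-gap tolerance 1e−8
(relative to the objective scale) with barrier multiplier 10.  The barrier
schedule and tolerances are engineering choices; the estimates are
insensitive to them well before these tolerances.  An all-zero trace
returns zero estimates with a "degenerate" status rather than an error.

Post-hoc spike thresholding zeroes entries below 0.5 × the population SD of
the spike-rate vector — spike trains are sparse and exponentially
distributed, so their SD is small and genuine events survive.  Everywhere a
threshold references a "standard deviation" the population (ddof=0)
convention is used; trial statistics (Fano factors, d′) use sample
variances (ddof=1).  Swapping conventions changes edge-case behaviour and
is deliberately not supported.

## Preprocessing

- **Motion exclusion.** A trial is dropped if any frame is displaced more
  than 2 × pixel size (Euclidean, µm) from the movie's first frame or moves
  more than 0.5 × pixel size between consecutive frames.  Both factors are
  parameters; defaults are the study values.
- **High-pass filtering.** Slow drift is removed by zeroing DCT-II
  components below 0.05 Hz (coefficient j ↦ frequency j·fs/2T); the output
  is mean-free and the operation idempotent.  The hard spectral cut leaves
  some edge ringing on non-bandlimited drift; RMS attenuation is the
  relevant measure.
- **ΔF/F.** F₀ is the mean of samples below mean + 2 SD (population SD),
  excluding transient-dominated frames so that spiking does not inflate the
  baseline.  A constant trace uses the plain mean; an empty selection falls
  back to the global mean with a warning; non-positive F₀ is an error.
- **ROI geometry.** Cell bodies are segmented from a seed disk by taking
  the brightest pixel as the centre and tracing the boundary along 72 polar
  rays (5° steps, linear interpolation) to the first radius below half the
  peak fluorescence.  Neuropil patches are annuli of 7–15 µm (decoding uses
  7–11 µm) around the cell centre, with pixels within 7 µm of any other
  cell centre and any vessel/astrocyte mask pixels excluded.  Coordinates
  are 0-based pixel indices; distances are µm via the pixel size; annulus
  membership is half-open `[r_in, r_out)` on pixel-centre distances.
- **Contamination correction.** `F_corr = F − S·F_np` with S estimated as
  the ratio of mean fluorescence inside a blood-vessel lumen (pure
  spillover, no indicator) to the surrounding neuropil; default S = 0.6
  with a 0.4–0.6 sensitivity-sweep utility.  The estimate is clipped to
  [0, 1).

## Trial statistics

Evoked responses are baseline-subtracted means: baseline over the last 3
pre-onset frames; response over a window one stimulus-duration long
(frames = round(stim_ms/1000 × frame rate), floor-centred for even
lengths) centred at the peak frame of the population-mean high-contrast
response (search window: onset to onset + stimulus + 1 s, ties to the
earliest frame).  Responsiveness: mean 100%-contrast response > 0.5% ΔF/F
for OGB, mean > 5% across conditions for GCaMP6s, both strict.  Fano
factors are per-direction variance/mean of ΔF/F(%) responses averaged over
the two directions at a contrast; conditions with fewer than 2 surviving
trials or non-positive means are skipped and logged.

## Noise correlations

Residuals subtract each (ROI, direction, contrast) condition mean over the
motion-surviving trials; unequal trial counts are allowed and conditions
are weighted equally when the two directions are averaged per contrast.
Cells enter as deconvolved (thresholded) spike responses, neuropil patches
as ΔF/F — neuropil aggregates mixed excitatory/inhibitory processes, so
spike inference is not meaningful there.  Pair distance is the distance
between anchor-cell centres (a patch inherits its cell's position); mixed
cell–neuropil pairs closer than 30 µm are excluded.  Distance profiles use
30 µm bins; the line is fit by OLS through the bin means against the mean
pair distance per bin (not the geometric bin centre), which makes an
exactly linear relation recover exactly.  The two-slope test is
`t = (α₁−α₂)/√(SE₁²+SE₂²)` with df = n₁+n₂−4, where n counts binned points
(the fits are to the binned plots).  The common-scale cell subtraction
regresses all neuropil responses in an FOV on [cell responses, 1] and
correlates the residuals.  p-values are reported raw; a Benjamini–Hochberg
option exists but is off by default, matching standard practice for these
group comparisons.

## Decoding

"Optimal linear decoding" is concretized as the two-class Fisher
discriminant with shared pooled covariance inverted by pseudo-inverse
(singular values below 1e−8 × σ_max dropped; singular covariances are
logged, not fatal), evaluated by stratified 10-fold cross-validation with
seeded shuffling; boundary ties are broken by a seeded coin flip.  Decoding
is always within a single contrast.  Population-size sweeps draw n features
without replacement, 1000 resamples by default.  Patch-size sweeps build
one feature per cell-centred annulus at radii (7–11), (7–50) … (7–250) µm;
because large patches overlap almost completely, a greedy filter drops any
patch whose column does not raise the matrix rank (singular values above
1e−8 × σ_max count).  d′ uses the pooled-SD denominator; the spatial d′
comparison between cells and their patches is tested against a null of
10,000 random permutations of the cell positions, with a two-sided
rank-based p (+1 correction) and a z-score against the null moments.

## The synthetic generator

The generator emulates the study conditions: 8 Hz frames (7–10 Hz range),
1.5 µm pixels (1.2–1.9), τ = 1 s, per-cell Poisson rates drawn from
0.8–5 Hz, salt-and-pepper direction preference with tuning depth 0.3,
2 directions × 3 contrasts (gains 1/0.7/0.4) × 80 repeats, 600 ms stimuli
with 1.5 s ISI, photon noise SD = 0.25 × the single-spike amplitude
(0.1 ΔF/F per spike), and contamination scale S = 0.6.

The neuropil field is a multivariate normal across patch locations whose
correlation matrix is `1 − s·d` (s = 4e−4 per µm by default, a decay
consistent with the ~10% drop over 200 µm seen in cortical recordings),
projected to the nearest PSD matrix by eigenvalue clipping; the realized
(post-projection) correlation matrix is stored as ground truth and the
generative profile slope is defined from it.  Trial responses mix the
shared field into every ROI — strongly for patches (weight 0.9% against
0.45% private noise, giving NP–NP correlations near 0.8) and weakly for
cells (weight 1% against 4% private noise, giving C–C near 0.05) — which
reproduces the NP–NP ≫ C–NP > C–C ordering and cell/neuropil Fano ratios
well above 1.  Patch direction biases (SD 0.05) are exactly demeaned across
the FOV when `balanced_np_tuning` is on, so the FOV-mean patch feature
carries no direction signal while individual reliable patches still do.

Frame-level datasets place somata with ≥ 15 µm separation, render the
observed cell fluorescence as true calcium + S × local neuropil + noise,
and provide a vessel-lumen trace (pure scaled neuropil on an 80-unit raw
baseline) for estimating S.  Pixel movies are an optional rasterization
(Gaussian somata on the neuropil background) for segmentation tests.

What the generator does **not** emulate: indicator rise time and
saturation, GCaMP supralinearity, slow photobleaching, z-motion, true
biophysical neuropil composition, and non-Gaussian field statistics.
Passing tests therefore demonstrate the correctness and calibration of the
estimators under the stated generative assumptions, not their performance
on arbitrary real recordings.

The brute-force oracle for the solver is an exhaustive multiresolution grid
search (full grid at 15 points per axis over `[0, 2·max|x_ls|]`, repeatedly
refined around the incumbent until the requested step): the objective is
convex, so refinement reaches the global minimum, and the search is fully
independent of the interior-point path.  It refuses more than 4 dimensions.

## Validation battery and problem sizes

`npil.validation` (driven by `tests/test_acceptance.py` and
`scripts/acceptance.py`) recomputes: solver-vs-oracle objective gaps (50
instances across the generic/spike/filter families); learning-curve
monotonicity (100 random 30-s traces); spike recovery (20 noisy 300-s
traces, median correlation; 5 noise-free multi-pixel traces, filter
cosine); the contamination round trip (S ∈ {0.4, 0.5, 0.6}); correlation
calibration (ρ ∈ {0, 0.25, 0.5, 0.8}, 480 trials, 200 simulations, plus a
trial-shuffle control); profile-slope recovery over 50 FOVs of 20 cells
with the two-slope type-I rate over 2000 simulations; decoder calibration
(200 shuffled runs of 160 trials, the analytic d′ = 1 problem at 10,000
trials, separable data); the d′ shuffle-null rejection rate (1000 runs of
25 ROIs, 10,000 shuffles each); and the qualitative FOV reproductions (25
cells × 480 trials).  These sizes keep the full battery under a minute
while leaving every Monte-Carlo tolerance comfortably resolvable.

## Known limitations

- The deconvolution assumes a single known τ; misspecified or time-varying
  kinetics bias the estimates, and no τ estimation is provided.
- The spike signal is continuous-valued; no discrete spike counts are
  inferred.
- The linear-decay correlation model of the neuropil field is an
  assumption; only small slopes (s·d_max ≪ 1) keep it near-PSD, and the
  PSD projection slightly perturbs the nominal slope (the realized matrix
  is what ground truth records).
- The Fisher decoder is the Bayes rule only under Gaussian equal-covariance
  classes; accuracies on other distributions are lower bounds on what a
  nonlinear decoder could achieve.
- Sub-pixel registration is out of scope: motion traces are inputs, and
  only the trial-exclusion logic is implemented.
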