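# Methods

## The decomposition

For zero-mean complex samples `x_t`, `y_t` (t = 1..n) all statistics are
plain sample moments: coherence `ρ_xy = ⟨x ȳ⟩/√(⟨|x|²⟩⟨|y|²⟩)`, conjugate
coherence `ρ_xȳ = ⟨xy⟩/√(⟨|x|²⟩⟨|y|²⟩)`, and the normalized fourth-order
cumulants `K_x = κ̃(x,x,x̄,x̄)`, `K_xy = κ̃(x,y,x̄,ȳ)` with

    κ(x1,x2,x3,x4) = μ(x1,x2,x3,x4) − μ(x1,x2)μ(x3,x4)
                     − μ(x1,x3)μ(x2,x4) − μ(x1,x4)μ(x2,x3).

Expanding the sample covariance of the power envelopes |x|², |y|² in these
moments yields, as pure algebra,

    cov(|x|²,|y|²) = |μ(x,ȳ)|² + κ(x,y,x̄,ȳ) + |μ(x,y)|²,

and the self-pair versions give the envelope variances.  Dividing through
produces the decomposition of the envelope Pearson correlation r_xy into a
coherence term |ρ_xy|², a cokurtosis term K_xy, and a conjugate-coherence
term |ρ_xȳ|², over the common denominator
√((1+K_x+|ρ_xx̄|²)(1+K_y+|ρ_yȳ|²)).  Because the derivation is an identity
for *sample* quantities, the package deliberately uses uncorrected sample
moments: any small-sample cumulant bias correction would break exactness.
The identity is enforced by property tests at 1e-10 relative error over
mixed families of inputs (proper/improper Gaussian, bursty, heavy-tailed,
constant-modulus carriers).

Interpretation anchors: for proper Gaussian pairs all fourth-order cumulants
vanish and r = |ρ|² (the classical Gaussian envelope-correlation relation);
K_xy equals the covariance of the unit-normalized powers in excess of the
matched-Gaussian value, so the normalized version
r_e = K_xy/√((1+K_x)(1+K_y)) is a correlation-like measure of co-occurrent
extreme envelope excursions.  A constant-modulus signal has K = −1 exactly
and an undefined power correlation (zero envelope variance); the
implementation flags near-zero envelope variance at a 1e-12 relative
threshold to absorb float roundoff in |e^{iθ}|².

Conventions: signals are demeaned by default (opt-out flag), matching the
zero-mean premise of the moment algebra.  Epoched data are concatenated
along the sample axis before averaging (pooled estimate); per-epoch
estimation is available by calling the estimators per epoch.  K_xy is
mathematically real; the implementation asserts |Im| < 1e-9·|K| + 1e-12 and
discards the numerical residue.

## Orthogonalization

Leakage removal subtracts the instantaneous linear contribution of x from y:
y⊥ = y − αx with α = √(⟨|y|²⟩/⟨|x|²⟩)·Re(ρ_xy), leaving ⟨x ȳ⊥⟩ purely
imaginary (asserted at 1e-10 of the power scale).  The post-orthogonalization
statistics have closed forms that are again finite-sample identities:

    |ρ_{x,y⊥}|² = Im(ρ)² / (1 − Re(ρ)²)
    K_{x,y⊥}    = (K_xy − 2 Re(κ̃(x,y,x̄,x̄)) Re(ρ) + K_x Re(ρ)²) / (1 − Re(ρ)²)

The mixed-cumulant cross term can be dropped (`neglect_mixed=True`) when only
marginal and pair cumulants are of interest; the full form is the default and
is verified against direct re-estimation on y⊥.  The predicted coherence
contribution c_{x,y⊥} uses the neglected-term form, and the depression factor
η = K_x Re(ρ)² + cot²(φ)(K_xy + K_x Re(ρ)²), φ = arg(ρ), is non-negative
whenever K_x, K_xy ≥ 0: orthogonalization can only reduce the coherence
contribution, and at φ = 0 it removes it entirely, leaving the non-Gaussian
power correlation.  Matrix-level runs compute both directed versions and
report their average (symmetric-matrix convention); collinear pairs
(|Re ρ| = 1) are rejected as degenerate.

## Spectral representations

Frequency route: STFT with 1-s Hann windows and 50 % overlap; the
coefficient series at the bin nearest the requested frequency (1-Hz spacing
at integer sampling rates).  Time route: zero-phase (forward–backward)
4th-order Butterworth band-pass at center ± 2 Hz, Hilbert analytic signal,
decimation by 5.  The band-pass already anti-aliases the decimation whenever
the decimated Nyquist clears the upper band edge; otherwise an explicit FIR
decimator is used.  Hann is the package's choice of taper for 50 %-overlap
estimation.  Group peak frequencies are the maxima of subject-averaged power
within a band, ties resolved to the lower frequency (logged), flat spectra
falling back to the band center with a warning.

## Bursts

Burst extraction z-scores each complex signal so that the *real part* has
unit SD, then thresholds |Re| at 3.  This normalization makes the threshold
exactly interpretable: for a Gaussian real part the expected burst rate is
2(1−Φ(3)) ≈ 0.0027, which is the calibration oracle.  For proper signals the
imaginary part gives statistically identical rasters (tested).  Pairwise
co-occurrence is the mean of the product of the two rasters, computed for
(x, y⊥x) and symmetrized with (y, x⊥y); subject matrices are averaged.
Co-occurrence is bounded by min of the rates, and equals the product of the
rates for independent channels.

## Corticothalamic simulator

Two identical mean-field models (cortical excitatory/inhibitory, thalamic
relay/reticular populations).  Dendritic potentials obey
(1/(αβ) d²/dt² + (1/α+1/β) d/dt + 1)V = Σν φ, rates follow
Q(V) = Qmax/(1+exp(−(V−θ)/σ)), and the cortical rate is damped by
(1/γ² d²/dt² + (1/γ) d/dt + 1)φ_e = Q_e (first-order coefficient 1/γ as a
package convention; the critically damped 2/γ variant is one keyword away
via `wave_damping=2.0`).  The i, r, s populations have effectively infinite
damping (φ = Q).  Corticothalamic propagation is delayed by τ each way;
cortical inhibitory inputs mirror excitatory ones (V_i = V_e), the standard
random-connectivity reduction.

Default parameters (registry set `corticothalamic-eyes-closed`, all
overridable): Qmax = 250 s⁻¹, θ = 15 mV, σ = 3.3 mV, α = 50 s⁻¹,
β = 200 s⁻¹, γ_e = 100 s⁻¹, τ = 40 ms, ν_ee = 1.2, ν_ei = −1.8, ν_se = 1.2,
ν_sr = −0.8, ν_re = 0.4, ν_rs = 0.2, ν_sn = 0.5 mV·s — standard published
eyes-closed values — and ν_es = 1.35 mV·s as the working point.  The package
located the Hopf onset of this configuration empirically near ν_es ≈ 1.5
(noise-free integration destabilizes between 1.50 and 1.55); ν_es = 1.35
puts the model close enough to the instability for state-dependent noise to
trigger large-amplitude excursions while the noise-driven linear regime
remains stable for inter-model couplings up to 0.05 mV·s.

The thalamic relay drive is φ_n(t) = φ_n0 + ξ_m(t) + χ·ξ_j(t)·φ_e(t−τ) with
φ_n0 = 0.5 and ξ ~ N(0, 0.1) white noise.  Integration is Euler–Maruyama at
dt = 1e-4 s; the white-noise convention scales each per-step draw by 1/√dt
(so SD 0.1 is the intensity of the continuous-time noise).  A pure per-step
convention (`noise_scaling="per_step"`) is provided; at dt = 1e-4 it leaves
so little band-limited noise power that the model never leaves the linear
regime, which is why √dt is the default.  χ balances additive against
state-dependent (multiplicative) noise: at χ = 0 the output is a
noise-driven linear alpha-band process; at χ ≳ 0.15 near the working point,
multiplicative kicks trigger intermittent high-amplitude oscillations —
bursts — and inter-model coupling (an additive, τ-delayed φ_e exchange
between the excitatory populations) synchronizes them.  Diffusive coupling
is deliberately not used, since it can suppress co-amplitudes and push the
cokurtosis negative.

Analysis of simulated traces: FIR decimation to 200 Hz, alpha-band analytic
signals (10 ± 2 Hz), 2 s trimmed at each end (filter and Hilbert edge
transients are common across channels and otherwise inflate envelope
correlations of weak signals).  The (χ × coupling) sweep averages each cell
over 3 independent 60-s realizations (after 5-s burn-in): single 60-s
realizations of bursting cells have high cokurtosis variance because a
handful of burst coincidences dominate the fourth moment.  The Gaussian null
for the χ = 0 row is built from jointly phase-randomized surrogates of the
decimated traces (auto- and cross-spectra preserved exactly, all
higher-order structure destroyed); the acceptance band is the null mean
± 5 null-SD of a rep-averaged estimate, chosen a priori to keep the
false-alarm probability negligible across the three-cell row.

## Beamformer

LCMV weights W = (LᵀΣ⁻¹L)⁻¹LᵀΣ⁻¹ with Σ⁻¹ ≈ (Σ+λI)⁻¹, λ = 1e-7 as an
absolute ridge (trace-scaled option available).  The three orientation
series are collapsed on the leading eigenvector of WΣW†, whose sign is fixed
by making its largest-magnitude component positive — the sign affects only
the phase of the output, never magnitude or fourth-order statistics.  ROI
series stack the member-vertex leadfields and reduce them to the dominant
3-dimensional spatial subspace (SVD) before applying the same unit-gain
pipeline.  Only toy-scale leadfields are in scope.

## Networks, surrogates, bootstrap, clustering

Connectivity sets hold the five aligned p×p matrices (power correlation and
its three terms, plus the coherence contribution); entrywise additivity is
checked on every build.  Seed maps are diagonal-excluded row means with an
optional at-mean thresholded view.  The frequency-domain surrogate scheme
draws proper complex Gaussian vectors matched to the empirical
cross-spectral matrix (Cholesky factor; ridge-stabilized if near-singular):
coherence is preserved, all cumulants vanish in expectation, so the null of
r − |ρ|² isolates non-Gaussian structure.  Bootstrap resamples subjects with
replacement (default B = 1000) around the pooled contributions — each term
summed over all region pairs and divided by the total.  Subnetworks come
from k-means over the columns of the cokurtosis matrix, k = 1..10, best of
10 seeded restarts per k, with the elbow formalized as the k maximizing the
second difference of the within-SS curve (the curve is always returned so
alternative rules can be applied).

## Synthetic ground truth

`bursting_pair` builds two-state amplitude-modulated proper Gaussian
carriers: gains s ∈ {1, A}, marginal burst probability p_b, joint
probability p_shared, background coherence g.  Its closed-form moments
(mixture algebra over the four joint burst states with Isserlis' theorem for
the conditional Gaussian moments) are unit-tested against an independent
brute-force state-enumeration oracle, and the generator returns them with
the samples.  Burst states are i.i.d. per sample by default; a two-state
Markov variant with geometric sojourns models temporally extended bursts and
leaves all single-time moments unchanged.  `improper_signal` plants a
circularity coefficient via unequal real/imaginary variances;
`cohort` plants block-structured co-bursting across regions and subjects;
`toy_forward` emits a random leadfield with one active oscillatory source
for beamformer checks.  Generators require explicit seeds.

What the generators do *not* emulate: 1/f background spectra mixed across
frequencies, volume-conduction mixing with realistic head geometry,
inter-subject variability in spectral peaks, and non-stationarities slower
than the burst process.  Passing tests therefore certify the estimators and
identities, and the qualitative burst phenomenology, not performance under
every property of real MEG recordings.

## Numerical choices and limitations

Problem sizes in tests and the acceptance script (10⁴-sample Gaussian
pairs × 200 replicates, 60-s simulation cells × 3 reps, 10⁶-sample burst
calibrations) were chosen so the whole suite completes in a couple of
minutes on one CPU while keeping Monte-Carlo error well below the tested
effect sizes.  Monte-Carlo assertions use 3-SE bands around closed-form
targets; exact identities use absolute tolerances of 1e-9..1e-12.  Known
limitations: the decomposition is undefined for constant-envelope signals;
the cokurtosis estimator has heavy-tailed sampling error on short bursty
records (hence rep-averaging in the sweep); the simulator's working point is
specific to the shipped parameter set and must be re-tuned if other
corticothalamic parameters are loaded; k-means subnetworks assume
block-like structure and the elbow rule needs k_max ≥ 3.
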