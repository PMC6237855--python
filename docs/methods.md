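# Methods

This note records the models, estimators and numerical choices behind
`hbdyn`, what the synthetic generators do and do not emulate, and the known
limitations.

## Geometric substrate

Trajectories are cubic-box, fixed-topology water in an extended-XYZ dialect
(atom count / comment / `El x y z [vx vy vz]`), Å and fs, molecules stored
contiguously as O,H,H. On load, H positions are unwrapped to the minimum
image relative to their O so intramolecular vectors are continuous across
the boundary. Each OH mode is reduced to a 1-D oscillator: bond length
r(t) = |min-image(r_H − r_O)| and relative momentum p(t) = μ(v_H − v_O)·û
with μ the O–H reduced mass (0.9482 amu). Using the reduced-mass relative
momentum (rather than the bare H momentum) makes (δr, δp/μω̄) a phase-space
pair whose complex combination rotates uniformly for a harmonic mode.

Hydrogen bonds use the standard liquid-water geometric criterion
r_OO ≤ 3.5 Å and H–O···O angle ≤ 30° (both configurable; no single criterion
is canonical and the energy-based metrics deliberately avoid needing one).
Each donor H binds at most one acceptor: the nearest O passing the
criterion, ties broken to the lower molecule index so assignment is
deterministic.

## Wavelet instantaneous frequency

The analysis signal per mode is f(t) = δr(t) − i·δp(t)/(μω̄), mean-removed,
with ω̄ fixed at the frequency-window center (3400 cm⁻¹ for the default
2800–4000 cm⁻¹ window). The sign convention makes f rotate with positive
angular frequency so it projects onto the analytic (positive-frequency)
wavelet. The transform is

    L_ψf(a, b) = a^(−1/2) ∫ f(t) ψ̄((t−b)/a) dt,
    ψ(u) = (σ²π)^(−1/4) e^{2πiλu} e^{−u²/2σ²},

with defaults λ = 1, σ = 2, evaluated by discrete quadrature truncated at
|t−b| > 4aσ (edge-clipped times are flagged, not dropped silently). Scales
map to wavenumbers as ν = λ/(a·dt·c); the default grid is geometric with
256 scales across the window (≈5 cm⁻¹ resolution near 3400 cm⁻¹).

**Scale selection.** For a pure tone the L2-normalized modulus |L| peaks at
a scale biased low in frequency by ≈1/(4πλσ²) relative (the a^{1/2} factor
tilts the Gaussian peak) — about 10 cm⁻¹ at 3400 cm⁻¹ with the defaults,
i.e. two grid steps. The frequency tracker therefore maximizes the
scale-normalized modulus |L|/√a by default, whose maximum sits exactly at
a = λ/ν for a tone; `selection="l2"` restores the literal modulus argmax.
With the default selection a pure tone is recovered within one scale-grid
step, and halving the grid step halves that bound; a linear chirp of
0.15 cm⁻¹/fs is tracked within one step as well (the wavelet's temporal
width, ≈aσ·dt ≈ 20 fs at these settings, sets how fast a modulation can be
followed). An argmax on the window boundary, or a numerically flat signal,
flags the sample.

## Pair energetics and the LSRI

Per-pair tables (TSV: frame, time_fs, donor_mol, donor_H, acceptor_mol,
dE_kJmol, dCT_au) carry ΔE_D→A (negative = stabilizing) and ΔCT_D→A. Frames
where a pair is not bonded are *absent* and stored as NaN — never zero,
which would fabricate decorrelation. Duplicate (frame, pair) rows and
non-uniform time grids are rejected at load.

For each bonded pair at a frame, with don(m)/acc(m) the summed ΔE of all
bonds molecule m donates/accepts:

    O_h = acc(D) + don(A) − don(D) − acc(A).

Sums include the pair's own bond by default (`exclude_self_bond` gives the
alternative reading, which differs by 2ΔE of the pair). Signed ΔE values
enter directly, fixing the sign convention: an isolated single-bond dimer
with ΔE = −20 kJ/mol has O_h = +40 kJ/mol. Two exact properties follow and
are tested: O_h is *invariant* under exchanging every bond's donor/acceptor
roles (the four terms swap pairwise), and per-molecule flux bookkeeping is
conserved (total donated = total accepted = ΣΔE over bonds). An optional
|ΔE| ≥ ε cutoff drops near-zero marginal contacts; ε defaults to 0.

## Linear frequency maps

Maps are ordinary least squares of y on ω (the field's convention for these
scatter fits), reporting slope, intercept, RMSE and sample count. Reference
coefficient sets for ambient liquid water are shipped with an explicit
interpretation: the small-magnitude printed coefficient is the slope per
cm⁻¹ and the large one the intercept, signed so |ΔE|, ΔCT and LSRI all
shrink toward zero as ω grows (weaker H-bond at higher stretch frequency):
ΔE = −150.6 + 0.0392·ω, ΔCT = 0.086 − 0.0000221·ω, LSRI = 72.34 − 0.01755·ω
(so LSRI(3400 cm⁻¹) ≈ 12.7 kJ/mol). The library fits maps from data; the
constants are documentation, not inputs to any estimator.

## Correlation estimators

`tcf` pools all (entity, origin) products per lag — the ensemble-average
reading of ⟨x(0)x(t)⟩ — using FFT autocorrelation per contiguous segment
(verified against a brute-force double loop at 1e-10). Pairs with gaps
contribute only contiguous bonded segments. Mean removal is configurable:

* `center=True` (default; HBCF/CTCF/LSRI-TCF): each entity's own mean —
  pairs genuinely differ in baseline strength;
* `center="global"` (FTCF): the pooled mean over all entities. Per-mode
  means estimated from a record only ~20 correlation times long are noisy
  enough to bias the pooled correlation tail visibly downward (a fitted
  slow constant of ≈0.64 ps from a planted 1.01 ps at the default problem
  size); identically distributed modes share one ensemble mean, so the
  pooled mean is the faithful δω = ω − ⟨ω⟩;
* `center=False`: the literal un-centered product correlation.

S_HB(t) is the probability that a bond intact at an origin stays intact at
*every* frame through t. Only origins whose observation window fits inside
the record count at each lag (standard censoring), so a permanently intact
bond gives exactly 1 at all lags. An `allowance` of k frames (default 0)
bridges transient breaks up to that length. N_HB uses per-molecule counts
n(t) (donated + accepted), fluctuations against the global mean, normalized
by ⟨δn²⟩; zero variance is an error, as is an empty bond record.

Bi-exponential fits run trust-region least squares from an 18-point
multistart grid (a₀ ∈ {0.3, 0.7} × τ₀ ∈ {0.02, 0.05, 0.1} ps × τ₁ ∈
{0.5, 1, 2} ps), bounds a₀ ∈ [0,1], τ > 0, tolerances 1e-14, with τ₀ ≤ τ₁
enforced by swapping (a₀ → 1−a₀). Noiseless curves are recovered to 1e-6
relative across random parameter draws. The default fit window is 0–4 ps or
40% of the maximum lag, whichever is smaller (long-lag estimates are noisy).

Block errors split the time axis into contiguous blocks (default 3,
matching three 8-ps mini-trajectories from a ~24 ps record), apply the full
estimator per block and report std/√n_blocks. With 3 blocks a ±2·SE
interval behaves like a t₂ statistic (~82% coverage, not 95%); the coverage
simulation in the test suite uses 8 blocks, where ~91% is attainable.

## Cumulant spectroscopy

Within the second-order cumulant (Gaussian) approximation everything
follows from g(t), the double cumulative-trapezoid integral of the
unnormalized frequency TCF converted to rad²/fs² via (2πc)². The classical
treatment keeps g real (no Stokes-shift imaginary part), appropriate for
frequency statistics from classical trajectories. The three rephasing
pathways of a two-level Condon chromophore share one envelope,

    R ∝ exp[−g(t₁) + g(t₂) − g(t₃) − g(t₁+t₂) − g(t₂+t₃) + g(t₁+t₂+t₃)],

so I(t₁,t₂) = ∫₀^{t₃max} |3R|² dt₃ (trapezoid; the worst-case integrand
tail/peak ratio is recorded and >1e-3 raises a truncation flag; doubling
t₃max then changes I by <0.1%). S(t₂) is a one-sided second-order finite
difference over t₁ ∈ {0, dt₁, 2dt₁}, default dt₁ = 2 fs. Because S is a
~1e-4 relative variation of I across that stencil, g is evaluated off-grid
with a cubic spline — linear interpolation on a 5-fs lag grid leaves ~1e-3
artifacts that corrupt the slope entirely. Default grids: t₂ ∈ [0, 4 ps] at
≤100 points, dt₃ = 2 fs, t₃max = 2 ps.

Closed-form checks: static modulation (C = Δ²) gives g = Δ²t²/2, a
t₂-independent slope (C(t₂) ≡ 1) and an echo at t₃ = t₁; motional narrowing
(Δτ_c = 0.1) gives Lorentzian free-induction decay I ∝ e^{−2Δ²τ_c t₁} with
no echo; an intermediate Kubo modulation (Δτ_c = 1) yields an S3PE slow
constant within 15% of τ_c. On a bi-exponential FTCF the S3PE slow constant
reproduces the FTCF's slow constant to ~1% — the echo slope is a faithful
spectral-diffusion clock, which is the scientific claim the package
packages.

ΔE- or ΔCT-driven echoes first rescale the (mean-free) series to frequency
units by dividing by the fitted linear-map slope; the conversion is an
interpretation (the phase accumulated by an HB-strength fluctuation is
defined only through the map) and is recorded in the outputs.

## Synthetic generators

The generators plant, exactly, the statistics the estimators measure:

* **Frequency process**: a sum of two independent Ornstein–Uhlenbeck
  processes with variances a₀Δ² and (1−a₀)Δ² and exact discrete updates
  x_{k+1} = ρx_k + √(var(1−ρ²))ξ, so the autocorrelation is exactly
  Δ²[a₀e^{−t/τ₀} + (1−a₀)e^{−t/τ₁}] — no spectral-filtering approximation.
  Defaults: mean 3400 cm⁻¹, Δ = 100 cm⁻¹, a₀ = 0.6, τ₀ = 0.1 ps, 5 fs,
  5000 frames, 128 modes (the scale of a 64-molecule, 25 ps study); the
  fast-component parameters are fixture choices, not literature recoveries.
* **Coupled observables**: dE/dCT/LSRI = intercept + slope·ω + N(0, σ) with
  σ matching the reference RMSEs (7.27 kJ/mol, 0.004 a.u.; LSRI σ = 5
  kJ/mol, a plausible mid-range value since no reference RMSE exists).
  The scatter is *white in time*. Consequently the synthetic HBCF/CTCF are
  noise-diluted copies of the FTCF: with signal sd slope·Δ ≈ 3.9 kJ/mol
  against σ = 7.27, the normalized pair TCF drops by ~78% within one frame
  and a two-exponential fit of the three-component curve pulls the slow
  constant below the planted value (≈0.62–0.65 ps in the worked example).
  Real EDA series have temporally correlated residuals and do not share
  this artifact — passing pipeline tests on the synthetic pair metrics
  shows estimator correctness, not that white scatter is a good model of
  EDA noise.
* **Markov bonds**: independent two-state chains via the exact discrete
  skeleton of the continuous-time process (per-step break probability
  π_u(1−e^{−rΔt}), r = k_break + k_form), so the indicator autocorrelation
  is exactly e^{−rt} and the continuous survival decays with constant
  −Δt/ln(1−p_break) ≈ 1/k_break (0.2% discretization bias at 5 fs/1.2 ps).
  Pair i bonds molecules 2i → 2i+1 so per-molecule counts stay independent.
  Short-time oscillatory structure of real HB correlations is deliberately
  not emulated.
* **Oscillator trajectories**: r(t) = r₀ + A·cos φ with φ̇ = 2πc·ω(t) and
  analytic velocities, embedded as a single water molecule; the wavelet →
  FTCF closed loop recovers the planted modulation (correlation >0.98
  against the planted series; the recovered TCF matches the realization's
  own TCF within 10%).

All generators are reproducible: same spec + seed → identical arrays.

## Verification problem sizes

The recovery checks run at the study-scale conditions: noiseless fit
recovery on 5-fs grids to 8 ps; the FTCF pipeline on 128 tracks × 24 ps
(recovery judged against 2 block-standard-errors — at this size the fitted
slow constant has an intrinsic spread of ≈0.1 ps across realizations, and
no weighting scheme reduces it because per-lag errors are correlated);
Markov kinetics on 500 pairs × 25 ps; the S3PE closed loop on 512 tracks ×
25 ps, where the input FTCF is converged enough (sd ≈ 0.05 ps) that the
check probes the deterministic cumulant chain rather than one realization's
noise. The full test suite runs in about half a minute on one CPU.

## Known limitations

* Two-level, Condon, classical cumulant response only: no 1→2 anharmonic
  pathway, no vibrational lifetime, no non-Condon dipole weighting, no
  finite pulses — S3PE shape is pure spectral diffusion.
* No stretched/tri-exponential relaxation models and no reactive-flux HB
  kinetics; the bi-exponential form is the only fit model.
* Cubic NVT/NVE boxes only; no triclinic cells, no MD engines wrapped.
* The EDA side consumes tables; no electronic-structure decomposition is
  performed or approximated.
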