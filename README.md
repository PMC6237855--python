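# hbdyn

Hydrogen-bond rearrangement dynamics of liquid water from molecular-dynamics
post-processing.

Water's anomalies trace back to the picosecond making and breaking of its
hydrogen-bond (HB) network. Nonlinear vibrational spectroscopies (three-pulse
photon echo, 2D-IR) probe this through the spectral diffusion of the OH
stretch, while energy-decomposition analyses of ab-initio MD quantify each
bond directly through the donor→acceptor delocalization energy ΔE_D→A and
charge transfer ΔCT_D→A. `hbdyn` connects the two pictures. It is aimed at
simulators who have an MD trajectory (positions + velocities) and per-pair
energy-decomposition tables and want energy-based HB dynamics metrics and
echo observables without any further electronic-structure work.

## What it computes

* **Instantaneous OH stretch frequencies** ω(t) per OH mode via the continuous
  wavelet transform of the complex signal δr(t) − i·δp(t)/(μω̄) with a
  Morlet–Grossman mother wavelet ψ(u) = (σ²π)^(−1/4) e^{2πiλu} e^{−u²/2σ²};
  the scale a maximizing the transform modulus gives ω = λ/(a·dt·c).
* **Linear frequency maps** y = b + m·ω for y ∈ {ΔE_D→A, ΔCT_D→A, LSRI} by
  ordinary least squares, with RMSE, plus 2-D probability densities P(ω, y).
* **LSRI**, the local solvent reorganization index of an H-bonded pair,
  O_h = D_Acc + A_Don − D_Don − A_Acc: the net energy flux through the
  donated/accepted bonds of the donor (D) and acceptor (A) molecules.
* **Time-correlation functions**: the HB-strength correlation (HBCF)
  ⟨ΔE(0)ΔE(t)⟩, charge-transfer correlation (CTCF), frequency-time
  correlation (FTCF) ⟨δω(0)δω(t)⟩, LSRI-TCF, the continuous HB survival
  S_HB(t), and the HB-number correlation C(t) = ⟨δn(0)δn(t)⟩/⟨δn²⟩ — each
  with bi-exponential fits f(t) = a₀e^{−t/τ₀} + (1−a₀)e^{−t/τ₁} and
  block-averaged uncertainties.
* **Echo observables** in the second-order cumulant approximation: lineshape
  g(t) = ∫₀ᵗdt′∫₀^{t′}dt″ C(t″), integrated echo intensity
  I(t₁,t₂) = ∫₀^∞ dt₃ |Σᵢ Rᵢ(t₁,t₂,t₃)|², and the slope of the three-pulse
  echo S(t₂) = ∂I/∂t₁|_{t₁=0} with its normalization C(t₂) = S(t₂)/S(0),
  driven by ω, ΔE or ΔCT fluctuations.
* **Synthetic generators** for every statistical structure above (sum-of-OU
  Gaussian frequency processes with exact bi-exponential autocorrelation,
  linearly coupled observables with planted RMSE, two-state Markov HBs,
  oscillator trajectories), so the entire pipeline is testable without MD.

## Worked example

The `run` pipeline generates the synthetic "paper-water" conditions (128 OH
modes, 5 fs sampling, 25 ps; Markov bonds with 1.2 ps continuous lifetime and
0.74 ps number-correlation relaxation), computes all six correlation
functions, fits, maps and S3PE curves, and writes a report bundle:

```sh
hbdyn run --preset paper-water --seed 7 --out run_full
```

prints (stderr):

```
hbdyn: wrote run_full/summary.json [8.69 s]
hbdyn: tau1 (ps): {'FTCF': 0.968, 'HBCF': 0.653, 'CTCF': 0.62, 'LSRI-TCF': 0.608, 'S_HB': 1.187, 'N_HB': 0.743}
```

`summary.json` carries each long time constant τ₁ with its 3-block standard
error, e.g. FTCF 0.968 ± 0.028 ps against the planted 1.01 ps, S_HB
1.187 ± 0.036 ps against the planted 1.2 ps, and N_HB 0.743 ± 0.015 ps
against the planted 0.74 ps. The fitted frequency maps recover the planted
couplings and scatter, e.g. for the HB strength

```json
"dE": {"slope": 0.0392, "intercept": -150.52, "rmse": 7.268, "n": 640000}
```

(ΔE in kJ/mol per cm⁻¹; RMSE planted at 7.27 kJ/mol). The S3PE long constant
from frequency fluctuations is 0.964 ps, close to the FTCF's 0.968 ps — the
echo slope tracks the loss of frequency correlation. The HBCF/CTCF/LSRI-TCF
constants (≈0.61–0.65 ps) sit below the planted slow constant because the
synthetic coupling adds temporally white scatter; see `docs/methods.md`.

Individual stages are available as `hbdyn synth | freq | tcf | maps | s3pe`,
e.g. wavelet tracks from an extended-XYZ trajectory with velocities:

```sh
hbdyn freq --traj water.xyz --dt 0.5 --box 12.43 --window 2800:4000
```

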