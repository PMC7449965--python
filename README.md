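# ffcrelax

Quantitative analysis of ¹H fast field-cycling (FFC) NMR relaxation
dispersion profiles from soft tissue, for relaxometry groups studying
tumour and muscle microstructure.

FFC-NMR measures the spin–lattice relaxation rate R₁ = 1/T₁ over several
decades of magnetic field, yielding a *dispersion profile* R₁(ν_H) whose
shape encodes molecular dynamics from nanoseconds to milliseconds.
`ffcrelax` implements the full analysis chain for such profiles:

1. **Relaxation model.** The rate is split into two dipolar terms,
   R₁(ν_H) = R₁ᴴᴴ(ν_H) + R₁ᴴᴺ(ν_H).  The ¹H–¹H part is model-free — a sum
   of three Lorentzian spectral-density terms for slow, intermediate and
   fast motions plus a frequency-independent offset:

   R₁ᴴᴴ(ω) = Σₖ Cₖᴴᴴ [ τₖ/(1+ω²τₖ²) + 4τₖ/(1+4ω²τₖ²) ] + A,  k ∈ {s, i, f}

   with ω = 2πν_H.  The ¹H–¹⁴N part models quadrupole relaxation
   enhancement (QRE): six Lorentzians of width 1/τ_Q centred at the ¹⁴N
   quadrupole transition frequencies ν₋ = ¾a_Q(1−η/3), ν₊ = ¾a_Q(1+η/3),
   ν₀ = ½ηa_Q, weighted by the orientation (Θ, Φ) of the H–N axis and
   scaled by the effective distance r_HN⁻⁶.  These produce the
   "quadrupole peaks" near 2–3 MHz seen in protein-rich tissue.
2. **Scaling.** Bulk-water content shifts whole profiles up and down, so
   each profile is multiplied by the factor that least-squares-matches
   its ≥ 4 MHz segment to a designated reference profile (closed form
   s = Σ ref·prof / Σ prof²).  A larger factor means longer raw T₁.
3. **Fitting.** Bounded, weighted (1/σ²) multi-start least squares in
   log₁₀ space for the scale parameters, with uncertainties from the
   local covariance and an optional residual bootstrap.
4. **Cohort statistics.** Welch t-tests of the pre-specified effects:
   myxoid tumour components on the factor (additive), tumour proximity on
   muscle factors (multiplicative, tested on logs), and the muscle-vs-
   sarcoma contrast of the fitted offset A — plus a hierarchical-
   clustering assistant that suggests dispersion groups.
5. **Synthetic cohorts.** A generator reproducing the study design this
   analysis targets: 70 evolution fields log-spaced from 10 kHz to 10 MHz
   with denser sampling in 0.4–3.5 MHz, 1–4 % per-point noise, the eight
   published tissue-group parameter sets (muscle I–III, sarcoma A–E) and
   patient-level scaling-factor structure with injected cohort effects.

## Worked example

```python
import numpy as np
from ffcrelax import FitConfig, fit_profile, group_preset, simulate_profile

preset = group_preset("II")                    # muscle dispersion group II
profile = simulate_profile(preset, noise_rel=0.02, seed=1, sample_id="demo")
result = fit_profile(profile, init=preset, config=FitConfig(seed=1))

hh, qre = result.params.hh, result.params.qre
print(f"tau_s = {hh.tau_s*1e6:.2f} +/- {result.uncertainties['tau_s']*1e6:.2f} us")
print(f"tau_i = {hh.tau_i*1e9:.0f} +/- {result.uncertainties['tau_i']*1e9:.0f} ns")
print(f"A     = {hh.a:.2f} +/- {result.uncertainties['a']:.2f} 1/s")
print(f"tau_Q = {qre.tau_q*1e6:.2f} us,  r_HN = {qre.r_hn:.2f} A")
print(f"C_s/C_i = {result.ratios['c_s/c_i']*1e3:.0f} e-3")
print(f"reduced chi^2 = {result.chi2_reduced:.2f}")
```

prints

```
tau_s = 5.67 +/- 0.72 us
tau_i = 669 +/- 40 ns
A     = 3.03 +/- 0.06 1/s
tau_Q = 0.97 us,  r_HN = 3.27 A
C_s/C_i = 210 e-3
reduced chi^2 = 0.80
```

The fitted slow correlation time (5.67 ± 0.72 µs) and offset (3.03 s⁻¹)
recover the generating group II values (5.36 µs, 3.03 s⁻¹) within their
uncertainties; τ_Q sits at the ~1 µs value common to all tissue groups,
and the reduced χ² near 1 confirms the 2 % noise model.  The dipolar
constants are only meaningful as the scale-free ratios C_s/C_i and
C_s/C_f, because scaled profiles carry an arbitrary overall amplitude.

A full simulate → scale → fit → stats run from the shell:

```bash
ffcrelax run --config examples/cohort.yaml --seed 1 --out runs/demo
```

writes profile tables, the scaling-factor table, per-sample fits, an
effects report and a machine-readable run manifest.  Two runs with the
same config and seed produce byte-identical numeric outputs.

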