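# Methods

This note documents the models, numerical choices and limitations of
`ffcrelax`. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute at run time.

## Relaxation model

The total ¹H spin–lattice rate is R₁(ν_H) = R₁ᴴᴴ(ν_H) + R₁ᴴᴺ(ν_H).

**¹H–¹H term (model-free).** Tissue dynamics are too heterogeneous for a
motional model, so R₁ᴴᴴ is decomposed into three Lorentzian
spectral-density pairs — slow, intermediate and fast processes — each
with a dipolar constant Cₖᴴᴴ (s⁻²) and correlation time τₖ, plus a
frequency-independent offset A (s⁻¹) that absorbs dynamics on the ~ns
scale or faster. Three terms is the smallest number that fits tissue
dispersions well; model selection between 2- and 3-term variants is out
of scope. The dipolar constant of an effective inter-proton distance r
is Cᴴᴴ = (3/10)(μ₀/4π · γ_H²ħ/r³)², available as
`dipolar_constant(r_Å)`.

**¹H–¹⁴N term (QRE).** At the fields covered here the ¹⁴N energy levels
are set by the quadrupole coupling alone: E₁ = ¼a_Q(1−η), E₂ = −½a_Q,
E₃ = ¼a_Q(1+η), giving transitions ν₋ = ¾a_Q(1−η/3), ν₊ = ¾a_Q(1+η/3)
and ν₀ = ν₊−ν₋ = ½ηa_Q. When the proton Larmor frequency crosses one of
these, relaxation is enhanced; R₁ᴴᴺ is the sum of six Lorentzians of
width 1/τ_Q centred at ±ν₋, ±ν₊, ±ν₀ with angular weights
(⅓+sin²Θcos²Φ), (⅓+sin²Θsin²Φ), (⅓+cos²Θ) — which always sum to 2 — and
an overall amplitude ∝ r_HN⁻⁶. With the tissue presets below, the
quadrupole peaks fall between 2 and 3 MHz.

**Conventions.** Public interfaces use linear frequency in Hz; ω = 2πν
is applied internally and uniformly, including ω± = 2πν±. a_Q is a
frequency (Hz), distances are Å at the interface (m internally), angles
degrees. The ¹⁴N gyromagnetic ratio is stored with its physical positive
sign; only its magnitude enters the squared prefactor. A is allowed to
be exactly 0 (lower bound of its fit range) even though physical tissue
offsets are positive.

## Scaling to a reference

Bulk-water content rescales whole profiles without changing their shape,
so profiles are compared after multiplying each by the factor s that
minimizes Σ(ref − s·prof)² over the points at ν ≥ 4 MHz — the region
dominated by fast, structure-insensitive dynamics. Choices:

* the cut-off is inclusive (ν ≥ 4.0 MHz), maximizing usable points;
* the comparison frame is the reference's own grid; the sample profile
  is interpolated onto it linearly in (log ν, log R₁), which is exact
  for power-law segments; errors are interpolated linearly in log ν;
* the factor is unweighted least squares (closed form
  s = Σref·prof/Σprof²), but measurement errors are propagated when the
  factor is applied (both R₁ and σ are multiplied);
* at least 3 common points are required; fewer is an error;
* factors are meaningful only relative to the chosen reference; the
  package never interprets their absolute values.

## Fitting

Weighted least squares Σ[(R₁ᵒᵇˢ−R₁ᵐᵒᵈ)/σ]² with σ = max(σᵢ, 0.01·R₁ᵒᵇˢ);
the 1 % relative floor reflects the instrument's typical 1–4 % errors
and guards against zero-error points. Numerical choices:

* C_s, C_i, C_f, τ_s, τ_i, τ_f and τ_Q are optimized as log₁₀(values) —
  they span ~4 decades and must stay positive; A and r_HN stay linear;
* bounds: τ_s ∈ [0.1, 100] µs, τ_i ∈ [0.01, 10] µs, τ_f ∈ [1, 100] ns,
  τ_Q ∈ [0.1, 10] µs, r_HN ∈ [1, 10] Å, A ∈ [0, 100] s⁻¹, C's within
  wide positive decades. The τ bounds overlap, so the slow>intermediate>
  fast ordering is additionally enforced: starts are reordered and any
  optimum violating it is rejected;
* η, a_Q, Θ and Φ are fixed by default at the values carried by the
  initial guess (the group presets, or central tissue values 0.41,
  3.28 MHz, 77°, 53° when no guess is given). They vary little between
  tissue groups and freeing all of them over-parameterizes a 70-point
  profile; any subset can be freed through `FitConfig.fixed`;
* multi-start: the first start is the supplied or data-driven heuristic
  guess (offset pinned just below the high-field plateau, dispersion
  drop split across canonical correlation times 5 µs/0.6 µs/40 ns);
  the remaining starts draw log-uniformly (linear parameters uniformly)
  within bounds, seeded. Lowest cost wins; ties go to the lowest start
  index. Optimizer: scipy `least_squares` (trf, `x_scale='jac'`);
* uncertainties come from the covariance at the optimum (pseudo-inverse
  of JᵀJ) rescaled by reduced χ², delta-transformed for log-fitted
  parameters; a residual-resampling bootstrap (default 200 replicates)
  is available for small-n robustness;
* group fits pool the points of all member profiles, each with its own
  σ, under one parameter vector — chosen over averaging profiles so
  heteroscedastic points keep their weights;
* degenerate inputs: a constant profile raises an identifiability
  error; fewer points than free parameters + 3 is an error; if no start
  converges to a physically ordered optimum a non-convergence error
  carries the best partial result.

Because C_s is arbitrary for scaled profiles, fits report the
dimensionless ratios C_s/C_i and C_s/C_f alongside the raw constants.

## Synthetic data

The generator emulates the acquisition and cohort structure the analysis
assumes, so that every stage is testable without any external data.

* **Grid:** 70 fields, 40 log-spaced over 10 kHz–10 MHz plus 30
  log-spaced over 0.4–3.5 MHz (the quadrupole-peak band); numerically
  coincident points are nudged apart by 10⁻⁹ relative. The 40/30 split
  is one interpretation of "denser sampling in the QRE band" and is
  configurable.
* **Noise:** one relative level per profile, uniform on [1 %, 4 %],
  applied pointwise as zero-mean Gaussian with σ = level·R₁; draws that
  would cross zero are redrawn. `r1_err` records σ.
* **Presets:** the eight published tissue-group parameter sets (muscle
  I–III, sarcoma A–E). Dipolar constants are published only as ratios,
  so C_s is fixed at 10⁶ s⁻² — chosen to put R₁ in the realistic
  ~3–50 s⁻¹ range — and C_i, C_f derived from the ratios. A fat preset
  exists purely as pipeline plumbing: real adipose dispersions follow
  polymer-melt power laws that the HH model does not represent, and fat
  profiles are excluded from scaling comparisons and fits.
* **Cohort:** per patient, a log-normal base factor (sd 0.15) and a plan
  of tumour/adjacent-muscle/remote-muscle/fat samples. Effects are
  injected on the factor scale exactly as reported: myxoid tumours get
  an additive −0.71 on their factor, adjacent muscle a ×1.21 multiplier.
  Tumour samples carry a ×1.5 baseline factor (tumours relax more
  slowly), which keeps myxoid-shifted factors positive. Each profile is
  the group curve divided by its factor, after aligning the group
  curve's high-field tail to the reference group's curve — this makes
  the generative factor *identical* to what the scaling stage measures,
  absorbing tail-shape differences between groups into the factor just
  as a reference-relative procedure does. The reference is the first
  muscle sample; its patient's base factor is pinned at 1 so recovered
  factors are expressed on the reference scale.
* The patient-level spread (0.15) is a calibration knob chosen so the
  dispersion of simulated factors resembles the reported uncertainty
  scales at the study's sample counts; it is not an estimate of real
  inter-patient variance. The 8 evolution times per field of the real
  pulse sequence are not simulated — the generator starts at the
  R₁-per-field level.

What passing tests on this generator do **not** show: robustness to
non-Gaussian or frequency-correlated noise, to fat-like power-law
dispersions inside the fitted classes, to within-patient factor
heterogeneity beyond the injected effects, or to mis-assigned group
labels. Real cohort data can violate all of these.

## Cohort statistics

Welch (unequal-variance) two-sided t-tests, matching each effect's
reported scale: the myxoid shift on raw factors (additive), the
proximity effect on log factors (reported multiplicatively), the
peak-amplitude contrast on fitted A (additive). 95 % CIs come from the
Welch degrees of freedom; identical constant arms return effect 0 with
p = 1 as a degenerate null rather than an error. No multiple-testing
correction is applied: three pre-specified hypotheses.

Because adjacent and remote muscle samples share patients, the unpaired
proximity test is conservative under the paired generator design (the
shared patient factor inflates the denominator); its type-I calibration
is therefore studied on an unpaired null layout in which different
patients provide the two arms.

The grouping assistant clusters scaled profiles by average-linkage
hierarchical clustering on the Euclidean distance between log R₁ curves
below 1 MHz. The metric is intentionally scale-sensitive: after
scaling, dispersion groups differ mainly in the *level* of their
low-field dispersion, which a mean-removing correlation metric would
discard (neighbouring groups then become indistinguishable). With no k
given, the silhouette-maximizing cut over k = 2…8 is chosen. Suggestions
never overwrite user labels — grouping remains an expert decision.

## Known limitations

* τ_Q is weakly identified from a single 70-point profile for groups
  with weak quadrupole peaks (large r_HN): the ~150 kHz peak width is
  sampled by only 1–2 grid points, so single-fit τ_Q estimates scatter
  by tens of percent and are right-skewed. Pooled group fits or
  averaging several profiles stabilize it.
* The offset A is called the quadrupole "peak amplitude" in comparative
  summaries; the model defines it as the frequency-independent HH
  offset. The muscle-vs-sarcoma contrast of A is computed on the model
  definition.
* Absolute scaling factors depend on the chosen reference profile and
  are not comparable across studies.
* Temperature dependence, paramagnetic relaxation and fat power-law
  models are out of scope.
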