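"""Synthetic dispersion profiles and cohorts for end-to-end testing.

No public relaxometry dataset accompanies the tissue study this package
analyses, so every pipeline stage is exercised on synthetic data that
emulates the acquisition and the cohort structure:

* a 70-field grid log-spaced between 10 kHz and 10 MHz with denser
  sampling between 0.4 and 3.5 MHz where the quadrupole peaks sit;
* per-point Gaussian noise with σ between 1 % and 4 % of R₁;
* one relaxation-parameter preset per dispersion group (muscle I–III,
  sarcoma A–E) taken from the fitted group parameters of the study —
  the dipolar constants are stated there only as the scale-free ratios
  C_s/C_i and C_s/C_f, so the generator fixes C_s at a documented
  absolute value (1 × 10⁶ s⁻²) and derives C_i, C_f from the ratios;
* patient-level scaling-factor structure with the two reported cohort
  effects injected on the factor scale: the presence of myxoid tumour
  components shifts the tumour factor by −0.71 (additive) and proximity
  to the tumour multiplies the muscle factor by 1.21.

Each emitted profile equals its group curve divided by the sample's true
factor (after aligning the group curve's high-field tail to the cohort
reference curve), so the downstream scaling stage recovers exactly the
injected factors, up to measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io_profiles import DispersionProfile, SampleMetadata
from .relaxation_model import HHParams, QREParams, RelaxationParams, r1_total
from .scaling import DEFAULT_F_MIN

__all__ = [
    "AcquisitionDesign",
    "CohortConfig",
    "CohortSim",
    "GROUP_PRESETS",
    "C_S_DEFAULT",
    "default_field_grid",
    "group_preset",
    "fat_preset",
    "simulate_profile",
    "draw_cohort_factors",
    "simulate_cohort",
]

C_S_DEFAULT = 1.0e6  # s^-2; arbitrary absolute scale of the scale-free presets


@dataclass(frozen=True)
class AcquisitionDesign:
    """Field grid and noise envelope of the emulated acquisition."""

    n_fields: int = 70
    f_lo: float = 1.0e4
    f_hi: float = 1.0e7
    dense_lo: float = 4.0e5
    dense_hi: float = 3.5e6
    n_dense_extra: int = 30
    noise_lo: float = 0.01
    noise_hi: float = 0.04

    def __post_init__(self) -> None:
        if not (self.f_lo < self.dense_lo < self.dense_hi < self.f_hi):
            raise ValueError("need f_lo < dense_lo < dense_hi < f_hi")
        if not 0 <= self.n_dense_extra < self.n_fields:
            raise ValueError("need 0 <= n_dense_extra < n_fields")
        if not 0 <= self.noise_lo <= self.noise_hi:
            raise ValueError("need 0 <= noise_lo <= noise_hi")


# Fitted group parameters: ratios are dimensionless (the printed values are
# x10^-3), times in seconds, a in s^-1, a_q in Hz, angles in degrees, r_hn in Å.
GROUP_PRESETS: dict[str, dict[str, float]] = {
    "I": dict(ratio_i=82.1e-3, ratio_f=9.72e-3, tau_s=5.21e-6, tau_i=530e-9,
              tau_f=38.6e-9, a=3.12, tau_q=1.02e-6, eta=0.42, a_q=3.25e6,
              theta=77.0, phi=53.0, r_hn=3.27),
    "II": dict(ratio_i=214e-3, ratio_f=23.3e-3, tau_s=5.36e-6, tau_i=640e-9,
               tau_f=38.9e-9, a=3.03, tau_q=1.04e-6, eta=0.40, a_q=3.29e6,
               theta=77.0, phi=57.0, r_hn=3.30),
    "III": dict(ratio_i=216e-3, ratio_f=23.4e-3, tau_s=6.03e-6, tau_i=879e-9,
                tau_f=39.8e-9, a=3.03, tau_q=1.07e-6, eta=0.41, a_q=3.30e6,
                theta=74.0, phi=57.0, r_hn=3.26),
    "A": dict(ratio_i=76.6e-3, ratio_f=6.5e-3, tau_s=4.46e-6, tau_i=516e-9,
              tau_f=39.6e-9, a=2.72, tau_q=0.98e-6, eta=0.42, a_q=3.26e6,
              theta=77.0, phi=48.0, r_hn=3.57),
    "B": dict(ratio_i=81.7e-3, ratio_f=9.3e-3, tau_s=4.90e-6, tau_i=524e-9,
              tau_f=41.0e-9, a=2.71, tau_q=1.00e-6, eta=0.40, a_q=3.26e6,
              theta=78.0, phi=53.0, r_hn=3.48),
    "C": dict(ratio_i=179e-3, ratio_f=22.3e-3, tau_s=5.27e-6, tau_i=527e-9,
              tau_f=37.3e-9, a=2.23, tau_q=1.00e-6, eta=0.41, a_q=3.29e6,
              theta=80.0, phi=52.0, r_hn=3.43),
    "D": dict(ratio_i=240e-3, ratio_f=29.8e-3, tau_s=5.35e-6, tau_i=610e-9,
              tau_f=41.2e-9, a=2.18, tau_q=1.03e-6, eta=0.41, a_q=3.29e6,
              theta=78.0, phi=54.0, r_hn=3.26),
    "E": dict(ratio_i=281e-3, ratio_f=35.4e-3, tau_s=5.88e-6, tau_i=899e-9,
              tau_f=41.4e-9, a=2.38, tau_q=1.02e-6, eta=0.40, a_q=3.30e6,
              theta=75.0, phi=53.0, r_hn=3.49),
}

MUSCLE_GROUP_LABELS = ("I", "II", "III")
SARCOMA_GROUP_LABELS = ("A", "B", "C", "D", "E")


def default_field_grid(design: AcquisitionDesign | None = None) -> np.ndarray:
    """The evolution-field grid: base log spacing plus a dense QRE band.

    Exactly ``n_fields`` strictly increasing frequencies:
    ``n_fields − n_dense_extra`` log-spaced over [f_lo, f_hi] plus
    ``n_dense_extra`` log-spaced over the dense band; coincident points
    are nudged apart by one part in 10⁹.
    """
    design = design or AcquisitionDesign()
    base = np.geomspace(design.f_lo, design.f_hi, design.n_fields - design.n_dense_extra)
    if design.n_dense_extra > 0:
        extra = np.geomspace(design.dense_lo, design.dense_hi, design.n_dense_extra)
        grid = np.concatenate([base, extra])
    else:
        grid = base
    grid = np.sort(grid)
    # nudge duplicates (numerically coincident points) to uniqueness
    for i in range(1, len(grid)):
        if grid[i] <= grid[i - 1]:
            grid[i] = grid[i - 1] * (1.0 + 1e-9)
    return grid


def group_preset(label: str, c_s: float = C_S_DEFAULT) -> RelaxationParams:
    """Relaxation parameters of dispersion group ``label`` (I–III, A–E).

    ``c_s`` sets the arbitrary absolute amplitude; C_i and C_f follow
    from the group's printed ratios, so C_s/C_i and C_s/C_f of the
    returned parameters reproduce those ratios exactly.
    """
    if label not in GROUP_PRESETS:
        raise ValueError(
            f"unknown group {label!r}; expected one of {tuple(GROUP_PRESETS)}"
        )
    g = GROUP_PRESETS[label]
    hh = HHParams(
        c_s=c_s,
        c_i=c_s / g["ratio_i"],
        c_f=c_s / g["ratio_f"],
        tau_s=g["tau_s"],
        tau_i=g["tau_i"],
        tau_f=g["tau_f"],
        a=g["a"],
    )
    qre = QREParams(
        a_q=g["a_q"], eta=g["eta"], tau_q=g["tau_q"],
        theta=g["theta"], phi=g["phi"], r_hn=g["r_hn"],
    )
    return RelaxationParams(hh=hh, qre=qre)


def fat_preset() -> RelaxationParams:
    """Synthetic HH-only parameter set standing in for adipose tissue.

    Fat dispersions in reality follow polymer-melt power laws and show no
    quadrupole peaks; this placeholder keeps fat samples flowing through
    the pipeline but does not model triglyceride dynamics.
    """
    hh = HHParams(
        c_s=2.0e5, c_i=2.0e6, c_f=2.0e7,
        tau_s=3.0e-6, tau_i=3.0e-7, tau_f=3.0e-8, a=1.5,
    )
    return RelaxationParams(hh=hh, qre=None)


def simulate_profile(
    params: RelaxationParams,
    design: AcquisitionDesign | None = None,
    noise_rel: float = 0.02,
    seed: int | np.random.Generator = 0,
    sample_id: str = "sim",
    metadata: SampleMetadata | None = None,
    amplitude: float = 1.0,
    grid: np.ndarray | None = None,
) -> DispersionProfile:
    """Simulate one dispersion profile.

    R₁ = amplitude · R₁ᵐᵒᵈᵉˡ(ν) on the acquisition grid plus zero-mean
    Gaussian noise with σ = noise_rel·R₁ pointwise; ``r1_err`` records
    that σ.  Draws that would produce non-positive R₁ are redrawn.
    Deterministic for a given integer seed.
    """
    if not 0 <= noise_rel <= 0.2:
        raise ValueError("noise_rel must be in [0, 0.2]")
    if grid is None:
        grid = default_field_grid(design)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    model = amplitude * np.asarray(r1_total(grid, params), dtype=float)
    sigma = noise_rel * model
    r1 = model + sigma * rng.standard_normal(len(grid))
    for _ in range(100):  # resample the rare draws crossing zero
        bad = r1 <= 0
        if not np.any(bad):
            break
        r1[bad] = model[bad] + sigma[bad] * rng.standard_normal(int(bad.sum()))
    else:
        r1 = np.maximum(r1, 1e-6)
    return DispersionProfile(
        sample_id=sample_id,
        frequencies=grid,
        r1=r1,
        r1_err=sigma,
        metadata=metadata or SampleMetadata(),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Generative description of a synthetic study.

    Per patient the plan draws ``n_tumour`` tumour samples, adjacent and
    remote muscle samples and fat samples.  ``effect_myxoid`` shifts the
    tumour scaling factor additively when the patient's tumour has myxoid
    components; ``effect_proximity`` multiplies the adjacent-muscle
    factor.  ``tumour_factor_mean`` is the baseline tumour factor
    (tumours relax more slowly, hence factors above 1);
    ``scaling_factor_sd`` is the patient-level log-normal spread.  The
    first patient's base factor is pinned at 1 so that factors are
    expressed on the scale of the cohort reference sample.
    """

    n_patients: int = 10
    n_tumour: int = 2
    n_adjacent_muscle: int = 1
    n_muscle: int = 1
    n_fat: int = 1
    sarcoma_probs: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.10, "B": 0.15, "C": 0.30, "D": 0.35, "E": 0.10}
    )
    muscle_probs: Mapping[str, float] = field(
        default_factory=lambda: {"I": 0.10, "II": 0.80, "III": 0.10}
    )
    myxoid_prob: float = 0.4
    effect_myxoid: float = -0.71
    effect_proximity: float = 1.21
    tumour_factor_mean: float = 1.5
    scaling_factor_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_tumour + self.n_adjacent_muscle + self.n_muscle + self.n_fat == 0:
            raise ValueError("degenerate plan: zero samples per patient")
        if self.n_adjacent_muscle + self.n_muscle == 0 and self.n_tumour > 0:
            raise ValueError("cohort needs at least one muscle sample as reference")
        for probs, labels in (
            (self.sarcoma_probs, SARCOMA_GROUP_LABELS),
            (self.muscle_probs, MUSCLE_GROUP_LABELS),
        ):
            if set(probs) != set(labels):
                raise ValueError(f"group probabilities must cover {labels}")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError("group probabilities must sum to 1")
        if not self.effect_proximity > 0:
            raise ValueError("effect_proximity must be > 0")
        if not 0 <= self.myxoid_prob <= 1:
            raise ValueError("myxoid_prob must be in [0, 1]")


@dataclass(frozen=True)
class CohortSim:
    """Profiles plus the generative truth table and the reference id."""

    profiles: list[DispersionProfile]
    truth: pd.DataFrame
    reference_id: str


def draw_cohort_factors(
    config: CohortConfig, rng: int | np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw the sample-level truth table (no profiles).

    Columns: sample_id, patient_code, tissue_class, group_label, myxoid,
    factor, noise_rel.  This is the statistical layer of
    :func:`simulate_cohort`; it is also used directly for fast
    null-calibration studies of the effect tests.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sarcoma_labels = list(SARCOMA_GROUP_LABELS)
    sarcoma_p = [config.sarcoma_probs[g] for g in sarcoma_labels]
    muscle_labels = list(MUSCLE_GROUP_LABELS)
    muscle_p = [config.muscle_probs[g] for g in muscle_labels]
    rows = []
    for ip in range(config.n_patients):
        patient = f"p{ip:02d}"
        base = 1.0 if ip == 0 else float(
            np.exp(rng.normal(0.0, config.scaling_factor_sd))
        )
        sarcoma_group = str(rng.choice(sarcoma_labels, p=sarcoma_p))
        muscle_group = str(rng.choice(muscle_labels, p=muscle_p))
        myxoid = bool(rng.random() < config.myxoid_prob)

        def add(tissue_class: str, idx: int, group: str | None, factor: float,
                is_myxoid: bool = False) -> None:
            rows.append(
                {
                    "sample_id": f"{patient}_{tissue_class}_{idx}",
                    "patient_code": patient,
                    "tissue_class": tissue_class,
                    "group_label": group,
                    "myxoid": is_myxoid,
                    "factor": max(factor, 0.05),
                    "noise_rel": float(rng.uniform(0.01, 0.04)),
                }
            )

        for i in range(config.n_muscle):
            add("muscle", i, muscle_group, base)
        for i in range(config.n_adjacent_muscle):
            add("adjacent_muscle", i, muscle_group, base * config.effect_proximity)
        for i in range(config.n_tumour):
            f = base * config.tumour_factor_mean
            if myxoid:
                f = f + config.effect_myxoid
            add("tumour", i, sarcoma_group, f, is_myxoid=myxoid)
        for i in range(config.n_fat):
            add("fat", i, None, base)
    return pd.DataFrame(rows)


def _noise_override(truth: pd.DataFrame, design: AcquisitionDesign) -> pd.DataFrame:
    # draw_cohort_factors uses the canonical 1-4 % envelope; if the design
    # narrows it, rescale the per-profile draws into the design's band.
    lo, hi = design.noise_lo, design.noise_hi
    if (lo, hi) == (0.01, 0.04):
        return truth
    u = (truth["noise_rel"] - 0.01) / 0.03
    truth = truth.copy()
    truth["noise_rel"] = lo + u * (hi - lo)
    return truth


def simulate_cohort(
    config: CohortConfig, design: AcquisitionDesign | None = None
) -> CohortSim:
    """Simulate a full synthetic cohort of dispersion profiles.

    The cohort reference is the first muscle sample; every profile is the
    group-preset curve, tail-aligned to the reference curve, divided by
    the sample's true factor — so scaling against the reference recovers
    the factor table produced by :func:`draw_cohort_factors`.
    Deterministic given ``config.seed``.
    """
    from .scaling import scale_factor  # local import to avoid cycles

    design = design or AcquisitionDesign()
    rng = np.random.default_rng(config.seed)
    truth = _noise_override(draw_cohort_factors(config, rng), design)
    grid = default_field_grid(design)

    muscle_mask = truth["tissue_class"].isin(["muscle", "adjacent_muscle"])
    if not muscle_mask.any():
        raise ValueError("cohort has no muscle sample to serve as reference")
    ref_row = truth[muscle_mask].iloc[0]
    reference_id = str(ref_row["sample_id"])

    # noise-free unit curves per group, and their high-field alignment
    # factor against the reference group's curve
    curves: dict[str, np.ndarray] = {}
    params_by_group: dict[str, RelaxationParams] = {}
    for g in list(GROUP_PRESETS):
        params_by_group[g] = group_preset(g)
        curves[g] = np.asarray(r1_total(grid, params_by_group[g]), dtype=float)
    params_by_group["fat"] = fat_preset()
    curves["fat"] = np.asarray(r1_total(grid, params_by_group["fat"]), dtype=float)

    ref_group = str(ref_row["group_label"])

    def alignment(group_key: str) -> float:
        if group_key == ref_group:
            return 1.0
        a = DispersionProfile("g", grid, curves[group_key], np.zeros_like(grid))
        b = DispersionProfile("ref", grid, curves[ref_group], np.zeros_like(grid))
        return scale_factor(a, b, DEFAULT_F_MIN).factor

    align = {g: alignment(g) for g in curves}

    profiles: list[DispersionProfile] = []
    for row in truth.itertuples(index=False):
        group_key = row.group_label if row.group_label is not None else "fat"
        if group_key is None or (isinstance(group_key, float) and np.isnan(group_key)):
            group_key = "fat"
        meta = SampleMetadata(
            patient_code=row.patient_code,
            tissue_class=row.tissue_class,
            myxoid=bool(row.myxoid),
            group_label=None if group_key == "fat" else str(group_key),
        )
        profiles.append(
            simulate_profile(
                params_by_group[group_key],
                noise_rel=float(row.noise_rel),
                seed=rng,
                sample_id=str(row.sample_id),
                metadata=meta,
                amplitude=align[group_key] / float(row.factor),
                grid=grid,
            )
        )
    return CohortSim(profiles=profiles, truth=truth, reference_id=reference_id)
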