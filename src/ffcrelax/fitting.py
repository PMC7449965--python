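"""Weighted nonlinear least-squares estimation of relaxation parameters.

A dispersion profile is fit by minimizing the weighted sum of squares
Σ[(R₁ᵒᵇˢ − R₁ᵐᵒᵈᵉˡ(ν))/σ]² over the free parameters of the three-process
¹H–¹H model plus the ¹H–¹⁴N QRE term.  The scale parameters (dipolar
constants and correlation times, spanning ~4 decades) are optimized in
log₁₀ space; the offset A and the distance r_HN stay linear.

By default the weakly identifiable quadrupole-tensor parameters η, a_Q,
Θ and Φ are held fixed at their initial values (they vary little between
tissues) and can be freed through :class:`FitConfig`.  Robustness against
local minima comes from a data-driven heuristic start plus random
multi-starts drawn log-uniformly within the bounds; the lowest-cost
converged start wins, ties broken by the lowest start index.

Weights are 1/σ² with σ = max(r1_err, error_floor·R₁ᵒᵇˢ); the relative
floor (1 % by default) covers points stored with zero error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .io_profiles import DispersionProfile
from .relaxation_model import (
    HHParams,
    QREParams,
    RelaxationParams,
    lorentzian_pair,
    r1_hn,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "FitError",
    "IdentifiabilityError",
    "NonConvergenceError",
    "DEFAULT_BOUNDS",
    "heuristic_init",
    "fit_profile",
    "fit_group",
    "bootstrap_uncertainties",
    "params_to_dict",
    "dict_to_params",
]

HH_NAMES = ("c_s", "c_i", "c_f", "tau_s", "tau_i", "tau_f", "a")
QRE_NAMES = ("tau_q", "r_hn", "a_q", "eta", "theta", "phi")
ALL_NAMES = HH_NAMES + QRE_NAMES

#: Parameters optimized as log₁₀(value); the rest are linear.
LOG_NAMES = frozenset({"c_s", "c_i", "c_f", "tau_s", "tau_i", "tau_f", "tau_q"})

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "c_s": (1e4, 1e8),
    "c_i": (1e5, 1e9),
    "c_f": (1e6, 1e10),
    "tau_s": (1e-7, 1e-4),
    "tau_i": (1e-8, 1e-5),
    "tau_f": (1e-9, 1e-7),
    "a": (0.0, 100.0),
    "tau_q": (1e-7, 1e-5),
    "r_hn": (1.0, 10.0),
    "a_q": (2.0e6, 4.5e6),
    "eta": (0.0, 1.0),
    "theta": (0.0, 180.0),
    "phi": (0.0, 360.0),
}

#: Generic QRE starting values used when no initial guess is supplied
#: (central values across tissue groups).
QRE_INIT = {"tau_q": 1.0e-6, "r_hn": 3.3, "a_q": 3.28e6, "eta": 0.41, "theta": 77.0, "phi": 53.0}


class FitError(RuntimeError):
    """Base class for fitting failures."""


class IdentifiabilityError(FitError):
    """The profile carries no usable dispersion information (constant R₁)."""


class NonConvergenceError(FitError):
    """No start converged; carries the best partial result if any."""

    def __init__(self, message: str, partial: "FitResult | None" = None):
        super().__init__(message)
        self.partial = partial


@dataclass(frozen=True)
class FitConfig:
    """Options of the weighted least-squares fit.

    ``fixed`` names parameters held at their initial values; ``bounds``
    entries override :data:`DEFAULT_BOUNDS`.  ``n_starts`` counts the
    initial guess plus the random restarts.
    """

    n_starts: int = 5
    seed: int = 0
    bounds: Mapping[str, tuple[float, float]] | None = None
    fixed: tuple[str, ...] = ("eta", "a_q", "theta", "phi")
    max_iterations: int = 4000
    tol: float = 1e-10
    error_floor: float = 0.01

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        for name in self.fixed:
            if name not in ALL_NAMES:
                raise ValueError(f"unknown parameter in fixed: {name!r}")

    def resolved_bounds(self) -> dict[str, tuple[float, float]]:
        out = dict(DEFAULT_BOUNDS)
        if self.bounds:
            out.update(self.bounds)
        return out


@dataclass(frozen=True)
class FitResult:
    """Estimated parameters with one-sigma uncertainties and fit quality.

    ``uncertainties`` maps each free parameter name to its one-sigma error
    (natural units, delta-method transformed for log-fitted parameters);
    ``ratios`` reports C_s/C_i and C_s/C_f, the scale-free quantities
    comparable across scaled profiles.
    """

    params: RelaxationParams
    uncertainties: dict[str, float]
    ratios: dict[str, float]
    chi2_reduced: float
    n_points: int
    converged: bool
    start_index: int
    cost: float

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.uncertainties.values()):
            raise ValueError("uncertainties must be >= 0")


def params_to_dict(p: RelaxationParams) -> dict[str, float]:
    """Flatten a parameter object into a name→value mapping."""
    d = {name: getattr(p.hh, name) for name in HH_NAMES}
    if p.qre is not None:
        d.update({name: getattr(p.qre, name) for name in QRE_NAMES})
    return d


def dict_to_params(d: Mapping[str, float], with_qre: bool) -> RelaxationParams:
    """Inverse of :func:`params_to_dict` (validates invariants)."""
    hh = HHParams(**{name: float(d[name]) for name in HH_NAMES})
    qre = QREParams(**{name: float(d[name]) for name in QRE_NAMES}) if with_qre else None
    return RelaxationParams(hh=hh, qre=qre)


def _eval_model(nu: np.ndarray, d: Mapping[str, float], with_qre: bool) -> np.ndarray:
    # Raw evaluation without dataclass validation: intermediate optimizer
    # iterates may transiently violate the tau ordering invariant.
    omega = 2.0 * np.pi * nu
    out = (
        d["c_s"] * lorentzian_pair(omega, d["tau_s"])
        + d["c_i"] * lorentzian_pair(omega, d["tau_i"])
        + d["c_f"] * lorentzian_pair(omega, d["tau_f"])
        + d["a"]
    )
    if with_qre:
        q = QREParams(
            a_q=d["a_q"], eta=d["eta"], tau_q=d["tau_q"],
            theta=d["theta"], phi=d["phi"], r_hn=d["r_hn"],
        )
        out = out + r1_hn(nu, q)
    return out


def heuristic_init(
    freqs: np.ndarray, r1: np.ndarray, with_qre: bool = True
) -> dict[str, float]:
    """Data-driven starting values.

    The offset is pinned just below the high-field plateau, the dispersion
    drop is split between the three processes at canonical tissue
    correlation times (5 µs / 0.6 µs / 40 ns), and the QRE block starts at
    the central tissue values.
    """
    r1 = np.asarray(r1, dtype=float)
    a0 = max(0.8 * float(np.min(r1)), 1e-3)
    drop = max(float(np.max(r1)) - a0, 1e-3)
    tau_s0, tau_i0, tau_f0 = 5.0e-6, 6.0e-7, 4.0e-8
    init = {
        "c_s": 0.5 * drop / (5.0 * tau_s0),
        "c_i": 0.3 * drop / (5.0 * tau_i0),
        "c_f": 0.2 * drop / (5.0 * tau_f0),
        "tau_s": tau_s0,
        "tau_i": tau_i0,
        "tau_f": tau_f0,
        "a": a0,
    }
    if with_qre:
        init.update(QRE_INIT)
    for name, (lo, hi) in DEFAULT_BOUNDS.items():
        if name in init:
            init[name] = float(np.clip(init[name], lo if lo > 0 else 0.0, hi))
    return init


def _to_internal(values: Sequence[float], names: Sequence[str]) -> np.ndarray:
    return np.array(
        [math.log10(v) if n in LOG_NAMES else v for v, n in zip(values, names)]
    )


def _from_internal(x: np.ndarray, names: Sequence[str]) -> list[float]:
    return [10.0**xi if n in LOG_NAMES else float(xi) for xi, n in zip(x, names)]


def _draw_start(
    rng: np.random.Generator,
    names: Sequence[str],
    bounds: Mapping[str, tuple[float, float]],
    r1_max: float,
) -> dict[str, float]:
    draw: dict[str, float] = {}
    for n in names:
        lo, hi = bounds[n]
        if n in LOG_NAMES:
            draw[n] = 10.0 ** rng.uniform(math.log10(lo), math.log10(hi))
        elif n == "a":
            draw[n] = rng.uniform(lo, min(hi, r1_max))
        else:
            draw[n] = rng.uniform(lo, hi)
    # keep the slow > intermediate > fast ordering at the start point
    if "tau_s" in draw and "tau_i" in draw:
        draw["tau_i"] = min(draw["tau_i"], draw["tau_s"] / 3.0)
    if "tau_i" in draw and "tau_f" in draw:
        draw["tau_f"] = min(draw["tau_f"], draw["tau_i"] / 3.0)
    return draw


def _fit_arrays(
    freqs: np.ndarray,
    r1: np.ndarray,
    r1_err: np.ndarray,
    init: Mapping[str, float],
    with_qre: bool,
    config: FitConfig,
) -> FitResult:
    n = len(freqs)
    if np.ptp(r1) <= 1e-10 * np.mean(r1):
        raise IdentifiabilityError("profile is constant in frequency; nothing to fit")

    names = [
        nm
        for nm in (ALL_NAMES if with_qre else HH_NAMES)
        if nm not in config.fixed
    ]
    if n < len(names) + 3:
        raise FitError(
            f"profile has {n} points; need at least {len(names) + 3} "
            f"for {len(names)} free parameters"
        )
    bounds = config.resolved_bounds()
    sigma = np.maximum(r1_err, config.error_floor * r1)
    fixed_values = {nm: float(init[nm]) for nm in init if nm not in names}

    def residuals(x: np.ndarray) -> np.ndarray:
        d = dict(fixed_values)
        d.update(zip(names, _from_internal(x, names)))
        return (r1 - _eval_model(freqs, d, with_qre)) / sigma

    lob = _to_internal([bounds[nm][0] if bounds[nm][0] > 0 or nm not in LOG_NAMES
                        else 1e-300 for nm in names], names)
    hib = _to_internal([bounds[nm][1] for nm in names], names)

    rng = np.random.default_rng(config.seed)
    starts: list[dict[str, float]] = [dict(init)]
    for _ in range(config.n_starts - 1):
        d = dict(init)
        d.update(_draw_start(rng, names, bounds, float(np.max(r1))))
        starts.append(d)

    best = None  # (cost, start_index, scipy result)
    for k, start in enumerate(starts):
        x0 = np.clip(
            _to_internal([max(start[nm], 1e-300) for nm in names], names), lob, hib
        )
        try:
            res = least_squares(
                residuals,
                x0,
                bounds=(lob, hib),
                method="trf",
                x_scale="jac",
                ftol=config.tol,
                xtol=config.tol,
                gtol=1e-14,
                max_nfev=config.max_iterations,
            )
        except Exception:
            continue
        vals = dict(fixed_values)
        vals.update(zip(names, _from_internal(res.x, names)))
        if not vals["tau_s"] > vals["tau_i"] > vals["tau_f"]:
            continue  # unphysical ordering: reject this start
        if best is None or res.cost < best[0] - 1e-12 * max(best[0], 1.0):
            best = (res.cost, k, res, vals)

    if best is None:
        raise NonConvergenceError("no start produced a physically ordered optimum")

    cost, start_index, res, vals = best
    dof = max(n - len(names), 1)
    chi2 = 2.0 * cost
    chi2_red = chi2 / dof

    # covariance from the local quadratic approximation of the cost,
    # rescaled by reduced chi-square to absorb mild sigma misestimation
    jtj = res.jac.T @ res.jac
    cov = np.linalg.pinv(jtj) * chi2_red
    sig_int = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    uncertainties = {}
    for nm, s_i in zip(names, sig_int):
        v = vals[nm]
        uncertainties[nm] = float(math.log(10.0) * v * s_i) if nm in LOG_NAMES else float(s_i)

    params = dict_to_params(vals, with_qre)
    converged = res.status > 0
    if not converged:
        raise NonConvergenceError(
            "best start stopped at the evaluation budget without converging",
            partial=FitResult(
                params=params,
                uncertainties=uncertainties,
                ratios={"c_s/c_i": vals["c_s"] / vals["c_i"], "c_s/c_f": vals["c_s"] / vals["c_f"]},
                chi2_reduced=chi2_red,
                n_points=n,
                converged=False,
                start_index=start_index,
                cost=cost,
            ),
        )
    return FitResult(
        params=params,
        uncertainties=uncertainties,
        ratios={"c_s/c_i": vals["c_s"] / vals["c_i"], "c_s/c_f": vals["c_s"] / vals["c_f"]},
        chi2_reduced=chi2_red,
        n_points=n,
        converged=True,
        start_index=start_index,
        cost=cost,
    )


def _init_mapping(
    init: RelaxationParams | Mapping[str, float] | None,
    freqs: np.ndarray,
    r1: np.ndarray,
    with_qre: bool | None,
) -> tuple[dict[str, float], bool]:
    if init is None:
        wq = True if with_qre is None else with_qre
        return heuristic_init(freqs, r1, with_qre=wq), wq
    if isinstance(init, RelaxationParams):
        return params_to_dict(init), init.qre is not None
    d = dict(init)
    return d, all(nm in d for nm in QRE_NAMES)


def fit_profile(
    profile: DispersionProfile,
    init: RelaxationParams | Mapping[str, float] | None = None,
    config: FitConfig | None = None,
    with_qre: bool | None = None,
) -> FitResult:
    """Fit a single dispersion profile.

    ``init`` seeds the first start and supplies the values of the fixed
    parameters; when omitted, :func:`heuristic_init` is used.  Set
    ``with_qre=False`` to fit an HH-only model (adipose tissue).
    """
    config = config or FitConfig()
    d, wq = _init_mapping(init, profile.frequencies, profile.r1, with_qre)
    return _fit_arrays(profile.frequencies, profile.r1, profile.r1_err, d, wq, config)


def fit_group(
    profiles: Sequence[DispersionProfile],
    init: RelaxationParams | Mapping[str, float] | None = None,
    config: FitConfig | None = None,
    with_qre: bool | None = None,
) -> FitResult:
    """Fit one parameter vector to the pooled points of several profiles.

    Intended for profiles already scaled to a common reference; each point
    keeps its own σ.  A single-profile group is identical to
    :func:`fit_profile`.
    """
    if len(profiles) == 0:
        raise ValueError("empty profile group")
    config = config or FitConfig()
    freqs = np.concatenate([p.frequencies for p in profiles])
    r1 = np.concatenate([p.r1 for p in profiles])
    err = np.concatenate([p.r1_err for p in profiles])
    d, wq = _init_mapping(init, freqs, r1, with_qre)
    return _fit_arrays(freqs, r1, err, d, wq, config)


def bootstrap_uncertainties(
    profile: DispersionProfile,
    result: FitResult,
    config: FitConfig | None = None,
    n_replicates: int = 200,
    seed: int = 0,
) -> dict[str, float]:
    """Residual-resampling bootstrap standard errors of the free parameters.

    Residuals of the fitted curve are resampled with replacement, added
    back to the model curve, and each replicate is refit from the fitted
    optimum (single start).  Returns the per-parameter standard deviation
    across replicates; more robust than the covariance estimate when the
    number of points is small.
    """
    config = config or FitConfig()
    rng = np.random.default_rng(seed)
    with_qre = result.params.qre is not None
    model = _eval_model(profile.frequencies, params_to_dict(result.params), with_qre)
    resid = profile.r1 - model
    refit_cfg = FitConfig(
        n_starts=1,
        seed=config.seed,
        bounds=config.bounds,
        fixed=config.fixed,
        max_iterations=config.max_iterations,
        tol=config.tol,
        error_floor=config.error_floor,
    )
    samples: dict[str, list[float]] = {nm: [] for nm in result.uncertainties}
    for _ in range(n_replicates):
        idx = rng.integers(0, len(resid), size=len(resid))
        r1_star = np.clip(model + resid[idx], 1e-6, None)
        boot_profile = profile.replace(r1=r1_star)
        try:
            fr = fit_profile(boot_profile, init=result.params, config=refit_cfg)
        except FitError:
            continue
        d = params_to_dict(fr.params)
        for nm in samples:
            samples[nm].append(d[nm])
    return {nm: float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")
            for nm, v in samples.items()}
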