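"""Cohort-level comparisons of scaling factors and fitted parameters.

Three pre-specified effects are tested with two-sided Welch (unequal
variance) t-tests, mirroring how each is reported:

* myxoid components vs not, on tumour scaling factors — additive
  difference (reported as −0.71);
* adjacent vs remote muscle, on muscle scaling factors — multiplicative
  ratio, tested on log factors (reported as ×1.21);
* muscle vs sarcoma, on the fitted offset A, the amplitude of the
  quadrupole-peak region baseline — additive difference (reported as
  +0.61).

No multiple-testing correction is applied (three pre-specified
hypotheses).  A hierarchical-clustering assistant suggests dispersion
groups from the low-frequency shape of scaled profiles; manually
assigned labels always remain authoritative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

from .io_profiles import DispersionProfile
from .scaling import resample_log

__all__ = [
    "EffectEstimate",
    "GroupAssignment",
    "welch_test",
    "effect_myxoid",
    "effect_proximity",
    "effect_peak_amplitude",
    "suggest_groups",
]


@dataclass(frozen=True)
class EffectEstimate:
    """A two-group effect with its 95 % CI and Welch-test p-value.

    ``effect`` is a difference of means (``mode='difference'``) or a
    geometric-mean ratio (``mode='log_ratio'``); the CI bounds are on the
    same scale as the effect.
    """

    effect: float
    ci_low: float
    ci_high: float
    ci_halfwidth: float
    p_value: float
    test: str
    mode: str
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each arm needs at least 2 observations")
        if not 0 < self.p_value <= 1:
            raise ValueError("p_value must be in (0, 1]")


def welch_test(x: Sequence[float], y: Sequence[float], mode: str = "difference") -> EffectEstimate:
    """Two-sided Welch t-test of x vs y.

    ``difference`` mode: effect = mean(x) − mean(y).  ``log_ratio`` mode
    (positive data only): the test runs on log values and the effect is
    exp(mean log x − mean log y), i.e. the ratio of geometric means, with
    the CI transformed to the ratio scale.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each arm needs at least 2 observations")
    if mode == "log_ratio":
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("log_ratio mode requires positive values")
        x, y = np.log(x), np.log(y)
    elif mode != "difference":
        raise ValueError(f"unknown mode {mode!r}")
    if np.var(x) == 0 and np.var(y) == 0:
        # degenerate limit: identical constants are a well-defined null
        if np.mean(x) == np.mean(y):
            eff, lo, hi = 0.0, 0.0, 0.0
            if mode == "log_ratio":
                eff, lo, hi = 1.0, 1.0, 1.0
            return EffectEstimate(
                effect=eff, ci_low=lo, ci_high=hi, ci_halfwidth=0.0,
                p_value=1.0, test="welch_t_two_sided", mode=mode,
                n1=len(x), n2=len(y),
            )
        raise ValueError("zero variance in both arms; Welch test undefined")
    res = stats.ttest_ind(x, y, equal_var=False)
    ci = res.confidence_interval(0.95)
    d = float(np.mean(x) - np.mean(y))
    lo, hi = float(ci.low), float(ci.high)
    if mode == "log_ratio":
        d, lo, hi = float(np.exp(d)), float(np.exp(lo)), float(np.exp(hi))
    p = float(res.pvalue)
    return EffectEstimate(
        effect=d,
        ci_low=lo,
        ci_high=hi,
        ci_halfwidth=0.5 * (hi - lo),
        p_value=min(max(p, np.finfo(float).tiny), 1.0),
        test="welch_t_two_sided",
        mode=mode,
        n1=len(x),
        n2=len(y),
    )


def _need_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing column(s) {missing}")


def effect_myxoid(factors: pd.DataFrame) -> EffectEstimate:
    """Myxoid-minus-non-myxoid difference of tumour scaling factors.

    ``factors`` needs columns ``factor`` and ``myxoid`` (boolean); rows
    are filtered to ``tissue_class == 'tumour'`` when that column exists.
    """
    _need_columns(factors, ["factor", "myxoid"], "effect_myxoid")
    if "tissue_class" in factors.columns:
        factors = factors[factors["tissue_class"] == "tumour"]
    myx = factors.loc[factors["myxoid"].astype(bool), "factor"].to_numpy()
    non = factors.loc[~factors["myxoid"].astype(bool), "factor"].to_numpy()
    return welch_test(myx, non, mode="difference")


def effect_proximity(factors: pd.DataFrame) -> EffectEstimate:
    """Adjacent-over-remote geometric-mean ratio of muscle scaling factors.

    ``factors`` needs columns ``factor`` and ``tissue_class`` with values
    ``adjacent_muscle`` and ``muscle``.
    """
    _need_columns(factors, ["factor", "tissue_class"], "effect_proximity")
    adj = factors.loc[factors["tissue_class"] == "adjacent_muscle", "factor"].to_numpy()
    rem = factors.loc[factors["tissue_class"] == "muscle", "factor"].to_numpy()
    return welch_test(adj, rem, mode="log_ratio")


def effect_peak_amplitude(fits: pd.DataFrame) -> EffectEstimate:
    """Muscle-minus-sarcoma difference of the fitted offset A.

    ``fits`` needs columns ``a`` (fitted offset, s⁻¹) and ``tissue_kind``
    with values ``muscle`` and ``sarcoma``.
    """
    _need_columns(fits, ["a", "tissue_kind"], "effect_peak_amplitude")
    mus = fits.loc[fits["tissue_kind"] == "muscle", "a"].to_numpy()
    sar = fits.loc[fits["tissue_kind"] == "sarcoma", "a"].to_numpy()
    return welch_test(mus, sar, mode="difference")


@dataclass(frozen=True)
class GroupAssignment:
    """Suggested dispersion-group labels from hierarchical clustering."""

    labels: dict[str, int]
    k: int
    silhouette: float


def suggest_groups(
    profiles: Sequence[DispersionProfile],
    k: int | None = None,
    f_max: float = 1.0e6,
) -> GroupAssignment:
    """Cluster scaled profiles by low-frequency dispersion.

    Average-linkage hierarchical clustering on the Euclidean distance
    between log R₁ curves restricted to ν < ``f_max`` (the region where
    the dispersion groups separate).  The metric is deliberately
    scale-sensitive: after scaling to a common reference, the groups
    differ mainly in the *level* of the low-field dispersion, which a
    mean-removing shape metric would discard.  With ``k=None`` the cut
    maximizing the mean silhouette over k = 2…min(n−1, 8) is chosen.
    All-identical profiles yield a single cluster.  This is an
    assistant: it never overwrites user-assigned group labels.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to suggest groups")
    # common low-frequency grid: the first profile's points below f_max
    # that every profile covers
    lo = max(p.frequencies[0] for p in profiles)
    hi = min(p.frequencies[-1] for p in profiles)
    base = profiles[0].frequencies
    grid = base[(base < f_max) & (base >= lo) & (base <= hi)]
    if len(grid) < 3:
        raise ValueError("profiles share fewer than 3 points below f_max")
    X = np.vstack([np.log(resample_log(p, grid).r1) for p in profiles])
    ids = [p.sample_id for p in profiles]

    if k == 1:
        return GroupAssignment(labels={i: 0 for i in ids}, k=1, silhouette=float("nan"))

    d = pdist(X, metric="euclidean")
    if np.max(d) < 1e-12:
        return GroupAssignment(labels={i: 0 for i in ids}, k=1, silhouette=float("nan"))
    Z = linkage(d, method="average")
    dm = squareform(d)

    def cut(kk: int) -> np.ndarray:
        return fcluster(Z, t=kk, criterion="maxclust") - 1

    if k is not None:
        labels = cut(k)
        sil = (
            float(silhouette_score(dm, labels, metric="precomputed"))
            if 2 <= len(set(labels)) <= len(ids) - 1
            else float("nan")
        )
        return GroupAssignment(labels=dict(zip(ids, map(int, labels))), k=int(k), silhouette=sil)

    best: tuple[float, int, np.ndarray] | None = None
    for kk in range(2, min(len(ids) - 1, 8) + 1):
        labels = cut(kk)
        if len(set(labels)) < 2:
            continue
        sil = float(silhouette_score(dm, labels, metric="precomputed"))
        if best is None or sil > best[0]:
            best = (sil, kk, labels)
    if best is None:
        return GroupAssignment(labels={i: 0 for i in ids}, k=1, silhouette=float("nan"))
    sil, kk, labels = best
    return GroupAssignment(labels=dict(zip(ids, map(int, labels))), k=int(kk), silhouette=sil)
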