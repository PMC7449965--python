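"""Tests for the cohort effect tests and the grouping assistant."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from ffcrelax.cohort_stats import (
    effect_myxoid,
    effect_peak_amplitude,
    effect_proximity,
    suggest_groups,
    welch_test,
)
from ffcrelax.synthetic_data import (
    CohortConfig,
    GROUP_PRESETS,
    draw_cohort_factors,
    group_preset,
    simulate_profile,
)

MYXOID_COHORT = CohortConfig(
    n_patients=40, n_tumour=1, n_adjacent_muscle=0, n_muscle=1, n_fat=0,
    myxoid_prob=0.5,
)
PROXIMITY_COHORT = CohortConfig(
    n_patients=20, n_tumour=0, n_adjacent_muscle=1, n_muscle=1, n_fat=0,
)


def _replace(cfg: CohortConfig, **kw) -> CohortConfig:
    import dataclasses

    return dataclasses.replace(cfg, **kw)


class TestWelch:
    def test_identical_samples_null(self):
        x = [1.0, 2.0, 3.0, 4.0]
        e = welch_test(x, list(x))
        assert e.effect == 0.0
        assert e.p_value == pytest.approx(1.0)

    def test_strong_separation_tiny_p(self, rng):
        x = rng.normal(1.0, 0.1, 20)
        y = rng.normal(0.0, 0.1, 20)
        e = welch_test(x, y)
        assert e.p_value < 1e-6
        assert e.effect == pytest.approx(1.0, abs=0.15)

    def test_agrees_with_permutation_oracle(self, rng):
        x = rng.normal(0.3, 1.0, 15)
        y = rng.normal(0.0, 1.0, 15)
        e = welch_test(x, y)
        pooled = np.concatenate([x, y])
        obs = abs(np.mean(x) - np.mean(y))
        count = 0
        n_shuffles = 10_000
        for _ in range(n_shuffles):
            rng.shuffle(pooled)
            if abs(np.mean(pooled[:15]) - np.mean(pooled[15:])) >= obs:
                count += 1
        p_perm = (count + 1) / (n_shuffles + 1)
        assert abs(e.p_value - p_perm) < 0.02

    def test_log_ratio_mode_requires_positive(self):
        with pytest.raises(ValueError):
            welch_test([1.0, 2.0], [-1.0, 2.0], mode="log_ratio")

    def test_too_small_arm_rejected(self):
        with pytest.raises(ValueError):
            welch_test([1.0], [1.0, 2.0])


class TestEffects:
    def test_myxoid_injected_effect_recovered(self):
        e = effect_myxoid(draw_cohort_factors(MYXOID_COHORT, 0))
        assert e.ci_low <= -0.71 <= e.ci_high
        assert e.p_value < 0.005

    def test_myxoid_null_effect_small(self):
        cfg = _replace(MYXOID_COHORT, effect_myxoid=0.0)
        e = effect_myxoid(draw_cohort_factors(cfg, 1))
        assert abs(e.effect) < 0.2
        assert e.p_value > 0.05

    def test_myxoid_sign_flip_flips_estimate(self):
        # same seed: base draws identical, so flipping the injected sign
        # mirrors the estimate exactly around the null estimate
        null = effect_myxoid(draw_cohort_factors(_replace(MYXOID_COHORT, effect_myxoid=0.0), 2))
        pos = effect_myxoid(draw_cohort_factors(_replace(MYXOID_COHORT, effect_myxoid=+0.71), 2))
        neg = effect_myxoid(draw_cohort_factors(_replace(MYXOID_COHORT, effect_myxoid=-0.71), 2))
        assert pos.effect - null.effect == pytest.approx(0.71, abs=1e-9)
        assert neg.effect - null.effect == pytest.approx(-0.71, abs=1e-9)

    def test_proximity_injected_ratio_recovered(self):
        e = effect_proximity(draw_cohort_factors(PROXIMITY_COHORT, 0))
        assert e.ci_low <= 1.21 <= e.ci_high

    def test_proximity_null_is_unit_ratio(self):
        cfg = _replace(PROXIMITY_COHORT, effect_proximity=1.0)
        e = effect_proximity(draw_cohort_factors(cfg, 3))
        assert e.effect == pytest.approx(1.0, abs=1e-9)

    def test_proximity_doubling_recovered_within_ci(self):
        cfg = _replace(PROXIMITY_COHORT, effect_proximity=2.0)
        e = effect_proximity(draw_cohort_factors(cfg, 4))
        assert e.ci_low <= 2.0 <= e.ci_high

    def test_peak_amplitude_preset_arithmetic(self):
        rows = [
            {"a": GROUP_PRESETS[g]["a"],
             "tissue_kind": "muscle" if g in ("I", "II", "III") else "sarcoma"}
            for g in GROUP_PRESETS
        ]
        e = effect_peak_amplitude(pd.DataFrame(rows))
        assert e.effect == pytest.approx(0.616, abs=1e-12)

    def test_peak_amplitude_equal_everywhere_is_zero(self):
        df = pd.DataFrame({"a": [2.0] * 6,
                           "tissue_kind": ["muscle"] * 3 + ["sarcoma"] * 3})
        e = effect_peak_amplitude(df)
        assert e.effect == 0.0
        assert e.p_value == 1.0


class TestCalibration:
    def test_type_i_error_of_effect_tests(self):
        # 2000 null cohorts per test; rejection rate at alpha=0.05 must sit
        # in [0.03, 0.07].  The proximity null uses unpaired arms (distinct
        # patients provide adjacent and remote samples) because the Welch
        # test assumes independent groups; in the paired default design the
        # unpaired test is conservative by construction.
        rng = np.random.default_rng(20240918)
        null_m = _replace(MYXOID_COHORT, effect_myxoid=0.0)
        adj_only = CohortConfig(n_patients=20, n_tumour=0, n_adjacent_muscle=1,
                                n_muscle=0, n_fat=0, effect_proximity=1.0)
        rem_only = CohortConfig(n_patients=20, n_tumour=0, n_adjacent_muscle=0,
                                n_muscle=1, n_fat=0)
        rej_m = n_m = rej_p = n_p = 0
        for _ in range(2000):
            t = draw_cohort_factors(null_m, rng)
            try:
                e = effect_myxoid(t)
            except ValueError:
                continue
            n_m += 1
            rej_m += e.p_value < 0.05
        for _ in range(2000):
            t = pd.concat([
                draw_cohort_factors(adj_only, rng),
                draw_cohort_factors(rem_only, rng),
            ])
            e = effect_proximity(t)
            n_p += 1
            rej_p += e.p_value < 0.05
        assert 0.03 <= rej_m / n_m <= 0.07
        assert 0.03 <= rej_p / n_p <= 0.07

    def test_estimator_dispersion_shrinks_with_n(self):
        # consistency: the spread of the recovered myxoid effect shrinks
        # as the arms grow from 10 to 40 patients per arm
        sds = {}
        for n in (10, 20, 40):
            cfg = _replace(MYXOID_COHORT, n_patients=2 * n)
            ests = []
            rng = np.random.default_rng(77)
            for _ in range(300):
                try:
                    ests.append(effect_myxoid(draw_cohort_factors(cfg, rng)).effect)
                except ValueError:
                    continue
            sds[n] = np.std(ests)
        assert sds[40] < sds[20] < sds[10]


class TestSuggestGroups:
    def test_extreme_groups_separate_without_noise(self):
        profs = [
            simulate_profile(group_preset(g), noise_rel=0.0, seed=i,
                             sample_id=f"{g}{i}")
            for g in ("A", "E") for i in range(3)
        ]
        res = suggest_groups(profs, k=2)
        labels = [res.labels[p.sample_id] for p in profs]
        assert len(set(labels[:3])) == 1
        assert len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_five_presets_recovered_at_2pct_noise(self):
        profs, truth = [], []
        for g in ("A", "B", "C", "D", "E"):
            for i in range(3):
                profs.append(simulate_profile(group_preset(g), noise_rel=0.02,
                                              seed=hash((g, i)) % 2**31,
                                              sample_id=f"{g}{i}"))
                truth.append(g)
        res = suggest_groups(profs, k=5)
        labels = [res.labels[p.sample_id] for p in profs]
        assert adjusted_rand_score(truth, labels) > 0.8

    def test_k1_single_label(self):
        profs = [simulate_profile(group_preset("C"), noise_rel=0.02, seed=i,
                                  sample_id=f"c{i}") for i in range(4)]
        res = suggest_groups(profs, k=1)
        assert set(res.labels.values()) == {0}

    def test_identical_profiles_single_cluster_not_error(self):
        p = simulate_profile(group_preset("C"), noise_rel=0.0, seed=0, sample_id="a")
        q = p.replace(sample_id="b")
        r = p.replace(sample_id="c")
        res = suggest_groups([p, q, r])
        assert res.k == 1
        assert set(res.labels.values()) == {0}

    def test_automatic_k_on_well_separated_groups(self):
        profs = [
            simulate_profile(group_preset(g), noise_rel=0.01, seed=i,
                             sample_id=f"{g}{i}")
            for g in ("A", "E") for i in range(4)
        ]
        res = suggest_groups(profs)
        assert res.k == 2
        assert res.silhouette > 0.5
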