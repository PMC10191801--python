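"""Rank correlations of timing and circular diel statistics."""

from itertools import combinations, permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from migtiming import rayleigh_test, spearman_by_group, watson_wheeler_test


def make_events(timings_by_sex_year, stage="MS1"):
    """timings_by_sex_year: {(sex, year): {tag: seasonal_day}}"""
    rows = []
    for (sex, year), d in timings_by_sex_year.items():
        for tag, day in d.items():
            rows.append({"tag_id": tag, "sex": sex, "year": year, "stage": stage,
                         "seasonal_day": day,
                         "diel_angle": 2 * np.pi * (day % 1.0)})
    return pd.DataFrame(rows)


class TestSpearman:
    def test_identical_order_gives_rho_one(self):
        t18 = {f"f{i}": 120.0 + i for i in range(5)}
        t19 = {f"f{i}": 130.0 + 2 * i for i in range(5)}
        ev = make_events({("F", 2018): t18, ("F", 2019): t19})
        res = [r for r in spearman_by_group(ev) if r.sex == "F" and r.stage == "MS1"]
        assert res[0].rho == pytest.approx(1.0)

    def test_reversed_order_gives_rho_minus_one(self):
        t18 = {f"f{i}": 120.0 + i for i in range(4)}
        t19 = {f"f{i}": 130.0 - i for i in range(4)}
        ev = make_events({("F", 2018): t18, ("F", 2019): t19})
        res = [r for r in spearman_by_group(ev) if r.sex == "F" and r.stage == "MS1"]
        assert res[0].rho == pytest.approx(-1.0)

    def test_t_approximation_close_to_exact_permutation_p(self):
        # n=5: compare the reported p against the exhaustive 5! permutation null
        rng = np.random.default_rng(0)
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        r_obs, p_approx = stats.spearmanr(x, y)
        null = []
        for perm in permutations(range(5)):
            null.append(abs(stats.spearmanr(x, y[list(perm)]).statistic))
        p_exact = np.mean(np.asarray(null) >= abs(r_obs) - 1e-12)
        assert abs(p_approx - p_exact) < 0.05

    def test_too_few_pairs_reports_no_p(self):
        ev = make_events({("F", 2018): {"a": 1.0, "b": 2.0},
                          ("F", 2019): {"a": 1.5, "b": 2.5}})
        res = [r for r in spearman_by_group(ev) if r.sex == "F" and r.stage == "MS1"]
        assert res[0].p is None and res[0].n == 2

    def test_only_complete_pairs_used(self):
        t18 = {f"f{i}": 120.0 + i for i in range(6)}
        t19 = {f"f{i}": 130.0 + i for i in range(4)}  # f4, f5 missing in year 2
        ev = make_events({("M", 2018): t18, ("M", 2019): t19})
        res = [r for r in spearman_by_group(ev) if r.sex == "M" and r.stage == "MS1"]
        assert res[0].n == 4

    @settings(deadline=None, max_examples=25)
    @given(st.permutations(list(range(6))))
    def test_invariant_to_monotone_transform(self, order):
        days = 120.0 + np.asarray(order, dtype=float)
        t18 = {f"f{i}": d for i, d in enumerate(days)}
        t19 = {f"f{i}": 125.0 + 0.5 * i for i in range(6)}
        ev_lin = make_events({("F", 2018): t18, ("F", 2019): t19})
        t18_exp = {k: float(np.exp(0.05 * v)) for k, v in t18.items()}
        ev_exp = make_events({("F", 2018): t18_exp, ("F", 2019): t19})
        r1 = spearman_by_group(ev_lin)[0].rho
        r2 = spearman_by_group(ev_exp)[0].rho
        assert r1 == pytest.approx(r2)

    def test_within_season_pairing(self):
        ev = pd.concat([
            make_events({("F", 2019): {f"f{i}": 120.0 + i for i in range(5)}}, "MS1"),
            make_events({("F", 2019): {f"f{i}": 150.0 + i for i in range(5)}}, "MS4"),
        ])
        res = spearman_by_group(ev, pairing="MS1_vs_MS4")
        assert res[0].rho == pytest.approx(1.0) and res[0].n == 5


class TestRayleigh:
    def test_all_angles_equal(self):
        r = rayleigh_test(np.full(10, 1.3))
        assert r.rbar == pytest.approx(1.0)
        assert r.z == pytest.approx(10.0)
        assert r.p < 1e-4

    def test_perfect_symmetry(self):
        r = rayleigh_test(np.array([0, np.pi / 2, np.pi, 3 * np.pi / 2]))
        assert r.rbar == pytest.approx(0.0, abs=1e-12)
        assert r.z == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0, abs=1e-6)

    def test_small_sample_refused(self):
        with pytest.raises(ValueError):
            rayleigh_test(np.array([0.1, 0.2, 0.3]))

    def test_p_decreases_with_concentration(self):
        n = 25
        rng = np.random.default_rng(3)
        ps = []
        for kappa in (0.2, 1.0, 3.0):
            a = rng.vonmises(0.0, kappa, n) % (2 * np.pi)
            ps.append(rayleigh_test(a).p)
        assert ps[0] > ps[1] > ps[2]

    def test_matches_independent_implementation(self):
        # cross-check statistic and p against pingouin's Rayleigh test
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(17)
        for n in (8, 20, 50):
            a = rng.vonmises(1.0, 0.7, n) % (2 * np.pi)
            z_pg, p_pg = pg.circ_rayleigh(a)
            mine = rayleigh_test(a)
            assert mine.z == pytest.approx(z_pg, rel=1e-9)
            assert mine.p == pytest.approx(p_pg, abs=1e-3)


def _ww_oracle(a, b):
    """Independent uniform-scores computation (resultant-length form)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    gamma = 2 * np.pi * ranks / len(pooled)
    w = 0.0
    for sl in (slice(0, len(a)), slice(len(a), None)):
        g = gamma[sl]
        R2 = np.sum(np.cos(g)) ** 2 + np.sum(np.sin(g)) ** 2
        w += R2 / len(g)
    return 2 * w


class TestWatsonWheeler:
    def test_identical_samples_not_significant(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 2 * np.pi, 12)
        res = watson_wheeler_test(a, a)
        assert res.p > 0.5

    def test_opposite_poles_detected(self):
        rng = np.random.default_rng(5)
        a = rng.vonmises(0.0, 8.0, 10) % (2 * np.pi)
        b = rng.vonmises(np.pi, 8.0, 10) % (2 * np.pi)
        assert watson_wheeler_test(a, b).p < 0.01

    def test_exact_permutation_oracle_small_sample(self):
        # n = 6 + 6: the chi-square p must agree with the exhaustive
        # permutation distribution of W to within its coarse resolution
        rng = np.random.default_rng(5)
        a = rng.vonmises(0.0, 2.0, 6) % (2 * np.pi)
        b = rng.vonmises(np.pi, 2.0, 6) % (2 * np.pi)
        obs = watson_wheeler_test(a, b)
        pooled = np.concatenate([a, b])
        idx = set(range(12))
        null = []
        for comb in combinations(range(12), 6):
            ga = pooled[list(comb)]
            gb = pooled[list(idx - set(comb))]
            null.append(watson_wheeler_test(ga, gb).w)
        p_exact = np.mean(np.asarray(null) >= obs.w - 1e-12)
        assert abs(obs.p - p_exact) < 0.05

    @settings(deadline=None, max_examples=20)
    @given(st.floats(min_value=0.0, max_value=2 * np.pi))
    def test_rotation_invariance(self, delta):
        rng = np.random.default_rng(9)
        a = rng.uniform(0, 2 * np.pi, 8)
        b = rng.uniform(0, 2 * np.pi, 9)
        w0 = watson_wheeler_test(a, b).w
        w1 = watson_wheeler_test((a + delta) % (2 * np.pi), (b + delta) % (2 * np.pi)).w
        assert w1 == pytest.approx(w0, abs=1e-9)

    def test_matches_independent_formulation(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            a = rng.uniform(0, 2 * np.pi, rng.integers(5, 15))
            b = rng.uniform(0, 2 * np.pi, rng.integers(5, 15))
            assert watson_wheeler_test(a, b).w == pytest.approx(_ww_oracle(a, b))

    def test_tiny_group_refused(self):
        with pytest.raises(ValueError):
            watson_wheeler_test(np.array([0.1]), np.array([0.2, 0.3]))
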