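"""Comigrant pairing, sharing counts, permutation test, speed comparison."""

import warnings

import numpy as np
import pandas as pd
import pytest

from migtiming import (ComigrantPair, count_shared, downstream_speed_comparison,
                       find_comigrant_pairs, permutation_test, social_test)
from migtiming.social import exhaustive_sharing_distribution


def passages(rows):
    return pd.DataFrame(rows, columns=["tag_id", "sex", "timestamp"]).assign(
        timestamp=lambda d: pd.to_datetime(d.timestamp)
    )


def pair_ids(pairs):
    return {frozenset((p.tag_a, p.tag_b)) for p in pairs}


class TestPairs:
    def test_single_pair_within_an_hour(self):
        p = find_comigrant_pairs(passages([
            ("a", "F", "2019-05-01 00:00"),
            ("b", "F", "2019-05-01 00:30"),
            ("c", "F", "2019-05-01 02:00"),
        ]))
        assert pair_ids(p) == {frozenset(("a", "b"))}

    def test_pairwise_not_transitive(self):
        p = find_comigrant_pairs(passages([
            ("a", "F", "2019-05-01 00:00"),
            ("b", "F", "2019-05-01 00:40"),
            ("c", "F", "2019-05-01 01:20"),
        ]))
        assert pair_ids(p) == {frozenset(("a", "b")), frozenset(("b", "c"))}

    def test_mixed_sex_never_pairs(self):
        p = find_comigrant_pairs(passages([
            ("a", "F", "2019-05-01 00:00"),
            ("b", "M", "2019-05-01 00:10"),
        ]))
        assert p == []

    def test_exact_hour_gap_excluded(self):
        p = find_comigrant_pairs(passages([
            ("a", "F", "2019-05-01 00:00"),
            ("b", "F", "2019-05-01 01:00"),
        ]))
        assert p == []

    def test_chained_mode_links_full_chain(self):
        p = find_comigrant_pairs(passages([
            ("a", "F", "2019-05-01 00:00"),
            ("b", "F", "2019-05-01 00:40"),
            ("c", "F", "2019-05-01 01:20"),
        ]), chained=True)
        assert pair_ids(p) == {frozenset(("a", "b")), frozenset(("b", "c")),
                               frozenset(("a", "c"))}


class TestCountShared:
    def test_hand_counts(self):
        pairs = [ComigrantPair("a", "b", 0.1, "F"), ComigrantPair("c", "d", 0.2, "F"),
                 ComigrantPair("e", "f", 0.3, "F")]
        trib = {"a": "T1", "b": "T1", "c": "T1", "d": "T2", "e": "T3", "f": "T3"}
        assert count_shared(pairs, trib) == 2

    def test_all_same_tributary(self):
        pairs = [ComigrantPair("a", "b", 0.1, "F"), ComigrantPair("b", "c", 0.2, "F")]
        assert count_shared(pairs, dict.fromkeys("abc", "T1")) == 2

    def test_random_toy_configurations_match_enumeration(self):
        rng = np.random.default_rng(31)
        for _ in range(6):
            n = int(rng.integers(4, 8))
            tags = [f"t{i}" for i in range(n)]
            labels = rng.choice(["A", "B", "C"], size=n)
            trib = dict(zip(tags, labels))
            k = int(rng.integers(1, 4))
            pairs = []
            for _ in range(k):
                i, j = rng.choice(n, size=2, replace=False)
                pairs.append(ComigrantPair(tags[i], tags[j], 0.5, "F"))
            expected = sum(trib[p.tag_a] == trib[p.tag_b] for p in pairs)
            assert count_shared(pairs, trib) == expected

    def test_unmapped_tag_refused(self):
        with pytest.raises(KeyError):
            count_shared([ComigrantPair("a", "zz", 0.1, "F")], {"a": "T1"})


class TestPermutation:
    def test_single_tributary_degenerate(self):
        pairs = [ComigrantPair("a", "b", 0.1, "F"), ComigrantPair("b", "c", 0.2, "F")]
        with pytest.warns(UserWarning, match="single tributary"):
            res = permutation_test(pairs, dict.fromkeys("abc", "T1"), list("abc"),
                                   n_iter=99, rng=0)
        assert res.p == 1.0
        assert res.sim_mean == res.n_pairs

    def test_expected_count_matches_exhaustive_enumeration(self):
        # 4 migrants, 2 disjoint pairs, labels {A, A, B, B}: enumerate all
        # 4!/(2!2!) = 6 distinct assignments for the exact E[n_sim]
        migrants = ["a", "b", "c", "d"]
        trib = {"a": "A", "b": "A", "c": "B", "d": "B"}
        pairs = [ComigrantPair("a", "b", 0.1, "F"), ComigrantPair("c", "d", 0.2, "F")]
        dist = exhaustive_sharing_distribution([(0, 1), (2, 3)], ["A", "A", "B", "B"])
        e_exact = sum(k * v for k, v in dist.items())
        res = permutation_test(pairs, trib, migrants, n_iter=100_000, rng=1)
        assert res.sim_mean == pytest.approx(e_exact, abs=0.02)

    def test_distribution_matches_enumeration_small_instance(self):
        rng = np.random.default_rng(7)
        labels = ["A", "A", "A", "B", "B", "C"]
        migrants = [f"m{i}" for i in range(6)]
        trib = dict(zip(migrants, labels))
        idx_pairs = [(0, 3), (1, 2), (4, 5)]
        pairs = [ComigrantPair(migrants[i], migrants[j], 0.1, "F") for i, j in idx_pairs]
        exact = exhaustive_sharing_distribution(idx_pairs, labels)
        n_iter = 100_000
        counts = np.zeros(len(pairs) + 1)
        lab = np.array(labels)
        ia = np.array([i for i, _ in idx_pairs])
        ib = np.array([j for _, j in idx_pairs])
        for _ in range(n_iter):
            perm = lab[rng.permutation(6)]
            counts[int(np.sum(perm[ia] == perm[ib]))] += 1
        empirical = {k: c / n_iter for k, c in enumerate(counts) if c}
        assert set(empirical) == set(exact)
        for k, v in exact.items():
            assert empirical[k] == pytest.approx(v, abs=0.01)

    def test_invariant_to_tributary_relabeling(self):
        migrants = list("abcdef")
        trib = {"a": "T1", "b": "T1", "c": "T2", "d": "T2", "e": "T3", "f": "T3"}
        relab = {k: {"T1": "X", "T2": "Y", "T3": "Z"}[v] for k, v in trib.items()}
        pairs = [ComigrantPair("a", "b", 0.1, "F"), ComigrantPair("c", "e", 0.2, "F")]
        r1 = permutation_test(pairs, trib, migrants, n_iter=999, rng=5)
        r2 = permutation_test(pairs, relab, migrants, n_iter=999, rng=5)
        assert r1.p == r2.p and r1.n_obs == r2.n_obs

    def test_invalid_iterations_refused(self):
        with pytest.raises(ValueError):
            permutation_test([], {"a": "T1"}, ["a"], n_iter=0)


class TestEndToEnd:
    def test_attraction_detected(self):
        from migtiming import SimConfig, SiteRegistry, derive_stage_events, simulate

        cfg = SimConfig(seed=4, social_alpha=2.0, fidelity_prob=0.0)
        sim = simulate(cfg)
        reg = SiteRegistry.default(cfg.mouth_to_gate_km, cfg.tributary_km)
        ev = derive_stage_events(sim.detections, reg)
        ev = ev.merge(sim.individuals[["tag_id", "sex"]], on="tag_id")
        res = social_test(ev, sim.individuals, stage="MS1", sex="F", n_iter=999, rng=9)
        assert res.n_pairs >= 30
        assert res.n_obs > res.sim_mean
        assert res.p < 0.05

    def test_rejects_non_gate_stage(self, default_events, default_sim):
        with pytest.raises(ValueError):
            social_test(default_events, default_sim.individuals, stage="MS2")


class TestSpeedComparison:
    def test_identical_groups(self):
        t, p = downstream_speed_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_welch_closed_form(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        t, p = downstream_speed_comparison(a, b)
        se = np.sqrt(a.var(ddof=1) / 3 + b.var(ddof=1) / 3)
        assert t == pytest.approx((a.mean() - b.mean()) / se)

    def test_label_swap_flips_sign(self):
        a, b = [1.0, 2.5, 3.5], [2.0, 4.0, 6.0]
        t1, p1 = downstream_speed_comparison(a, b)
        t2, p2 = downstream_speed_comparison(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_tiny_groups_refused(self):
        with pytest.raises(ValueError):
            downstream_speed_comparison([1.0], [2.0, 3.0])
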