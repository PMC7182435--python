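"""Developmental-variation statistic: distances, pairing, Wilcoxon, LOESS."""

import itertools

import numpy as np
import pandas as pd
import pytest

from molardev.devstate import DEFAULT_SCHEMA, DevState, enumerate_state_space
from molardev.devvar import (
    compare_strain_variability,
    loess_fit,
    neighbor_pairs,
    state_distance,
    temporal_profile,
)


class TestStateDistance:
    def test_identity(self):
        z = DevState((0, 0, 0, 0))
        assert state_distance(z, z) == 0

    def test_forced_by_definition(self):
        assert state_distance(DevState((1, 0, 0, 0)), DevState((0, 2, 1, 0))) == 4

    def test_max_distance_over_full_state_space(self):
        states = enumerate_state_space(DEFAULT_SCHEMA)
        dmax = max(
            state_distance(a, b) for a, b in itertools.combinations(states, 2)
        )
        assert dmax == 7
        assert dmax == state_distance(DevState((0, 0, 0, 0)), DevState((2, 2, 2, 1)))

    def test_metric_axioms_exhaustively(self):
        states = enumerate_state_space(DEFAULT_SCHEMA)
        arr = np.array([s.scores for s in states])
        D = np.abs(arr[:, None, :] - arr[None, :, :]).sum(axis=2)
        assert (D >= 0).all()
        assert (np.diag(D) == 0).all()
        assert ((D == 0) == np.eye(len(states), dtype=bool)).all()
        assert (D == D.T).all()
        # triangle inequality over all 54^3 triples
        assert (D[:, None, :] <= D[:, :, None] + D[None, :, :]).all()

    def test_schema_mismatch_rejected(self):
        with pytest.raises(ValueError):
            state_distance(DevState((0, 0)), DevState((0, 0, 0, 0)))


def _embryos(ids, ages, scores, strain="S"):
    rows = []
    for i, a, s in zip(ids, ages, scores):
        rows.append(dict(embryo_id=i, strain=strain, cdpc=a,
                         **dict(zip(DEFAULT_SCHEMA.columns, s))))
    return pd.DataFrame(rows)


class TestNeighborPairs:
    def test_boundary_is_strict(self):
        t = _embryos(["a", "b"], [14.0, 14.25], [(0, 0, 0, 0)] * 2)
        assert neighbor_pairs(t, window=0.25) == []
        t2 = _embryos(["a", "b"], [14.0, 14.2499], [(0, 0, 0, 0)] * 2)
        assert len(neighbor_pairs(t2, window=0.25)) == 1

    def test_identical_ages_form_complete_graph(self):
        n = 7
        t = _embryos([f"e{i}" for i in range(n)], [14.0] * n, [(0, 0, 0, 0)] * n)
        assert len(neighbor_pairs(t)) == n * (n - 1) // 2

    def test_matches_brute_force_double_loop(self):
        ages = [13.9, 14.0, 14.1, 14.3, 14.35]
        scores = [(0, 0, 0, 0), (1, 0, 0, 0), (1, 1, 0, 0), (2, 1, 1, 0), (2, 2, 1, 1)]
        t = _embryos(list("abcde"), ages, scores)
        pairs = {(p.embryo_a, p.embryo_b): p for p in neighbor_pairs(t, window=0.25)}
        expected = {}
        for i in range(5):
            for j in range(i + 1, 5):
                if abs(ages[i] - ages[j]) < 0.25:
                    d = sum(abs(x - y) for x, y in zip(scores[i], scores[j]))
                    expected[tuple(sorted(("abcde"[i], "abcde"[j])))] = d
        assert {tuple(sorted(k)): v.distance for k, v in pairs.items()} == expected

    def test_pairs_stay_within_strain(self):
        t = pd.concat([
            _embryos(["a1", "a2"], [14.0, 14.1], [(0, 0, 0, 0)] * 2, strain="A"),
            _embryos(["b1"], [14.05], [(1, 0, 0, 0)], strain="B"),
        ], ignore_index=True)
        pairs = neighbor_pairs(t)
        assert {(p.embryo_a, p.embryo_b) for p in pairs} == {("a1", "a2")}

    def test_invalid_window_rejected(self):
        t = _embryos(["a", "b"], [14.0, 14.1], [(0, 0, 0, 0)] * 2)
        with pytest.raises(ValueError):
            neighbor_pairs(t, window=0.0)


class TestWilcoxon:
    def test_exact_small_sample_enumeration(self):
        # {3,3,3} vs {0,0,0}: the most extreme of C(6,3)=20 assignments,
        # two-sided exact p = 2/20
        rep = compare_strain_variability(np.array([3.0, 3, 3]), np.array([0.0, 0, 0]))
        assert rep["method"] == "exact"
        assert rep["p_value"] == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        rep = compare_strain_variability(np.array([0.0, 1, 2]), np.array([0.0, 1, 2]))
        assert rep["p_value"] == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 7, 60).astype(float)
        b = rng.integers(0, 5, 80).astype(float)
        p1 = compare_strain_variability(a, b)["p_value"]
        p2 = compare_strain_variability(a**2 + 1, b**2 + 1)["p_value"]
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_strain_variability(np.array([1.0]), np.array([]))

    def test_null_calibration_in_weak_dependence_regime(self):
        """Identical generating parameters for the two strains: the median
        two-sided p over 200 replicates sits in the central band.

        Single-embryo litters and known ages are used so overlapping pairs are
        only weakly dependent; in clustered designs the pair-level rank-sum
        test is anti-conservative (a documented caveat of the method).
        """
        from molardev.synthetic import DEFAULT_TIMINGS, default_config, generate_cohort

        def null_p(seed):
            cfg = default_config(
                seed=seed, n_litters_per_strain=24, litter_size_range=(1, 1),
                timing_jitter_sd={"FVB": 0.12, "DUHi": 0.12},
                character_timing={"FVB": DEFAULT_TIMINGS["FVB"],
                                  "DUHi": DEFAULT_TIMINGS["FVB"]},
            )
            emb, lat = generate_cohort(cfg)
            emb = emb.merge(lat.embryos[["embryo_id", "true_age"]], on="embryo_id")
            emb["cdpc"] = emb["true_age"]
            pa = neighbor_pairs(emb[emb["strain"] == "DUHi"])
            pb = neighbor_pairs(emb[emb["strain"] == "FVB"])
            return compare_strain_variability(pa, pb)["p_value"]

        ps = np.array([null_p(s) for s in range(1, 201)])
        assert 0.3 <= np.median(ps) <= 0.7


class TestLoess:
    def test_reproduces_constants(self):
        x = np.linspace(0, 10, 25)
        y = np.full(25, 3.7)
        np.testing.assert_allclose(loess_fit(x, y), y, atol=1e-12)

    def test_reproduces_lines_exactly_with_degree_one(self):
        x = np.linspace(0, 10, 30)
        y = 2.5 * x - 1.0
        for span in (0.3, 0.75, 1.0):
            np.testing.assert_allclose(loess_fit(x, y, span=span), y, atol=1e-10)

    def test_matches_per_point_weighted_least_squares_oracle(self):
        rng = np.random.default_rng(7)
        x = np.sort(rng.uniform(0, 5, 20))
        y = np.sin(x) + rng.normal(0, 0.2, 20)
        span = 0.75
        k = int(np.ceil(span * len(x)))
        fitted = loess_fit(x, y, span=span)
        for i, x0 in enumerate(x):
            d = np.abs(x - x0)
            h = np.sort(d)[k - 1]
            w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
            X = np.column_stack([np.ones_like(x), x - x0])
            A = X.T @ (w[:, None] * X)
            b = X.T @ (w * y)
            beta = np.linalg.solve(A, b)
            assert fitted[i] == pytest.approx(beta[0], abs=1e-10)

    def test_agrees_with_statsmodels_lowess(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        x = np.sort(rng.uniform(0, 8, 40))
        y = np.cos(x) + rng.normal(0, 0.1, 40)
        ours = loess_fit(x, y, span=0.5)
        ref = sm.nonparametric.lowess(y, x, frac=0.5, it=0, return_sorted=False)
        np.testing.assert_allclose(ours, ref, atol=0.05)

    def test_identical_x_rejected(self):
        with pytest.raises(ValueError):
            loess_fit(np.ones(5), np.arange(5.0))


class TestTemporalProfile:
    def test_zero_variation_cohort_gives_flat_zero(self):
        n = 12
        t = _embryos([f"e{i}" for i in range(n)],
                     np.linspace(14.0, 14.5, n), [(1, 1, 0, 0)] * n)
        profile = temporal_profile(t)
        np.testing.assert_allclose(profile.per_embryo["mean_distance"], 0.0)
        np.testing.assert_allclose(profile.curve["fitted"], 0.0, atol=1e-12)

    def test_duplication_changes_only_neighbour_count_bookkeeping(self):
        """Doubling every embryo: each mean distance becomes 2S/(2k+1) (the
        duplicate contributes one zero-distance pair); verified against a
        brute-force recomputation, and the smoothed curve equals the LOESS
        of those recomputed means."""
        rng = np.random.default_rng(5)
        n = 15
        ages = np.sort(rng.uniform(14.0, 15.0, n))
        scores = [tuple(rng.integers(0, 2, 4)) for _ in range(n)]
        t = _embryos([f"e{i}" for i in range(n)], ages, scores)
        doubled = pd.concat(
            [t, t.assign(embryo_id=t["embryo_id"] + "_dup")], ignore_index=True
        )
        p1 = temporal_profile(t)
        p2 = temporal_profile(doubled)
        # oracle: per-embryo sums/counts from an O(n^2) scan of the originals
        sums = dict.fromkeys(t["embryo_id"], 0.0)
        counts = dict.fromkeys(t["embryo_id"], 0)
        for i in range(n):
            for j in range(i + 1, n):
                if abs(ages[i] - ages[j]) < 0.25:
                    d = sum(abs(a - b) for a, b in zip(scores[i], scores[j]))
                    for e in (f"e{i}", f"e{j}"):
                        sums[e] += d
                        counts[e] += 1
        expected = {
            e: 2 * sums[e] / (2 * counts[e] + 1) for e in sums
        }
        got = p2.per_embryo.set_index(
            p2.per_embryo["embryo_id"].str.removesuffix("_dup")
        )["mean_distance"]
        for e, v in expected.items():
            np.testing.assert_allclose(got.loc[e], v, atol=1e-12)
        # curve is exactly the LOESS of the per-embryo means
        xs = p2.per_embryo["cdpc"].to_numpy()
        ys = p2.per_embryo["mean_distance"].to_numpy()
        refit = loess_fit(xs, ys, span=0.75, x_eval=p2.curve["cdpc"].to_numpy())
        np.testing.assert_allclose(p2.curve["fitted"], refit, atol=1e-12)
        # and the original (unduplicated) means follow S/k
        for e in sums:
            if counts[e]:
                np.testing.assert_allclose(
                    p1.per_embryo.set_index("embryo_id")["mean_distance"].loc[e],
                    sums[e] / counts[e], atol=1e-12,
                )

    def test_no_neighbours_is_an_error(self):
        t = _embryos(["a", "b"], [13.0, 15.0], [(0, 0, 0, 0)] * 2)
        with pytest.raises(ValueError, match="neighbour"):
            temporal_profile(t)
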