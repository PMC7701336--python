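"""Pearson/MIC dependence measures and the feature-screening stage."""

from itertools import combinations, islice

import numpy as np
import pandas as pd
import pytest

from cardioclust.mic import MICInputError, mic, mic_approx, mic_exact
from cardioclust.screening import (
    ConstantFeatureError,
    pearson_r,
    screen_features,
)


# ---------------------------------------------------------------------------
# independent brute-force MIC oracle: enumerate ALL admissible grids
# ---------------------------------------------------------------------------


def _partition_assignment(n, cuts):
    rows = np.zeros(n, dtype=int)
    for r, c in enumerate(cuts):
        rows[c + 1 :] = r + 1
    return rows


def _value_boundaries(sorted_vals):
    return np.nonzero(np.diff(sorted_vals) != 0)[0]


def _best_mi_over_v_partitions(u_bins, n_u_bins, v_order, v_boundaries, n_v_bins):
    """Max MI over ALL contiguous partitions of v into ``n_v_bins`` bins,
    for a fixed assignment of points to ``n_u_bins`` u-bins (vectorized)."""
    n = len(u_bins)
    if len(v_boundaries) < n_v_bins - 1:
        return -np.inf
    # prefix counts of u-bins along the v-sorted order
    P = np.zeros((n + 1, n_u_bins))
    P[np.arange(1, n + 1), u_bins[v_order]] = 1.0
    P = np.cumsum(P, axis=0)
    best = -np.inf
    combos_iter = combinations(v_boundaries, n_v_bins - 1)
    while True:
        block = list(islice(combos_iter, 60_000))
        if not block:
            break
        cuts = np.asarray(block, dtype=int)
        bounds = np.concatenate(
            [
                np.zeros((len(cuts), 1), int),
                cuts + 1,
                np.full((len(cuts), 1), n),
            ],
            axis=1,
        )
        cnt = np.diff(P[bounds], axis=1)  # (C, n_v_bins, n_u_bins)
        p = cnt / n
        pv = p.sum(axis=2, keepdims=True)
        pu = p.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = p * np.log2(p / (pv * pu))
        mi = np.nansum(terms, axis=(1, 2))
        best = max(best, float(mi.max()))
    return best


def mic_bruteforce(x, y, alpha=0.6):
    """Exhaustive MIC oracle: every grid shape, every pair of contiguous
    partitions (cuts only between distinct values)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    b = int(np.floor(n**alpha))
    best = 0.0
    for u, v in ((x, y), (y, x)):
        ou = np.argsort(u, kind="mergesort")
        ov = np.argsort(v, kind="mergesort")
        bu = _value_boundaries(u[ou])
        bv = _value_boundaries(v[ov])
        a = 2
        while a * a <= b:
            for nb in range(a, b // a + 1):
                if len(bu) < a - 1:
                    continue
                u_bins = np.empty(n, int)
                for ucuts in combinations(bu, a - 1):
                    u_bins[ou] = _partition_assignment(n, ucuts)
                    mi = _best_mi_over_v_partitions(u_bins, a, ov, bv, nb)
                    val = mi / np.log2(min(a, nb))
                    if val > best:
                        best = val
            a += 1
    return best


class TestPearson:
    def test_identity_and_affine(self, rng):
        x = rng.normal(size=50)
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -2 * x + 3) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # x=(1,2,3,4), y=(1,3,2,4): cov=1.0, sd_x=sd_y=sqrt(1.25) -> r=0.8
        assert pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_input_raises(self):
        with pytest.raises(ConstantFeatureError):
            pearson_r([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestMIC:
    def test_constant_y_is_zero(self, rng):
        x = rng.uniform(size=40)
        assert mic(x, np.ones(40)) == 0.0

    def test_too_small_n_raises(self):
        with pytest.raises(MICInputError):
            mic(np.arange(8.0), np.arange(8.0))

    def test_noiseless_functional_relationship_near_one(self, rng):
        x = rng.uniform(size=200)
        assert mic_approx(x, 3 * x - 1) >= 0.99
        assert mic_approx(x, (x - 0.5) ** 2) >= 0.99

    @pytest.mark.parametrize("n", [12, 20, 30, 40, 50])
    @pytest.mark.parametrize("kind", ["linear", "quadratic", "noise"])
    def test_exact_mode_matches_bruteforce_oracle(self, n, kind, rng):
        x = rng.uniform(size=n)
        if kind == "linear":
            y = 2 * x + 0.2 * rng.normal(size=n)
        elif kind == "quadratic":
            y = (x - 0.5) ** 2 + 0.1 * rng.normal(size=n)
        else:
            y = rng.uniform(size=n)
        got = mic_exact(x, y)
        want = mic_bruteforce(x, y)
        assert got == pytest.approx(want, abs=1e-9)

    def test_exact_dominates_heuristic(self, rng):
        # the heuristic searches a subset of grids, so it can never exceed
        # the exact optimum
        for _ in range(5):
            x = rng.uniform(size=45)
            y = x + 0.5 * rng.normal(size=45)
            assert mic_approx(x, y) <= mic_exact(x, y) + 1e-9

    def test_monotone_transformation_invariance(self, rng):
        x = rng.uniform(size=120)
        y = x + 0.3 * rng.normal(size=120)
        base = mic_approx(x, y)
        assert mic_approx(np.exp(x), y) == pytest.approx(base, abs=1e-12)
        ranks = np.argsort(np.argsort(y)).astype(float)
        assert mic_approx(x, ranks) == pytest.approx(base, abs=1e-12)

    def test_independent_null_level(self):
        # frozen regression level from this implementation's own null run:
        # mean MIC of independent uniforms at n=1000 sits near 0.135
        vals = []
        for seed in range(20):
            r = np.random.default_rng(1000 + seed)
            vals.append(mic_approx(r.uniform(size=1000), r.uniform(size=1000)))
        m = float(np.mean(vals))
        assert m < 0.25
        assert m == pytest.approx(0.135, abs=0.04)


class TestScreening:
    def test_default_cohort_flags_only_the_definitional_pair(self, screening_report):
        rep = screening_report
        assert len(rep.flagged_pairs) == 1
        a, b, r, m, trig = rep.flagged_pairs[0]
        assert {a, b} == {"V_LV_ES", "EF_LV"}
        assert abs(r) > 0.7
        assert rep.dropped == ["EF_LV"]
        assert len(rep.selected) == 8
        assert "EF_LV" not in rep.selected

    def test_definitional_pair_has_largest_abs_r(self, screening_report):
        pt = screening_report.pair_table()
        top = pt.loc[pt["abs_r"].idxmax()]
        assert {top["feature_a"], top["feature_b"]} == {"V_LV_ES", "EF_LV"}

    def test_matrix_invariants(self, screening_report):
        rep = screening_report
        np.testing.assert_allclose(np.diag(rep.pearson_matrix), 1.0)
        np.testing.assert_allclose(rep.pearson_matrix, rep.pearson_matrix.T)
        np.testing.assert_allclose(rep.mic_matrix, rep.mic_matrix.T)
        assert sorted(rep.selected + rep.dropped) == sorted(rep.feature_names)

    def test_independent_noise_nothing_flagged(self, rng):
        df = pd.DataFrame(
            rng.normal(size=(300, 5)), columns=[f"f{i}" for i in range(5)]
        )
        rep = screen_features(df, drop_preference=None)
        assert rep.flagged_pairs == []
        assert rep.selected == list(df.columns)

    def test_duplicated_column_dropped(self, rng):
        df = pd.DataFrame(
            rng.normal(size=(200, 3)), columns=["a", "b", "c"]
        )
        df["d"] = df["a"]
        rep = screen_features(df, drop_preference=None)
        assert any({p[0], p[1]} == {"a", "d"} for p in rep.flagged_pairs)
        assert len(rep.dropped) == 1
        assert rep.dropped[0] in {"a", "d"}

    def test_row_permutation_invariance(self, features, screening_report):
        sub = features.head(400)
        rep1 = screen_features(sub)
        perm = sub.sample(frac=1.0, random_state=5)
        rep2 = screen_features(perm)
        np.testing.assert_allclose(rep1.pearson_matrix, rep2.pearson_matrix, atol=1e-12)
        np.testing.assert_allclose(rep1.mic_matrix, rep2.mic_matrix, atol=1e-12)
        assert rep1.selected == rep2.selected

    def test_threshold_validation(self, features):
        with pytest.raises(Exception):
            screen_features(features, r_threshold=1.5)
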