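from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest

from sarcomap import (UndefinedTestError, build_table3, caix_stratification,
                      compare_visits, mann_whitney_u, pearson_p_from_r,
                      pearson_t, wilcoxon_signed_rank)
from sarcomap.stats import validate_cohort


# ---------------------------------------------------------------------------
# independent enumeration oracles

def exact_wilcoxon_p(diffs):
    """Two-sided signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    mid = ranks.sum() / 2.0
    dev_obs = abs(w_obs - mid)
    count = 0
    for signs in product((0, 1), repeat=n):
        w = ranks[np.asarray(signs, bool)].sum()
        if abs(w - mid) >= dev_obs - 1e-12:
            count += 1
    return count / 2.0 ** n


def exact_mwu_p(a, b):
    """Two-sided U-test p by enumerating all group assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    na = len(a)

    def u_of(idx):
        grp = pooled[list(idx)]
        rest = np.delete(pooled, list(idx))
        return np.sum(grp[:, None] > rest[None, :]) + 0.5 * np.sum(
            grp[:, None] == rest[None, :])

    u_obs = u_of(range(na))
    mid = na * len(b) / 2.0
    dev_obs = abs(u_obs - mid)
    hits = total = 0
    for idx in combinations(range(len(pooled)), na):
        total += 1
        if abs(u_of(idx) - mid) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


class TestWilcoxon:
    def test_all_zero_differences_undefined(self):
        a = np.arange(5.0)
        with pytest.raises(UndefinedTestError):
            wilcoxon_signed_rank(a, a)

    def test_five_positive_differences_exact(self):
        res = wilcoxon_signed_rank(np.zeros(5), np.array([1., 2., 3., 4., 5.]))
        assert res.statistic == 15.0  # W+ = sum of all ranks
        assert res.p_value == pytest.approx(2 / 32)
        assert res.method == "exact"

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_at_n8(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=8)
        b = a + rng.normal(size=8)
        res = wilcoxon_signed_rank(a, b)
        assert res.p_value == pytest.approx(exact_wilcoxon_p(b - a), abs=1e-12)

    def test_zero_differences_dropped_and_counted(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([1.0, 2.0, 5.0, 1.0])
        res = wilcoxon_signed_rank(a, b)
        assert res.n == 2


class TestMannWhitney:
    def test_identical_groups_midrank_u(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 4.5  # n_a * n_b / 2 under midranks

    def test_complete_separation_exact(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2 / C(6,3)
        assert res.method == "exact"

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_at_4v5(self, seed):
        rng = np.random.default_rng(100 + seed)
        a, b = rng.normal(size=4), rng.normal(0.5, 1.0, size=5)
        res = mann_whitney_u(a, b)
        assert res.p_value == pytest.approx(exact_mwu_p(a, b), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestPearson:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        res = pearson_t(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_and_affine_invariance(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        r_xy = pearson_t(x, y).r
        assert pearson_t(y, x).r == pytest.approx(r_xy, abs=1e-12)
        assert pearson_t(3 * x - 7, 0.5 * y + 2).r == pytest.approx(r_xy, abs=1e-12)

    def test_t_distribution_p_at_study_sample_size(self):
        # t = r sqrt((n-2)/(1-r^2)) on 10 df
        assert pearson_p_from_r(-0.64, 12) == pytest.approx(0.025, abs=5e-4)
        assert pearson_p_from_r(-0.66, 12) == pytest.approx(0.0195, abs=5e-4)

    def test_constant_input_undefined(self):
        with pytest.raises(UndefinedTestError):
            pearson_t(np.ones(5), np.arange(5.0))

    def test_missing_pairs_dropped(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, np.nan])
        y = np.array([2.0, 4.0, 6.0, 8.0, 1.0])
        assert pearson_t(x, y).n == 4


# ---------------------------------------------------------------------------
# cohort-level reports

def make_cohort(n=12, seed=0, missing3=()):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        pid = f"P{i:02d}"
        hist = dict(cd31_score=rng.normal(20, 5), ki67_score=rng.normal(30, 8),
                    hif_score=rng.normal(15, 4), hypoxia_score=rng.normal(0, 1.5),
                    caix_positive=bool(i % 2))
        for visit in (1, 2, 3):
            miss = visit == 3 and pid in missing3
            rows.append({
                "patient": pid, "visit": visit,
                "t1_median": np.nan if miss else rng.normal(1100, 150),
                "adc_median": np.nan if miss else rng.normal(1400, 200),
                "iauc60_median": np.nan if miss else rng.normal(10, 3),
                "volume_cm3": np.nan if miss else rng.lognormal(3.3, 0.4),
                **hist,
            })
    return pd.DataFrame(rows)


class TestBuildTable3:
    def test_affine_imaging_histology_relation_gives_unit_r(self):
        cohort = make_cohort()
        v1 = cohort["visit"] == 1
        cohort.loc[v1, "iauc60_median"] = \
            -2.0 * cohort.loc[v1, "hypoxia_score"] + 5.0
        t3 = build_table3(cohort)
        cell = t3[(t3.visit == 1) & (t3.histology == "hypoxia_score")
                  & (t3.imaging == "iauc60_median")].iloc[0]
        assert cell.r == pytest.approx(-1.0)

    def test_row_order_invariance(self):
        cohort = make_cohort(seed=5)
        shuffled = cohort.sample(frac=1.0, random_state=11).reset_index(drop=True)
        pd.testing.assert_frame_equal(build_table3(cohort), build_table3(shuffled))

    def test_grid_shape_and_insufficient_pairs(self):
        cohort = make_cohort(missing3=[f"P{i:02d}" for i in range(10)])
        t3 = build_table3(cohort)
        assert len(t3) == 3 * 4 * 4  # visits x histology x imaging
        v3 = t3[t3.visit == 3]
        assert v3.n.max() == 2 and v3.r.isna().all()

    def test_histology_constancy_enforced(self):
        cohort = make_cohort()
        cohort.loc[0, "ki67_score"] += 1.0
        with pytest.raises(ValueError, match="constant across visits"):
            validate_cohort(cohort)


class TestCompareVisits:
    def test_identical_visits_undefined_flagged(self):
        cohort = make_cohort()
        cohort.loc[cohort.visit == 2, "t1_median"] = \
            cohort.loc[cohort.visit == 1, "t1_median"].to_numpy()
        out = compare_visits(cohort, "t1_median", 1, 2)
        assert out["method"] == "undefined" and np.isnan(out["p_value"])

    def test_uniform_decrease_gives_minimal_exact_p(self):
        cohort = make_cohort()
        v1 = cohort.loc[cohort.visit == 1, "t1_median"].to_numpy()
        cohort.loc[cohort.visit == 2, "t1_median"] = v1 * 0.8
        out = compare_visits(cohort, "t1_median", 1, 2)
        assert out["p_value"] == pytest.approx(2 / 2**12)
        assert out["median_change"] < 0

    def test_missing_visit_bookkeeping(self):
        cohort = make_cohort(missing3=["P00", "P01", "P02"])
        out = compare_visits(cohort, "adc_median", 1, 3)
        assert out["n_pairs"] == 9 and out["n_excluded"] == 3


def test_caix_stratification_grid():
    cohort = make_cohort()
    # inject a clean T1 separation at every visit
    pos = cohort["caix_positive"].astype(bool)
    cohort.loc[pos, "t1_median"] = 800.0 + np.arange(pos.sum())
    cohort.loc[~pos, "t1_median"] = 1400.0 + np.arange((~pos).sum())
    strat = caix_stratification(cohort)
    assert len(strat) == 3 * 4
    t1_rows = strat[strat.imaging == "t1_median"]
    assert (t1_rows.p_value < 0.05).all()
    assert (t1_rows.method == "exact").all()
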