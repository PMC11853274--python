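"""Paired t-tests, BH-FDR adjustment, star annotation and mode grouping."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from splicedisp import simulate as sim
from splicedisp.dispersion import count_kmers_by_site, profile
from splicedisp.kmers import PATTERNS, SubsetPartition
from splicedisp.region_stats import (
    DEFAULT_REGIONS,
    AlignmentError,
    RegionSpec,
    bh_adjust,
    compare_modes,
    paired_t,
    significance_groups,
    stars,
)


class TestRegions:
    def test_default_site_counts_and_df(self):
        by_name = {r.name: r for r in DEFAULT_REGIONS}
        assert by_name["upstream"].n_sites == 44 and by_name["upstream"].df == 43
        assert by_name["core"].n_sites == 7 and by_name["core"].df == 6
        assert by_name["downstream"].n_sites == 44 and by_name["downstream"].df == 43

    def test_core_labels_skip_zero(self):
        assert RegionSpec("core", -6, 1).site_labels() == [-6, -5, -4, -3, -2, -1, 1]

    def test_custom_bounds(self):
        assert RegionSpec("custom", -10, -1).df == 9


class TestPairedT:
    def test_identical_profiles(self):
        t, df, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, df, p) == (0.0, 2, 1.0)

    def test_closed_form_differences(self):
        t, df, p = paired_t([2.0, 3.0, 4.0], [1.0, 1.0, 1.0])  # d = (1, 2, 3)
        assert t == pytest.approx(2.0 / (1.0 / math.sqrt(3)), abs=1e-9)
        assert df == 2

    def test_zero_variance_nonzero_mean(self):
        t, df, p = paired_t([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])
        assert math.isinf(t) and t > 0
        assert p == 0.0

    def test_matches_scipy_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = rng.integers(3, 60)
            x, y = rng.normal(size=n), rng.normal(size=n)
            t, df, p = paired_t(x, y)
            ref = sps.ttest_rel(x, y)
            assert t == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-12)
            assert df == n - 1

    def test_too_short(self):
        with pytest.raises(ValueError):
            paired_t([1.0], [2.0])


def _bh_naive(p):
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBH:
    def test_step_up_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_agrees_with_reference_step_up(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), _bh_naive(p), atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])


class TestStars:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.2, "ns"), (0.051, "ns"), (0.05, "*"), (0.03, "*"),
            (0.01, "**"), (0.002, "**"), (0.001, "***"),
            (0.0001, "****"), (1e-9, "****"),
        ],
    )
    def test_thresholds_inclusive(self, p, expected):
        assert stars(p) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            stars(1.2)


@pytest.fixture(scope="module")
def null_profiles():
    part = SubsetPartition.build(6)
    cfg = sim.GeneratorConfig(n_per_mode=400, seed=21)
    return {
        m: profile(count_kmers_by_site(sim.generate_windows(cfg, m)), part)
        for m in ("common", "constitutive", "alternative")
    }


class TestCompareModes:
    def test_identical_profiles_all_ns_group_c(self, null_profiles):
        prof = null_profiles["common"]
        res = compare_modes({"a": prof, "b": prof.copy()})
        assert (res["t"] == 0.0).all()
        assert (res["p_adj"] == 1.0).all()
        assert (res["group"] == "C").all()

    def test_grouping_partitions_patterns(self, null_profiles):
        res = compare_modes(null_profiles)
        groups = significance_groups(res)
        for region in ("upstream", "core", "downstream"):
            sub = groups[groups["region"] == region]
            assert sorted(sub["pattern"]) == sorted(PATTERNS)
            assert set(sub["group"]) <= {"A", "B", "C"}

    def test_df_reflects_region_bounds(self, null_profiles):
        res = compare_modes(null_profiles, regions=[RegionSpec("custom", -10, -1)])
        assert (res["df"] == 9).all()

    def test_pairs_are_unordered_and_complete(self, null_profiles):
        res = compare_modes(null_profiles)
        per_region = res[res["region"] == "upstream"]
        assert len(per_region) == 16 * 3  # 16 patterns x 3 unordered pairs

    def test_mismatched_site_grid_raises(self, null_profiles):
        trimmed = null_profiles["common"]
        trimmed = trimmed[trimmed["site"] > -40]
        with pytest.raises(AlignmentError):
            compare_modes({"a": null_profiles["constitutive"], "b": trimmed})

    def test_single_mode_rejected(self, null_profiles):
        with pytest.raises(ValueError):
            compare_modes({"a": null_profiles["common"]})


def test_type_one_error_smoke():
    """Null draws from one generator stay mostly non-significant.

    Adjacent hexamer sites share five of six bases, so the per-site values
    are autocorrelated and exact nominal control is not expected; this is a
    smoke-level bound on the pooled false-positive fraction.
    """
    part = SubsetPartition.build(6)
    flagged, total = 0, 0
    for seed in range(20):
        cfg = sim.GeneratorConfig(n_per_mode=2000, seed=100 + seed)
        a, b = sim.generate_null_pair(cfg)
        profiles = {
            "a": profile(count_kmers_by_site(a), part),
            "b": profile(count_kmers_by_site(b), part),
        }
        res = compare_modes(profiles)
        flagged += int((res["p_adj"] <= 0.05).sum())
        total += len(res)
    assert flagged / total < 0.20
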