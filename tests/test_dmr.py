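"""Primary DMR calling, the control-consistency cascade, shuffle validation,
effect sizes and covariate filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from episcope import dmr, simulate


def _null_counts(n_sites=60, n_samples=12, seed=0, delta_sites=(), delta=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_samples):
        for i in range(n_sites):
            pi = 0.5 + (delta if i in delta_sites and s < n_samples // 2 else 0.0)
            cov = 30
            rows.append((f"s{s}", "chr1", 1000 + 10 * i, rng.binomial(cov, pi), cov))
    return pd.DataFrame(rows, columns=["sample", "chrom", "pos", "mc", "cov"])


class TestPrimaryCaller:
    def test_statistic_matches_bruteforce(self, rng):
        mc = rng.integers(0, 20, size=(3, 40)).astype(float)
        cov = mc + rng.integers(1, 20, size=(3, 40))
        obs = dmr.site_rms_statistic(mc, cov)
        for j in range(40):
            fr = mc[:, j] / cov[:, j]
            pooled = mc[:, j].sum() / cov[:, j].sum()
            assert obs[j] == pytest.approx(np.sqrt(np.mean((fr - pooled) ** 2)), abs=1e-12)

    def test_null_yields_no_candidates(self):
        counts = _null_counts(seed=1)
        groups = {f"s{i}": ("g1" if i < 6 else "g2") for i in range(12)}
        out = dmr.call_primary_dmrs(counts, groups, n_permutations=100, seed=0)
        assert len(out) <= 2  # expectation ~0 at FDR 0.05

    def test_planted_region_detected_and_merged(self):
        # 5 consecutive CpGs (10 bp apart, << max_gap) with delta 0.4
        counts = _null_counts(seed=2, delta_sites=(20, 21, 22, 23, 24), delta=0.4)
        groups = {f"s{i}": ("g1" if i < 6 else "g2") for i in range(12)}
        out = dmr.call_primary_dmrs(counts, groups, n_permutations=200, seed=0)
        planted = out[(out["start"] <= 1200 - 1) & (out["end"] >= 1240)]
        assert len(planted) == 1
        assert planted["n_sites"].iloc[0] == 5

    def test_distant_sites_not_merged(self):
        counts = _null_counts(n_sites=2, seed=3, delta_sites=(0, 1), delta=0.45)
        counts["pos"] = np.where(counts["pos"] == 1000, 1000, 5000)  # 4 kb apart
        groups = {f"s{i}": ("g1" if i < 6 else "g2") for i in range(12)}
        out = dmr.call_primary_dmrs(counts, groups, n_permutations=200, seed=0, max_gap=250)
        assert len(out) == 2
        assert (out["n_sites"] == 1).all()  # singleton-CpG regions allowed


class TestMethylationLevel:
    def _regions(self):
        return pd.DataFrame(
            {"region_id": ["r1"], "chrom": ["chr1"], "start": [100], "end": [200]}
        )

    def test_worked_ratio(self):
        counts = pd.DataFrame(
            {
                "sample": ["a", "a"],
                "chrom": ["chr1", "chr1"],
                "pos": [101, 150],
                "mc": [3, 1],
                "cov": [4, 6],
            }
        )
        lev = dmr.add_methylation_level(self._regions(), counts)
        assert lev.loc["r1", "a"] == pytest.approx(0.4)

    def test_zero_coverage_is_missing(self):
        counts = pd.DataFrame(
            {"sample": ["a"], "chrom": ["chr1"], "pos": [500], "mc": [1], "cov": [2]}
        )
        lev = dmr.add_methylation_level(self._regions(), counts)
        assert np.isnan(lev.loc["r1", "a"])

    def test_additive_over_site_batches(self, rng):
        pos = rng.choice(np.arange(101, 200), 20, replace=False)
        counts = pd.DataFrame(
            {
                "sample": "a",
                "chrom": "chr1",
                "pos": pos,
                "mc": rng.integers(0, 5, 20),
                "cov": rng.integers(5, 10, 20),
            }
        )
        full = dmr.add_methylation_level(self._regions(), counts)
        merged = pd.concat([counts.iloc[:10], counts.iloc[10:]])
        again = dmr.add_methylation_level(self._regions(), merged)
        assert full.loc["r1", "a"] == pytest.approx(again.loc["r1", "a"])


class TestInternalFilter:
    def test_null_retention_near_analytic_rate(self):
        levels, samples, _ = simulate.simulate_region_levels(
            n_regions=1000, n_true=0, seed=4
        )
        gmap = samples.set_index("sample")["cohort"].to_dict()
        out = dmr.filter_internal_control(levels, gmap)
        # min of 6 correlated pairwise tests: alpha_eff in (0.05, 0.30)
        rate = out["retained"].mean()
        assert 0.03 < rate < 0.35

    def test_planted_effect_power(self):
        levels, samples, truth = simulate.simulate_region_levels(
            n_regions=400, n_true=200, delta=0.3, level_sd=0.05, seed=5
        )
        gmap = samples.set_index("sample")["cohort"].to_dict()
        out = dmr.filter_internal_control(levels, gmap)
        power = out.loc[truth["is_edmr"].to_numpy(), "retained"].mean()
        assert power > 0.99

    def test_degenerate_constant_levels_dropped(self):
        levels = pd.DataFrame(
            [[0.5] * 8], index=["r"], columns=[f"s{i}" for i in range(8)]
        )
        gmap = {f"s{i}": ("a" if i < 4 else "b") for i in range(8)}
        out = dmr.filter_internal_control(levels, gmap)
        assert not out["retained"].iloc[0]
        assert np.isnan(out["min_p"].iloc[0])

    def test_pvalues_match_reference(self, rng):
        a = rng.normal(0.4, 0.05, size=(20, 6))
        b = rng.normal(0.5, 0.05, size=(20, 7))
        levels = pd.DataFrame(
            np.hstack([a, b]), columns=[f"x{i}" for i in range(6)] + [f"y{i}" for i in range(7)]
        )
        gmap = {c: c[0] for c in levels.columns}
        out = dmr.filter_internal_control(levels, gmap)
        for r in range(20):
            ref = stats.ttest_ind(a[r], b[r]).pvalue
            assert out["p_x_vs_y"].iloc[r] == pytest.approx(ref, abs=1e-10)


class TestExternalFilter:
    def _world(self, **kw):
        levels, samples, truth = simulate.simulate_region_levels(seed=6, **kw)
        gmap = samples.set_index("sample")["cohort"].to_dict()
        return levels, gmap, truth

    def test_planted_exposure_shift_retained(self):
        levels, gmap, truth = self._world(n_regions=300, n_true=100, delta=0.3)
        out = dmr.filter_external_control(
            levels, gmap, "exposure", ("hiv_pre", "flu_pre", "commercial")
        )
        # sensitivity is capped by the control-consistency rule: a true
        # region is lost whenever any control-control pair is spuriously
        # significant (~1 - 0.95^3 with correlated tests)
        assert out.loc[truth["is_edmr"].to_numpy(), "retained"].mean() > 0.9
        assert out.columns.str.startswith("p_").sum() == 6  # all six tests recorded

    def test_batch_artifact_rejected(self):
        levels, gmap, truth = self._world(
            n_regions=200, n_true=0, n_batch_regions=100, batch_shift=0.3
        )
        out = dmr.filter_external_control(
            levels, gmap, "exposure", ("hiv_pre", "flu_pre", "commercial")
        )
        assert out.loc[truth["is_batch"].to_numpy(), "retained"].mean() < 0.05

    def test_identical_groups_dropped(self):
        levels = pd.DataFrame(
            np.full((3, 8), 0.5) + np.arange(8) * 1e-4,
            columns=[f"s{i}" for i in range(8)],
        )
        gmap = {
            "s0": "e", "s1": "e",
            "s2": "c1", "s3": "c1",
            "s4": "c2", "s5": "c2",
            "s6": "c3", "s7": "c3",
        }
        out = dmr.filter_external_control(levels, gmap, "e", ("c1", "c2", "c3"))
        assert not out["retained"].any()

    def test_requires_three_controls(self, levels_world):
        gmap = levels_world["samples"].set_index("sample")["cohort"].to_dict()
        with pytest.raises(ValueError):
            dmr.filter_external_control(
                levels_world["levels"], gmap, "exposure", ("hiv_pre", "flu_pre")
            )
        with pytest.raises(ValueError):
            dmr.filter_external_control(
                levels_world["levels"], gmap, "exposure", ("hiv_pre", "flu_pre", "absent")
            )


class TestShuffleValidate:
    def _cascade(self):
        return lambda lv, gm: dmr.filter_external_control(
            lv, gm, "exposure", ("hiv_pre", "flu_pre", "commercial")
        )

    def test_fixed_seed_reproducible(self, levels_world):
        gmap = levels_world["samples"].set_index("sample")["cohort"].to_dict()
        r1 = dmr.shuffle_validate(levels_world["levels"], gmap, self._cascade(), 20, seed=9)
        r2 = dmr.shuffle_validate(levels_world["levels"], gmap, self._cascade(), 20, seed=9)
        np.testing.assert_array_equal(r1.shuffled_counts, r2.shuffled_counts)
        assert r1.observed_count == r2.observed_count

    def test_planted_exceeds_shuffles(self, levels_world):
        gmap = levels_world["samples"].set_index("sample")["cohort"].to_dict()
        res = dmr.shuffle_validate(levels_world["levels"], gmap, self._cascade(), 50, seed=1)
        assert res.exceeds_95th

    def test_rejects_zero_iterations(self, levels_world):
        gmap = levels_world["samples"].set_index("sample")["cohort"].to_dict()
        with pytest.raises(ValueError):
            dmr.shuffle_validate(levels_world["levels"], gmap, self._cascade(), 0)


class TestCohensD:
    def test_worked_example(self):
        assert dmr.cohens_d([0.1, 0.2, 0.3], [0.4, 0.5, 0.6]) == pytest.approx(-3.0, abs=1e-12)

    def test_identical_groups(self, rng):
        x = rng.normal(size=10)
        assert dmr.cohens_d(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_undefined(self):
        assert np.isnan(dmr.cohens_d([0.5, 0.5], [0.5, 0.5]))

    @given(
        st.lists(st.floats(-1, 1), min_size=2, max_size=8),
        st.lists(st.floats(-1, 1), min_size=2, max_size=8),
    )
    @settings(max_examples=100, deadline=None)
    def test_antisymmetric_and_matches_oracle(self, x, y):
        import statistics

        n1, n2 = len(x), len(y)
        s2 = ((n1 - 1) * statistics.variance(x) + (n2 - 1) * statistics.variance(y)) / (n1 + n2 - 2)
        if s2 <= 0:
            assert np.isnan(dmr.cohens_d(x, y))
        else:
            expected = (statistics.mean(x) - statistics.mean(y)) / np.sqrt(s2)
            assert dmr.cohens_d(x, y) == pytest.approx(expected, abs=1e-12)
            assert dmr.cohens_d(y, x) == pytest.approx(-dmr.cohens_d(x, y), abs=1e-12)


class TestCovariateFilter:
    def test_age_driven_region_excluded_exposure_region_retained(self):
        levels, samples, truth = simulate.simulate_region_levels(
            n_regions=200,
            n_true=50,
            delta=0.3,
            n_age_regions=50,
            age_effect=0.005,
            seed=8,
        )
        meta = samples.set_index("sample")
        out = dmr.filter_covariates(levels, meta)
        age_mask = truth["is_age"].to_numpy()
        edmr_mask = truth["is_edmr"].to_numpy()
        assert out.loc[age_mask, "retained"].mean() < 0.1  # slope 0.005/yr over ~40yr
        assert out.loc[edmr_mask, "retained"].mean() > 0.7  # balanced covariates

    def test_constant_covariate_skipped(self, levels_world):
        meta = levels_world["samples"].set_index("sample").copy()
        meta["sex"] = "F"
        out = dmr.filter_covariates(levels_world["levels"], meta)
        assert not any(c == "p_sex_M" for c in out.columns)

    def test_ancestry_regions_flagged(self):
        levels, samples, truth = simulate.simulate_region_levels(
            n_regions=150, n_true=0, seed=12
        )
        meta = samples.set_index("sample")
        anc = (meta["ancestry"] == "AFR").to_numpy(dtype=float)
        # plant an ancestry effect into the first 30 regions
        lv = levels.copy()
        lv.iloc[:30] = np.clip(lv.iloc[:30].to_numpy() + 0.25 * anc[None, :], 0, 1)
        out = dmr.ancestry_edmrs(lv, meta)
        assert out["ancestry_associated"].iloc[:30].mean() > 0.9
        assert out["ancestry_associated"].iloc[30:].mean() < 0.05

    def test_direction_assignment(self):
        levels = pd.DataFrame(
            {"a1": [0.2], "a2": [0.25], "b1": [0.8], "b2": [0.75]}, index=["r"]
        )
        gmap = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        status = dmr.group_direction(levels, gmap)
        assert status.loc["r", "status_A"] == "hypo"
        assert status.loc["r", "status_B"] == "hyper"
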