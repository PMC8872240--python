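"""Down-sampling, Delta f statistics, trendlines and recommendations."""

import numpy as np
import pytest
from scipy import stats

import paleometh as pm
from paleometh import io as pio


def track(positions, f_hat, n_obs=None, ncpg=25, cov=10.0):
    positions = np.asarray(positions)
    f_hat = np.asarray(f_hat, dtype=float)
    if n_obs is None:
        n_obs = np.where(np.isnan(f_hat), 0, 3)
    return pm.FTrack(
        positions=positions, f_hat=f_hat, n_obs=n_obs,
        ncpg_window=ncpg, coverage_label=cov,
    )


class TestDownsample:
    def test_target_equal_current_is_identity(self, small_ref, small_meth):
        reads = pm.simulate_reads(
            small_ref, small_meth, pm.DamageModel(), mean_cov=3, seed=1
        )
        same = pm.downsample_reads(reads, reads.mean_cov, seed=2)
        assert len(same) == len(reads)
        assert np.array_equal(same.base_codes, reads.base_codes)

    def test_kept_count_in_binomial_ci(self, small_ref, small_meth):
        reads = pm.simulate_reads(
            small_ref, small_meth, pm.DamageModel(), mean_cov=30, seed=3
        )
        n = len(reads)
        assert n > 10000
        half = pm.downsample_reads(reads, reads.mean_cov / 2, seed=4)
        lo, hi = stats.binom.interval(0.99, n, 0.5)
        assert lo <= len(half) <= hi

    def test_cannot_upsample(self, small_ref, small_meth):
        reads = pm.simulate_reads(
            small_ref, small_meth, pm.DamageModel(), mean_cov=2, seed=5
        )
        with pytest.raises(ValueError):
            pm.downsample_reads(reads, 50.0, seed=6)

    def test_deterministic_given_seed(self, small_ref, small_meth):
        reads = pm.simulate_reads(
            small_ref, small_meth, pm.DamageModel(), mean_cov=5, seed=7
        )
        a = pm.downsample_reads(reads, 2.0, seed=8)
        b = pm.downsample_reads(reads, 2.0, seed=8)
        assert np.array_equal(a.starts, b.starts)


class TestDeltaF:
    def test_identical_tracks_give_zero(self):
        t = track([1, 5, 9], [0.1, 0.6, 0.9])
        d = pm.delta_f(t, t)
        assert np.all(d == 0.0)

    def test_range_endpoints_attained(self):
        a = track([1, 5], [1.0, 0.0])
        b = track([1, 5], [0.0, 1.0])
        d = pm.delta_f(a, b)
        assert set(d) == {1.0, -1.0}

    def test_missing_sites_excluded(self):
        a = track([1, 5, 9], [0.1, np.nan, 0.9])
        b = track([1, 5, 9], [0.2, 0.5, 0.8])
        assert len(pm.delta_f(a, b)) == 2

    def test_mismatched_windows_rejected(self):
        a = track([1], [0.1], ncpg=25)
        b = track([1], [0.1], ncpg=50)
        with pytest.raises(ValueError):
            pm.delta_f(a, b)


class TestSummarizePrecision:
    def test_zero_dispersion(self):
        full = track([1, 3, 5, 7], [0.2, 0.4, 0.6, 0.8])
        table = pm.summarize_precision({2.0: full}, full)
        assert table.sd_delta_f[0] == 0.0
        assert table.n_compared[0] == 4

    def test_hand_computed_sample_sd(self):
        full = track([1, 3], [0.5, 0.5])
        lev = track([1, 3], [0.4, 0.6])  # Delta f = {-0.1, +0.1}
        table = pm.summarize_precision({2.0: lev}, full)
        assert table.sd_delta_f[0] == pytest.approx(0.1414214, abs=1e-6)

    def test_single_compared_site_rejected(self):
        full = track([1, 3], [0.5, np.nan])
        lev = track([1, 3], [0.4, 0.2])
        with pytest.raises(ValueError):
            pm.summarize_precision({2.0: lev}, full)


class TestFitTrendline:
    def test_sqrt_law_exact_recovery(self):
        levels = np.array([1, 3, 5, 10, 15, 20], dtype=float)
        sds = 0.5 * np.sqrt(1 / levels - 1 / 24) + 0.01
        fit = pm.fit_trendline(levels, sds, 24.0, form="sqrt-law")
        assert fit.params["a"] == pytest.approx(0.5, abs=1e-6)
        assert fit.params["d"] == pytest.approx(0.01, abs=1e-6)
        assert fit.r_squared >= 0.9999

    def test_exponential_exact_recovery(self):
        levels = np.array([1, 3, 5, 10, 15, 20], dtype=float)
        sds = 0.4 * np.exp(-0.12 * levels) + 0.05
        fit = pm.fit_trendline(levels, sds, 24.0, form="exponential")
        assert fit.params["a"] == pytest.approx(0.4, rel=1e-4)
        assert fit.params["b"] == pytest.approx(0.12, rel=1e-4)
        assert fit.r_squared >= 0.9999

    def test_constant_input_degenerate_not_error(self):
        levels = np.array([1.0, 3.0, 5.0])
        for form in ("sqrt-law", "power", "exponential"):
            fit = pm.fit_trendline(
                levels, np.full(3, 0.2), 24.0, form=form
            )
            assert fit.r_squared == 0.0
            assert fit.degenerate

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            pm.fit_trendline(
                np.array([1.0, 3.0]), np.array([0.3, 0.2]), 24.0
            )

    def test_invalid_inputs_rejected(self):
        lv = np.array([0.0, 3.0, 5.0])
        with pytest.raises(ValueError):
            pm.fit_trendline(lv, np.full(3, 0.1), 24.0)
        with pytest.raises(ValueError):
            pm.fit_trendline(
                np.array([1.0, 3.0, 5.0]),
                np.array([0.1, -0.1, 0.1]),
                24.0,
            )


class TestRecommendCoverage:
    def _table(self, sds, levels=(1, 3, 5, 10, 15, 20)):
        n = len(levels)
        return pm.PrecisionTable(
            levels=np.array(levels, dtype=float),
            sd_delta_f=np.array(sds, dtype=float),
            n_compared=np.full(n, 100),
            n_noncovered=np.zeros(n, dtype=int),
        )

    def test_threshold_rule_example(self):
        table = self._table([0.30, 0.20, 0.12, 0.06, 0.04, 0.03])
        rec = pm.recommend_coverage(table, 24.0, factor=2.0)
        assert rec.ref_level == 20.0
        assert rec.sd_ref == 0.03
        assert rec.threshold == pytest.approx(0.06)
        assert rec.recommended_level == 10.0

    def test_only_ref_level_meets_threshold(self):
        table = self._table([0.50, 0.40, 0.30, 0.25, 0.20, 0.03])
        rec = pm.recommend_coverage(table, 24.0, factor=2.0)
        assert rec.recommended_level == 20.0

    def test_huge_factor_recommends_smallest_level(self):
        table = self._table([0.30, 0.20, 0.12, 0.06, 0.04, 0.03])
        rec = pm.recommend_coverage(table, 24.0, factor=1e9)
        assert rec.recommended_level == 1.0

    def test_monotone_in_factor(self):
        table = self._table([0.31, 0.22, 0.13, 0.07, 0.045, 0.03])
        prev = np.inf
        for factor in (1.0, 1.5, 2.0, 3.0, 5.0, 10.0):
            rec = pm.recommend_coverage(table, 24.0, factor=factor)
            level = rec.recommended_level or np.inf
            assert level <= prev
            prev = level


class TestRunExperiment:
    def test_empty_grid_rejected(self, tiny_config):
        cfg = tiny_config.replace(grid=())
        with pytest.raises(ValueError):
            pm.run_experiment(cfg)

    def test_deterministic_outputs(self, tiny_config, tmp_path):
        files = []
        for run in ("a", "b"):
            res = pm.run_experiment(tiny_config)
            p = tmp_path / f"precision_{run}.tsv"
            pio.write_precision_tsv(res.table, p)
            pio.write_ftrack_tsv(
                res.tracks[1.0], tmp_path / f"track_{run}.tsv"
            )
            files.append(p)
        assert files[0].read_bytes() == files[1].read_bytes()
        assert (tmp_path / "track_a.tsv").read_bytes() == (
            tmp_path / "track_b.tsv"
        ).read_bytes()

    def test_structure_and_invariants(self, tiny_config):
        res = pm.run_experiment(tiny_config)
        t = res.table
        assert np.array_equal(t.levels, [1.0, 3.0, 5.0])
        # non-covered counts shrink as coverage grows
        assert np.all(np.diff(t.n_noncovered) <= 0)
        assert np.all(t.sd_delta_f >= 0)
        for lev in (1.0, 3.0, 5.0):
            d = pm.delta_f(res.tracks[lev], res.tracks[8.0])
            assert d.min() >= -1.0 and d.max() <= 1.0

    def test_sd_decreases_with_coverage(self, tiny_config):
        res = pm.run_experiment(tiny_config)
        assert np.all(np.diff(res.table.sd_delta_f) < 0)


class TestNestingInvariance:
    def test_two_stage_thinning_matches_direct(self):
        # Thinning 30x -> 10x -> 5x and 30x -> 5x must give the same
        # Delta-f dispersion in distribution (two-sample t test).
        ref = pm.generate_reference(100_000, 1000, seed=61)
        meth = pm.generate_methylome(ref, seed=62)
        cfg = pm.ExperimentConfig(
            ref_length=100_000, n_cpg=1000, full_cov=30.0, grid=(5,),
        )
        sd_two, sd_one = [], []
        for seed in range(4):
            reads = pm.simulate_reads(
                ref, meth, cfg.damage_model(), mean_cov=30, seed=100 + seed
            )
            from paleometh.precision import _estimate_track

            full_track = _estimate_track(reads, ref, cfg, 30.0)
            mid = pm.downsample_reads(reads, 10.0, seed=200 + seed)
            via = pm.downsample_reads(mid, 5.0, seed=300 + seed)
            direct = pm.downsample_reads(reads, 5.0, seed=400 + seed)
            for out, reads5 in ((sd_two, via), (sd_one, direct)):
                tr = _estimate_track(reads5, ref, cfg, 5.0)
                out.append(float(np.std(pm.delta_f(tr, full_track), ddof=1)))
        _, p = stats.ttest_ind(sd_two, sd_one)
        assert p > 0.01
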