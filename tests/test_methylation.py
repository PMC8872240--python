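"""Windowed binomial ML methylation estimation."""

import numpy as np
import pytest

import paleometh as pm
from paleometh.methylation import window_loglik
from paleometh.simulate import I_MAX


def flat_profile(delta: float = 0.1) -> pm.DamageProfile:
    return pm.DamageProfile(
        delta_hat=np.full(I_MAX + 1, delta),
        n_obs=np.full(I_MAX + 1, 1000),
    )


def cpg_pileup(counts: list[tuple[int, dict, dict]]) -> pm.SitePileup:
    """Pileup of CpG-only sites from (pos, {i: n_C}, {i: n_T}) triples."""
    n = len(counts)
    n_c = np.zeros((n, I_MAX + 1), dtype=np.int64)
    n_t = np.zeros((n, I_MAX + 1), dtype=np.int64)
    for row, (_, cs, ts) in enumerate(counts):
        for i, v in cs.items():
            n_c[row, i] = v
        for i, v in ts.items():
            n_t[row, i] = v
    return pm.SitePileup(
        site_pos=np.array([c[0] for c in counts]),
        is_cpg=np.ones(n, dtype=bool),
        n_c=n_c,
        n_t=n_t,
    )


class TestEstimateF:
    def test_all_c_window_gives_zero(self):
        pile = cpg_pileup([(10, {0: 8, 3: 12}, {})])
        track = pm.estimate_f(pile, flat_profile(0.1), rho=2.0, eps=0.0)
        assert track.f_hat[0] == 0.0

    def test_all_t_window_gives_one(self):
        pile = cpg_pileup([(10, {}, {0: 10})])
        track = pm.estimate_f(pile, flat_profile(0.2), rho=4.0, eps=0.0)
        assert track.f_hat[0] == 1.0

    @pytest.mark.parametrize(
        "n_t,n_c,du,rho",
        [
            (3, 7, 0.1, 4.0),  # analytic f = (0.3-0.1)/0.3 = 2/3
            (2, 8, 0.1, 3.0),
            (5, 5, 0.2, 2.0),
            (1, 19, 0.05, 5.0),
        ],
    )
    def test_single_position_matches_closed_form(self, n_t, n_c, du, rho):
        # With every observation at one read position and eps = 0 the
        # MLE is clip((t - du) / (dm - du), 0, 1) for t = n_T/(n_C+n_T).
        pile = cpg_pileup([(10, {0: n_c}, {0: n_t})])
        track = pm.estimate_f(
            pile, flat_profile(du), rho=rho, eps=0.0
        )
        t = n_t / (n_t + n_c)
        dm = min(1.0, rho * du)
        expected = np.clip((t - du) / (dm - du), 0.0, 1.0)
        assert track.f_hat[0] == pytest.approx(expected, abs=1e-4)

    def test_mixed_window_matches_brute_force_grid(self):
        rng = np.random.default_rng(99)
        grid = np.arange(0.0, 1.0 + 5e-5, 1e-4)
        for _ in range(20):
            n_c = {i: int(rng.integers(0, 30)) for i in range(4)}
            n_t = {i: int(rng.integers(0, 6)) for i in range(4)}
            pile = cpg_pileup([(10, n_c, n_t)])
            du = float(rng.uniform(0.05, 0.3))
            rho = float(rng.uniform(1.5, 4.0))
            prof = flat_profile(du)
            track = pm.estimate_f(pile, prof, rho=rho, eps=0.001)
            if np.isnan(track.f_hat[0]):
                continue
            t_arr = np.zeros(I_MAX + 1)
            c_arr = np.zeros(I_MAX + 1)
            for i, v in n_t.items():
                t_arr[i] = v
            for i, v in n_c.items():
                c_arr[i] = v
            dm = np.minimum(1.0, rho * prof.delta_hat)
            ll = window_loglik(
                t_arr, c_arr, grid, prof.delta_hat, dm, 0.001
            )
            best = grid[np.argmax(ll)]
            ll_hat = window_loglik(
                t_arr, c_arr, track.f_hat[0], prof.delta_hat, dm, 0.001
            )
            assert ll_hat >= ll.max() - 1e-9
            assert abs(track.f_hat[0] - best) <= 1e-4

    def test_window_pools_downstream_sites(self):
        # Moving counts between sites inside the window leaves the
        # pooled likelihood, hence f_hat, unchanged (count sufficiency).
        a = cpg_pileup([(10, {0: 5}, {0: 3}), (20, {0: 5}, {0: 1})])
        b = cpg_pileup([(10, {0: 9}, {0: 4}), (20, {0: 1}, {})])
        fa = pm.estimate_f(a, flat_profile(), ncpg=25).f_hat[0]
        fb = pm.estimate_f(b, flat_profile(), ncpg=25).f_hat[0]
        assert fa == fb

    def test_ncpg_zero_uses_focal_site_only(self):
        pile = cpg_pileup([(10, {0: 10}, {}), (20, {}, {0: 10})])
        track = pm.estimate_f(pile, flat_profile(), rho=3.0, ncpg=0,
                              eps=0.0)
        assert track.f_hat[0] == 0.0
        assert track.f_hat[1] == 1.0

    def test_uncovered_focal_site_is_missing(self):
        pile = cpg_pileup([(10, {}, {}), (20, {0: 10}, {0: 2})])
        track = pm.estimate_f(pile, flat_profile())
        assert np.isnan(track.f_hat[0])  # no focal observations
        assert not np.isnan(track.f_hat[1])
        assert track.n_noncovered == 1

    def test_masked_site_excluded_from_track_and_windows(self):
        pile = cpg_pileup(
            [(10, {0: 10}, {}), (20, {12: 0}, {12: 20}), (30, {0: 10}, {})]
        )
        prof = flat_profile(0.1)
        masked = pm.mask_mutations(pile, prof)
        assert masked.masked[1]
        track = pm.estimate_f(masked, prof)
        assert np.isnan(track.f_hat[1])
        # windows skip the masked site: remaining all-C windows give 0
        assert track.f_hat[0] == 0.0

    def test_rho_one_is_non_identifiable(self):
        pile = cpg_pileup([(10, {0: 5}, {0: 5})])
        with pytest.raises(pm.NonIdentifiableError):
            pm.estimate_f(pile, flat_profile(0.2), rho=1.0)

    def test_degenerate_profile_raises(self):
        pile = cpg_pileup([(10, {}, {0: 3})])
        with pytest.raises(pm.DegenerateProfileError):
            pm.estimate_f(pile, flat_profile(0.0), rho=2.0, eps=0.0)


class TestRecoverParametersReport:
    def test_perfect_track(self):
        track = pm.FTrack(
            positions=np.array([1, 5, 9]),
            f_hat=np.array([0.1, 0.5, 0.9]),
            n_obs=np.array([3, 3, 3]),
            ncpg_window=25,
            coverage_label=10.0,
        )
        rep = pm.recover_parameters_report(
            track, np.array([0.1, 0.5, 0.9])
        )
        assert rep["bias"] == 0.0
        assert rep["rmse"] == 0.0
        assert rep["n_compared"] == 3
        assert rep["pearson_r"] == pytest.approx(1.0) or np.isnan(
            rep["pearson_r"]
        )

    def test_constant_truth_reports_missing_correlation(self):
        track = pm.FTrack(
            positions=np.array([1, 5]),
            f_hat=np.array([0.2, 0.6]),
            n_obs=np.array([3, 3]),
            ncpg_window=25,
            coverage_label=10.0,
        )
        rep = pm.recover_parameters_report(track, np.array([0.5, 0.5]))
        assert np.isnan(rep["pearson_r"])
        assert rep["n_compared"] == 2

    def test_rmse_decreases_with_coverage(self):
        ref = pm.generate_reference(100_000, 1000, seed=51)
        meth = pm.generate_methylome(ref, seed=52)
        dmg = pm.DamageModel()
        rmse = {}
        for cov in (3, 30):
            reads = pm.simulate_reads(ref, meth, dmg, mean_cov=cov, seed=53)
            pile = pm.build_pileup(reads, ref)
            prof = pm.estimate_damage_profile(pile)
            pile = pm.mask_mutations(pile, prof)
            track = pm.estimate_f(pile, prof, coverage_label=cov)
            rmse[cov] = pm.recover_parameters_report(track, meth)["rmse"]
        assert rmse[30] < rmse[3]
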