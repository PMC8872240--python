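"""Windowed binomial maximum-likelihood estimation of CpG methylation.

For each focal CpG the estimator pools C/T observations from the focal
site and the ``ncpg`` CpG sites downstream (truncated at the chromosome
end; 25 or 50 in practice), and maximizes over the methylation fraction
f in [0, 1] the binomial log-likelihood in which the per-read-position
T-probability mixes the methylated and unmethylated deamination rates:

    non-UDG:  P_T(f, i) = D + (eps/3) * (1 - D),
              D = f * delta_m(i) + (1 - f) * delta_u(i)
    UDG:      P_T(f, i) = f * delta_m(i) + eps/3

with delta_u(i) taken from the estimated damage profile and
delta_m(i) = min(1, rho * delta_u(i)).  The maximizer is located on a
dense grid (step 1e-3) and refined by golden-section search to 1e-6;
flat stretches resolve to the smallest maximizing f.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .pileup import DamageProfile, SitePileup

__all__ = [
    "FTrack",
    "NonIdentifiableError",
    "DegenerateProfileError",
    "estimate_f",
    "window_loglik",
    "recover_parameters_report",
]

_GRID_STEP = 1e-3
_REFINE_TOL = 1e-6
_INV_GOLD = (np.sqrt(5.0) - 1.0) / 2.0


class NonIdentifiableError(ValueError):
    """The likelihood is flat in f (e.g. rho = 1 in non-UDG mode)."""


class DegenerateProfileError(ValueError):
    """T observations exist but the model assigns them zero probability."""


@dataclass
class FTrack:
    """Per-focal-CpG methylation estimates at one coverage level.

    ``f_hat`` is NaN where the focal CpG has zero observations (site
    not covered) or was masked as a sequence variant.
    """

    positions: np.ndarray  # int64, reference positions of all CpGs
    f_hat: np.ndarray  # float64 in [0,1] or NaN
    n_obs: np.ndarray  # int64, observations at the focal site
    ncpg_window: int
    coverage_label: float
    ref_name: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.f_hat = np.asarray(self.f_hat, dtype=np.float64)
        self.n_obs = np.asarray(self.n_obs, dtype=np.int64)

    @property
    def n_defined(self) -> int:
        return int(np.count_nonzero(~np.isnan(self.f_hat)))

    @property
    def n_noncovered(self) -> int:
        """Focal CpGs with zero observations (f undefined)."""
        return int(np.count_nonzero(self.n_obs == 0))


def _t_prob(
    f: np.ndarray, du: np.ndarray, dm: np.ndarray, eps: float, mode: str
) -> np.ndarray:
    """P(observe T | f, read position) for f broadcast against du/dm."""
    if mode == "non-UDG":
        d = f * dm + (1.0 - f) * du
        return d + (eps / 3.0) * (1.0 - d)
    return np.minimum(f * dm + eps / 3.0, 1.0)


def window_loglik(
    t: np.ndarray,
    c: np.ndarray,
    f: float | np.ndarray,
    du: np.ndarray,
    dm: np.ndarray,
    eps: float,
    mode: str = "non-UDG",
) -> np.ndarray:
    """Log-likelihood of pooled window counts at methylation f.

    ``t`` and ``c`` are T/C counts per read position (matching ``du``
    and ``dm``); ``f`` may be scalar or an array broadcast on a new
    leading axis.  Exposed for oracle/diagnostic use.
    """
    f = np.atleast_1d(np.asarray(f, dtype=np.float64))[:, None]
    p = _t_prob(f, du[None, :], dm[None, :], eps, mode)
    with np.errstate(divide="ignore", invalid="ignore"):
        term_t = np.where(t[None, :] > 0, t[None, :] * np.log(p), 0.0)
        term_c = np.where(c[None, :] > 0, c[None, :] * np.log1p(-p), 0.0)
    return np.squeeze((term_t + term_c).sum(axis=1))


def _window_counts(
    pileup: SitePileup, ncpg: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pooled per-read-position counts for each focal CpG window.

    Windows run over the unmasked CpG sites in positional order: focal
    plus the ``ncpg`` next sites, truncated at the end.  Returns
    (positions, focal depth, pooled T counts, pooled C counts).
    """
    cpgs = pileup.cpg_view()
    n = cpgs.n_sites
    # Cumulative sums along the site axis allow O(1) window pooling.
    csum_t = np.vstack([np.zeros_like(cpgs.n_t[:1]), np.cumsum(cpgs.n_t, 0)])
    csum_c = np.vstack([np.zeros_like(cpgs.n_c[:1]), np.cumsum(cpgs.n_c, 0)])
    hi = np.minimum(np.arange(n) + ncpg + 1, n)
    lo = np.arange(n)
    t_win = csum_t[hi] - csum_t[lo]
    c_win = csum_c[hi] - csum_c[lo]
    focal_depth = (cpgs.n_c + cpgs.n_t).sum(axis=1)
    return cpgs.site_pos, focal_depth, t_win, c_win


def estimate_f(
    pileup: SitePileup,
    profile: DamageProfile,
    rho: float = 2.0,
    eps: float = 0.001,
    ncpg: int = 25,
    mode: str = "non-UDG",
    coverage_label: float = float("nan"),
    delta_m: np.ndarray | None = None,
) -> FTrack:
    """Estimate methylation f for every focal CpG of the pileup.

    ``delta_u(i)`` comes from ``profile``; ``delta_m(i)`` is
    ``min(1, rho * delta_u(i))`` unless an explicit ``delta_m`` table is
    supplied (needed in UDG mode, where unmethylated deamination leaves
    no T signal from which to scale).  Observations at read positions
    where the profile is undefined are dropped.  ``f_hat`` is NaN for
    focal CpGs with zero observations and for masked sites.
    """
    if ncpg < 0:
        raise ValueError("ncpg must be >= 0")
    du_full = profile.delta_hat
    usable = ~np.isnan(du_full)
    du = np.where(usable, du_full, 0.0)
    if delta_m is None:
        dm = np.minimum(1.0, rho * du)
    else:
        dm = np.asarray(delta_m, dtype=np.float64)
        if dm.shape != du.shape:
            raise ValueError("delta_m table shape mismatch")

    pos, focal_depth, t_win, c_win = _window_counts(pileup, ncpg)
    # Drop unusable read positions from the pooled counts.
    t_win = np.where(usable[None, :], t_win, 0)
    c_win = np.where(usable[None, :], c_win, 0)

    has_obs = (t_win + c_win).sum(axis=1) > 0
    # Degenerate: T observed at a position where P_T == 0 for every f.
    p_t_max = _t_prob(np.array([1.0]), du, dm, eps, mode).ravel()
    dead = usable & (p_t_max <= 0.0)
    if np.any(t_win[:, dead] > 0):
        raise DegenerateProfileError(
            "T observations at read positions where the damage model "
            "assigns them zero probability"
        )
    if mode == "non-UDG" and np.any(has_obs):
        informative = usable & (dm > du)
        if not np.any(informative):
            raise NonIdentifiableError(
                "delta_m(i) == delta_u(i) at every supported read "
                "position; the likelihood is flat in f (is rho > 1?)"
            )

    n = len(pos)
    f_hat = np.full(n, np.nan)
    active = focal_depth > 0
    if np.any(active):
        f_hat[active] = _maximize(
            t_win[active], c_win[active], du, dm, eps, mode
        )

    # Re-expand over the full CpG set (masked sites become NaN).
    all_cpg_pos = pileup.site_pos[pileup.is_cpg]
    all_depth = (
        (pileup.n_c + pileup.n_t).sum(axis=1)[pileup.is_cpg]
    )
    full_f = np.full(len(all_cpg_pos), np.nan)
    idx = np.searchsorted(all_cpg_pos, pos)
    full_f[idx] = f_hat
    return FTrack(
        positions=all_cpg_pos,
        f_hat=full_f,
        n_obs=all_depth,
        ncpg_window=ncpg,
        coverage_label=coverage_label,
        ref_name=pileup.ref_name,
    )


def _maximize(
    t: np.ndarray,
    c: np.ndarray,
    du: np.ndarray,
    dm: np.ndarray,
    eps: float,
    mode: str,
) -> np.ndarray:
    """Vectorized grid search + golden-section refinement per window."""
    grid = np.arange(0.0, 1.0 + _GRID_STEP / 2, _GRID_STEP)
    # (n_f, I) probability table shared by all windows.
    p = _t_prob(grid[:, None], du[None, :], dm[None, :], eps, mode)
    with np.errstate(divide="ignore"):
        log_p = np.log(p)
        log_q = np.log1p(-p)
    log_p[~np.isfinite(log_p)] = -1e300  # zero-prob cells; counts may be 0
    log_q[~np.isfinite(log_q)] = -1e300
    ll = t @ log_p.T + c @ log_q.T  # (n_win, n_f)
    best = np.argmax(ll, axis=1)  # first max -> smallest f on exact ties

    lo = grid[np.maximum(best - 1, 0)]
    hi = grid[np.minimum(best + 1, len(grid) - 1)]

    def ll_at(f_vec: np.ndarray) -> np.ndarray:
        pv = _t_prob(f_vec[:, None], du[None, :], dm[None, :], eps, mode)
        with np.errstate(divide="ignore"):
            lp = np.log(pv)
            lq = np.log1p(-pv)
        lp[~np.isfinite(lp)] = -1e300
        lq[~np.isfinite(lq)] = -1e300
        return np.einsum("ij,ij->i", t, lp) + np.einsum("ij,ij->i", c, lq)

    x1 = hi - _INV_GOLD * (hi - lo)
    x2 = lo + _INV_GOLD * (hi - lo)
    f1, f2 = ll_at(x1), ll_at(x2)
    while np.max(hi - lo) > _REFINE_TOL:
        go_left = f1 >= f2  # ties shrink rightward -> smaller f kept
        hi = np.where(go_left, x2, hi)
        lo = np.where(go_left, lo, x1)
        x1 = hi - _INV_GOLD * (hi - lo)
        x2 = lo + _INV_GOLD * (hi - lo)
        f1, f2 = ll_at(x1), ll_at(x2)
    mid = (lo + hi) / 2.0
    # Prefer the exact grid point (notably the boundaries 0 and 1) when
    # it is at least as likely as the refined interior value.
    grid_f = grid[best]
    keep_grid = ll_at(grid_f) >= ll_at(mid)
    out = np.where(keep_grid, grid_f, mid)
    return np.clip(out, 0.0, 1.0)


def recover_parameters_report(
    f_track: FTrack, truth: "np.ndarray | object"
) -> dict:
    """Compare an FTrack against the true methylome.

    ``truth`` is a Methylome or an array of true levels aligned with
    ``f_track.positions``.  Statistics are computed over focal CpGs
    with a defined estimate; Pearson r is NaN when either side is
    constant.
    """
    levels = np.asarray(getattr(truth, "levels", truth), dtype=np.float64)
    if len(levels) != len(f_track.positions):
        raise ValueError("truth does not align with the track's CpG set")
    ok = ~np.isnan(f_track.f_hat)
    est = f_track.f_hat[ok]
    tru = levels[ok]
    n = int(ok.sum())
    if n == 0:
        return {"bias": np.nan, "rmse": np.nan, "pearson_r": np.nan,
                "n_compared": 0}
    err = est - tru
    bias = float(err.mean())
    rmse = float(np.sqrt((err**2).mean()))
    if n < 2 or np.ptp(est) == 0.0 or np.ptp(tru) == 0.0:
        r = np.nan
    else:
        r = float(stats.pearsonr(est, tru)[0])
    return {"bias": bias, "rmse": rmse, "pearson_r": r, "n_compared": n}
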