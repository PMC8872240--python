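"""Per-site pileups, damage-profile estimation, and mutation masking.

A *cytosine site* is any reference position that a read can interrogate
in its own strand's cytosine context: every forward-strand C, and every
G (a reverse-strand cytosine).  Observations are stratified by the
read-position index i (distance to the read's 5' end, capped at I_MAX)
because post-mortem deamination is strongly position dependent.

Strand handling: forward reads contribute at forward C positions
(C observed -> n_C, T -> n_T); reverse reads contribute at reference G
positions with complemented observations (G -> n_C, A -> n_T).  The G
of a CpG is folded into the CpG's C site, merging both strands of the
symmetric CpG; a non-CpG G is kept as its own site.  Reads of the
opposite strand carry no deamination information about a site and are
not counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import I_MAX, ReadSet, ReferenceChrom

__all__ = [
    "SitePileup",
    "DamageProfile",
    "build_pileup",
    "estimate_damage_profile",
    "mask_mutations",
]

_A, _C, _G, _T = 0, 1, 2, 3


@dataclass
class SitePileup:
    """Stratified C/T counts at cytosine sites.

    ``n_c[s, i]`` and ``n_t[s, i]`` count C- and T-observations (in the
    read's cytosine frame) at site ``s`` and read position ``i``.
    """

    site_pos: np.ndarray  # int64, sorted forward-frame positions
    is_cpg: np.ndarray  # bool
    n_c: np.ndarray  # int64, shape (n_sites, I_MAX + 1)
    n_t: np.ndarray  # int64, same shape
    ref_name: str = ""
    i_max: int = I_MAX
    masked: np.ndarray = field(default=None)  # bool, True = removed

    def __post_init__(self) -> None:
        self.site_pos = np.asarray(self.site_pos, dtype=np.int64)
        self.is_cpg = np.asarray(self.is_cpg, dtype=bool)
        self.n_c = np.asarray(self.n_c, dtype=np.int64)
        self.n_t = np.asarray(self.n_t, dtype=np.int64)
        if self.masked is None:
            self.masked = np.zeros(len(self.site_pos), dtype=bool)
        else:
            self.masked = np.asarray(self.masked, dtype=bool)

    @property
    def n_sites(self) -> int:
        return len(self.site_pos)

    def site_depth(self) -> np.ndarray:
        """Total observations per site, summed over read positions."""
        return (self.n_c + self.n_t).sum(axis=1)

    def cpg_view(self) -> "SitePileup":
        """Pileup restricted to unmasked CpG sites."""
        sel = self.is_cpg & ~self.masked
        return SitePileup(
            site_pos=self.site_pos[sel],
            is_cpg=self.is_cpg[sel],
            n_c=self.n_c[sel],
            n_t=self.n_t[sel],
            ref_name=self.ref_name,
            i_max=self.i_max,
        )


@dataclass
class DamageProfile:
    """Estimated unmethylated deamination rate per read position.

    ``delta_hat[i]`` is NaN where ``n_obs[i] == 0`` (no support).
    """

    delta_hat: np.ndarray  # float64, length I_MAX + 1, NaN = undefined
    n_obs: np.ndarray  # int64

    def __post_init__(self) -> None:
        self.delta_hat = np.asarray(self.delta_hat, dtype=np.float64)
        self.n_obs = np.asarray(self.n_obs, dtype=np.int64)
        ok = self.delta_hat[~np.isnan(self.delta_hat)]
        if ok.size and (ok.min() < 0.0 or ok.max() > 1.0):
            raise ValueError("delta_hat values must lie in [0, 1]")


def build_pileup(reads: ReadSet, ref: ReferenceChrom) -> SitePileup:
    """Count C/T observations at every cytosine site of ``ref``.

    The site table is dense over the reference (every forward C and
    every non-CpG G, with CpG Gs folded into the C site), so uncovered
    sites are present with zero counts.
    """
    L = len(ref)
    codes = ref.codes
    cpg_c = np.zeros(L, dtype=bool)
    if len(ref.cpg_pos):
        cpg_c[ref.cpg_pos] = True
    cpg_g = np.zeros(L, dtype=bool)
    if len(ref.cpg_pos):
        cpg_g[ref.cpg_pos + 1] = True

    # Site table: forward Cs plus non-CpG Gs.
    is_site = (codes == _C) | ((codes == _G) & ~cpg_g)
    site_pos = np.flatnonzero(is_site).astype(np.int64)
    is_cpg = cpg_c[site_pos]
    n_sites = len(site_pos)
    width = I_MAX + 1

    # Reference position -> site row, with CpG Gs redirected to the C row.
    site_of = np.full(L, -1, dtype=np.int64)
    site_of[site_pos] = np.arange(n_sites)
    if len(ref.cpg_pos):
        site_of[ref.cpg_pos + 1] = site_of[ref.cpg_pos]

    n_c = np.zeros((n_sites, width), dtype=np.int64)
    n_t = np.zeros((n_sites, width), dtype=np.int64)
    if len(reads) == 0:
        return SitePileup(site_pos, is_cpg, n_c, n_t, ref_name=ref.name)

    lengths = reads.lengths
    total = int(lengths.sum())
    within = np.arange(total, dtype=np.int64) - np.repeat(
        reads.offsets[:-1], lengths
    )
    refpos = np.repeat(reads.starts, lengths) + within
    rev_b = np.repeat(reads.strands, lengths)
    read_i = np.where(rev_b, np.repeat(lengths, lengths) - 1 - within, within)
    i_cap = np.minimum(read_i, I_MAX)
    obs = reads.base_codes

    refbase = codes[refpos]
    # Strand-matched cytosine context only.
    ctx = np.where(rev_b, refbase == _G, refbase == _C)
    # Complement reverse observations into C/T classes.
    as_c = ctx & np.where(rev_b, obs == _G, obs == _C)
    as_t = ctx & np.where(rev_b, obs == _A, obs == _T)

    for sel, target in ((as_c, n_c), (as_t, n_t)):
        rows = site_of[refpos[sel]]
        key = rows * width + i_cap[sel]
        target += np.bincount(
            key, minlength=n_sites * width
        ).reshape(n_sites, width)
    return SitePileup(site_pos, is_cpg, n_c, n_t, ref_name=ref.name)


def estimate_damage_profile(pileup: SitePileup) -> DamageProfile:
    """Estimate delta_u(i) from non-CpG cytosine sites.

    Non-CpG cytosines are assumed fully unmethylated (vertebrate
    non-CpG methylation is negligible), so the pooled T fraction at
    read position i estimates the unmethylated deamination rate
    there.  Positions without support are NaN.
    """
    non_cpg = ~pileup.is_cpg
    c = pileup.n_c[non_cpg].sum(axis=0)
    t = pileup.n_t[non_cpg].sum(axis=0)
    n = c + t
    if n.sum() == 0:
        raise ValueError("no non-CpG cytosine observations in pileup")
    with np.errstate(invalid="ignore"):
        delta = np.where(n > 0, t / np.maximum(n, 1), np.nan)
    return DamageProfile(delta_hat=delta, n_obs=n)


def mask_mutations(
    pileup: SitePileup,
    profile: DamageProfile,
    interior_start: int = 10,
    t_frac_threshold: float = 0.9,
    min_support: int = 5,
) -> SitePileup:
    """Flag CpG sites that are C>T (or complemented A>G) variants.

    At read positions ``i >= interior_start`` deamination is near the
    background rate, so a site whose interior T fraction reaches
    ``t_frac_threshold`` (with at least ``min_support`` interior
    observations) carries a genotype variant rather than methylation
    and is removed from downstream estimation.  Returns a new pileup
    with those sites masked; all counts are preserved.
    """
    if not 0 < interior_start <= I_MAX:
        raise ValueError("interior_start must be in (0, I_MAX]")
    if not 0.5 < t_frac_threshold <= 1.0:
        raise ValueError("t_frac_threshold must be in (0.5, 1]")
    c_int = pileup.n_c[:, interior_start:].sum(axis=1)
    t_int = pileup.n_t[:, interior_start:].sum(axis=1)
    n_int = c_int + t_int
    with np.errstate(invalid="ignore"):
        frac = np.where(n_int > 0, t_int / np.maximum(n_int, 1), 0.0)
    newly = pileup.is_cpg & (n_int >= min_support) & (
        frac >= t_frac_threshold
    )
    return SitePileup(
        site_pos=pileup.site_pos,
        is_cpg=pileup.is_cpg,
        n_c=pileup.n_c,
        n_t=pileup.n_t,
        ref_name=pileup.ref_name,
        i_max=pileup.i_max,
        masked=pileup.masked | newly,
    )
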