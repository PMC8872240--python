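"""Synthetic ancient-DNA data generation.

Produces a reference chromosome with planted CpG sites, a bimodal
vertebrate-like methylome, and sets of short fragments carrying
position-dependent post-mortem cytosine deamination.  All ground truth
(CpG coordinates, per-site methylation levels, damage parameters) is
known exactly, which makes these data suitable for validating
methylation estimators and coverage-titration experiments.

Conventions
-----------
* Coordinates are 0-based, half-open.
* Read-position index ``i`` is the distance from the read's own 5' end,
  capped at ``I_MAX`` (damage is terminal; beyond the cap the interior
  rate applies).
* Reverse-strand reads are stored as forward-frame observation strings:
  damage is applied in read frame (C->T on the read's own strand) and
  then projected, so reverse-strand deamination appears as G->A on the
  forward reference frame.
* The library is treated as double-stranded with symmetric damage on
  both strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "I_MAX",
    "ReferenceChrom",
    "Methylome",
    "DamageModel",
    "ReadSet",
    "generate_reference",
    "generate_methylome",
    "simulate_reads",
]

#: Cap on the read-position index used for damage tables.
I_MAX = 25

# Base encoding used internally: A=0, C=1, G=2, T=3, gap(deleted)=4.
_BASES = np.frombuffer(b"ACGT-", dtype=np.uint8)
_A, _C, _G, _T, _GAP = 0, 1, 2, 3, 4


@dataclass(frozen=True)
class ReferenceChrom:
    """A synthetic chromosome whose CpG sites are planted and exhaustive.

    The background sequence is generated free of CG dinucleotides, so
    ``cpg_pos`` (positions of the C of each forward-strand CpG) lists
    *every* CpG in ``seq``.
    """

    name: str
    seq: str
    cpg_pos: np.ndarray  # int64, strictly increasing

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "cpg_pos", np.asarray(self.cpg_pos, dtype=np.int64)
        )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def codes(self) -> np.ndarray:
        """Sequence as uint8 codes (A=0, C=1, G=2, T=3)."""
        raw = np.frombuffer(self.seq.encode("ascii"), dtype=np.uint8)
        lut = np.zeros(256, dtype=np.uint8)
        lut[ord("A")], lut[ord("C")] = _A, _C
        lut[ord("G")], lut[ord("T")] = _G, _T
        return lut[raw]

    def validate(self) -> None:
        if set(self.seq) - set("ACGT"):
            raise ValueError("sequence contains non-ACGT characters")
        if np.any(np.diff(self.cpg_pos) <= 0):
            raise ValueError("cpg_pos not strictly increasing")
        for p in self.cpg_pos:
            if self.seq[p : p + 2] != "CG":
                raise ValueError(f"position {p} is not a CpG")
        n_cg = self.seq.count("CG")
        if n_cg != len(self.cpg_pos):
            raise ValueError(
                f"{n_cg} CG dinucleotides in sequence but "
                f"{len(self.cpg_pos)} listed"
            )


@dataclass(frozen=True)
class Methylome:
    """True per-CpG methylation levels, constant within blocks of CpGs."""

    levels: np.ndarray  # float64 in [0, 1], one per CpG
    block_len: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "levels", np.asarray(self.levels, dtype=np.float64)
        )
        if self.levels.size and (
            self.levels.min() < 0.0 or self.levels.max() > 1.0
        ):
            raise ValueError("methylation levels must lie in [0, 1]")


@dataclass(frozen=True)
class DamageModel:
    """Generative model of post-mortem cytosine deamination.

    The unmethylated deamination probability decays geometrically from
    the fragment end::

        delta_u(i) = delta_bg + (delta_max - delta_bg) * decay**i

    and methylated cytosines deaminate faster by a constant factor::

        delta_m(i) = min(1, rho * delta_u(i))

    Parameters
    ----------
    delta_max : terminal unmethylated deamination probability.
    decay : per-position geometric decay factor, in (0, 1).
    delta_bg : interior background deamination rate.
    rho : ratio delta_m / delta_u (>= 1).
    eps : per-base sequencing error rate (uniform over the three
        alternative bases).
    mode : ``"non-UDG"`` (deaminated unmethylated C read as T) or
        ``"UDG"`` (uracils excised, leaving gaps; only 5mC-derived T
        survives).
    """

    delta_max: float = 0.30
    decay: float = 0.30
    delta_bg: float = 0.01
    rho: float = 2.0
    eps: float = 0.001
    mode: str = "non-UDG"

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta_max <= 1.0:
            raise ValueError("delta_max must be in [0, 1]")
        if not 0.0 < self.decay < 1.0:
            raise ValueError("decay must be in (0, 1)")
        if not 0.0 <= self.delta_bg <= 1.0:
            raise ValueError("delta_bg must be in [0, 1]")
        if self.rho < 1.0:
            raise ValueError("rho must be >= 1")
        if not 0.0 <= self.eps <= 0.25:
            raise ValueError("eps must be in [0, 0.25]")
        if self.mode not in ("non-UDG", "UDG"):
            raise ValueError("mode must be 'non-UDG' or 'UDG'")

    def delta_u(self, i: np.ndarray | int) -> np.ndarray:
        """Unmethylated deamination probability at read position i."""
        i = np.minimum(np.asarray(i), I_MAX)
        return self.delta_bg + (self.delta_max - self.delta_bg) * self.decay**i

    def delta_m(self, i: np.ndarray | int) -> np.ndarray:
        """Methylated deamination probability at read position i."""
        return np.minimum(1.0, self.rho * self.delta_u(i))


@dataclass
class ReadSet:
    """A set of simulated aligned fragments in forward-frame storage.

    ``base_codes`` concatenates the observation codes of all reads
    (A=0, C=1, G=2, T=3, 4=gap for UDG-excised bases); read ``k`` spans
    ``base_codes[offsets[k]:offsets[k] + lengths[k]]`` and aligns to
    reference positions ``starts[k] .. starts[k] + lengths[k]``.
    """

    starts: np.ndarray  # int64
    lengths: np.ndarray  # int64
    strands: np.ndarray  # bool, True = reverse
    base_codes: np.ndarray  # uint8, concatenated
    ref_length: int
    offsets: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        self.strands = np.asarray(self.strands, dtype=bool)
        self.base_codes = np.asarray(self.base_codes, dtype=np.uint8)
        self.offsets = np.concatenate(
            ([0], np.cumsum(self.lengths))
        ).astype(np.int64)

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def mean_cov(self) -> float:
        """Total aligned (non-gap) bases divided by reference length."""
        if self.ref_length == 0:
            return 0.0
        n_aligned = int(np.count_nonzero(self.base_codes != _GAP))
        return n_aligned / self.ref_length

    def bases(self, k: int) -> str:
        """Forward-frame observation string of read ``k`` ('-' = gap)."""
        codes = self.base_codes[self.offsets[k] : self.offsets[k + 1]]
        return _BASES[codes].tobytes().decode("ascii")

    def subset(self, keep: np.ndarray) -> "ReadSet":
        """New ReadSet with the reads selected by boolean mask ``keep``."""
        keep = np.asarray(keep, dtype=bool)
        base_mask = np.repeat(keep, self.lengths)
        return ReadSet(
            starts=self.starts[keep],
            lengths=self.lengths[keep],
            strands=self.strands[keep],
            base_codes=self.base_codes[base_mask],
            ref_length=self.ref_length,
        )


def _cg_free_background(length: int, rng: np.random.Generator) -> np.ndarray:
    """Random uint8 base codes of given length containing no CG pair."""
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    # A 'G' preceded by 'C' is resampled from {A, T}; replacing the G
    # cannot create a new CG, so one sweep converges.
    while True:
        bad = np.flatnonzero((codes[:-1] == _C) & (codes[1:] == _G)) + 1
        if bad.size == 0:
            return codes
        codes[bad] = rng.choice(
            np.array([_A, _T], dtype=np.uint8), size=bad.size
        )


def generate_reference(
    length: int, n_cpg: int, seed: int, name: str = "chrS"
) -> ReferenceChrom:
    """Generate a CG-free background with ``n_cpg`` planted CpG sites.

    CpG positions are sampled uniformly subject to a minimum spacing of
    3 bp between the C's of consecutive sites, so planted dinucleotides
    never overlap or abut.  Deterministic given ``seed``.
    """
    if length < 1000:
        raise ValueError("length must be >= 1000")
    if not 0 <= n_cpg <= length // 10:
        raise ValueError("n_cpg must be in [0, length/10]")
    gap = 3  # min distance between consecutive planted C positions
    # Positions range over [0, length-2] so the G fits; with minimum
    # spacing the feasibility condition is (n_cpg-1)*gap <= length-2.
    if n_cpg > 0 and (n_cpg - 1) * gap > length - 2:
        raise ValueError("n_cpg too dense to place without adjacency")
    rng = np.random.default_rng(seed)
    codes = _cg_free_background(length, rng)
    if n_cpg > 0:
        # Uniform sample of sorted positions with min gap: sample a
        # combination from the contracted range, then re-expand.
        contracted = length - 1 - (n_cpg - 1) * (gap - 1)
        picks = np.sort(
            rng.choice(contracted, size=n_cpg, replace=False)
        ).astype(np.int64)
        cpg_pos = picks + (gap - 1) * np.arange(n_cpg)
        codes[cpg_pos] = _C
        codes[cpg_pos + 1] = _G
        # Planting 'CG' cannot create a CpG elsewhere: the pair ends in
        # G (never a C followed by our G on the left of the plant) and
        # starts with C (x,C is never CG).
    else:
        cpg_pos = np.empty(0, dtype=np.int64)
    seq = _BASES[codes].tobytes().decode("ascii")
    return ReferenceChrom(name=name, seq=seq, cpg_pos=cpg_pos)


def generate_methylome(
    ref: ReferenceChrom,
    p_high: float = 0.75,
    beta_high: tuple[float, float] = (8.0, 2.0),
    beta_low: tuple[float, float] = (1.0, 9.0),
    block_len: int = 50,
    seed: int = 0,
) -> Methylome:
    """Draw a bimodal methylome over the reference's CpG sites.

    CpGs are partitioned into consecutive blocks of ``block_len`` sites.
    Each block is independently assigned a single level: with
    probability ``p_high`` a draw from ``Beta(*beta_high)`` (methylated
    compartment), otherwise from ``Beta(*beta_low)`` (unmethylated
    compartment, e.g. CpG islands).  Levels are shared across the block,
    mimicking the regional coherence of vertebrate methylomes.
    """
    if not 0.0 <= p_high <= 1.0:
        raise ValueError("p_high must be in [0, 1]")
    if min(beta_high) <= 0 or min(beta_low) <= 0:
        raise ValueError("beta parameters must be > 0")
    if block_len < 1:
        raise ValueError("block_len must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(ref.cpg_pos)
    n_blocks = -(-n // block_len) if n else 0
    is_high = rng.random(n_blocks) < p_high
    levels_block = np.where(
        is_high,
        rng.beta(*beta_high, size=n_blocks),
        rng.beta(*beta_low, size=n_blocks),
    )
    levels = np.repeat(levels_block, block_len)[:n]
    return Methylome(levels=levels, block_len=block_len)


def _truncated_lognorm_mean(
    logmu: float, logsigma: float, lo: float, hi: float
) -> float:
    """Mean of a lognormal truncated to [lo, hi]."""
    # Partial expectation of the lognormal in closed form.
    phi = stats.norm.cdf
    num = np.exp(logmu + logsigma**2 / 2) * (
        phi((np.log(hi) - logmu - logsigma**2) / logsigma)
        - phi((np.log(lo) - logmu - logsigma**2) / logsigma)
    )
    den = phi((np.log(hi) - logmu) / logsigma) - phi(
        (np.log(lo) - logmu) / logsigma
    )
    return float(num / den)


def _sample_fraglens(
    n: int, logmu: float, logsigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Lognormal fragment lengths truncated to [20, 150] by inverse CDF."""
    lo = stats.norm.cdf((np.log(20.0) - logmu) / logsigma)
    hi = stats.norm.cdf((np.log(150.0) - logmu) / logsigma)
    u = rng.uniform(lo, hi, size=n)
    lens = np.exp(logmu + logsigma * stats.norm.ppf(u))
    return np.clip(np.round(lens), 20, 150).astype(np.int64)


def simulate_reads(
    ref: ReferenceChrom,
    meth: Methylome,
    dmg: DamageModel,
    mean_cov: float,
    fraglen_logmu: float = 4.0,
    fraglen_logsigma: float = 0.35,
    seed: int = 0,
) -> ReadSet:
    """Simulate aligned aDNA fragments with deamination damage.

    The fragment count is Poisson with mean chosen so the realized
    coverage approximates ``mean_cov``; starts and strands are uniform.
    Damage is applied per cytosine of the fragment's own strand at
    read-frame distance ``i`` from its 5' end: a CpG cytosine at site
    ``s`` converts with probability ``m_s*delta_m(i) +
    (1-m_s)*delta_u(i)`` (non-UDG), any other cytosine with
    ``delta_u(i)``.  In UDG mode deaminated unmethylated cytosines are
    excised (gap), while 5mC-derived thymines survive.  Sequencing error
    ``eps`` then hits every emitted base independently.
    """
    if mean_cov < 0:
        raise ValueError("mean_cov must be >= 0")
    if mean_cov > 10000:
        raise ValueError("mean_cov > 10000: refusing runaway simulation")
    if len(meth.levels) != len(ref.cpg_pos):
        raise ValueError("methylome does not match reference CpG count")

    rng = np.random.default_rng(seed)
    L = len(ref)
    empty = ReadSet(
        starts=np.empty(0, dtype=np.int64),
        lengths=np.empty(0, dtype=np.int64),
        strands=np.empty(0, dtype=bool),
        base_codes=np.empty(0, dtype=np.uint8),
        ref_length=L,
    )
    if mean_cov == 0:
        return empty
    mean_len = _truncated_lognorm_mean(
        fraglen_logmu, fraglen_logsigma, 20.0, 150.0
    )
    n_frags = rng.poisson(mean_cov * L / mean_len)
    if n_frags == 0:
        return empty
    lengths = _sample_fraglens(n_frags, fraglen_logmu, fraglen_logsigma, rng)
    lengths = np.minimum(lengths, L)
    starts = (rng.random(n_frags) * (L - lengths + 1)).astype(np.int64)
    rev = rng.random(n_frags) < 0.5

    offsets = np.concatenate(([0], np.cumsum(lengths)))
    total = int(offsets[-1])
    # Flat arrays over all read bases.
    within = np.arange(total, dtype=np.int64) - np.repeat(
        offsets[:-1], lengths
    )
    refpos = np.repeat(starts, lengths) + within
    rev_b = np.repeat(rev, lengths)
    read_i = np.where(rev_b, np.repeat(lengths, lengths) - 1 - within, within)
    i_cap = np.minimum(read_i, I_MAX)

    obs = ref.codes[refpos].copy()  # forward-frame observations

    # Per-reference-position lookup of methylation (CpG C and its G).
    m_at = np.full(L, -1.0)
    if len(ref.cpg_pos):
        m_at[ref.cpg_pos] = meth.levels
        m_at[ref.cpg_pos + 1] = meth.levels  # symmetric CpG methylation

    # Cytosines in read frame: forward read over ref C, reverse over ref G.
    is_read_c = np.where(rev_b, obs == _G, obs == _C)
    # For those, the relevant CpG level: forward uses m_at[pos] when the
    # pos is a CpG C; reverse uses m_at[pos] when pos is a CpG G.  The
    # m_at table covers both; non-CpG cytosines have m_at == -1.
    m_here = m_at[refpos]
    is_cpg_c = is_read_c & (m_here >= 0)

    du = dmg.delta_u(i_cap)
    dm = dmg.delta_m(i_cap)
    u = rng.random(total)
    m_eff = np.where(is_cpg_c, m_here, 0.0)
    if dmg.mode == "non-UDG":
        p_conv = m_eff * dm + (1.0 - m_eff) * du
        deam = is_read_c & (u < p_conv)
        # Read-frame C->T projects to forward-frame T (fwd) or A (rev).
        obs[deam & ~rev_b] = _T
        obs[deam & rev_b] = _A
    else:  # UDG: methylated deamination -> T, unmethylated -> excised gap
        p_t = m_eff * dm
        p_gap = (1.0 - m_eff) * du
        to_t = is_read_c & (u < p_t)
        to_gap = is_read_c & ~to_t & (u < p_t + p_gap)
        obs[to_t & ~rev_b] = _T
        obs[to_t & rev_b] = _A
        obs[to_gap] = _GAP

    # Sequencing error on every emitted (non-gap) base: uniform over the
    # three alternatives; the alternative set is symmetric under strand
    # complement, so errors are drawn directly in the forward frame.
    emitted = obs != _GAP
    err = emitted & (rng.random(total) < dmg.eps)
    n_err = int(np.count_nonzero(err))
    if n_err:
        shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
        obs[err] = (obs[err] + shift) % 4

    return ReadSet(
        starts=starts,
        lengths=lengths,
        strands=rev,
        base_codes=obs,
        ref_length=L,
    )
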