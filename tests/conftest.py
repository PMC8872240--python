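"""Shared fixtures: small synthetic datasets built at test time."""

from __future__ import annotations

import numpy as np
import pytest

import paleometh as pm


@pytest.fixture(scope="session")
def small_ref() -> pm.ReferenceChrom:
    """20 kb reference with 200 planted CpGs."""
    return pm.generate_reference(20_000, 200, seed=11)


@pytest.fixture(scope="session")
def small_meth(small_ref) -> pm.Methylome:
    return pm.generate_methylome(small_ref, block_len=20, seed=12)


@pytest.fixture(scope="session")
def default_damage() -> pm.DamageModel:
    return pm.DamageModel()


@pytest.fixture(scope="session")
def tiny_config() -> pm.ExperimentConfig:
    """Down-scaled experiment used for orchestration tests."""
    return pm.ExperimentConfig(
        ref_length=60_000,
        n_cpg=600,
        full_cov=8.0,
        grid=(1, 3, 5),
        seed=5,
        name="tiny",
    )


def hand_reference() -> pm.ReferenceChrom:
    """Tiny hand-written reference: one CpG at 2, non-CpG C at 7, G at 10."""
    #       0123456789012
    seq = "AACGTTACTTGA"
    return pm.ReferenceChrom(name="mini", seq=seq, cpg_pos=np.array([2]))


def make_readset(ref: pm.ReferenceChrom, reads: list[tuple[int, str, str]]):
    """Build a ReadSet from (start, strand, forward-frame bases) tuples."""
    lut = {c: i for i, c in enumerate("ACGT-")}
    starts = np.array([r[0] for r in reads], dtype=np.int64)
    strands = np.array([r[1] == "-" for r in reads], dtype=bool)
    lengths = np.array([len(r[2]) for r in reads], dtype=np.int64)
    codes = np.array(
        [lut[c] for r in reads for c in r[2]], dtype=np.uint8
    ) if reads else np.empty(0, dtype=np.uint8)
    return pm.ReadSet(
        starts=starts,
        lengths=lengths,
        strands=strands,
        base_codes=codes,
        ref_length=len(ref),
    )
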