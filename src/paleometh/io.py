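"""Readers and writers for the package's on-disk formats.

TSV dialect: tab-separated columns, a single ``#``-prefixed header line
naming the columns (preceded by optional ``## key=value`` metadata
lines), and ``.`` for missing values.  bedGraph follows the UCSC
convention (0-based, half-open).  FASTA goes through Biopython; SAM
emission/ingestion goes through pysam and exists for interoperability
only.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .methylation import FTrack
from .pileup import DamageProfile, SitePileup
from .precision import CoverageRecommendation, PrecisionTable, TrendFit
from .simulate import I_MAX, Methylome, ReadSet, ReferenceChrom

__all__ = [
    "write_fasta", "read_fasta",
    "write_methylome_tsv", "read_methylome_tsv",
    "write_reads_tsv", "read_reads_tsv",
    "write_sam", "read_sam",
    "write_pileup_tsv", "read_pileup_tsv",
    "write_profile_tsv", "read_profile_tsv",
    "write_ftrack_tsv", "read_ftrack_tsv",
    "write_bedgraph",
    "write_precision_tsv", "write_trendfit_tsv", "write_recommendation_tsv",
]

MISSING = "."


def _meta_and_header(path: Path) -> tuple[dict, list[str], list[list[str]]]:
    meta: dict[str, str] = {}
    header: list[str] = []
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                key, _, val = line[2:].strip().partition("=")
                meta[key] = val
            elif line.startswith("#"):
                header = line[1:].split("\t")
            else:
                fields = line.split("\t")
                if header and len(fields) != len(header):
                    raise ValueError(
                        f"{path}: line {lineno}: expected "
                        f"{len(header)} fields, got {len(fields)}"
                    )
                rows.append(fields)
    return meta, header, rows


# ---------------------------------------------------------------- FASTA

def write_fasta(ref: ReferenceChrom, path: str | Path) -> None:
    rec = SeqRecord(Seq(ref.seq), id=ref.name, description="")
    SeqIO.write([rec], str(path), "fasta")


def read_fasta(path: str | Path) -> ReferenceChrom:
    """Load a reference; CpG positions are re-derived from the sequence."""
    rec = next(SeqIO.parse(str(path), "fasta"))
    seq = str(rec.seq).upper()
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    cpg = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
    return ReferenceChrom(name=rec.id, seq=seq, cpg_pos=cpg.astype(np.int64))


# ------------------------------------------------------------ methylome

def write_methylome_tsv(
    meth: Methylome, ref: ReferenceChrom, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(f"## ref={ref.name}\n")
        fh.write(f"## block_len={meth.block_len}\n")
        fh.write("#pos\tlevel\n")
        for p, m in zip(ref.cpg_pos, meth.levels):
            fh.write(f"{p}\t{m:.6f}\n")


def read_methylome_tsv(path: str | Path) -> tuple[np.ndarray, Methylome]:
    meta, _, rows = _meta_and_header(Path(path))
    pos = np.array([int(r[0]) for r in rows], dtype=np.int64)
    lev = np.array([float(r[1]) for r in rows])
    return pos, Methylome(levels=lev, block_len=int(meta.get("block_len", 1)))


# ---------------------------------------------------------------- reads

def write_reads_tsv(reads: ReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"## ref_length={reads.ref_length}\n")
        fh.write("#start\tstrand\tbases\n")
        for k in range(len(reads)):
            strand = "-" if reads.strands[k] else "+"
            fh.write(f"{reads.starts[k]}\t{strand}\t{reads.bases(k)}\n")


def read_reads_tsv(path: str | Path) -> ReadSet:
    meta, _, rows = _meta_and_header(Path(path))
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT-"):
        lut[b] = i
    starts, strands, codes, lengths = [], [], [], []
    for r in rows:
        starts.append(int(r[0]))
        strands.append(r[1] == "-")
        bc = lut[np.frombuffer(r[2].encode(), dtype=np.uint8)]
        if np.any(bc == 255):
            raise ValueError(f"invalid base in read at start {r[0]}")
        codes.append(bc)
        lengths.append(len(bc))
    return ReadSet(
        starts=np.array(starts, dtype=np.int64),
        lengths=np.array(lengths, dtype=np.int64),
        strands=np.array(strands, dtype=bool),
        base_codes=(
            np.concatenate(codes) if codes else np.empty(0, dtype=np.uint8)
        ),
        ref_length=int(meta.get("ref_length", 0)),
    )


# ------------------------------------------------------------------ SAM

def write_sam(
    reads: ReadSet, ref: ReferenceChrom, path: str | Path
) -> None:
    """Emit reads as an aligned SAM file (gaps become deletion CIGARs)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": ref.name, "LN": len(ref)}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for k in range(len(reads)):
            bases = reads.bases(k)
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"frag{k}"
            a.reference_id = 0
            a.reference_start = int(reads.starts[k])
            a.mapping_quality = 60
            a.flag = 16 if reads.strands[k] else 0
            seq_parts, cigar = [], []
            for ch in bases:
                if ch == "-":
                    if cigar and cigar[-1][0] == 2:
                        cigar[-1] = (2, cigar[-1][1] + 1)
                    else:
                        cigar.append((2, 1))
                else:
                    seq_parts.append(ch)
                    if cigar and cigar[-1][0] == 0:
                        cigar[-1] = (0, cigar[-1][1] + 1)
                    else:
                        cigar.append((0, 1))
            a.query_sequence = "".join(seq_parts)
            a.cigartuples = cigar
            out.write(a)


def read_sam(path: str | Path) -> ReadSet:
    """Ingest aligned SAM back into a forward-frame ReadSet."""
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT-"):
        lut[b] = i
    starts, strands, codes, lengths = [], [], [], []
    ref_length = 0
    with pysam.AlignmentFile(str(path), "r") as fh:
        ref_length = fh.header.to_dict()["SQ"][0]["LN"]
        for a in fh:
            if a.is_unmapped:
                continue
            seq = a.query_sequence
            out = []
            qpos = 0
            for op, ln in a.cigartuples:
                if op == 0:  # M
                    out.append(seq[qpos : qpos + ln])
                    qpos += ln
                elif op == 2:  # D -> gap placeholders
                    out.append("-" * ln)
                else:
                    raise ValueError(f"unsupported CIGAR op {op}")
            bc = lut[np.frombuffer("".join(out).encode(), dtype=np.uint8)]
            starts.append(a.reference_start)
            strands.append(a.is_reverse)
            codes.append(bc)
            lengths.append(len(bc))
    return ReadSet(
        starts=np.array(starts, dtype=np.int64),
        lengths=np.array(lengths, dtype=np.int64),
        strands=np.array(strands, dtype=bool),
        base_codes=(
            np.concatenate(codes) if codes else np.empty(0, dtype=np.uint8)
        ),
        ref_length=ref_length,
    )


# --------------------------------------------------------------- pileup

def write_pileup_tsv(pileup: SitePileup, path: str | Path) -> None:
    """Write nonzero count cells; every CpG site appears at least once.

    Sites absent from the file are zero-count non-CpG sites; the reader
    therefore reconstructs a pileup whose site table is the set of
    written sites.
    """
    with open(path, "w") as fh:
        fh.write(f"## ref={pileup.ref_name}\n")
        fh.write(f"## i_max={pileup.i_max}\n")
        fh.write("#site_pos\tis_cpg\tread_pos\tn_C\tn_T\tmasked\n")
        nz = (pileup.n_c + pileup.n_t) > 0
        nz[pileup.is_cpg, 0] = True  # keep every CpG site present
        for s, i in zip(*np.nonzero(nz)):
            fh.write(
                f"{pileup.site_pos[s]}\t{int(pileup.is_cpg[s])}\t{i}\t"
                f"{pileup.n_c[s, i]}\t{pileup.n_t[s, i]}\t"
                f"{int(pileup.masked[s])}\n"
            )


def read_pileup_tsv(path: str | Path) -> SitePileup:
    path = Path(path)
    meta: dict[str, str] = {}
    header_seen = False
    recs: list[tuple[int, int, int, int, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                key, _, val = line[2:].strip().partition("=")
                meta[key] = val
                continue
            if line.startswith("#"):
                header_seen = True
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(
                    f"{path}: line {lineno}: expected 6 fields, "
                    f"got {len(fields)}"
                )
            try:
                recs.append(tuple(int(x) for x in fields))
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: {exc}"
                ) from None
    if not header_seen:
        raise ValueError(f"{path}: missing '#'-prefixed header line")
    i_max = int(meta.get("i_max", I_MAX))
    arr = np.array(recs, dtype=np.int64).reshape(-1, 6)
    site_pos = (
        np.unique(arr[:, 0]) if len(arr) else np.empty(0, dtype=np.int64)
    )
    row = np.searchsorted(site_pos, arr[:, 0]) if len(arr) else []
    n = len(site_pos)
    is_cpg = np.zeros(n, dtype=bool)
    masked = np.zeros(n, dtype=bool)
    n_c = np.zeros((n, i_max + 1), dtype=np.int64)
    n_t = np.zeros((n, i_max + 1), dtype=np.int64)
    for (pos, cpg, i, c, t, m), r in zip(recs, row):
        is_cpg[r] = bool(cpg)
        masked[r] = masked[r] or bool(m)
        n_c[r, i] += c
        n_t[r, i] += t
    return SitePileup(
        site_pos=site_pos,
        is_cpg=is_cpg,
        n_c=n_c,
        n_t=n_t,
        ref_name=meta.get("ref", ""),
        i_max=i_max,
        masked=masked,
    )


# -------------------------------------------------------------- profile

def write_profile_tsv(profile: DamageProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#read_pos\tdelta_hat\tn_obs\n")
        for i, (d, n) in enumerate(zip(profile.delta_hat, profile.n_obs)):
            val = MISSING if np.isnan(d) else f"{d:.6f}"
            fh.write(f"{i}\t{val}\t{n}\n")


def read_profile_tsv(path: str | Path) -> DamageProfile:
    _, _, rows = _meta_and_header(Path(path))
    n = len(rows)
    delta = np.full(n, np.nan)
    nobs = np.zeros(n, dtype=np.int64)
    for r in rows:
        i = int(r[0])
        delta[i] = np.nan if r[1] == MISSING else float(r[1])
        nobs[i] = int(r[2])
    return DamageProfile(delta_hat=delta, n_obs=nobs)


# --------------------------------------------------------------- FTrack

def write_ftrack_tsv(track: FTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"## ref={track.ref_name}\n")
        fh.write(f"## ncpg={track.ncpg_window}\n")
        fh.write(f"## coverage={track.coverage_label:g}\n")
        fh.write("#pos\tf_hat\tn_obs\n")
        for p, f, n in zip(track.positions, track.f_hat, track.n_obs):
            val = MISSING if np.isnan(f) else f"{f:.6f}"
            fh.write(f"{p}\t{val}\t{n}\n")


def read_ftrack_tsv(path: str | Path) -> FTrack:
    meta, _, rows = _meta_and_header(Path(path))
    pos = np.array([int(r[0]) for r in rows], dtype=np.int64)
    f = np.array(
        [np.nan if r[1] == MISSING else float(r[1]) for r in rows]
    )
    n = np.array([int(r[2]) for r in rows], dtype=np.int64)
    return FTrack(
        positions=pos,
        f_hat=f,
        n_obs=n,
        ncpg_window=int(meta.get("ncpg", 0)),
        coverage_label=float(meta.get("coverage", "nan")),
        ref_name=meta.get("ref", ""),
    )


def write_bedgraph(track: FTrack, path: str | Path) -> None:
    """UCSC bedGraph of f over CpG dinucleotides (missing sites skipped)."""
    with open(path, "w") as fh:
        fh.write(
            f'track type=bedGraph name="f_{track.coverage_label:g}x"\n'
        )
        for p, f in zip(track.positions, track.f_hat):
            if not np.isnan(f):
                fh.write(f"{track.ref_name}\t{p}\t{p + 2}\t{f:.6f}\n")


# ------------------------------------------------------------ precision

def write_precision_tsv(table: PrecisionTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#level\tsd_delta_f\tn_compared\tn_noncovered\n")
        for lev, sd, nc, nn in zip(
            table.levels, table.sd_delta_f, table.n_compared,
            table.n_noncovered,
        ):
            fh.write(f"{lev:g}\t{sd:.6f}\t{nc}\t{nn}\n")


def write_trendfit_tsv(fit: TrendFit, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#form\tparams\tr_squared\tdegenerate\n")
        params = ",".join(f"{k}={v:.6g}" for k, v in fit.params.items())
        fh.write(
            f"{fit.form}\t{params}\t{fit.r_squared:.6f}\t"
            f"{int(fit.degenerate)}\n"
        )


def write_recommendation_tsv(
    rec: CoverageRecommendation, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#ref_level\tsd_ref\tfactor\tthreshold\trecommended_level\n"
        )
        level = (
            MISSING
            if rec.recommended_level is None
            else f"{rec.recommended_level:g}"
        )
        fh.write(
            f"{rec.ref_level:g}\t{rec.sd_ref:.6f}\t{rec.factor:g}\t"
            f"{rec.threshold:.6f}\t{level}\n"
        )
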