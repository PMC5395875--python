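"""Domain types and on-disk formats for loci, sequences, peak tables and Hi-C matrices.

Coordinates are 0-based half-open internally (BED convention). Readers for
formats whose conventions differ (e.g. 1-based inclusive coordinate strings
in FASTA headers) accept a ``dialect`` flag.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

DNA_ALPHABET = ("A", "C", "G", "T")
#: characters legal in a stored locus sequence (N marks ambiguity, never counted)
VALID_SEQ_CHARS = frozenset("ACGTN")

_COORD_RE = re.compile(r"^(?P<chrom>[\w.]+):(?P<start>\d+)-(?P<end>\d+)$")


@dataclass(frozen=True)
class GenomicLocus:
    """A genomic interval with a stable identifier.

    ``start``/``end`` follow the 0-based half-open convention, so
    ``length == end - start``.
    """

    chrom: str
    start: int
    end: int
    id: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"locus {self.id!r}: need 0 <= start < end, got {self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def distance_to(self, other: "GenomicLocus") -> float:
        """Edge-to-edge distance in bp; 0 when overlapping, inf across chromosomes."""
        if self.chrom != other.chrom:
            return math.inf
        if self.end <= other.start:
            return other.start - self.end
        if other.end <= self.start:
            return self.start - other.end
        return 0


@dataclass(frozen=True)
class LocusSequence:
    """A DNA sequence attached to its locus; uppercased A/C/G/T with N allowed."""

    locus: GenomicLocus
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"locus {self.locus.id!r}: empty sequence")
        bad = set(self.seq) - VALID_SEQ_CHARS
        if bad:
            raise ValueError(
                f"locus {self.locus.id!r}: invalid sequence character(s) "
                f"{sorted(bad)!r}; only A/C/G/T/N are accepted"
            )
        if len(self.seq) != self.locus.length:
            raise ValueError(
                f"locus {self.locus.id!r}: sequence length {len(self.seq)} != "
                f"locus length {self.locus.length}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PeakRecord:
    row_id: str
    col_id: str
    replicate: str
    called: bool
    fdr: float


@dataclass
class ReplicatePeakTable:
    """Per-replicate peak calls for (row locus, column locus) pairs.

    One record per (row, col, replicate, fdr level); duplicates are rejected.
    """

    records: list[PeakRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for r in self.records:
            key = (r.row_id, r.col_id, r.replicate, r.fdr)
            if key in seen:
                raise ValueError(f"duplicate peak record {key}")
            seen.add(key)

    @property
    def replicates(self) -> list[str]:
        return sorted({r.replicate for r in self.records})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.row_id, r.col_id, r.replicate, r.called, r.fdr) for r in self.records],
            columns=["row_id", "col_id", "replicate", "called", "fdr"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReplicatePeakTable":
        recs = [
            PeakRecord(
                str(row.row_id),
                str(row.col_id),
                str(row.replicate),
                _parse_bool(row.called),
                float(row.fdr),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(recs)


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in {"1", "true", "t", "yes"}:
        return True
    if s in {"0", "false", "f", "no"}:
        return False
    raise ValueError(f"cannot interpret {v!r} as a boolean peak call")


@dataclass
class SparseContactMatrix:
    """Sparse intra-chromosomal contact matrix at one resolution.

    Entries are stored upper-triangular (``bin_i <= bin_j``) in bp start
    coordinates that are multiples of ``resolution``. ``norm_vector[b]`` is the
    balancing factor for the bin starting at ``b * resolution``; NaN marks a
    bin that could not be balanced.
    """

    resolution: int
    chrom: str
    bin_i: np.ndarray
    bin_j: np.ndarray
    counts: np.ndarray
    norm_vector: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bin_i = np.asarray(self.bin_i, dtype=np.int64)
        self.bin_j = np.asarray(self.bin_j, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if not (len(self.bin_i) == len(self.bin_j) == len(self.counts)):
            raise ValueError("bin_i, bin_j and counts must have equal length")
        if np.any(self.counts < 0):
            raise ValueError("negative contact counts are not allowed")
        if np.any(self.bin_i % self.resolution) or np.any(self.bin_j % self.resolution):
            raise ValueError(f"bin coordinates must be multiples of {self.resolution}")
        # canonical upper-triangular storage, merged duplicates
        lo = np.minimum(self.bin_i, self.bin_j)
        hi = np.maximum(self.bin_i, self.bin_j)
        order = np.lexsort((hi, lo))
        lo, hi, cnt = lo[order], hi[order], self.counts[order]
        if len(lo):
            keys = lo * (hi.max() + 1) + hi if len(hi) else lo
            uniq, first = np.unique(keys, return_index=True)
            if len(uniq) != len(keys):
                # duplicates legal only if they agree (symmetric (i,j)/(j,i) lines)
                grp = np.searchsorted(uniq, keys)
                for g in range(len(uniq)):
                    vals = cnt[grp == g]
                    if not np.allclose(vals, vals[0]):
                        raise ValueError(
                            f"conflicting duplicate entries for bin pair "
                            f"({lo[grp == g][0]}, {hi[grp == g][0]})"
                        )
                lo, hi, cnt = lo[first], hi[first], cnt[first]
        self.bin_i, self.bin_j, self.counts = lo, hi, cnt
        if self.norm_vector is not None:
            self.norm_vector = np.asarray(self.norm_vector, dtype=np.float64)
            max_idx = int(self.bin_j.max() // self.resolution) if len(self.bin_j) else -1
            if len(self.norm_vector) <= max_idx:
                raise ValueError(
                    f"normalization vector of length {len(self.norm_vector)} does not "
                    f"cover maximum bin index {max_idx}"
                )

    @property
    def n_entries(self) -> int:
        return len(self.counts)

    def bin_index(self, bp: int) -> int:
        return bp // self.resolution


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _locus_from_header(rec_id: str, description: str, seq_len: int, dialect: str) -> GenomicLocus:
    """Parse ``id chrom:start-end`` headers; fall back to a coordinate-free locus."""
    fields = description.split()
    coord = None
    for tok in fields[1:]:
        m = _COORD_RE.match(tok)
        if m:
            coord = m
            break
    if coord is None and len(fields) > 1:
        raise ValueError(
            f"malformed FASTA header {description!r}: expected 'id chrom:start-end'"
        )
    if coord is None:
        return GenomicLocus(chrom="unknown", start=0, end=seq_len, id=rec_id)
    start = int(coord["start"])
    end = int(coord["end"])
    if dialect == "one-based":
        start -= 1
    elif dialect != "bed":
        raise ValueError(f"unknown coordinate dialect {dialect!r}")
    return GenomicLocus(chrom=coord["chrom"], start=start, end=end, id=rec_id)


def read_fasta(
    path: str | Path,
    bed: str | Path | None = None,
    dialect: str = "bed",
) -> list[LocusSequence]:
    """Read locus sequences from FASTA.

    Headers of the form ``>id chrom:start-end`` carry coordinates directly
    (``dialect='bed'`` for 0-based half-open, ``'one-based'`` for 1-based
    inclusive as printed in publications). Plain ``>id`` headers may be paired
    with a companion BED file mapping ids to coordinates.
    """
    path = Path(path)
    bed_loci = {l.id: l for l in read_bed(bed)} if bed is not None else {}
    out: list[LocusSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_SEQ_CHARS
        if bad:
            raise ValueError(
                f"record {rec.id!r}: invalid character(s) {sorted(bad)!r} in sequence"
            )
        if rec.id in bed_loci:
            locus = bed_loci[rec.id]
            if locus.length != len(seq):
                raise ValueError(
                    f"record {rec.id!r}: sequence length {len(seq)} inconsistent "
                    f"with BED interval length {locus.length}"
                )
        else:
            locus = _locus_from_header(rec.id, rec.description, len(seq), dialect)
        out.append(LocusSequence(locus=locus, seq=seq))
    if not out:
        logger.warning("FASTA file %s contained no records", path)
    return out


def write_fasta(path: str | Path, seqs: Iterable[LocusSequence]) -> None:
    records = [
        SeqRecord(
            Seq(s.seq),
            id=s.locus.id,
            description=f"{s.locus.id} {s.locus.chrom}:{s.locus.start}-{s.locus.end}",
        )
        for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicLocus]:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "id"],
        usecols=[0, 1, 2, 3],
        dtype={"chrom": str, "id": str},
    )
    loci = [
        GenomicLocus(row.chrom, int(row.start), int(row.end), row.id)
        for row in df.itertuples(index=False)
    ]
    ids = [l.id for l in loci]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate locus ids in {path}")
    return loci


def write_bed(path: str | Path, loci: Iterable[GenomicLocus]) -> None:
    with open(path, "w") as fh:
        for l in loci:
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{l.id}\n")


# ---------------------------------------------------------------------------
# Peak tables
# ---------------------------------------------------------------------------

def read_peak_table(path: str | Path) -> ReplicatePeakTable:
    df = pd.read_csv(path, sep="\t")
    required = {"row_id", "col_id", "replicate", "called", "fdr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peak table {path} missing column(s) {sorted(missing)}")
    return ReplicatePeakTable.from_frame(df)


def write_peak_table(path: str | Path, table: ReplicatePeakTable) -> None:
    df = table.to_frame()
    df["called"] = df["called"].map({True: "1", False: "0"})
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Hi-C triplets
# ---------------------------------------------------------------------------

def read_sparse_hic(
    path_matrix: str | Path,
    path_norm: str | Path | None,
    resolution: int,
    chrom: str,
) -> SparseContactMatrix:
    """Read a whitespace-separated (bin_i, bin_j, count) triplet file plus an
    optional one-factor-per-line balancing vector."""
    df = pd.read_csv(
        path_matrix,
        sep=r"\s+",
        header=None,
        names=["bin_i", "bin_j", "count"],
        dtype={"bin_i": np.int64, "bin_j": np.int64, "count": np.float64},
    )
    norm = None
    if path_norm is not None:
        norm = np.loadtxt(path_norm, dtype=np.float64, ndmin=1)
    return SparseContactMatrix(
        resolution=resolution,
        chrom=chrom,
        bin_i=df["bin_i"].to_numpy(),
        bin_j=df["bin_j"].to_numpy(),
        counts=df["count"].to_numpy(),
        norm_vector=norm,
    )


def write_sparse_hic(
    path_matrix: str | Path,
    m: SparseContactMatrix,
    path_norm: str | Path | None = None,
) -> None:
    with open(path_matrix, "w") as fh:
        for i, j, c in zip(m.bin_i, m.bin_j, m.counts):
            c_str = str(int(c)) if float(c).is_integer() else repr(float(c))
            fh.write(f"{i}\t{j}\t{c_str}\n")
    if path_norm is not None:
        if m.norm_vector is None:
            raise ValueError("matrix has no normalization vector to write")
        np.savetxt(path_norm, m.norm_vector, fmt="%.10g")


# ---------------------------------------------------------------------------
# Predictions
# ---------------------------------------------------------------------------

def write_predictions(
    path: str | Path,
    records: Sequence[tuple[str, float, int]],
) -> None:
    """Write (locus_id, decision_value, predicted_label) rows as TSV,
    ordered by locus id."""
    for locus_id, dv, _ in records:
        if not np.isfinite(dv):
            raise ValueError(f"non-finite decision value for locus {locus_id!r}")
    with open(path, "w") as fh:
        fh.write("locus_id\tdecision_value\tpredicted_label\n")
        for locus_id, dv, label in sorted(records, key=lambda r: r[0]):
            fh.write(f"{locus_id}\t{dv:.10g}\t{label:d}\n")


def read_predictions(path: str | Path) -> list[tuple[str, float, int]]:
    df = pd.read_csv(path, sep="\t")
    return [
        (str(r.locus_id), float(r.decision_value), int(r.predicted_label))
        for r in df.itertuples(index=False)
    ]
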