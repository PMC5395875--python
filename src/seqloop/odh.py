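"""Oligomer distance histogram (ODH) features and the linear ODH kernel.

A sequence s over the DNA alphabet is represented by counting, for every
ordered pair of K-mers (m_i, m_j) and every separation d in {0..D}, the
number of occurrence pairs at start positions p1 <= p2 with p2 - p1 = d,
m_i at p1 and m_j at p2. Concatenating the histograms over all M^2 K-mer
pairs gives a fixed-length vector Phi(s) of dimension M^2 * (D+1) with
M = 4^K; the kernel between two sequences is the plain inner product
Phi(a) . Phi(b), so a sequence kernel matrix is X^T X for the stacked
feature matrix X.

Separation d = 0 holds the self-pairs: each K-mer occurrence paired with
itself, so only diagonal (i == i) keys occur at d = 0. K-mer occurrences
overlapping a non-ACGT character contribute nothing. Occurrence pairs
further apart than D are dropped.

Feature vectors are stored sparsely as sorted flat integer keys
``(i * M + j) * (D + 1) + d`` with integer counts; this keeps the K = 5
case (dimension 105,906,176) tractable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .genomic import DNA_ALPHABET, LocusSequence

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(DNA_ALPHABET):
    _BASE_CODE[ord(_b)] = _i


@dataclass(frozen=True)
class ODHConfig:
    """Parameters of the ODH feature space.

    K
        oligomer length (3 and 5 are the typical working values).
    D
        maximum separation between K-mer start positions, in bp (default 100).
    """

    K: int
    D: int = 100
    alphabet: tuple[str, ...] = DNA_ALPHABET
    l2_normalize: bool = False

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.D < 0:
            raise ValueError("D must be >= 0")

    @property
    def n_kmers(self) -> int:
        """M = |alphabet|^K, the number of distinct K-mers."""
        return len(self.alphabet) ** self.K

    @property
    def dimension(self) -> int:
        """Total feature dimension M^2 * (D + 1)."""
        return self.n_kmers ** 2 * (self.D + 1)

    def key(self, i: int, j: int, d: int) -> int:
        """Flat index of the (K-mer i, K-mer j, separation d) coordinate."""
        M = self.n_kmers
        if not (0 <= i < M and 0 <= j < M and 0 <= d <= self.D):
            raise ValueError(f"({i}, {j}, {d}) outside feature space bounds")
        return (i * M + j) * (self.D + 1) + d

    def unkey(self, key: int) -> tuple[int, int, int]:
        M = self.n_kmers
        pair, d = divmod(int(key), self.D + 1)
        i, j = divmod(pair, M)
        return i, j, d


def kmer_index(kmer: str, config: ODHConfig) -> int:
    """Bijective base-4 encoding of a K-mer (A=0, C=1, G=2, T=3, MSB first)."""
    if len(kmer) != config.K:
        raise ValueError(f"K-mer {kmer!r} has length {len(kmer)}, expected {config.K}")
    idx = 0
    for ch in kmer:
        code = _BASE_CODE[ord(ch)] if ord(ch) < 256 else -1
        if code < 0:
            raise ValueError(f"K-mer {kmer!r} contains non-ACGT character {ch!r}")
        idx = idx * 4 + int(code)
    return idx


def kmer_string(index: int, config: ODHConfig) -> str:
    """Inverse of :func:`kmer_index`."""
    if not 0 <= index < config.n_kmers:
        raise ValueError(f"K-mer index {index} out of range")
    out = []
    for _ in range(config.K):
        index, r = divmod(index, 4)
        out.append(DNA_ALPHABET[r])
    return "".join(reversed(out))


@dataclass
class ODHFeatureVector:
    """Sparse Phi(s): sorted flat keys with positive counts."""

    config: ODHConfig
    keys: np.ndarray
    counts: np.ndarray
    sample_id: str | None = None

    def __post_init__(self) -> None:
        self.keys = np.asarray(self.keys, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if len(self.keys) != len(self.counts):
            raise ValueError("keys and counts must have equal length")
        if len(self.keys) and np.any(np.diff(self.keys) <= 0):
            order = np.argsort(self.keys)
            self.keys = self.keys[order]
            self.counts = self.counts[order]
            if np.any(np.diff(self.keys) == 0):
                raise ValueError("duplicate feature keys")
        if np.any(self.counts < 0):
            raise ValueError("negative feature counts")

    @property
    def nnz(self) -> int:
        return len(self.keys)

    def total(self) -> float:
        """Total pair count (for un-normalized vectors: the number of counted
        occurrence pairs)."""
        return float(self.counts.sum())

    def get(self, i: int, j: int, d: int) -> float:
        key = self.config.key(i, j, d)
        pos = np.searchsorted(self.keys, key)
        if pos < len(self.keys) and self.keys[pos] == key:
            return float(self.counts[pos])
        return 0.0

    def items(self) -> Iterable[tuple[tuple[int, int, int], float]]:
        for k, c in zip(self.keys, self.counts):
            yield self.config.unkey(k), float(c)

    def to_dense(self) -> np.ndarray:
        """Dense Phi(s); only sensible for small K and D."""
        v = np.zeros(self.config.dimension)
        v[self.keys] = self.counts
        return v


def _encode_positions(seq: str, K: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 codes of all K-mer start positions and a validity mask
    (False where the window touches a non-ACGT character)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    base = _BASE_CODE[arr]
    P = len(seq) - K + 1
    codes = np.zeros(P, dtype=np.int64)
    valid = np.ones(P, dtype=bool)
    for k in range(K):
        window = base[k : k + P]
        codes = codes * 4 + np.where(window >= 0, window, 0)
        valid &= window >= 0
    return codes, valid


def odh_transform(seq: LocusSequence | str, config: ODHConfig) -> ODHFeatureVector:
    """Compute the sparse ODH feature vector of a sequence.

    Raises ``ValueError`` for sequences shorter than K (distinguishable from
    a legal all-zero vector on an all-N sequence).
    """
    if isinstance(seq, LocusSequence):
        s, sid = seq.seq, seq.locus.id
    else:
        s, sid = str(seq).upper(), None
    K, D, M = config.K, config.D, config.n_kmers
    if len(s) < K:
        raise ValueError(f"sequence of length {len(s)} is shorter than K={K}")
    codes, valid = _encode_positions(s, K)
    P = len(codes)
    chunks = []
    for d in range(0, min(D, P - 1) + 1):
        if d == 0:
            c = codes[valid]
            if len(c):
                chunks.append((c * M + c) * (D + 1))
        else:
            mask = valid[:-d] & valid[d:]
            if mask.any():
                i = codes[:-d][mask]
                j = codes[d:][mask]
                chunks.append((i * M + j) * (D + 1) + d)
    if chunks:
        flat = np.concatenate(chunks)
        keys, counts = np.unique(flat, return_counts=True)
    else:
        keys = np.empty(0, dtype=np.int64)
        counts = np.empty(0, dtype=np.int64)
    counts = counts.astype(np.float64)
    if config.l2_normalize and len(counts):
        counts = counts / np.linalg.norm(counts)
    return ODHFeatureVector(config=config, keys=keys, counts=counts, sample_id=sid)


def odh_dot(a: ODHFeatureVector, b: ODHFeatureVector) -> float:
    """Sparse inner product Phi(a) . Phi(b); requires identical configs."""
    if a.config != b.config:
        raise ValueError("feature vectors have different ODH configurations")
    _, ia, ib = np.intersect1d(a.keys, b.keys, assume_unique=True, return_indices=True)
    return float(np.dot(a.counts[ia], b.counts[ib]))


def _stack(samples: Sequence[ODHFeatureVector]) -> sp.csr_matrix:
    cfg = samples[0].config
    for s in samples:
        if s.config != cfg:
            raise ValueError("all samples must share one ODH configuration")
    indptr = np.cumsum([0] + [s.nnz for s in samples])
    indices = np.concatenate([s.keys for s in samples]) if len(samples) else np.empty(0)
    data = np.concatenate([s.counts for s in samples]) if len(samples) else np.empty(0)
    return sp.csr_matrix(
        (data, indices, indptr), shape=(len(samples), cfg.dimension)
    )


@dataclass
class KernelMatrix:
    """Symmetric Gram matrix of ODH inner products."""

    values: np.ndarray
    row_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("kernel matrix must be square")
        if not np.allclose(self.values, self.values.T, rtol=1e-10, atol=1e-8):
            raise ValueError("kernel matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])


def kernel_matrix(samples: Sequence[ODHFeatureVector]) -> KernelMatrix:
    """N x N Gram matrix K = X^T X of the stacked feature vectors."""
    if len(samples) < 1:
        raise ValueError("need at least one sample")
    X = _stack(samples)
    G = (X @ X.T).toarray()
    G = (G + G.T) / 2.0
    ids = [s.sample_id or f"s{i}" for i, s in enumerate(samples)]
    return KernelMatrix(values=G, row_ids=ids)


def cross_kernel(
    train: Sequence[ODHFeatureVector], test: Sequence[ODHFeatureVector]
) -> np.ndarray:
    """Rectangular kernel with entry (t, r) = Phi(test[t]) . Phi(train[r])."""
    if not train or not test:
        return np.zeros((len(test), len(train)))
    if train[0].config != test[0].config:
        raise ValueError("train and test samples must share one ODH configuration")
    Xtr = _stack(train)
    Xte = _stack(test)
    return (Xte @ Xtr.T).toarray()


def dump_feature_tsv(path: str | Path, vec: ODHFeatureVector) -> None:
    """Debug dump: one row per stored (kmer_i, kmer_j, d, count)."""
    cfg = vec.config
    with open(path, "w") as fh:
        fh.write("kmer_i\tkmer_j\td\tcount\n")
        for (i, j, d), c in vec.items():
            fh.write(f"{kmer_string(i, cfg)}\t{kmer_string(j, cfg)}\t{d}\t{c:.10g}\n")
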