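"""Synthetic fixtures with known ground truth.

Three generators emulate the pipeline's inputs:

* random locus sequences with planted distance-constrained K-mer pair
  signals (optionally short tandem-repeat tracts) distinguishing positives
  from negatives,
* replicate peak-call tables with controllable replicate agreement, and
* distance-decay sparse Hi-C matrices at 5/10/25 kb with enriched cells,
  where the coarser matrices are literal sums of their 5 kb constituent
  cells.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .genomic import (
    GenomicLocus,
    LocusSequence,
    PeakRecord,
    ReplicatePeakTable,
    SparseContactMatrix,
    DNA_ALPHABET,
)

HIC_RESOLUTIONS = (5000, 10000, 25000)


@dataclass(frozen=True)
class PlantedSignal:
    """A K-mer pair planted at exact separation ``distance`` in positives.

    ``tandem_unit`` (a 1-3 bp string) optionally plants a tandem-repeat
    tract of ``tract_length`` copies instead of/alongside the pair,
    mimicking di-/trinucleotide repeat signals.
    """

    left_kmer: str = "ACGTT"
    right_kmer: str = "GGATC"
    distance: int = 20
    planting_probability: float = 1.0
    copies: int = 2
    tandem_unit: str | None = "GT"
    tract_length: tuple[int, int] = (8, 14)

    def __post_init__(self) -> None:
        if not 0 <= self.planting_probability <= 1:
            raise ValueError("planting_probability must lie in [0, 1]")
        if self.distance < 0:
            raise ValueError("distance must be >= 0")
        if self.tandem_unit is not None and not 1 <= len(self.tandem_unit) <= 3:
            raise ValueError("tandem repeat unit length must be 1-3")

    @property
    def footprint(self) -> int:
        """Minimum sequence length able to host one planted pair."""
        return self.distance + len(self.right_kmer) + max(
            0, len(self.left_kmer) - self.distance
        )


@dataclass
class SyntheticDatasetSpec:
    """Study conditions for one synthetic locus set.

    Lengths are drawn uniformly from ``length_range``; the default range
    mirrors restriction-fragment-like loci of diverse lengths while staying
    cheap to transform. ``base_composition`` is (A, C, G, T) and defaults to
    uniform; ``label_noise`` flips labels after planting, modeling peak-call
    error.
    """

    n_pos: int = 60
    n_neg: int = 200
    length_range: tuple[int, int] = (500, 1500)
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    signals: tuple[PlantedSignal, ...] = (PlantedSignal(),)
    label_noise: float = 0.0
    seed: int = 0
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("sample counts must be non-negative")
        if not 0 <= self.label_noise <= 1:
            raise ValueError("label_noise must lie in [0, 1]")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base composition must sum to 1")


def _random_seq(rng: np.random.Generator, length: int, comp: Sequence[float]) -> np.ndarray:
    return rng.choice(4, size=length, p=np.asarray(comp, dtype=float))


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(DNA_ALPHABET[c] for c in codes)


def _str_to_codes(s: str) -> np.ndarray:
    lut = {b: i for i, b in enumerate(DNA_ALPHABET)}
    return np.array([lut[c] for c in s], dtype=np.int64)


def generate_sequences(
    spec: SyntheticDatasetSpec,
) -> tuple[list[LocusSequence], np.ndarray, list[dict]]:
    """Generate labeled locus sequences with planted signals.

    Returns (sequences, labels, truth) where labels are 1/0 (after optional
    label noise) and truth records every planted occurrence as a dict with
    sequence id, signal, and offset. Skipped plantings (sequence too short)
    are recorded with offset None.
    """
    rng = np.random.default_rng(spec.seed)
    seqs: list[LocusSequence] = []
    labels = np.zeros(spec.n_pos + spec.n_neg, dtype=int)
    labels[: spec.n_pos] = 1
    truth: list[dict] = []
    gap = 10_000  # synthetic loci tiled along one chromosome
    cursor = 0
    for n in range(spec.n_pos + spec.n_neg):
        positive = n < spec.n_pos
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        codes = _random_seq(rng, length, spec.base_composition)
        if positive:
            for sig in spec.signals:
                for _ in range(sig.copies):
                    if rng.random() > sig.planting_probability:
                        continue
                    if sig.tandem_unit is not None:
                        unit = _str_to_codes(sig.tandem_unit)
                        n_rep = int(rng.integers(sig.tract_length[0], sig.tract_length[1] + 1))
                        tract = np.tile(unit, n_rep)
                        if len(tract) > length:
                            truth.append(
                                {"seq": f"L{n}", "signal": "tandem", "offset": None}
                            )
                            continue
                        off = int(rng.integers(0, length - len(tract) + 1))
                        codes[off : off + len(tract)] = tract
                        truth.append(
                            {"seq": f"L{n}", "signal": "tandem", "offset": off, "n_rep": n_rep}
                        )
                    left = _str_to_codes(sig.left_kmer)
                    right = _str_to_codes(sig.right_kmer)
                    span = sig.distance + len(right)
                    if span > length:
                        truth.append(
                            {"seq": f"L{n}", "signal": "pair", "offset": None}
                        )
                        continue
                    off = int(rng.integers(0, length - span + 1))
                    codes[off : off + len(left)] = left
                    codes[off + sig.distance : off + sig.distance + len(right)] = right
                    truth.append({"seq": f"L{n}", "signal": "pair", "offset": off})
        locus = GenomicLocus(spec.chrom, cursor, cursor + length, f"L{n}")
        cursor += length + gap
        seqs.append(LocusSequence(locus=locus, seq=_codes_to_str(codes)))
    if spec.label_noise > 0:
        flip = rng.random(len(labels)) < spec.label_noise
        labels = np.where(flip, 1 - labels, labels)
    return seqs, labels, truth


def generate_peak_table(
    labels: Sequence[int],
    locus_ids: Sequence[str],
    model_locus_id: str,
    replicates: Sequence[str] = ("rep1", "rep2"),
    agreement_rate: float = 1.0,
    fdr_level: float = 10.0,
    seed: int = 0,
) -> ReplicatePeakTable:
    """Replicate peak calls for the given true labels.

    With probability ``agreement_rate`` all replicates agree with the truth;
    otherwise the pair is called in a random non-empty proper subset of
    replicates (so it lands in the uncalled partition).
    """
    if not 0 <= agreement_rate <= 1:
        raise ValueError("agreement_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    reps = list(replicates)
    records = []
    for lid, y in zip(locus_ids, labels):
        if rng.random() < agreement_rate:
            calls = {r: bool(y) for r in reps}
        else:
            k = int(rng.integers(1, len(reps)))  # non-empty proper subset
            chosen = set(rng.choice(len(reps), size=k, replace=False).tolist())
            calls = {r: (i in chosen) for i, r in enumerate(reps)}
        for r in reps:
            records.append(
                PeakRecord(
                    row_id=str(lid),
                    col_id=model_locus_id,
                    replicate=r,
                    called=calls[r],
                    fdr=fdr_level,
                )
            )
    return ReplicatePeakTable(records)


def generate_hic(
    n_bins: int = 100,
    decay_exponent: float = 0.8,
    enriched_cells: Sequence[tuple[int, int, float]] = (),
    base_count: float = 400.0,
    norm_jitter: float = 0.03,
    seed: int = 0,
    chrom: str = "chrS",
) -> tuple[dict[int, SparseContactMatrix], list[dict]]:
    """Distance-decay Hi-C matrices at 5/10/25 kb with planted enrichment.

    The balanced signal at 5 kb bin pair (i, j) has mean
    ``base_count * (1 + |i - j|) ** -decay_exponent``, multiplied by ``fold``
    for cells listed in ``enriched_cells`` (5 kb bin indices, i <= j). Raw
    counts are Poisson draws of the signal scaled by per-bin factors near 1;
    the 10/25 kb raw matrices are exact sums of their constituent 5 kb cells.

    Returns ({resolution: matrix}, truth) with truth recording every
    enriched cell.
    """
    for i, j, fold in enriched_cells:
        if fold <= 0:
            raise ValueError("enrichment fold must be positive")
        if not (0 <= i <= j < n_bins):
            raise ValueError(f"enriched cell ({i}, {j}) outside the matrix")
    rng = np.random.default_rng(seed)
    res0 = HIC_RESOLUTIONS[0]
    ii, jj = np.triu_indices(n_bins)
    lam = base_count * (1.0 + (jj - ii)) ** (-decay_exponent)
    enrich = {(i, j): fold for i, j, fold in enriched_cells}
    for (i, j), fold in enrich.items():
        mask = (ii == i) & (jj == j)
        lam[mask] *= fold
    norm0 = 1.0 + norm_jitter * rng.standard_normal(n_bins)
    norm0 = np.clip(norm0, 0.5, 2.0)
    raw = rng.poisson(lam * norm0[ii] * norm0[jj]).astype(np.float64)

    matrices: dict[int, SparseContactMatrix] = {}
    nz = raw > 0
    matrices[res0] = SparseContactMatrix(
        resolution=res0,
        chrom=chrom,
        bin_i=ii[nz] * res0,
        bin_j=jj[nz] * res0,
        counts=raw[nz],
        norm_vector=norm0,
    )
    for res in HIC_RESOLUTIONS[1:]:
        # a coarse cell is the sum over its constituent unordered fine pairs
        factor = res // res0
        n_coarse = int(np.ceil(n_bins / factor))
        coarse = np.zeros((n_coarse, n_coarse))
        np.add.at(coarse, (ii // factor, jj // factor), raw)
        ci, cj = np.triu_indices(n_coarse)
        vals = coarse[ci, cj]
        nzc = vals > 0
        normc = 1.0 + norm_jitter * rng.standard_normal(n_coarse)
        normc = np.clip(normc, 0.5, 2.0)
        # balancing factors of an aggregated matrix stay near 1 by construction
        matrices[res] = SparseContactMatrix(
            resolution=res,
            chrom=chrom,
            bin_i=ci[nzc] * res,
            bin_j=cj[nzc] * res,
            counts=vals[nzc],
            norm_vector=normc,
        )
    truth = [
        {"bin_i": i, "bin_j": j, "fold": fold, "resolution": res0}
        for (i, j), fold in sorted(enrich.items())
    ]
    return matrices, truth
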