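"""Training-label construction from replicate peak calls, and Hi-C
observed/expected significance labeling for independent validation.

The 5C side: for one model-defining locus (a column of the contact matrix),
row loci called a peak in *all* replicates form the positive class
("TruePeaks"), loci called in *no* replicate the negative class ("NonPeaks"),
and loci called in some but not all replicates are left out of training.

The Hi-C side: raw counts are balanced with the supplied per-bin factors,
observed/expected (O/E) values are computed against a per-distance expected
profile, and a partner bin counts as significantly interacting when its O/E
meets the cutoff at the primary resolution (5 kb) AND at one of the coarser
confirmation resolutions (10 kb or 25 kb).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genomic import GenomicLocus, ReplicatePeakTable, SparseContactMatrix

logger = logging.getLogger(__name__)


@dataclass
class ContactLabelSet:
    """Per-model partition of the tested row loci."""

    model_locus_id: str
    positives: list[str]
    negatives: list[str]
    uncalled: list[str]
    fdr_level: float

    def __post_init__(self) -> None:
        sets = [set(self.positives), set(self.negatives), set(self.uncalled)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("positives, negatives and uncalled must be disjoint")

    @property
    def n_tested(self) -> int:
        return len(self.positives) + len(self.negatives) + len(self.uncalled)


def binarize_contacts(
    table: ReplicatePeakTable, model_locus_id: str, fdr_level: float
) -> ContactLabelSet:
    """Partition row loci tested against one column locus into
    TruePeaks / NonPeaks / uncalled based on replicate agreement."""
    replicates = set(table.replicates)
    calls: dict[str, dict[str, bool]] = {}
    for r in table.records:
        if r.col_id != model_locus_id or r.fdr != fdr_level:
            continue
        calls.setdefault(r.row_id, {})[r.replicate] = r.called
    if not calls:
        raise ValueError(
            f"model locus {model_locus_id!r} absent from peak table at "
            f"FDR {fdr_level}"
        )
    positives, negatives, uncalled = [], [], []
    for row_id in sorted(calls):
        per_rep = calls[row_id]
        missing = replicates - set(per_rep)
        if missing:
            logger.warning(
                "pair (%s, %s) missing from replicate(s) %s; treated as uncalled",
                row_id,
                model_locus_id,
                sorted(missing),
            )
            uncalled.append(row_id)
        elif all(per_rep.values()):
            positives.append(row_id)
        elif not any(per_rep.values()):
            negatives.append(row_id)
        else:
            uncalled.append(row_id)
    logger.info(
        "model %s @ FDR %g: %d positives, %d negatives, %d uncalled",
        model_locus_id,
        fdr_level,
        len(positives),
        len(negatives),
        len(uncalled),
    )
    return ContactLabelSet(
        model_locus_id=model_locus_id,
        positives=positives,
        negatives=negatives,
        uncalled=uncalled,
        fdr_level=fdr_level,
    )


@dataclass(frozen=True)
class HiCValidationConfig:
    """Multi-resolution O/E significance rule.

    ``oe_cutoff`` is inclusive (O/E >= cutoff). A partner is significant when
    it meets the cutoff at ``primary_resolution`` and at any one of the
    ``confirm_resolutions`` (in the coarser bin containing its primary bin).
    """

    oe_cutoff: float = 2.5
    primary_resolution: int = 5000
    confirm_resolutions: tuple[int, ...] = (10000, 25000)
    min_distance_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if self.oe_cutoff <= 0:
            raise ValueError("oe_cutoff must be positive")
        if self.primary_resolution >= min(self.confirm_resolutions):
            raise ValueError("primary resolution must be finer than confirmations")


@dataclass
class OEMatrix:
    """Observed/expected values and the distance-stratified expected profile."""

    resolution: int
    chrom: str
    oe: dict[tuple[int, int], float]
    expected_profile: np.ndarray
    bin_offset: int = 0  # first bin index of the profiled span

    def get(self, bin_i: int, bin_j: int) -> float:
        if bin_j < bin_i:
            bin_i, bin_j = bin_j, bin_i
        return self.oe.get((bin_i, bin_j), 0.0)


def normalize_hic(m: SparseContactMatrix) -> SparseContactMatrix:
    """Apply the per-bin balancing factors: count / (norm[i] * norm[j]).

    Entries touching a NaN factor (unbalanceable bin) or a zero factor are
    dropped.
    """
    if m.norm_vector is None:
        raise ValueError("matrix carries no normalization vector")
    idx_i = m.bin_i // m.resolution
    idx_j = m.bin_j // m.resolution
    ni = m.norm_vector[idx_i]
    nj = m.norm_vector[idx_j]
    keep = np.isfinite(ni) & np.isfinite(nj) & (ni != 0) & (nj != 0)
    dropped = int((~keep).sum())
    if dropped:
        logger.warning(
            "dropping %d entries touching unnormalizable bins", dropped
        )
    counts = m.counts[keep] / (ni[keep] * nj[keep])
    return SparseContactMatrix(
        resolution=m.resolution,
        chrom=m.chrom,
        bin_i=m.bin_i[keep],
        bin_j=m.bin_j[keep],
        counts=counts,
        norm_vector=np.ones_like(m.norm_vector),
    )


def observed_expected(m: SparseContactMatrix) -> OEMatrix:
    """O/E transform of a normalized matrix.

    The expected value at bin distance d is the mean normalized count over
    *all* bin pairs at that distance within the span of bins present,
    structural zeros included; O/E of a stored entry is its normalized count
    divided by the expected value at its distance.
    """
    if m.n_entries == 0:
        return OEMatrix(
            resolution=m.resolution,
            chrom=m.chrom,
            oe={},
            expected_profile=np.empty(0),
        )
    idx_i = m.bin_i // m.resolution
    idx_j = m.bin_j // m.resolution
    lo = int(min(idx_i.min(), idx_j.min()))
    hi = int(max(idx_i.max(), idx_j.max()))
    span = hi - lo + 1
    dist = idx_j - idx_i
    sums = np.zeros(span, dtype=np.float64)
    np.add.at(sums, dist, m.counts)
    n_pairs = span - np.arange(span)  # pairs at each bin distance in the span
    expected = sums / n_pairs
    obs_exp = expected[dist]
    if np.any((m.counts > 0) & (obs_exp <= 0)):
        raise ValueError("zero expected value at a distance with observations")
    oe_vals = np.where(obs_exp > 0, m.counts / np.where(obs_exp > 0, obs_exp, 1.0), 0.0)
    oe = {
        (int(i), int(j)): float(v)
        for i, j, v in zip(idx_i, idx_j, oe_vals)
    }
    return OEMatrix(
        resolution=m.resolution,
        chrom=m.chrom,
        oe=oe,
        expected_profile=expected,
        bin_offset=lo,
    )


def _locus_bins(locus: GenomicLocus, resolution: int) -> list[int]:
    """All bin indices overlapped by the locus at the given resolution."""
    first = locus.start // resolution
    last = (locus.end - 1) // resolution
    return list(range(first, last + 1))


def hic_significant_partners(
    oes: Mapping[int, OEMatrix],
    model_locus: GenomicLocus,
    cfg: HiCValidationConfig,
) -> tuple[list[int], list[int]]:
    """Identify significantly interacting partner bins of a model locus.

    Returns (significant, tested) lists of partner bin indices at the primary
    resolution. Tested bins are those with any non-zero normalized contact
    against any bin of the model locus at the primary resolution; significant
    bins additionally satisfy O/E >= cutoff at the primary resolution and, in
    the containing coarser bin, at 10 kb or 25 kb.
    """
    for res in (cfg.primary_resolution, *cfg.confirm_resolutions):
        if res not in oes:
            raise ValueError(f"missing O/E matrix at resolution {res}")
    primary = oes[cfg.primary_resolution]
    model_bins = _locus_bins(model_locus, cfg.primary_resolution)
    tested: set[int] = set()
    primary_sig: dict[int, int] = {}  # partner bin -> a model bin it qualifies against
    for (bi, bj), val in primary.oe.items():
        for mb in model_bins:
            if bi == mb or bj == mb:
                partner = bj if bi == mb else bi
                tested.add(partner)
                if val >= cfg.oe_cutoff and partner not in primary_sig:
                    primary_sig[partner] = mb
    significant = []
    for partner, mb in sorted(primary_sig.items()):
        confirmed = False
        for res in cfg.confirm_resolutions:
            factor = res // cfg.primary_resolution
            cb_partner = partner // factor
            # the partner must confirm against the coarser bin of *some* model bin
            for mb2 in model_bins:
                cb_model = mb2 // factor
                if oes[res].get(cb_partner, cb_model) >= cfg.oe_cutoff:
                    confirmed = True
                    break
            if confirmed:
                break
        if confirmed:
            significant.append(partner)
    return significant, sorted(tested)


def distance_filter(
    bins: Sequence[int],
    model_locus: GenomicLocus,
    min_distance_bp: int,
    resolution: int,
) -> list[int]:
    """Keep partner bins whose nearest edge lies more than ``min_distance_bp``
    from the model locus's nearest edge."""
    if min_distance_bp == 0:
        return list(bins)
    out = []
    for b in bins:
        start = b * resolution
        end = start + resolution
        if end <= model_locus.start:
            dist = model_locus.start - end
        elif start >= model_locus.end:
            dist = start - model_locus.end
        else:
            dist = 0
        if dist > min_distance_bp:
            out.append(b)
    return out


def write_validation_tsv(
    path: str | Path,
    oes: Mapping[int, OEMatrix],
    model_locus: GenomicLocus,
    cfg: HiCValidationConfig,
) -> None:
    """TSV of per-partner O/E values, the significance call, and the
    beyond-band flag."""
    significant, tested = hic_significant_partners(oes, model_locus, cfg)
    sig = set(significant)
    beyond = set(
        distance_filter(tested, model_locus, cfg.min_distance_bp, cfg.primary_resolution)
    )
    model_bins = _locus_bins(model_locus, cfg.primary_resolution)
    with open(path, "w") as fh:
        res_cols = "\t".join(
            f"oe_{r // 1000}k" for r in (cfg.primary_resolution, *cfg.confirm_resolutions)
        )
        fh.write(f"bin\t{res_cols}\tsignificant\tbeyond_band\n")
        for b in tested:
            vals = []
            for res in (cfg.primary_resolution, *cfg.confirm_resolutions):
                factor = res // cfg.primary_resolution
                best = max(
                    oes[res].get(b // factor, mb // factor) for mb in model_bins
                )
                vals.append(f"{best:.6g}")
            fh.write(
                f"{b}\t" + "\t".join(vals) + f"\t{int(b in sig)}\t{int(b in beyond)}\n"
            )
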