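"""Interpretation of the averaged SVM weight vector.

Because the ODH kernel is linear, every entry of the primal weight vector
is the coefficient of one K-mer pair at one separation d. Two views are
provided:

* AMPD ("absolute max per distance"): at every d, the most positive and the
  most negative entry, displayed as adjoined 2K-mers "left|right".
* TopN: the N highest (or lowest) signed entries overall; entries selected
  at the same distance are stacked into a position-wise weight matrix
  (PWWM) and summarized as a consensus motif.

The PWWM for a set of selected 2K-mers with weight magnitudes |w_m| puts
into cell (base, p) the sum of |w_m| over motifs carrying that base at
position p, then divides every column by the total magnitude so each column
sums to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .genomic import DNA_ALPHABET
from .odh import ODHConfig, kmer_string
from .svm import SparseWeightVector

logger = logging.getLogger(__name__)

_BASE_ROW = {b: r for r, b in enumerate(DNA_ALPHABET)}
_LOGO_COLORS = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}


def _adjoined(i: int, j: int, cfg: ODHConfig) -> str:
    return f"{kmer_string(i, cfg)}|{kmer_string(j, cfg)}"


@dataclass
class AMPDEntry:
    distance: int
    pair: str  # adjoined "left|right"
    weight: float


@dataclass
class AMPDTable:
    config: ODHConfig
    positive: list[AMPDEntry]  # one per distance, most positive coefficient
    negative: list[AMPDEntry]  # one per distance, most negative coefficient

    def __post_init__(self) -> None:
        for p, n in zip(self.positive, self.negative):
            if p.weight < 0 or n.weight > 0:
                raise ValueError("AMPD polarity invariant violated")


@dataclass
class TopNSelection:
    N: int
    polarity: str  # "positive" | "negative"
    threshold: float  # N-th best signed value, the dashed inner circle
    entries: list[tuple[int, str, float]]  # (distance, adjoined pair, weight)


@dataclass
class PWWM:
    """|alphabet| x 2K column-normalized weight matrix for one distance."""

    distance: int
    matrix: np.ndarray
    normalizer: float  # sum of selected weight magnitudes at this distance

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if np.any(self.matrix < 0):
            raise ValueError("PWWM entries must be non-negative")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-12):
            raise ValueError("every PWWM column must sum to 1")

    def consensus(self) -> str:
        return "".join(DNA_ALPHABET[r] for r in np.argmax(self.matrix, axis=0))


def ampd(weight: SparseWeightVector, cfg: ODHConfig) -> AMPDTable:
    """Per-distance extrema of the weight vector.

    Absent coordinates count as weight 0; ties break to the lexicographically
    first adjoined 2K-mer (which coincides with the smallest flat pair index
    under the A<C<G<T encoding).
    """
    Dp1 = cfg.D + 1
    pair_idx = weight.keys // Dp1
    dists = weight.keys % Dp1
    pos_entries: list[AMPDEntry] = []
    neg_entries: list[AMPDEntry] = []
    zero_pair = _adjoined(0, 0, cfg)
    for d in range(cfg.D + 1):
        m = dists == d
        best_pos, best_pos_pair = 0.0, zero_pair
        best_neg, best_neg_pair = 0.0, zero_pair
        if m.any():
            vals = weight.values[m]
            pairs = pair_idx[m]
            # scan in pair-index order so the first strict improvement wins ties
            order = np.argsort(pairs)
            for p, v in zip(pairs[order], vals[order]):
                if v > best_pos:
                    best_pos, best_pos_pair = float(v), None
                    best_pos_idx = int(p)
                if v < best_neg:
                    best_neg, best_neg_pair = float(v), None
                    best_neg_idx = int(p)
            if best_pos_pair is None:
                i, j = divmod(best_pos_idx, cfg.n_kmers)
                best_pos_pair = _adjoined(i, j, cfg)
            if best_neg_pair is None:
                i, j = divmod(best_neg_idx, cfg.n_kmers)
                best_neg_pair = _adjoined(i, j, cfg)
        pos_entries.append(AMPDEntry(d, best_pos_pair, best_pos))
        neg_entries.append(AMPDEntry(d, best_neg_pair, best_neg))
    return AMPDTable(config=cfg, positive=pos_entries, negative=neg_entries)


def topn(weight: SparseWeightVector, N: int = 25, polarity: str = "positive") -> TopNSelection:
    """Top-N entries by signed value (positive panel) or bottom-N (negative).

    Ties break lexicographically on the adjoined 2K-mer, then on distance.
    """
    if polarity not in ("positive", "negative"):
        raise ValueError("polarity must be 'positive' or 'negative'")
    cfg = weight.config
    sign = 1.0 if polarity == "positive" else -1.0
    mask = sign * weight.values > 0
    keys = weight.keys[mask]
    vals = weight.values[mask]
    if len(keys) < N:
        logger.warning(
            "requested top %d %s entries but only %d stored; taking all",
            N,
            polarity,
            len(keys),
        )
        N_eff = len(keys)
    else:
        N_eff = N
    Dp1 = cfg.D + 1
    pairs = keys // Dp1
    dists = keys % Dp1
    order = np.lexsort((dists, pairs, -sign * vals))
    sel = order[:N_eff]
    entries = []
    for k in sel:
        i, j = divmod(int(pairs[k]), cfg.n_kmers)
        entries.append((int(dists[k]), _adjoined(i, j, cfg), float(vals[k])))
    threshold = float(vals[sel[-1]]) if N_eff else 0.0
    return TopNSelection(N=N_eff, polarity=polarity, threshold=threshold, entries=entries)


def pwwm(
    selected: Sequence[tuple[str, float]],
    K: int,
    distance: int = 0,
) -> PWWM:
    """Build the column-normalized PWWM from (2K-mer motif, |weight|) pairs.

    Motifs may be given with or without the '|' separator; all must have
    length 2K after removing it.
    """
    if not selected:
        raise ValueError("no motifs selected")
    mat = np.zeros((len(DNA_ALPHABET), 2 * K))
    total = 0.0
    for motif, mag in selected:
        motif = motif.replace("|", "")
        if len(motif) != 2 * K:
            raise ValueError(
                f"motif {motif!r} has length {len(motif)}, expected {2 * K}"
            )
        if mag <= 0:
            raise ValueError("weight magnitudes must be positive")
        for p, base in enumerate(motif):
            mat[_BASE_ROW[base], p] += mag
        total += mag
    return PWWM(distance=distance, matrix=mat / total, normalizer=total)


def pwwms_from_selection(sel: TopNSelection, K: int) -> dict[int, PWWM]:
    """One PWWM per distance represented in a TopN selection."""
    by_d: dict[int, list[tuple[str, float]]] = {}
    for d, motif, w in sel.entries:
        by_d.setdefault(d, []).append((motif, abs(w)))
    return {d: pwwm(motifs, K, distance=d) for d, motifs in sorted(by_d.items())}


# ---------------------------------------------------------------------------
# TSV dumps
# ---------------------------------------------------------------------------

def write_ampd_tsv(path: str | Path, table: AMPDTable) -> None:
    with open(path, "w") as fh:
        fh.write("distance\tpositive_pair\tpositive_weight\tnegative_pair\tnegative_weight\n")
        for p, n in zip(table.positive, table.negative):
            fh.write(f"{p.distance}\t{p.pair}\t{p.weight:.10g}\t{n.pair}\t{n.weight:.10g}\n")


def write_topn_tsv(path: str | Path, sel: TopNSelection) -> None:
    with open(path, "w") as fh:
        fh.write(f"# polarity={sel.polarity}\tN={sel.N}\tthreshold={sel.threshold:.10g}\n")
        fh.write("distance\tpair\tweight\n")
        for d, motif, w in sel.entries:
            fh.write(f"{d}\t{motif}\t{w:.10g}\n")


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _deterministic_save(fig, path: str | Path) -> None:
    path = Path(path)
    meta: dict | None = None
    if path.suffix == ".png":
        meta = {"Software": "seqloop"}
    elif path.suffix == ".svg":
        plt.rcParams["svg.hashsalt"] = "seqloop"
        meta = {"Date": None}
    fig.savefig(path, metadata=meta)
    plt.close(fig)


def render_ampd(table: AMPDTable, path: str | Path) -> None:
    """Mirrored horizontal bar chart: distances on the vertical axis, weights
    on the horizontal; even distances in the outer label column, odd in the
    inner, for legibility."""
    ds = [e.distance for e in table.positive]
    pos_w = [e.weight for e in table.positive]
    neg_w = [e.weight for e in table.negative]
    fig, ax = plt.subplots(figsize=(9, max(4, 0.12 * len(ds) + 1)))
    ax.barh(ds, pos_w, color="#255C99", label="positive class")
    ax.barh(ds, neg_w, color="#D62839", label="negative class")
    max_w = max([abs(w) for w in pos_w + neg_w] + [1e-12])
    # even-distance labels in the outer column, odd in the inner
    for e in table.positive:
        if e.weight != 0:
            x = max_w * (1.45 if e.distance % 2 == 0 else 1.05)
            ax.text(x, e.distance, e.pair, fontsize=4, va="center", family="monospace")
    for e in table.negative:
        if e.weight != 0:
            x = -max_w * (1.45 if e.distance % 2 == 0 else 1.05)
            ax.text(x, e.distance, e.pair, fontsize=4, va="center", ha="right", family="monospace")
    ax.set_xlim(-2.1 * max_w, 2.1 * max_w)
    ax.set_xlabel("SVM weight")
    ax.set_ylabel("distance d between K-mer starts (bp)")
    ax.axvline(0, color="black", lw=0.5)
    ax.legend(loc="lower right", fontsize=6)
    fig.tight_layout()
    _deterministic_save(fig, path)


def render_topn(
    sel: TopNSelection,
    pwwms: dict[int, PWWM],
    path: str | Path,
    D: int | None = None,
) -> None:
    """Radial TopN view: one spoke per distance, length = largest selected
    weight magnitude at that distance; spokes meeting the threshold are
    colored by polarity, the dashed inner circle marks the threshold, and
    consensus motifs annotate the spoke tips."""
    if D is None:
        D = max([d for d, _, _ in sel.entries], default=0)
    by_d: dict[int, float] = {}
    for d, _, w in sel.entries:
        by_d[d] = max(by_d.get(d, 0.0), abs(w))
    color = "#255C99" if sel.polarity == "positive" else "#D62839"
    fig = plt.figure(figsize=(7, 7))
    ax = fig.add_subplot(projection="polar")
    thresh = abs(sel.threshold)
    rmax = max(list(by_d.values()) + [thresh, 1e-12]) * 1.3
    for d in range(D + 1):
        theta = 2 * np.pi * d / (D + 1)
        mag = by_d.get(d, 0.0)
        if mag >= thresh and mag > 0:
            ax.plot([theta, theta], [0, mag], color=color, lw=1.2)
            if d in pwwms:
                ax.text(
                    theta,
                    min(mag * 1.12, rmax * 0.97),
                    pwwms[d].consensus(),
                    fontsize=5,
                    ha="center",
                    family="monospace",
                )
        elif mag > 0:
            ax.plot([theta, theta], [0, mag], color="0.6", lw=0.8)
    if thresh > 0:
        ax.plot(
            np.linspace(0, 2 * np.pi, 256),
            np.full(256, thresh),
            ls="--",
            lw=0.8,
            color="0.3",
        )
    ax.set_rmax(rmax)
    ax.set_xticks([2 * np.pi * d / (D + 1) for d in range(0, D + 1, max(1, (D + 1) // 12))])
    ax.set_xticklabels(
        [str(d) for d in range(0, D + 1, max(1, (D + 1) // 12))], fontsize=6
    )
    ax.set_yticklabels([])
    ax.set_title(f"Top{sel.N} ({sel.polarity}) K-mer pairs by weight", fontsize=9)
    fig.tight_layout()
    _deterministic_save(fig, path)
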