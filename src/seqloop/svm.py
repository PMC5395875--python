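"""Locus-specific SVM training on precomputed ODH kernels.

One classifier is trained per model-defining locus: a 5-fold nested
stratified cross-validation selects the SVM cost from a log grid
10^{-3..3} by mean inner-fold AUC; the minority class's misclassification
cost is up-weighted by the class ratio; each outer fold contributes a test
AUC and, because the ODH kernel is linear in Phi, a sparse primal weight
vector recovered as the dual-coefficient-weighted sum of support-vector
feature vectors. The five fold weight vectors are averaged into one
representative vector used downstream for interpretation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .genomic import GenomicLocus
from .odh import ODHConfig, ODHFeatureVector, cross_kernel, kernel_matrix, kmer_string

logger = logging.getLogger(__name__)

DEFAULT_COST_GRID = tuple(10.0 ** c for c in range(-3, 4))


@dataclass(frozen=True)
class TrainingConfig:
    cost_grid: tuple[float, ...] = DEFAULT_COST_GRID
    outer_folds: int = 5
    inner_folds: int = 5
    holdout_fraction: float = 0.20
    class_weighting: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        grid = tuple(self.cost_grid)
        if len(grid) < 1 or any(c <= 0 for c in grid) or list(grid) != sorted(set(grid)):
            raise ValueError("cost_grid must be strictly increasing positive values")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("need at least 2 folds")
        if not 0 <= self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must lie in [0, 1)")


@dataclass
class SparseWeightVector:
    """A sparse primal SVM weight vector over (kmer_i, kmer_j, d) keys."""

    config: ODHConfig
    keys: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.keys = np.asarray(self.keys, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        order = np.argsort(self.keys)
        self.keys = self.keys[order]
        self.values = self.values[order]

    def get(self, i: int, j: int, d: int) -> float:
        key = self.config.key(i, j, d)
        pos = np.searchsorted(self.keys, key)
        if pos < len(self.keys) and self.keys[pos] == key:
            return float(self.values[pos])
        return 0.0

    def dot(self, phi: ODHFeatureVector) -> float:
        _, ia, ib = np.intersect1d(
            self.keys, phi.keys, assume_unique=True, return_indices=True
        )
        return float(np.dot(self.values[ia], phi.counts[ib]))


@dataclass
class FoldModel:
    support_indices: np.ndarray  # indices into the training sample list
    dual_coef: np.ndarray  # signed alpha_i * y_i, aligned with support_indices
    bias: float
    cost: float
    test_auc: float
    weight: SparseWeightVector


@dataclass
class LocusModel:
    """Trained locus-specific predictor: per-fold dual solutions plus the
    fold-averaged primal weight vector."""

    model_locus: GenomicLocus | None
    odh_config: ODHConfig
    folds: list[FoldModel]
    samples: list[ODHFeatureVector]
    averaged_weight: SparseWeightVector


@dataclass
class EvaluationReport:
    mean_auc: float
    auc_per_fold: list[float]
    positive_count: int
    negative_count: int
    chosen_costs: list[float]
    oof_decision_values: np.ndarray | None = None
    oof_auc: float | None = None

    def __post_init__(self) -> None:
        if self.auc_per_fold and not np.isclose(
            self.mean_auc, float(np.mean(self.auc_per_fold))
        ):
            raise ValueError("mean_auc must equal the mean of auc_per_fold")


def auc(decision_values: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC (ties count 1/2); errors on one-class input."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(y, np.asarray(decision_values, dtype=float)))


def stratified_split(
    labels: Sequence[int], fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic stratified train/hold-out index split."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 members to stratify")
    idx = np.arange(len(y))
    if fraction == 0:
        return idx, np.empty(0, dtype=int)
    train_idx, hold_idx = train_test_split(
        idx, test_size=fraction, stratify=y, random_state=seed
    )
    return np.sort(train_idx), np.sort(hold_idx)


def _class_weight(y: np.ndarray, enabled: bool) -> dict | None:
    if not enabled:
        return None
    classes, counts = np.unique(y, return_counts=True)
    minority = classes[np.argmin(counts)]
    ratio = counts.max() / counts.min()
    return {int(minority): float(ratio)}


def _fit_svc(G: np.ndarray, y: np.ndarray, cost: float, weighting: bool) -> SVC:
    clf = SVC(
        C=cost,
        kernel="precomputed",
        class_weight=_class_weight(y, weighting),
        shrinking=True,
    )
    clf.fit(G, y)
    return clf


def _select_cost(
    G: np.ndarray, y: np.ndarray, cfg: TrainingConfig, seed: int
) -> float:
    """Inner stratified CV over the cost grid; ties go to the smallest cost."""
    inner = StratifiedKFold(n_splits=cfg.inner_folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        # single-class inner folds on tiny classes are skipped below
        warnings.filterwarnings(
            "ignore", message="The least populated class", category=UserWarning
        )
        splits = list(inner.split(np.zeros(len(y)), y))
    mean_aucs = []
    for cost in cfg.cost_grid:
        fold_aucs = []
        for tr, va in splits:
            if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
                continue
            clf = _fit_svc(G[np.ix_(tr, tr)], y[tr], cost, cfg.class_weighting)
            dv = clf.decision_function(G[np.ix_(va, tr)])
            fold_aucs.append(auc(dv, y[va]))
        mean_aucs.append(np.mean(fold_aucs) if fold_aucs else -np.inf)
    best = int(np.argmax(mean_aucs))  # argmax takes the first (smallest cost) on ties
    return cfg.cost_grid[best]


def recover_weight_vector(
    dual_coefs: Sequence[float],
    support_samples: Sequence[ODHFeatureVector],
) -> SparseWeightVector:
    """w = sum_s (alpha_s y_s) Phi(s), exploiting linearity of the ODH kernel."""
    if len(dual_coefs) != len(support_samples):
        raise ValueError("dual coefficients and support samples misaligned")
    if not support_samples:
        raise ValueError("no support samples")
    cfg = support_samples[0].config
    all_keys = np.concatenate([s.keys for s in support_samples])
    all_vals = np.concatenate(
        [c * s.counts for c, s in zip(dual_coefs, support_samples)]
    )
    uk, inv = np.unique(all_keys, return_inverse=True)
    w = np.zeros(len(uk))
    np.add.at(w, inv, all_vals)
    keep = w != 0
    return SparseWeightVector(config=cfg, keys=uk[keep], values=w[keep])


def _mean_weight(weights: Sequence[SparseWeightVector]) -> SparseWeightVector:
    cfg = weights[0].config
    all_keys = np.concatenate([w.keys for w in weights])
    all_vals = np.concatenate([w.values for w in weights])
    uk, inv = np.unique(all_keys, return_inverse=True)
    v = np.zeros(len(uk))
    np.add.at(v, inv, all_vals)
    return SparseWeightVector(config=cfg, keys=uk, values=v / len(weights))


def train_locus_model(
    samples: Sequence[ODHFeatureVector],
    labels: Sequence[int],
    cfg: TrainingConfig,
    model_locus: GenomicLocus | None = None,
    precomputed_gram: np.ndarray | None = None,
) -> tuple[LocusModel, EvaluationReport]:
    """Nested stratified CV on the full labeled set.

    Outer folds give the reported test AUCs and the per-fold weight vectors;
    cost selection happens in the inner loop on the outer-training split only.
    ``precomputed_gram`` lets callers reuse an already-computed Gram matrix
    (it must equal ``kernel_matrix(samples).values``).
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    if counts.min() < cfg.outer_folds:
        raise ValueError(
            f"need at least {cfg.outer_folds} samples per class, got {counts.min()}"
        )
    G = precomputed_gram if precomputed_gram is not None else kernel_matrix(samples).values

    folds: list[FoldModel] = []
    oof_dv = np.full(len(y), np.nan)
    seed = cfg.seed
    for attempt in range(2):
        outer = StratifiedKFold(n_splits=cfg.outer_folds, shuffle=True, random_state=seed)
        splits = list(outer.split(np.zeros(len(y)), y))
        if all(len(np.unique(y[te])) == 2 and len(np.unique(y[tr])) == 2 for tr, te in splits):
            break
        if attempt == 1:
            raise ValueError("could not build folds containing both classes")
        seed += 1  # refold once with a shifted seed
    for fold_no, (tr, te) in enumerate(splits):
        cost = _select_cost(G[np.ix_(tr, tr)], y[tr], cfg, seed + 1 + fold_no)
        clf = _fit_svc(G[np.ix_(tr, tr)], y[tr], cost, cfg.class_weighting)
        dv = clf.decision_function(G[np.ix_(te, tr)])
        fold_auc = auc(dv, y[te])
        oof_dv[te] = dv
        support_local = clf.support_
        support_global = tr[support_local]
        dual = clf.dual_coef_.ravel()
        weight = recover_weight_vector(dual, [samples[i] for i in support_global])
        folds.append(
            FoldModel(
                support_indices=support_global,
                dual_coef=dual,
                bias=float(clf.intercept_[0]),
                cost=cost,
                test_auc=fold_auc,
                weight=weight,
            )
        )
        logger.info("outer fold %d: cost %g, test AUC %.4f", fold_no, cost, fold_auc)
    averaged = _mean_weight([f.weight for f in folds])
    model = LocusModel(
        model_locus=model_locus,
        odh_config=samples[0].config,
        folds=folds,
        samples=list(samples),
        averaged_weight=averaged,
    )
    aucs = [f.test_auc for f in folds]
    report = EvaluationReport(
        mean_auc=float(np.mean(aucs)),
        auc_per_fold=aucs,
        positive_count=int(counts[classes == classes.max()][0]),
        negative_count=int(counts[classes == classes.min()][0]),
        chosen_costs=[f.cost for f in folds],
        oof_decision_values=oof_dv,
        oof_auc=auc(oof_dv, y),
    )
    return model, report


def predict(
    model: LocusModel, samples: Sequence[ODHFeatureVector]
) -> list[tuple[float, int]]:
    """Score unseen loci: per-fold kernel-form decision values averaged across
    folds; the label is the sign of the average."""
    if not samples:
        return []
    if samples[0].config != model.odh_config:
        raise ValueError("sample ODH configuration differs from the model's")
    dv_total = np.zeros(len(samples))
    for fold in model.folds:
        support = [model.samples[i] for i in fold.support_indices]
        K = cross_kernel(support, samples)  # (n_test, n_support)
        dv_total += K @ fold.dual_coef + fold.bias
    dv_mean = dv_total / len(model.folds)
    return [(float(v), 1 if v > 0 else 0) for v in dv_mean]


def predict_primal(
    model: LocusModel, samples: Sequence[ODHFeatureVector]
) -> np.ndarray:
    """Same scores via the recovered primal weights (w . Phi(x) + b averaged
    over folds); used to verify dual/primal equivalence."""
    out = np.zeros(len(samples))
    for fold in model.folds:
        for t, s in enumerate(samples):
            out[t] += fold.weight.dot(s) + fold.bias
    return out / len(model.folds)


# ---------------------------------------------------------------------------
# Model serialization
# ---------------------------------------------------------------------------

def save_model(model: LocusModel, report: EvaluationReport, outdir: str | Path) -> None:
    """Serialize a model as a directory of plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = model.odh_config
    meta = {
        "K": cfg.K,
        "D": cfg.D,
        "l2_normalize": cfg.l2_normalize,
        "model_locus": None
        if model.model_locus is None
        else {
            "chrom": model.model_locus.chrom,
            "start": model.model_locus.start,
            "end": model.model_locus.end,
            "id": model.model_locus.id,
        },
        "mean_auc": report.mean_auc,
        "auc_per_fold": report.auc_per_fold,
        "chosen_costs": report.chosen_costs,
        "positive_count": report.positive_count,
        "negative_count": report.negative_count,
    }
    (outdir / "model.json").write_text(json.dumps(meta, indent=2) + "\n")
    for n, fold in enumerate(model.folds):
        with open(outdir / f"fold{n}_dual.tsv", "w") as fh:
            fh.write(f"# cost={fold.cost:.10g}\tbias={fold.bias:.10g}\n")
            fh.write("support_index\tdual_coef\n")
            for i, c in zip(fold.support_indices, fold.dual_coef):
                fh.write(f"{i}\t{c:.10g}\n")
    with open(outdir / "averaged_weights.tsv", "w") as fh:
        fh.write("kmer_i\tkmer_j\td\tweight\n")
        for k, v in zip(model.averaged_weight.keys, model.averaged_weight.values):
            i, j, d = cfg.unkey(k)
            fh.write(
                f"{kmer_string(i, cfg)}\t{kmer_string(j, cfg)}\t{d}\t{v:.10g}\n"
            )
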