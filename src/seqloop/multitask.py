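"""Multitask SVM learning across loci.

Each locus-specific prediction problem is a task. Samples from all tasks
are pooled and a single SVM is trained on the product kernel

    K_MTL((s_A, t_A), (s_B, t_B)) = K_S(s_A, s_B) * K_T(t_A, t_B)

where K_S is the ODH kernel between candidate-partner sequences and K_T is
the task-similarity kernel: the ODH inner product between the
model-defining locus sequences themselves, computed with the same K and D
as the sample kernel. The product of two PSD kernels is PSD (Schur product
theorem), so the pooled problem remains a valid SVM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .genomic import GenomicLocus, LocusSequence
from .odh import (
    ODHConfig,
    ODHFeatureVector,
    KernelMatrix,
    kernel_matrix,
    odh_transform,
)
from .svm import (
    EvaluationReport,
    TrainingConfig,
    _fit_svc,
    _select_cost,
    auc,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TaskDescriptor:
    task_id: str
    model_locus: GenomicLocus
    model_locus_sequence: LocusSequence


@dataclass
class TaskKernel:
    values: np.ndarray
    task_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.task_ids)
        if self.values.shape != (n, n):
            raise ValueError("task kernel shape inconsistent with task ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("task kernel must be symmetric")
        if np.any(np.diag(self.values) <= 0):
            raise ValueError("task kernel diagonal must be positive")

    def index(self, task_id: str) -> int:
        return self.task_ids.index(task_id)


def task_similarity(
    tasks: Sequence[TaskDescriptor],
    cfg: ODHConfig,
    cosine: bool = False,
) -> TaskKernel:
    """Task kernel from ODH dot products of the model-defining locus
    sequences; ``cosine=True`` rescales to unit self-similarity."""
    if len(tasks) < 2:
        raise ValueError("need at least two tasks")
    for t in tasks:
        if len(t.model_locus_sequence.seq) < cfg.K:
            raise ValueError(
                f"task {t.task_id!r}: model locus sequence shorter than K={cfg.K}"
            )
    phis = [odh_transform(t.model_locus_sequence, cfg) for t in tasks]
    G = kernel_matrix(phis).values
    if cosine:
        norms = np.sqrt(np.diag(G))
        G = G / np.outer(norms, norms)
    return TaskKernel(values=G, task_ids=[t.task_id for t in tasks])


def mtl_kernel(
    sample_kernel: KernelMatrix,
    task_kernel: TaskKernel,
    sample_to_task: Sequence[str],
) -> KernelMatrix:
    """Elementwise product kernel over (sample, task) tuples."""
    n = sample_kernel.n
    if len(sample_to_task) != n:
        raise ValueError("sample_to_task length must match the sample kernel")
    try:
        tidx = np.array([task_kernel.index(t) for t in sample_to_task])
    except ValueError as e:
        raise ValueError(f"sample mapped to unknown task: {e}") from e
    T = task_kernel.values[np.ix_(tidx, tidx)]
    return KernelMatrix(
        values=sample_kernel.values * T, row_ids=list(sample_kernel.row_ids)
    )


@dataclass
class TaskResult:
    task_id: str
    auc: float | None  # None for auxiliary tasks (one class only)
    n_pos: int
    n_neg: int


@dataclass
class MTLReport:
    per_task: list[TaskResult]
    chosen_costs: list[float]
    oof_decision_values: np.ndarray

    @property
    def mean_auc(self) -> float:
        aucs = [t.auc for t in self.per_task if t.auc is not None]
        return float(np.mean(aucs))

    @property
    def std_auc(self) -> float:
        aucs = [t.auc for t in self.per_task if t.auc is not None]
        return float(np.std(aucs))


def train_mtl(
    tasks: Sequence[TaskDescriptor],
    samples_per_task: Mapping[str, Sequence[ODHFeatureVector]],
    labels_per_task: Mapping[str, Sequence[int]],
    cfg: TrainingConfig,
    odh_config: ODHConfig | None = None,
    cosine_task_kernel: bool = False,
) -> MTLReport:
    """Train one SVM over the pooled (sample, task) tuples on the product
    kernel and evaluate per task from out-of-fold decision values.

    Cost selection and the outer-fold protocol mirror the single-task
    pipeline; folds are stratified on the label over the pooled set. A task
    whose samples carry a single label contributes training data but gets no
    AUC of its own.
    """
    task_ids = [t.task_id for t in tasks]
    all_samples: list[ODHFeatureVector] = []
    all_labels: list[int] = []
    sample_task: list[str] = []
    for tid in task_ids:
        for s, y in zip(samples_per_task[tid], labels_per_task[tid]):
            all_samples.append(s)
            all_labels.append(int(y))
            sample_task.append(tid)
    y = np.array(all_labels)
    if len(np.unique(y)) < 2:
        raise ValueError("pooled sample set must contain both classes")
    cfg_odh = odh_config or all_samples[0].config

    K_S = kernel_matrix(all_samples)
    if len(tasks) == 1:
        G = K_S.values  # degenerate MTL reduces to single-task pooling
    else:
        K_T = task_similarity(tasks, cfg_odh, cosine=cosine_task_kernel)
        G = mtl_kernel(K_S, K_T, sample_task).values

    seed = cfg.seed
    for attempt in range(2):
        outer = StratifiedKFold(n_splits=cfg.outer_folds, shuffle=True, random_state=seed)
        splits = list(outer.split(np.zeros(len(y)), y))
        if all(len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2 for tr, te in splits):
            break
        if attempt == 1:
            raise ValueError("could not build folds containing both classes")
        seed += 1
    oof_dv = np.full(len(y), np.nan)
    costs = []
    for fold_no, (tr, te) in enumerate(splits):
        cost = _select_cost(G[np.ix_(tr, tr)], y[tr], cfg, seed + 1 + fold_no)
        clf = _fit_svc(G[np.ix_(tr, tr)], y[tr], cost, cfg.class_weighting)
        oof_dv[te] = clf.decision_function(G[np.ix_(te, tr)])
        costs.append(cost)

    sample_task_arr = np.array(sample_task)
    per_task = []
    for tid in task_ids:
        mask = sample_task_arr == tid
        yt = y[mask]
        n_pos = int((yt == yt.max()).sum()) if len(np.unique(yt)) == 2 else int((yt == 1).sum())
        n_neg = int(len(yt) - n_pos)
        if len(np.unique(yt)) < 2:
            per_task.append(TaskResult(tid, None, n_pos, n_neg))
            logger.info("task %s: auxiliary only (single class)", tid)
        else:
            a = auc(oof_dv[mask], yt)
            per_task.append(TaskResult(tid, a, n_pos, n_neg))
            logger.info("task %s: out-of-fold AUC %.4f", tid, a)
    return MTLReport(per_task=per_task, chosen_costs=costs, oof_decision_values=oof_dv)
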