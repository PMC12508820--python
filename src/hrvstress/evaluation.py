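"""Repeated participant-level cross-validation and classification metrics.

Model performance is estimated by repeated k-fold cross-validation with fold
assignment at the participant level, so that no subject contributes segments
to more than one of the train / validation / test sets of any split — the
standard guard against identity leakage in within-subject physiological
classification. Folds are stratified by diagnostic group. Within one
repetition the k splits rotate roles: split i tests on fold i, validates on
fold (i+1) mod k, and trains on the remaining k-2 folds.

Two training strategies are compared. "separate" trains, validates and tests
entirely within one diagnostic group; "combined" trains a single model on the
pooled groups and reports test metrics separately per group (plus pooled).
Both strategies share the same fold plans per repetition, so their metrics
are paired.

Reported metrics — accuracy, AUROC, sensitivity, specificity — are pooled
over the k test folds within a repetition and then summarized across
repetitions as mean +/- SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .preprocess import Segment
from .resnet1d import ModelSpec, TrainConfig, build_model, predict, train

__all__ = [
    "TASKS",
    "FoldPlan",
    "Metrics",
    "CVConfig",
    "CVResult",
    "participant_folds",
    "compute_metrics",
    "run_repeated_cv",
]

logger = logging.getLogger(__name__)

#: task name -> (labels used, positive label)
TASKS: Dict[str, Tuple[Tuple[str, str], str]] = {
    "phase5min": (("baseline", "stress"), "stress"),
    "b4b5": (("B5", "B4"), "B4"),
    "b5s1": (("B5", "S1"), "S1"),
    "s1s2": (("S1", "S2"), "S2"),
}


@dataclass(frozen=True)
class FoldPlan:
    """Participant -> fold assignment for one repetition of k-fold CV."""

    repetition: int
    k: int
    assignment: Dict[str, int]

    def splits(self) -> List[Tuple[List[str], List[str], List[str]]]:
        """(train, validation, test) participant lists for each of the k splits."""
        by_fold: Dict[int, List[str]] = {f: [] for f in range(self.k)}
        for pid in sorted(self.assignment):
            by_fold[self.assignment[pid]].append(pid)
        out = []
        for i in range(self.k):
            test = by_fold[i]
            val = by_fold[(i + 1) % self.k]
            train_pids = [
                pid
                for f in range(self.k)
                if f not in (i, (i + 1) % self.k)
                for pid in by_fold[f]
            ]
            out.append((train_pids, val, test))
        return out


def participant_folds(
    participants: Sequence,
    k: int = 10,
    seed: int = 0,
    repetition: int = 1,
) -> FoldPlan:
    """Group-stratified participant-level fold assignment.

    ``participants`` may be Participant objects or (id, group) pairs. Within
    each group, shuffled participants are dealt round-robin from a random
    starting fold, keeping per-group fold counts within one of each other.
    """
    pairs = [
        (p.id, p.group) if hasattr(p, "id") else (p[0], p[1]) for p in participants
    ]
    groups: Dict[str, List[str]] = {}
    for pid, g in pairs:
        groups.setdefault(g, []).append(pid)
    for g, pids in groups.items():
        if len(pids) < k:
            raise ValueError(
                f"group {g} has {len(pids)} participants, fewer than k={k} folds"
            )
    rng = np.random.default_rng([seed, repetition])
    assignment: Dict[str, int] = {}
    for g in sorted(groups):
        pids = sorted(groups[g])
        rng.shuffle(pids)
        offset = int(rng.integers(k))
        for i, pid in enumerate(pids):
            assignment[pid] = (offset + i) % k
    return FoldPlan(repetition=repetition, k=k, assignment=assignment)


class Metrics(NamedTuple):
    accuracy: float
    auroc: float
    sensitivity: float
    specificity: float


def compute_metrics(
    labels: np.ndarray, probabilities: np.ndarray, threshold: float = 0.5
) -> Metrics:
    """Threshold metrics plus AUROC (ties counted 0.5, via rank statistic).

    A prediction is positive iff its probability >= threshold. With a single
    class present the AUROC is undefined and reported as NaN (with a logged
    warning); the thresholded metrics are still returned.
    """
    labels = np.asarray(labels, dtype=int)
    probabilities = np.asarray(probabilities, dtype=float)
    if labels.shape != probabilities.shape:
        raise ValueError("labels and probabilities must have the same length")
    preds = (probabilities >= threshold).astype(int)
    tp = int(np.sum((preds == 1) & (labels == 1)))
    tn = int(np.sum((preds == 0) & (labels == 0)))
    fp = int(np.sum((preds == 1) & (labels == 0)))
    fn = int(np.sum((preds == 0) & (labels == 1)))
    n_pos, n_neg = tp + fn, tn + fp
    accuracy = (tp + tn) / len(labels)
    sensitivity = tp / n_pos if n_pos else float("nan")
    specificity = tn / n_neg if n_neg else float("nan")
    if n_pos == 0 or n_neg == 0:
        logger.warning("AUROC undefined: only one class present")
        auroc = float("nan")
    else:
        auroc = float(roc_auc_score(labels, probabilities))
    return Metrics(accuracy, auroc, sensitivity, specificity)


@dataclass(frozen=True)
class CVConfig:
    """Settings for one repeated-CV experiment."""

    reps: int = 10
    folds: int = 10
    seed: int = 0
    model_spec: ModelSpec = field(default_factory=ModelSpec)
    train_config: TrainConfig = field(default_factory=TrainConfig)


@dataclass
class CVResult:
    """Per-repetition and aggregate metrics for one task x strategy x group."""

    task: str
    strategy: str
    group: str
    per_repetition: List[Metrics]

    def aggregate(self) -> Dict[str, Tuple[float, float]]:
        """mean +/- SD of each metric across repetitions."""
        out = {}
        for name in Metrics._fields:
            vals = np.array([getattr(m, name) for m in self.per_repetition])
            out[name] = (float(np.nanmean(vals)), float(np.nanstd(vals, ddof=1))
                         if len(vals) > 1 else 0.0)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r, m in enumerate(self.per_repetition, start=1):
            for name in Metrics._fields:
                rows.append(
                    {"task": self.task, "strategy": self.strategy,
                     "group": self.group, "repetition": r,
                     "metric": name, "value": getattr(m, name)}
                )
        return pd.DataFrame(rows)


def _task_segments(segments: Sequence[Segment], task: str) -> List[Segment]:
    labels, _ = TASKS[task]
    out = [s for s in segments if s.label in labels]
    if not out:
        raise ValueError(f"no segments carry the labels {labels} for task {task!r}")
    return out


def _audit_disjoint(train_p: Iterable[str], val_p: Iterable[str],
                    test_p: Iterable[str]) -> None:
    train_s, val_s, test_s = set(train_p), set(val_p), set(test_p)
    overlap = (train_s & val_s) | (train_s & test_s) | (val_s & test_s)
    if overlap:
        raise AssertionError(f"participant leakage across split roles: {overlap}")


def run_repeated_cv(
    segments: Sequence[Segment],
    task: str,
    strategy: str,
    cfg: CVConfig,
    participants: Optional[Sequence[Tuple[str, str]]] = None,
) -> List[CVResult]:
    """Run the full repeated-CV experiment for one task and strategy.

    Returns one CVResult per diagnostic group present, plus a pooled "all"
    result for the combined strategy. ``participants`` defaults to the
    (participant_id, group) pairs appearing in the segments.
    """
    if strategy not in ("separate", "combined"):
        raise ValueError("strategy must be 'separate' or 'combined'")
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    segs = _task_segments(segments, task)
    _, positive = TASKS[task]
    if participants is None:
        seen: Dict[str, str] = {}
        for s in segs:
            seen[s.participant_id] = s.group
        participants = sorted(seen.items())
    group_names = sorted({g for _, g in participants})

    by_pid: Dict[str, List[Segment]] = {}
    for s in segs:
        by_pid.setdefault(s.participant_id, []).append(s)

    def gather(pids: Iterable[str], group: Optional[str] = None) -> List[Segment]:
        out = []
        for pid in pids:
            for s in by_pid.get(pid, []):
                if group is None or s.group == group:
                    out.append(s)
        return out

    n_models = 0
    # collected[group] = list over repetitions of (labels, probabilities)
    collected: Dict[str, List[Tuple[List[int], List[float]]]] = {}

    for rep in range(1, cfg.reps + 1):
        plan = participant_folds(participants, k=cfg.folds, seed=cfg.seed,
                                 repetition=rep)
        rep_store: Dict[str, Tuple[List[int], List[float]]] = {}
        for split_i, (train_p, val_p, test_p) in enumerate(plan.splits()):
            _audit_disjoint(train_p, val_p, test_p)
            model_seed = int(
                np.random.default_rng([cfg.seed, rep, split_i]).integers(2**31)
            )
            if strategy == "combined":
                tr, va, te = gather(train_p), gather(val_p), gather(test_p)
                model = build_model(cfg.model_spec, seed=model_seed)
                train(model, tr, va, replace(cfg.train_config, seed=model_seed),
                      positive_label=positive)
                probs = predict(model, te)
                n_models += 1
                for s, p in zip(te, probs):
                    for key in (s.group, "all"):
                        ys, ps = rep_store.setdefault(key, ([], []))
                        ys.append(1 if s.label == positive else 0)
                        ps.append(float(p))
            else:  # separate: one model per group, within-group data only
                for g in group_names:
                    tr = gather(train_p, g)
                    va = gather(val_p, g)
                    te = gather(test_p, g)
                    if not tr or not va or not te:
                        continue
                    model = build_model(cfg.model_spec, seed=model_seed)
                    train(model, tr, va,
                          replace(cfg.train_config, seed=model_seed),
                          positive_label=positive)
                    probs = predict(model, te)
                    n_models += 1
                    ys, ps = rep_store.setdefault(g, ([], []))
                    ys.extend(1 if s.label == positive else 0 for s in te)
                    ps.extend(float(p) for p in probs)
        for g, (ys, ps) in rep_store.items():
            collected.setdefault(g, []).append((ys, ps))

    results = []
    for g, reps in sorted(collected.items()):
        per_rep = [compute_metrics(np.array(ys), np.array(ps)) for ys, ps in reps]
        results.append(CVResult(task=task, strategy=strategy, group=g,
                                per_repetition=per_rep))
    logger.info("repeated CV (%s/%s): trained %d models over %d repetitions",
                task, strategy, n_models, cfg.reps)
    results_n_models = n_models
    for r in results:
        r.n_models_trained = results_n_models  # type: ignore[attr-defined]
    return results
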