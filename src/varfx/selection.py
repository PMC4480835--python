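"""Greedy bottom-up feature selection, per-network union, backward elimination.

Selection operates per network (per cross-validation rotation): starting from
an empty set, the (descriptor, window) candidate that maximizes AUC on the
rotation's cross-training fold is added, until no candidate improves beyond a
tolerance or a step budget is exhausted.  One fold — specific to each
network — is held out of the whole procedure.  Per-network selections are
merged by order-preserving union (the same provider at two windows stays as
two entries), then backward elimination removes every descriptor whose
removal does not alter the mean test-rotation two-state accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .ensemble import NetworkConfig, train_network
from .features import (
    FeatureDescriptor,
    ProviderRegistry,
    Scaler,
    assemble_feature_matrix,
)
from .homology import FoldAssignment, Rotation, crossval_splits
from .io import EFFECT, VariantDataset
from .metrics import confusion_counts, q2

logger = logging.getLogger(__name__)

IMPROVEMENT_TOLERANCE = 1e-3


@dataclass
class SelectionState:
    """Outcome of one per-network greedy forward pass."""

    selected: list[FeatureDescriptor] = field(default_factory=list)
    candidates: list[FeatureDescriptor] = field(default_factory=list)
    history: list[float] = field(default_factory=list)  # best cross-train AUC per step
    held_out_fold: int | None = None


def _rows_for_rotation(dataset: VariantDataset, folds: FoldAssignment,
                       rotation: Rotation, held_out_fold: int | None):
    labeled = dataset.labeled()
    if held_out_fold is not None and held_out_fold in (
            rotation.crosstrain_fold, *rotation.train_folds):
        raise ValueError(
            f"held-out fold {held_out_fold} appears in the selection rotation")
    y = np.array([1 if v.label == EFFECT else 0 for v in labeled])
    row_fold = np.array([folds.protein_to_fold[v.protein_id] for v in labeled])
    train = np.flatnonzero(np.isin(row_fold, rotation.train_folds))
    ct = np.flatnonzero(row_fold == rotation.crosstrain_fold)
    return labeled, y, row_fold, train, ct


def _crosstrain_auc(dataset, registry, descriptors, labeled, y, train, ct,
                    config) -> float:
    fm = assemble_feature_matrix(dataset, descriptors, registry, variants=labeled)
    if fm.n_excluded:
        keep = np.array(fm.variant_indices)
        remap = -np.ones(len(labeled), dtype=int)
        remap[keep] = np.arange(len(keep))
        train = remap[train]; train = train[train >= 0]
        ct = remap[ct]; ct = ct[ct >= 0]
        y = y[keep]
    scaler = Scaler.fit(fm.X, train)
    Xs = scaler.transform(fm.X)
    model = train_network(Xs[train], y[train], Xs[ct], y[ct], config)
    return model.best_auc


def greedy_forward_select(dataset: VariantDataset, folds: FoldAssignment,
                          rotation: Rotation,
                          candidates: Sequence[FeatureDescriptor],
                          registry: ProviderRegistry,
                          config: NetworkConfig,
                          budget: int = 25,
                          tolerance: float = IMPROVEMENT_TOLERANCE,
                          held_out_fold: int | None = None) -> SelectionState:
    """Iteratively add the candidate maximizing cross-train AUC.

    Stops when no candidate improves the AUC by more than ``tolerance`` or
    after ``budget`` accepted steps.  Ties break to the lowest candidate
    index; seeds are derived per (step, candidate), so the procedure is
    deterministic.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidates given")
    labeled, y, _, train, ct = _rows_for_rotation(dataset, folds, rotation,
                                                  held_out_fold)
    state = SelectionState(candidates=list(candidates), held_out_fold=held_out_fold)
    best_auc = -np.inf
    for step in range(budget):
        best_candidate = None
        best_candidate_auc = -np.inf
        for j, cand in enumerate(state.candidates):
            cfg = replace(config, seed=config.seed + 10_000 * step + j)
            auc = _crosstrain_auc(dataset, registry, state.selected + [cand],
                                  labeled, y, train, ct, cfg)
            if auc > best_candidate_auc:  # strict: ties keep lowest index
                best_candidate_auc = auc
                best_candidate = cand
        if best_candidate is None or best_candidate_auc <= best_auc + tolerance:
            break
        state.selected.append(best_candidate)
        state.candidates.remove(best_candidate)
        state.history.append(best_candidate_auc)
        best_auc = best_candidate_auc
        logger.info("selection step %d: +%s (cross-train AUC %.4f)",
                    step, best_candidate.name, best_candidate_auc)
        if not state.candidates:
            break
    return state


def union_feature_sets(states: Sequence[SelectionState]) -> list[FeatureDescriptor]:
    """Order-preserving union; the same provider at distinct windows is kept twice."""
    if not states:
        raise ValueError("at least one selection state required")
    seen = set()
    union = []
    for state in states:
        for d in state.selected:
            key = (d.provider, d.window, d.name)
            if key not in seen:
                seen.add(key)
                union.append(d)
    return union


def mean_test_q2(dataset: VariantDataset, folds: FoldAssignment,
                 descriptors: Sequence[FeatureDescriptor],
                 registry: ProviderRegistry, config: NetworkConfig,
                 threshold: float = -0.05, seed: int = 0) -> float:
    """Mean two-state accuracy over all test rotations for a feature set."""
    labeled = dataset.labeled()
    y = np.array([1 if v.label == EFFECT else 0 for v in labeled])
    row_fold = np.array([folds.protein_to_fold[v.protein_id] for v in labeled])
    fm = assemble_feature_matrix(dataset, list(descriptors), registry, variants=labeled)
    if fm.n_excluded:
        keep = np.array(fm.variant_indices)
        y = y[keep]
        row_fold = row_fold[keep]
    q2_values = []
    for i, rotation in enumerate(crossval_splits(folds)):
        train = np.flatnonzero(np.isin(row_fold, rotation.train_folds))
        ct = np.flatnonzero(row_fold == rotation.crosstrain_fold)
        test = np.flatnonzero(row_fold == rotation.test_fold)
        scaler = Scaler.fit(fm.X, train)
        Xs = scaler.transform(fm.X)
        cfg = replace(config, seed=seed + 1_000 * i)
        model = train_network(Xs[train], y[train], Xs[ct], y[ct], cfg)
        diff = model.difference(Xs[test])
        predicted = ["effect" if d > threshold else "neutral" for d in diff]
        actual = ["effect" if t == 1 else "neutral" for t in y[test]]
        q2_values.append(q2(confusion_counts(zip(predicted, actual))))
    return float(np.mean(q2_values))


def backward_eliminate(dataset: VariantDataset, folds: FoldAssignment,
                       selected: Sequence[FeatureDescriptor],
                       registry: ProviderRegistry, config: NetworkConfig,
                       tolerance: float = IMPROVEMENT_TOLERANCE,
                       seed: int = 0) -> list[FeatureDescriptor]:
    """Remove every descriptor whose removal does not lower mean test Q2 by
    more than ``tolerance``; one fixed-order pass, repeated until stable."""
    current = list(selected)
    if not current:
        raise ValueError("selected descriptor list must be non-empty")
    baseline = mean_test_q2(dataset, folds, current, registry, config, seed=seed)
    changed = True
    sweep = 0
    while changed and len(current) > 1:
        changed = False
        sweep += 1
        for d in list(current):
            trial = [x for x in current if x is not d]
            score = mean_test_q2(dataset, folds, trial, registry, config,
                                 seed=seed + 97 * sweep)
            if score >= baseline - tolerance:
                logger.info("backward elimination: -%s (Q2 %.4f -> %.4f)",
                            d.name, baseline, score)
                current = trial
                baseline = score
                changed = True
    return current


def selection_report(state: SelectionState) -> pd.DataFrame:
    """Tabular report: step, descriptor, window, cross-train AUC."""
    rows = [
        {"step": i, "descriptor": d.provider, "window": d.window,
         "crosstrain_auc": auc}
        for i, (d, auc) in enumerate(zip(state.selected, state.history))
    ]
    return pd.DataFrame(rows, columns=["step", "descriptor", "window", "crosstrain_auc"])
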