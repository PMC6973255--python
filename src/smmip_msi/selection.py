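"""Backward-forward stepwise selection of a minimal marker subset.

Starting from the full panel, backward steps drop the marker whose removal
best preserves (or improves) the objective; forward steps re-add a removed
marker when it strictly improves the objective; the search stops at a fixed
point.  The default objective is leave-one-out cross-validated accuracy,
tie-broken by the mean absolute score (the margin), so the selected subset
never scores below the full panel on the objective.

Because the naive-Bayes parameters of each marker do not depend on which
other markers are in the subset, every leave-one-out fold is fitted once on
the full panel and each marker's additive log-odds contribution to the
held-out sample is cached; any subset is then scored by summing columns of
that contribution matrix.  This is exactly equivalent to refitting per
subset (the independent oracle in the test suite does exactly that).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .classifier import MSI_H, MSS, MSIClassifier


@dataclass
class SelectionTraceEntry:
    step: int
    move: str  # "remove" | "add" | "stop"
    marker: str | None
    subset_size: int
    objective: float
    margin: float


@dataclass
class SelectionResult:
    selected: list[str]
    objective: float
    margin: float
    full_panel_objective: float
    trace: list[SelectionTraceEntry] = field(default_factory=list)

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(t) for t in self.trace])


class _LooContributions:
    """Per-fold, per-marker additive log10-odds contributions."""

    def __init__(self, X: pd.DataFrame, y, params: dict):
        y = np.asarray(y, dtype=object)
        self.y = y
        template = MSIClassifier(**params)
        self.prior_term = math.log10(
            (1.0 - template.prior_mss) / template.prior_mss
        )
        self.markers = [c[:-2] for c in X.columns if c.endswith(":d")]
        n = len(X)
        self.contrib = np.zeros((n, len(self.markers)))
        self.has_d = np.zeros((n, len(self.markers)), dtype=bool)
        for i in range(n):
            train_idx = np.arange(n) != i
            clf = MSIClassifier(**params).fit(X.iloc[train_idx], y[train_idx])
            row = X.iloc[i]
            traits = clf.dichotomize(row)
            for j, m in enumerate(self.markers):
                D, B = traits[m]
                if D is None:
                    continue
                self.has_d[i, j] = True
                ph, ps = clf.p_d_[MSI_H][m], clf.p_d_[MSS][m]
                c = math.log10(ph / ps) if D else math.log10((1 - ph) / (1 - ps))
                if B is not None:
                    qh, qs = clf.p_b_[MSI_H][m], clf.p_b_[MSS][m]
                    c += math.log10(qh / qs) if B else math.log10((1 - qh) / (1 - qs))
                self.contrib[i, j] = c

    def objective(self, subset: list[str]) -> tuple[float, float]:
        """(LOO accuracy, mean |score| margin) of a marker subset."""
        idx = [self.markers.index(m) for m in subset]
        scores = self.prior_term + self.contrib[:, idx].sum(axis=1)
        scorable = self.has_d[:, idx].any(axis=1)
        calls = np.where(scores > 0, MSI_H, MSS)
        correct = (calls == self.y) & scorable
        acc = float(correct.mean())
        margin = float(np.abs(scores[scorable]).mean()) if scorable.any() else 0.0
        return acc, margin


def _discriminability(clf: MSIClassifier) -> dict[str, float]:
    """|log10 P(D=1|MSI-H)/P(D=1|MSS)| per marker, from a full-data fit."""
    return {
        m: abs(math.log10(clf.p_d_[MSI_H][m] / clf.p_d_[MSS][m]))
        for m in clf.markers_
    }


def stepwise_select(
    X: pd.DataFrame,
    y,
    objective: str = "loo",
    **classifier_params,
) -> SelectionResult:
    """Backward-forward stepwise marker selection.

    Ties in the backward step are broken by removing the marker with the
    smallest deletion-trait discriminability, then lexicographically by
    name.  Deterministic given the data.

    ``objective`` may be "loo" (leave-one-out accuracy, default) or
    "training" (reclassification accuracy of the full training set).
    """
    if len(X) == 0:
        raise ValueError("empty training data")
    if objective not in ("loo", "training"):
        raise ValueError("objective must be 'loo' or 'training'")
    if objective == "loo":
        machine = _LooContributions(X, y, classifier_params)
    else:
        machine = _TrainingContributions(X, y, classifier_params)
    full_clf = MSIClassifier(**classifier_params).fit(X, y)
    disc = _discriminability(full_clf)
    markers = list(machine.markers)
    current = list(markers)
    cur_acc, cur_margin = machine.objective(current)
    full_objective = cur_acc
    trace = [SelectionTraceEntry(0, "start", None, len(current), cur_acc, cur_margin)]
    removed: list[str] = []
    seen = {frozenset(current)}
    step = 0
    while True:
        step += 1
        # backward: drop the marker whose removal keeps accuracy >= current,
        # preferring higher resulting (accuracy, margin); ties -> least
        # discriminative marker, then name
        best_removal = None
        if len(current) > 1:
            candidates = []
            for m in current:
                subset = [x for x in current if x != m]
                acc, margin = machine.objective(subset)
                if acc >= cur_acc:
                    candidates.append(((-acc, -margin, disc[m], m), m, acc, margin))
            if candidates:
                candidates.sort()
                best_removal = candidates[0]
        if best_removal is not None:
            _, m, acc, margin = best_removal
            current = [x for x in current if x != m]
            removed.append(m)
            cur_acc, cur_margin = acc, margin
            trace.append(
                SelectionTraceEntry(step, "remove", m, len(current), acc, margin)
            )
            key = frozenset(current)
            if key in seen:
                break
            seen.add(key)
            continue
        # forward: re-add a removed marker only on strict improvement of
        # (accuracy, margin)
        best_addition = None
        for m in removed:
            subset = current + [m]
            acc, margin = machine.objective(subset)
            if (acc, margin) > (cur_acc, cur_margin):
                cand = ((-acc, -margin, -disc[m], m), m, acc, margin)
                if best_addition is None or cand < best_addition:
                    best_addition = cand
        if best_addition is not None:
            _, m, acc, margin = best_addition
            current.append(m)
            removed.remove(m)
            cur_acc, cur_margin = acc, margin
            trace.append(
                SelectionTraceEntry(step, "add", m, len(current), acc, margin)
            )
            key = frozenset(current)
            if key in seen:
                break
            seen.add(key)
            continue
        trace.append(
            SelectionTraceEntry(step, "stop", None, len(current), cur_acc, cur_margin)
        )
        break
    selected = [m for m in markers if m in current]
    return SelectionResult(
        selected=selected,
        objective=cur_acc,
        margin=cur_margin,
        full_panel_objective=full_objective,
        trace=trace,
    )


class _TrainingContributions(_LooContributions):
    """Same contribution cache but fitted once on the full training set."""

    def __init__(self, X: pd.DataFrame, y, params: dict):
        y = np.asarray(y, dtype=object)
        self.y = y
        clf = MSIClassifier(**params).fit(X, y)
        self.prior_term = math.log10((1.0 - clf.prior_mss) / clf.prior_mss)
        self.markers = list(clf.markers_)
        n = len(X)
        self.contrib = np.zeros((n, len(self.markers)))
        self.has_d = np.zeros((n, len(self.markers)), dtype=bool)
        for i in range(n):
            traits = clf.dichotomize(X.iloc[i])
            for j, m in enumerate(self.markers):
                D, B = traits[m]
                if D is None:
                    continue
                self.has_d[i, j] = True
                ph, ps = clf.p_d_[MSI_H][m], clf.p_d_[MSS][m]
                c = math.log10(ph / ps) if D else math.log10((1 - ph) / (1 - ps))
                if B is not None:
                    qh, qs = clf.p_b_[MSI_H][m], clf.p_b_[MSS][m]
                    c += math.log10(qh / qs) if B else math.log10((1 - qh) / (1 - qs))
                self.contrib[i, j] = c

    def objective(self, subset: list[str]) -> tuple[float, float]:
        return super().objective(subset)


def exhaustive_best_accuracy(
    X: pd.DataFrame, y, max_markers: int | None = None, **classifier_params
) -> float:
    """Best LOO accuracy over all non-empty marker subsets (small panels only)."""
    machine = _LooContributions(X, y, classifier_params)
    k = len(machine.markers)
    limit = k if max_markers is None else min(k, max_markers)
    best = 0.0
    for r in range(1, limit + 1):
        for subset in combinations(machine.markers, r):
            acc, _ = machine.objective(list(subset))
            best = max(best, acc)
    return best


class StepwiseMarkerSelector(BaseEstimator):
    """sklearn-style wrapper around :func:`stepwise_select`.

    ``fit`` stores ``selected_markers_`` and the search ``trace_``;
    ``transform`` restricts a summary frame to the selected markers'
    columns.
    """

    def __init__(self, objective: str = "loo", **classifier_params):
        self.objective = objective
        self.classifier_params = classifier_params

    def fit(self, X: pd.DataFrame, y) -> "StepwiseMarkerSelector":
        result = stepwise_select(X, y, objective=self.objective, **self.classifier_params)
        self.selected_markers_ = result.selected
        self.objective_ = result.objective
        self.trace_ = result.trace
        self.result_ = result
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        cols = [
            c
            for c in X.columns
            if any(c == f"{m}:d" or c == f"{m}:p" for m in self.selected_markers_)
        ]
        return X[cols]
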