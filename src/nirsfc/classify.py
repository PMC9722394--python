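"""Repeated stratified 5-fold LDA classification over connectivity features.

The classifier is classic two-class linear discriminant analysis: class
means, pooled within-class covariance and training-fraction priors, i.e.
the Bayes rule under a shared-covariance Gaussian model.  Accuracy is
estimated with stratified 5-fold cross-validation, the whole scheme
repeated (N = 10 by default) with fresh random fold partitions, and
reported per repeat together with mean +/- SD and the maximum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .connectivity import ConnectivityMatrix

logger = logging.getLogger(__name__)


@dataclass
class LDAModel:
    classes: np.ndarray          # (2,)
    means: np.ndarray            # (2, d)
    cov: np.ndarray              # (d, d) pooled within-class covariance
    priors: np.ndarray           # (2,)
    _cov_inv: np.ndarray = field(repr=False, default=None)

    def decision(self, x: np.ndarray) -> np.ndarray:
        """Per-class discriminant scores delta_k(x)."""
        x = np.atleast_2d(np.asarray(x, float))
        scores = np.empty((x.shape[0], 2))
        for kk in range(2):
            mu = self.means[kk]
            a = self._cov_inv @ mu
            scores[:, kk] = x @ a - 0.5 * mu @ a + np.log(self.priors[kk])
        return scores

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.classes[np.argmax(self.decision(x), axis=1)]


def lda_train(features: np.ndarray, labels: np.ndarray,
              ridge: float = 1e-8) -> LDAModel:
    """Fit two-class LDA (means, pooled covariance, priors).

    A singular pooled covariance is regularised with a ridge jitter of
    ``ridge`` times the mean diagonal (with a warning).
    """
    x = np.asarray(features, float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    d = x.shape[1]
    means = np.empty((2, d))
    pooled = np.zeros((d, d))
    priors = np.empty(2)
    n = x.shape[0]
    for kk, c in enumerate(classes):
        xc = x[y == c]
        if xc.shape[0] < 2:
            raise ValueError(f"class {c!r} needs >= 2 training subjects")
        means[kk] = xc.mean(axis=0)
        pooled += (xc.shape[0] - 1) * np.cov(xc, rowvar=False).reshape(d, d)
        priors[kk] = xc.shape[0] / n
    pooled /= n - 2

    try:
        cov_inv = np.linalg.inv(pooled)
        if not np.all(np.isfinite(cov_inv)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        logger.warning("singular pooled covariance; applying ridge jitter")
        jitter = ridge * max(np.mean(np.diag(pooled)), 1.0)
        cov_inv = np.linalg.inv(pooled + jitter * np.eye(d))
    return LDAModel(classes=classes, means=means, cov=pooled, priors=priors,
                    _cov_inv=cov_inv)


@dataclass
class CVReport:
    """Per-repeat cross-validated accuracies for one feature set (percent)."""

    name: str
    accuracies: np.ndarray       # (repeats,)
    k: int
    seed: int
    fold_seeds: tuple[int, ...] = ()

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 else 0.0

    @property
    def max(self) -> float:
        return float(np.max(self.accuracies))

    def to_row(self) -> dict:
        row = {"feature_set": self.name}
        row.update({f"N{i + 1}": a for i, a in enumerate(self.accuracies)})
        row["mean"] = self.mean
        row["sd"] = self.sd
        row["max"] = self.max
        return row


def repeated_cv(features: np.ndarray, labels: np.ndarray, k: int = 5,
                repeats: int = 10, seed: int = 0,
                name: str = "features",
                aggregate: str = "pooled") -> CVReport:
    """Repeated stratified k-fold LDA cross-validation.

    Each repeat draws a fresh class-stratified k-fold partition; the
    repeat's accuracy pools correct/total over the concatenated validation
    folds (``aggregate="fold_mean"`` averages per-fold accuracies
    instead).  Per-repeat fold seeds derive deterministically from
    ``seed``.
    """
    x = np.asarray(features, float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class ({counts.min()}) < k ({k})")
    fold_seeds = tuple(
        int(s) for s in
        np.random.SeedSequence(int(seed)).generate_state(repeats) % (2 ** 31)
    )
    accs = np.empty(repeats)
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=fold_seeds[r])
        correct = 0
        total = 0
        fold_accs = []
        for train, test in skf.split(x, y):
            model = lda_train(x[train], y[train])
            pred = model.predict(x[test])
            correct += int((pred == y[test]).sum())
            total += len(test)
            fold_accs.append((pred == y[test]).mean())
        if aggregate == "pooled":
            accs[r] = 100.0 * correct / total
        elif aggregate == "fold_mean":
            accs[r] = 100.0 * float(np.mean(fold_accs))
        else:
            raise ValueError("aggregate must be 'pooled' or 'fold_mean'")
    return CVReport(name=name, accuracies=accs, k=k, seed=int(seed),
                    fold_seeds=fold_seeds)


def _edge_features(matrices: list[ConnectivityMatrix],
                   edges: list[tuple[str, str]]) -> tuple[np.ndarray, np.ndarray]:
    x = np.array([[cm.edge(a, b) for (a, b) in edges] for cm in matrices])
    y = np.array([cm.group for cm in matrices])
    return x, y


def run_classification(matrices_by_level: dict[str, list[ConnectivityMatrix]],
                       stats_by_level: dict[str, pd.DataFrame],
                       k: int = 5, repeats: int = 10, seed: int = 0,
                       auc_screen: float = 0.65) -> list[CVReport]:
    """Screen edges per level and run repeated CV on each, plus the union.

    ROI-level features are the FDR-significant edges with AUC above
    ``auc_screen``; channel-level features are the edges with adjusted
    p < 0.01.  Each selected edge is evaluated alone and the per-level
    union as an "All above" row, mirroring the screening-study report.
    Selection is frozen on the full cohort before cross-validation (the
    screening procedure itself); nested selection is out of scope here.
    """
    reports: list[CVReport] = []
    any_matrices = next(iter(matrices_by_level.values()), [])
    group_sizes = np.unique([cm.group for cm in any_matrices], return_counts=True)[1]
    if group_sizes.size and group_sizes.min() < k:
        logger.warning("smallest group (%d) below k=%d folds; skipping "
                       "classification", group_sizes.min(), k)
        return reports
    for level, matrices in matrices_by_level.items():
        table = stats_by_level[level]
        if level == "roi":
            sel = table[(table["sig"]) & (table["auc"] > auc_screen)]
            sel = sel.sort_values("auc")
        else:
            sel = table[table["strong"]].sort_values("p_fdr", ascending=False)
        edges = [(r.node_i, r.node_j) for r in sel.itertuples()]
        if not edges:
            logger.warning("no %s-level edges pass screening", level)
            continue
        for edge in edges:
            x, y = _edge_features(matrices, [edge])
            reports.append(repeated_cv(x, y, k=k, repeats=repeats, seed=seed,
                                       name=f"{edge[0]}-{edge[1]}"))
        if len(edges) > 1:
            x, y = _edge_features(matrices, edges)
            reports.append(repeated_cv(x, y, k=k, repeats=repeats, seed=seed,
                                       name=f"All above ({level})"))
    return reports


def reports_to_frame(reports: list[CVReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in reports])
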