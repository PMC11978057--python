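"""Stratified k-fold benchmarking and the extractor x classifier grid.

Cross-validation is stratified 10-fold by default.  All fold-dependent
feature state (eigenbasis, visual-word codebook) is refitted inside each
fold on the training indices only; the extractor records those indices so
leakage is auditable after the fact.  Both the mean of fold accuracies and
the pooled fraction correct are reported (the grid displays the pooled
value).

Custom extractors and trainers can be injected for testing: an extractor
needs ``prepare/fit/transform``; a trainer is any ``(X, y, seed) -> model``
callable whose model has ``classes`` and ``predict_confidence``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import classify
from .features import make_extractor

logger = logging.getLogger(__name__)

DEFAULT_FOLDS = 10


class StratificationError(ValueError):
    """Some class has fewer samples than the requested fold count."""


@dataclass
class CVReport:
    """Cross-validation outcome for one extractor x classifier pair."""

    extractor: str
    classifier: str
    fold_accuracies: np.ndarray
    per_class_precision: dict[str, float]
    confusion: pd.DataFrame  # rows true, cols predicted
    fit_history: list[np.ndarray] = field(default_factory=list)
    fold_assignment: np.ndarray | None = None

    @property
    def mean_accuracy(self) -> float:
        """Mean of the per-fold accuracies."""
        return float(np.mean(self.fold_accuracies))

    @property
    def pooled_accuracy(self) -> float:
        """Overall fraction correct pooled over all test folds."""
        total = self.confusion.to_numpy().sum()
        return float(np.diag(self.confusion.to_numpy()).sum() / total)

    def to_dict(self) -> dict:
        return {
            "extractor": self.extractor,
            "classifier": self.classifier,
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean_accuracy": self.mean_accuracy,
            "pooled_accuracy": self.pooled_accuracy,
            "per_class_precision": self.per_class_precision,
            "confusion": {
                "classes": list(self.confusion.index),
                "counts": self.confusion.to_numpy().tolist(),
            },
        }


def per_class_precision(confusion: pd.DataFrame) -> dict[str, float]:
    """Precision per class: diagonal / column sum (predicted positives).

    Classes never predicted have undefined precision and are absent from
    the returned map.
    """
    mat = confusion.to_numpy().astype(float)
    out: dict[str, float] = {}
    for j, cls in enumerate(confusion.columns):
        col = mat[:, j].sum()
        if col > 0:
            out[str(cls)] = float(mat[j, j] / col)
    return out


def _fold_assignment(y: np.ndarray, folds: int, seed: int) -> np.ndarray:
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        bad = classes[counts.argmin()]
        raise StratificationError(
            f"class {bad!r} has {counts.min()} samples, fewer than {folds} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[test_idx] = f
    return assignment


def _default_trainer(spec: classify.ClassifierSpec):
    def trainer(X, y, seed):
        return classify.train(X, list(y), spec, seed=seed)
    return trainer


def cross_validate(
    images: list[np.ndarray],
    labels: list[str],
    extractor,
    spec=None,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    trainer=None,
    fold_assignment: np.ndarray | None = None,
    prepared: bool = False,
) -> CVReport:
    """Stratified k-fold cross-validation of one extractor/classifier pair.

    Parameters
    ----------
    extractor : str or extractor object
        Scheme name (``EF``, ``LBP-H``, ``SIFT-BoW``, ``SURF-BoW``) or a
        ready extractor instance.
    spec : ClassifierSpec, optional
        Ignored when ``trainer`` is given.
    trainer : callable, optional
        ``(X, y, seed) -> model`` override; the model must expose
        ``classes`` and ``predict_confidence``.
    fold_assignment : ndarray, optional
        Precomputed per-sample fold ids (reused across grid cells).
    prepared : bool
        True when ``extractor.prepare(images)`` was already called.
    """
    y = np.array([str(l) for l in labels])
    if isinstance(extractor, str):
        extractor = make_extractor(extractor, seed=seed)
    if fold_assignment is None:
        fold_assignment = _fold_assignment(y, folds, seed)
    folds = int(fold_assignment.max()) + 1
    if trainer is None:
        if spec is None:
            raise ValueError("either spec or trainer must be given")
        trainer = _default_trainer(spec)
        clf_name = spec.name
    else:
        clf_name = getattr(trainer, "name", getattr(spec, "name", "custom"))

    classes = np.unique(y)
    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    if not prepared:
        extractor.prepare(images)
    fold_acc = np.zeros(folds)
    for f in range(folds):
        test_idx = np.flatnonzero(fold_assignment == f)
        train_idx = np.flatnonzero(fold_assignment != f)
        extractor.fit(train_idx)
        Xtr = extractor.transform(train_idx)
        Xte = extractor.transform(test_idx)
        model = trainer(Xtr, y[train_idx], seed)
        pred = np.asarray(model.predict(Xte))
        fold_acc[f] = np.mean(pred == y[test_idx])
        for t, p in zip(y[test_idx], pred):
            conf.loc[t, p] += 1

    return CVReport(
        extractor=getattr(extractor, "scheme", "custom"),
        classifier=clf_name,
        fold_accuracies=fold_acc,
        per_class_precision=per_class_precision(conf),
        confusion=conf,
        fit_history=list(getattr(extractor, "fit_history", [])),
        fold_assignment=fold_assignment,
    )


def comparison_grid(
    images: list[np.ndarray],
    labels: list[str],
    extractors: list | None = None,
    classifiers: list | None = None,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    max_evals: int = 6,
) -> tuple[pd.DataFrame, dict[tuple[str, str], CVReport]]:
    """Evaluate the full extractor x classifier cross-product.

    The same fold assignment is reused for every cell.  Returns the
    accuracy matrix (classifier rows, extractor columns, percent, 2
    decimals — pooled accuracy) plus the full per-cell reports.  A failed
    cell is marked NaN and the grid completes.
    """
    y = np.array([str(l) for l in labels])
    if extractors is None:
        extractors = ["LBP-H", "EF", "SIFT-BoW", "SURF-BoW"]
    if classifiers is None:
        classifiers = classify.standard_suite(max_evals=max_evals)
    assignment = _fold_assignment(y, folds, seed)

    ext_objs = [make_extractor(e, seed=seed) if isinstance(e, str) else e
                for e in extractors]
    reports: dict[tuple[str, str], CVReport] = {}
    clf_names = [getattr(c, "name", str(c)) for c in classifiers]
    grid = pd.DataFrame(np.nan, index=clf_names,
                        columns=[e.scheme for e in ext_objs])
    classes = np.unique(y)
    for ext in ext_objs:
        ext.prepare(images)
        # accumulators per classifier; a cell failure marks it and moves on
        accs = {c: np.zeros(folds) for c in clf_names}
        confs = {c: pd.DataFrame(0, index=classes, columns=classes, dtype=int)
                 for c in clf_names}
        failed: set[str] = set()
        # features computed once per fold, shared by every classifier row
        for f in range(folds):
            test_idx = np.flatnonzero(assignment == f)
            train_idx = np.flatnonzero(assignment != f)
            ext.fit(train_idx)
            Xtr = ext.transform(train_idx)
            Xte = ext.transform(test_idx)
            for spec, cname in zip(classifiers, clf_names):
                if cname in failed:
                    continue
                try:
                    model = classify.train(Xtr, list(y[train_idx]), spec, seed=seed)
                    pred = np.asarray(model.predict(Xte))
                except Exception as exc:
                    logger.error("grid cell (%s, %s) failed: %s",
                                 cname, ext.scheme, exc)
                    failed.add(cname)
                    continue
                accs[cname][f] = np.mean(pred == y[test_idx])
                for t, p in zip(y[test_idx], pred):
                    confs[cname].loc[t, p] += 1
        for cname in clf_names:
            if cname in failed:
                continue
            rep = CVReport(
                extractor=ext.scheme, classifier=cname,
                fold_accuracies=accs[cname],
                per_class_precision=per_class_precision(confs[cname]),
                confusion=confs[cname],
                fit_history=list(ext.fit_history),
                fold_assignment=assignment,
            )
            reports[(cname, ext.scheme)] = rep
            grid.loc[cname, ext.scheme] = round(100.0 * rep.pooled_accuracy, 2)
    return grid, reports
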