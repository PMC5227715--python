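"""Jackknife (leave-one-out) and stratified k-fold evaluation.

Each round re-runs the full training recipe — motif-vocabulary mining,
hyperparameter grid search and all three base classifiers — on the training
portion only, then predicts the held-out windows. That re-mining is what
keeps the discriminative-substring features honest: a vocabulary mined once
on the full dataset has already seen every held-out window and inflates
accuracy. A ``reuse_vocabulary`` fast mode exposing exactly that leak exists
for illustration and is never the default.

Metrics are the four standard ones: sensitivity Sn = TP/(TP+FN), specificity
Sp = TN/(TN+FP), accuracy Acc = (TP+TN)/N and the Matthews correlation
coefficient MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import sqrt
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import model as model_mod
from .exceptions import ConfigError, FoldError, M6aVoteError
from .model import PredictionRecord, TrainingRecipe
from .motif import mine_discriminative_substrings
from .seqio import NEGATIVE_LABEL, POSITIVE_LABEL, SiteWindow

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_records(cls, records: Sequence[PredictionRecord]) -> "ConfusionMatrix":
        tp = tn = fp = fn = 0
        for rec in records:
            truth = rec.window.label
            if truth == POSITIVE_LABEL:
                if rec.label == POSITIVE_LABEL:
                    tp += 1
                else:
                    fn += 1
            elif truth == NEGATIVE_LABEL:
                if rec.label == NEGATIVE_LABEL:
                    tn += 1
                else:
                    fp += 1
            else:
                raise ConfigError("cannot score an unlabeled window")
        return cls(TP=tp, TN=tn, FP=fp, FN=fn)


@dataclass(frozen=True)
class MetricsReport:
    Sn: float
    Sp: float
    Acc: float
    MCC: float
    degenerate: bool = False  # MCC forced to 0 by an empty marginal

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("metric\tvalue\n")
            for name in ("Sn", "Sp", "Acc", "MCC"):
                fh.write(f"{name}\t{getattr(self, name):.6f}\n")


def compute_metrics(cm: ConfusionMatrix, degenerate: str = "error") -> MetricsReport:
    """Sn/Sp/Acc/MCC from a confusion matrix.

    ``degenerate="zero"`` reports 0 (flagged) instead of raising when a
    marginal needed by Sn, Sp or MCC is empty.
    """
    if cm.n == 0:
        raise ConfigError("empty confusion matrix")
    flag = False

    def _ratio(num: int, den: int, name: str) -> float:
        nonlocal flag
        if den == 0:
            if degenerate == "zero":
                flag = True
                return 0.0
            raise ConfigError(f"{name} undefined: empty marginal")
        return num / den

    sn = _ratio(cm.TP, cm.TP + cm.FN, "Sn")
    sp = _ratio(cm.TN, cm.TN + cm.FP, "Sp")
    acc = (cm.TP + cm.TN) / cm.n
    denom = (cm.TP + cm.FP) * (cm.TP + cm.FN) * (cm.TN + cm.FP) * (cm.TN + cm.FN)
    if denom == 0:
        if degenerate != "zero":
            raise ConfigError("MCC undefined: an empty marginal")
        flag = True
        mcc = 0.0
    else:
        mcc = (cm.TP * cm.TN - cm.FP * cm.FN) / sqrt(denom)
    return MetricsReport(Sn=sn, Sp=sp, Acc=acc, MCC=mcc, degenerate=flag)


def _validate_dataset(windows: Sequence[SiteWindow]) -> np.ndarray:
    y = np.array([1 if w.label == POSITIVE_LABEL else -1 for w in windows])
    if len(windows) < 4:
        raise ConfigError(f"need at least 4 labeled windows, got {len(windows)}")
    if len(set(w.label for w in windows)) < 2:
        raise ConfigError("both classes must be present")
    return y


def _train_round(
    train_windows: list[SiteWindow],
    recipe: TrainingRecipe,
    seed: int,
    round_index: int,
    shared_vocabulary=None,
):
    labels = {w.label for w in train_windows}
    if len(labels) < 2:
        raise FoldError(round_index, "training fold lost one class entirely")
    try:
        if shared_vocabulary is None:
            return model_mod.train_ensemble(train_windows, recipe, seed)
        return _train_with_shared_vocab(train_windows, recipe, seed, shared_vocabulary)
    except M6aVoteError as exc:
        raise FoldError(round_index, str(exc)) from exc


def _train_with_shared_vocab(train_windows, recipe, seed, vocab):
    """Train with a pre-mined vocabulary (fast/leaky mode)."""
    from sklearn.model_selection import GridSearchCV, StratifiedKFold
    from sklearn.svm import SVC

    from .motif import encode_motifs_sparse

    residues = [w.residues for w in train_windows]
    y = np.array([1 if w.label == POSITIVE_LABEL else -1 for w in train_windows])
    min_class = min(int((y == 1).sum()), int((y == -1).sum()))
    cv = StratifiedKFold(
        n_splits=min(recipe.inner_cv, min_class), shuffle=True, random_state=seed
    )
    X = encode_motifs_sparse(residues, vocab)
    search = GridSearchCV(
        SVC(kernel="linear"), {"C": list(recipe.c_grid)}, cv=cv, scoring="accuracy"
    )
    search.fit(X, y)
    motif_clf = model_mod.BaseClassifier(
        kind="motif",
        svc=search.best_estimator_,
        cv_accuracy=float(search.best_score_),
        best_params=dict(search.best_params_),
        vocabulary=vocab,
    )
    psednc_clf = model_mod.train_base(train_windows, "psednc", recipe, seed)
    gkm_clf = model_mod.train_base(train_windows, "gkm", recipe, seed)
    classifiers = (psednc_clf, motif_clf, gkm_clf)
    if recipe.weighting == "uniform":
        weights = (1 / 3, 1 / 3, 1 / 3)
    else:
        acc = np.array([c.cv_accuracy for c in classifiers], dtype=float)
        weights = tuple(acc / acc.sum())
    return model_mod.EnsembleModel(
        classifiers=classifiers,
        weights=weights,
        seed=seed,
        training_fingerprint=model_mod.training_fingerprint(train_windows),
    )


def jackknife(
    windows: Sequence[SiteWindow],
    recipe: TrainingRecipe = TrainingRecipe(),
    seed: int = 0,
    reuse_vocabulary: bool = False,
) -> tuple[ConfusionMatrix, MetricsReport, list[PredictionRecord]]:
    """Leave-one-out evaluation: n rounds, each re-fitting the full recipe.

    With ``reuse_vocabulary`` the motif vocabulary is mined once on the whole
    dataset — faster, but the held-out window leaks into the features.
    """
    windows = list(windows)
    _validate_dataset(windows)
    shared = None
    if reuse_vocabulary:
        pos = [w.residues for w in windows if w.label == POSITIVE_LABEL]
        neg = [w.residues for w in windows if w.label == NEGATIVE_LABEL]
        shared = mine_discriminative_substrings(
            pos, neg, recipe.motif_min_len, recipe.motif_max_len,
            recipe.motif_minimal_only,
        )
        logger.warning("reuse_vocabulary=True: motif features leak held-out windows")
    records: list[PredictionRecord] = []
    for i in range(len(windows)):
        train = windows[:i] + windows[i + 1 :]
        ens = _train_round(train, recipe, seed, i, shared)
        records.extend(model_mod.predict(ens, [windows[i]]))
        logger.info("jackknife round %d/%d done", i + 1, len(windows))
    cm = ConfusionMatrix.from_records(records)
    return cm, compute_metrics(cm, degenerate="zero"), records


def kfold(
    windows: Sequence[SiteWindow],
    k: int = 10,
    recipe: TrainingRecipe = TrainingRecipe(),
    seed: int = 0,
    reuse_vocabulary: bool = False,
) -> tuple[ConfusionMatrix, MetricsReport, list[PredictionRecord]]:
    """Stratified k-fold evaluation; ``k == n`` reduces to the jackknife."""
    windows = list(windows)
    y = _validate_dataset(windows)
    if k > len(windows):
        raise ConfigError(f"k={k} exceeds dataset size n={len(windows)}")
    if k == len(windows):
        return jackknife(windows, recipe, seed, reuse_vocabulary)
    shared = None
    if reuse_vocabulary:
        pos = [w.residues for w in windows if w.label == POSITIVE_LABEL]
        neg = [w.residues for w in windows if w.label == NEGATIVE_LABEL]
        shared = mine_discriminative_substrings(
            pos, neg, recipe.motif_min_len, recipe.motif_max_len,
            recipe.motif_minimal_only,
        )
        logger.warning("reuse_vocabulary=True: motif features leak held-out windows")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    records: list[PredictionRecord] = []
    for round_index, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        train = [windows[i] for i in train_idx]
        test = [windows[i] for i in test_idx]
        ens = _train_round(train, recipe, seed, round_index, shared)
        records.extend(model_mod.predict(ens, test))
        logger.info("fold %d/%d done", round_index + 1, k)
    cm = ConfusionMatrix.from_records(records)
    return cm, compute_metrics(cm, degenerate="zero"), records


def base_classifier_accuracies(records: Sequence[PredictionRecord]) -> dict[str, float]:
    """Held-out accuracy of each base classifier, recomputed from the records."""
    out = {}
    for idx, kind in enumerate(model_mod.KINDS):
        correct = sum(1 for r in records if r.base_labels[idx] == r.window.label)
        out[kind] = correct / len(records)
    return out


def write_per_window_records(records: Sequence[PredictionRecord], path) -> None:
    """Persist per-window predictions (with truth) for audit."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "transcript_id\tcenter_pos\ttruth\tpredicted\tV_positive\tV_negative"
            "\tpsednc_label\tmotif_label\tgkm_label\n"
        )
        for r in records:
            w = r.window
            fh.write(
                f"{w.transcript_id}\t{w.center_pos}\t{w.label}\t{r.label}"
                f"\t{r.v_positive:.6f}\t{r.v_negative:.6f}\t"
                + "\t".join(r.base_labels)
                + "\n"
            )
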