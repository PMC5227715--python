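"""Ensemble of three heterogeneous SVM base classifiers with weighted voting.

The three views of a 51-nt candidate window are:

* ``psednc`` — the (16 + lambda)-dimensional pseudo dinucleotide composition,
  classified by an RBF-kernel SVM;
* ``motif``  — a sparse Boolean vector over class-discriminative substrings
  mined from the training fold, classified by a linear SVM;
* ``gkm``    — no explicit features: an SVM on the precomputed, cosine-
  normalized gapped k-mer string kernel.

Hyperparameters of every base classifier are chosen by stratified k-fold
cross-validated grid search inside the training fold only. The ensemble
prediction is a weighted vote: V_i = sum_k w_k * [pre(C_k) == class_i], and
the final label is the argmax of V, with a deterministic tie-break (the label
of the largest-weight classifier). For three independent classifiers of equal
accuracy q in (0.5, 1), majority voting achieves 3q^2 - 2q^3 > q, which is
why the ensemble can beat every one of its parts.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from . import gkm as gkm_mod
from . import motif as motif_mod
from . import psednc as psednc_mod
from .exceptions import ConfigError, TrainingError
from .seqio import NEGATIVE_LABEL, POSITIVE_LABEL, SiteWindow

KINDS = ("psednc", "motif", "gkm")

#: Regularization grid: 2^-5 .. 2^15 in powers of 4.
DEFAULT_C_GRID = tuple(2.0**e for e in range(-5, 16, 2))
#: RBF width grid: 2^-15 .. 2^3 in powers of 4.
DEFAULT_GAMMA_GRID = tuple(2.0**e for e in range(-15, 4, 2))

ARCHIVE_FORMAT_VERSION = 1


@dataclass(frozen=True)
class TrainingRecipe:
    """Everything needed to train the ensemble on a fold, reproducibly."""

    psednc: psednc_mod.PseDncConfig = field(default_factory=psednc_mod.PseDncConfig)
    motif_min_len: int = 4
    motif_max_len: int = 12
    motif_minimal_only: bool = True
    gkm: gkm_mod.GkmParams = field(default_factory=gkm_mod.GkmParams)
    weighting: str = "uniform"  # or "cv_accuracy"
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    inner_cv: int = 5

    def __post_init__(self):
        if self.weighting not in ("uniform", "cv_accuracy"):
            raise ConfigError(f"unknown weighting policy {self.weighting!r}")
        if self.inner_cv < 2:
            raise ConfigError("inner_cv must be >= 2")


@dataclass
class BaseClassifier:
    """One trained view-specific SVM plus the state its encoder needs."""

    kind: str
    svc: SVC
    cv_accuracy: float
    best_params: dict
    psednc_config: psednc_mod.PseDncConfig | None = None
    property_table: psednc_mod.PropertyTable | None = None
    vocabulary: motif_mod.MotifVocabulary | None = None
    gkm_params: gkm_mod.GkmParams | None = None
    train_residues: tuple[str, ...] | None = None  # gkm only: kernel anchors

    def predict_residues(self, residues: Sequence[str]) -> np.ndarray:
        """Predict +1 (m6A) / -1 labels for normalized sequences."""
        if self.kind == "psednc":
            X = psednc_mod.encode_psednc(
                residues, self.psednc_config, self.property_table
            )
        elif self.kind == "motif":
            X = motif_mod.encode_motifs_sparse(residues, self.vocabulary)
        elif self.kind == "gkm":
            X = gkm_mod.gkm_cross_matrix(
                residues, list(self.train_residues), self.gkm_params, normalize=True
            )
        else:  # pragma: no cover - guarded at construction
            raise ConfigError(f"unknown classifier kind {self.kind!r}")
        return self.svc.predict(X).astype(int)


@dataclass
class EnsembleModel:
    """Three base classifiers (psednc, motif, gkm), voting weights and tie-break."""

    classifiers: tuple[BaseClassifier, BaseClassifier, BaseClassifier]
    weights: tuple[float, float, float]
    tie_break: str = "largest_weight"
    seed: int = 0
    training_fingerprint: str = ""
    format_version: int = ARCHIVE_FORMAT_VERSION

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ConfigError(f"weights must be non-negative and sum to 1, got {self.weights}")
        kinds = tuple(c.kind for c in self.classifiers)
        if kinds != KINDS:
            raise ConfigError(f"classifiers must be ordered {KINDS}, got {kinds}")


@dataclass(frozen=True)
class PredictionRecord:
    window: SiteWindow
    label: str
    v_positive: float
    v_negative: float
    base_labels: tuple[str, str, str]  # psednc, motif, gkm


@dataclass(frozen=True)
class VotingScenario:
    """Accuracies of three independent base classifiers, each in (0.5, 1]."""

    p1: float
    p2: float
    p3: float

    def __post_init__(self):
        for name, p in (("p1", self.p1), ("p2", self.p2), ("p3", self.p3)):
            if not (0.5 < p <= 1.0):
                raise ConfigError(f"{name}={p} outside the (0.5, 1] domain")

    @property
    def ps(self) -> tuple[float, float, float]:
        return (self.p1, self.p2, self.p3)


def _split_windows(windows: Sequence[SiteWindow]) -> tuple[list[str], np.ndarray]:
    residues = [w.residues for w in windows]
    y = []
    for w in windows:
        if w.label == POSITIVE_LABEL:
            y.append(1)
        elif w.label == NEGATIVE_LABEL:
            y.append(-1)
        else:
            raise TrainingError(
                f"window on {w.transcript_id!r} at {w.center_pos} is unlabeled"
            )
    return residues, np.asarray(y)


def _check_two_classes(y: np.ndarray) -> None:
    n_pos, n_neg = int((y == 1).sum()), int((y == -1).sum())
    if n_pos < 2 or n_neg < 2:
        raise TrainingError(
            f"need at least 2 windows per class, got {n_pos} positive / {n_neg} negative"
        )


def training_fingerprint(windows: Sequence[SiteWindow]) -> str:
    """Order-insensitive sha256 of the labeled training material."""
    h = hashlib.sha256()
    for item in sorted((w.residues, str(w.label)) for w in windows):
        h.update("\t".join(item).encode())
        h.update(b"\n")
    return h.hexdigest()


def train_base(
    windows: Sequence[SiteWindow],
    kind: str,
    recipe: TrainingRecipe = TrainingRecipe(),
    seed: int = 0,
) -> BaseClassifier:
    """Train one view-specific SVM with in-fold cross-validated grid search."""
    if kind not in KINDS:
        raise ConfigError(f"unknown classifier kind {kind!r}; expected one of {KINDS}")
    residues, y = _split_windows(windows)
    _check_two_classes(y)
    min_class = min(int((y == 1).sum()), int((y == -1).sum()))
    n_splits = min(recipe.inner_cv, min_class)
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)

    extra: dict = {}
    if kind == "psednc":
        table = psednc_mod.standardize_properties(psednc_mod.builtin_property_table())
        X = psednc_mod.encode_psednc(residues, recipe.psednc, table)
        grid = {"C": list(recipe.c_grid), "gamma": list(recipe.gamma_grid)}
        base = SVC(kernel="rbf")
        extra = {"psednc_config": recipe.psednc, "property_table": table}
    elif kind == "motif":
        return _train_motif(residues, y, recipe, cv)
    else:  # gkm
        X = gkm_mod.gkm_kernel_matrix(residues, recipe.gkm, normalize=True).values
        grid = {"C": list(recipe.c_grid)}
        base = SVC(kernel="precomputed")
        extra = {"gkm_params": recipe.gkm, "train_residues": tuple(residues)}

    search = GridSearchCV(base, grid, cv=cv, scoring="accuracy", n_jobs=1, refit=True)
    search.fit(X, y)
    return BaseClassifier(
        kind=kind,
        svc=search.best_estimator_,
        cv_accuracy=float(search.best_score_),
        best_params=dict(search.best_params_),
        **extra,
    )


def _train_motif(
    residues: list[str], y: np.ndarray, recipe: TrainingRecipe, cv
) -> BaseClassifier:
    """Linear SVM on discriminative-substring features.

    The vocabulary is itself part of the model, so the inner CV re-mines it
    on each inner training split — mining once on the full fold would leak
    the validation sequences into the features and make every C look
    perfect. Per-sequence substring sets are precomputed so the re-mining
    costs only set algebra.
    """
    sets = [
        motif_mod.substring_set(r, recipe.motif_min_len, recipe.motif_max_len)
        for r in residues
    ]

    def _mine(indices) -> motif_mod.MotifVocabulary:
        return motif_mod.mine_from_substring_sets(
            [sets[i] for i in indices if y[i] == 1],
            [sets[i] for i in indices if y[i] == -1],
            recipe.motif_min_len, recipe.motif_max_len, recipe.motif_minimal_only,
        )

    fold_scores = []
    for train_idx, val_idx in cv.split(np.zeros(len(y)), y):
        vocab = _mine(train_idx)
        if not vocab.entries:  # no discriminative substring: majority guess
            majority = 1 if (y[train_idx] == 1).sum() >= (y[train_idx] == -1).sum() else -1
            fold_scores.append(
                [float((y[val_idx] == majority).mean())] * len(recipe.c_grid)
            )
            continue
        X_tr = motif_mod.encode_sets_sparse([sets[i] for i in train_idx], vocab)
        X_va = motif_mod.encode_sets_sparse([sets[i] for i in val_idx], vocab)
        fold_scores.append(
            [
                SVC(kernel="linear", C=C).fit(X_tr, y[train_idx]).score(X_va, y[val_idx])
                for C in recipe.c_grid
            ]
        )
    mean_scores = np.mean(fold_scores, axis=0)
    best_idx = int(np.argmax(mean_scores))  # first grid point on ties
    best_c = recipe.c_grid[best_idx]

    vocab = _mine(range(len(residues)))
    X = motif_mod.encode_sets_sparse(sets, vocab)
    svc = SVC(kernel="linear", C=best_c).fit(X, y)
    return BaseClassifier(
        kind="motif",
        svc=svc,
        cv_accuracy=float(mean_scores[best_idx]),
        best_params={"C": best_c},
        vocabulary=vocab,
    )


def vote(
    per_classifier_labels: Sequence[str],
    weights: Sequence[float],
    tie_break: str = "largest_weight",
) -> tuple[str, float, float]:
    """Weighted vote over three base labels: returns (label, V_pos, V_neg).

    V_i sums the weights of the classifiers agreeing with class_i; the final
    label maximizes V_i. An exact tie falls to the label of the classifier
    carrying the largest weight (first such classifier on weight ties).
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ConfigError(f"weights must be non-negative and sum to 1, got {weights}")
    labels = list(per_classifier_labels)
    v_pos = float(sum(wk for wk, lab in zip(w, labels) if lab == POSITIVE_LABEL))
    v_neg = float(sum(wk for wk, lab in zip(w, labels) if lab == NEGATIVE_LABEL))
    if v_pos > v_neg:
        final = POSITIVE_LABEL
    elif v_neg > v_pos:
        final = NEGATIVE_LABEL
    else:
        if tie_break != "largest_weight":
            raise ConfigError(f"unknown tie_break {tie_break!r}")
        final = labels[int(np.argmax(w))]
    return final, v_pos, v_neg


def train_ensemble(
    windows: Sequence[SiteWindow],
    recipe: TrainingRecipe = TrainingRecipe(),
    seed: int = 0,
) -> EnsembleModel:
    """Train the three base classifiers on one fold and set the vote weights."""
    classifiers = tuple(train_base(windows, kind, recipe, seed) for kind in KINDS)
    if recipe.weighting == "uniform":
        weights = (1 / 3, 1 / 3, 1 / 3)
    else:
        acc = np.array([c.cv_accuracy for c in classifiers], dtype=float)
        if acc.sum() == 0:
            weights = (1 / 3, 1 / 3, 1 / 3)
        else:
            weights = tuple(acc / acc.sum())
    return EnsembleModel(
        classifiers=classifiers,
        weights=weights,
        seed=seed,
        training_fingerprint=training_fingerprint(windows),
    )


def predict(model: EnsembleModel, windows: Sequence[SiteWindow]) -> list[PredictionRecord]:
    """Vote the three base classifiers over candidate windows."""
    if not windows:
        return []
    residues = [w.residues for w in windows]
    base_preds = [clf.predict_residues(residues) for clf in model.classifiers]
    records = []
    for i, w in enumerate(windows):
        labels = tuple(
            POSITIVE_LABEL if base_preds[k][i] == 1 else NEGATIVE_LABEL
            for k in range(3)
        )
        final, v_pos, v_neg = vote(labels, model.weights, model.tie_break)
        records.append(
            PredictionRecord(
                window=w, label=final, v_positive=v_pos, v_negative=v_neg,
                base_labels=labels,
            )
        )
    return records


def voting_accuracy_closed_form(scenario: VotingScenario) -> float:
    """Probability that at least 2 of 3 independent voters are correct:

    P = p1 p2 p3 + p1 p2 (1-p3) + p1 (1-p2) p3 + (1-p1) p2 p3.

    For p1 = p2 = p3 = q this is 3q^2 - 2q^3, which exceeds q on (0.5, 1).
    """
    p1, p2, p3 = scenario.ps
    return (
        p1 * p2 * p3
        + p1 * p2 * (1 - p3)
        + p1 * (1 - p2) * p3
        + (1 - p1) * p2 * p3
    )


def simulate_voting(scenario: VotingScenario, n_trials: int, seed: int = 0) -> float:
    """Monte-Carlo estimate of the majority-vote accuracy."""
    if n_trials < 1:
        raise ConfigError(f"n_trials must be >= 1, got {n_trials}")
    rng = np.random.default_rng(seed)
    correct = rng.random((n_trials, 3)) < np.asarray(scenario.ps)
    return float((correct.sum(axis=1) >= 2).mean())


def save_model(model: EnsembleModel, path) -> None:
    """Persist the ensemble as a single self-contained archive file."""
    joblib.dump({"format_version": ARCHIVE_FORMAT_VERSION, "model": model}, path)


def load_model(path) -> EnsembleModel:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != ARCHIVE_FORMAT_VERSION:
        raise ConfigError(f"unsupported model archive version {version!r}")
    return payload["model"]
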