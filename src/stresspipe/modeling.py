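"""Model training and the five-way cross-environment evaluation matrix.

The classification task is binary stress recognition from session-level
feature vectors.  Five model types cross the training/testing
environment (laboratory vs. daily life) with the ground-truth family
(known protocol context vs. PSS-5 self-report):

* LLKC — lab-to-lab, known-context labels (baseline vs. stressor phase)
* LLSR — lab-to-lab, self-report labels
* DDSR — daily-to-daily, self-report labels
* LDKC — trained on lab known-context, tested on daily self-reports
* LDSR — trained on lab self-reports, tested on daily self-reports

Each cell combines a feature modality (HRV, EDA or both), a classifier
(MLP 2×5, random forest with 100 trees, 3-NN, RBF-kernel SVM, logistic
regression at the 0.5 threshold), correlation-based feature selection,
exact-balance random undersampling of the majority class and per-feature
min-max normalization.  In cross-validation these preparation steps are
fit inside each training fold by default; a ``global_prep`` switch
reproduces the conventional—but leaky—global preparation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .config import DEFAULT_CONFIG, PipelineConfig
from .io_e4 import SessionRecord, records_to_frame
from .labeling import RELAXED, STRESSED
from .schema import MODALITY_COLUMNS
from .synthetic_data import StudyDataset

logger = logging.getLogger(__name__)

CLASSIFIERS = ("mlp", "rf", "knn", "svm", "logreg")
MODALITIES = ("hrv", "eda", "combined")
MODEL_TYPES = ("LLKC", "LLSR", "DDSR", "LDKC", "LDSR")

#: best-k defaults: 10 combined, 5 per single modality
DEFAULT_K = {"hrv": 5, "eda": 5, "combined": 10}

LABEL_CODES = {RELAXED: 0, STRESSED: 1}


@dataclass(frozen=True)
class ModelSpec:
    """One classifier/modality configuration of a matrix cell."""

    classifier: str = "rf"
    modality: str = "combined"
    k_features: Optional[int] = None      # None -> modality default
    selection: str = "correlation_rank"   # or "cfs_subset"

    def __post_init__(self) -> None:
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def k(self) -> int:
        return self.k_features if self.k_features is not None else DEFAULT_K[self.modality]


@dataclass
class LabeledDataset:
    """Feature matrix with a materialized binary label column."""

    X: pd.DataFrame               # feature columns only
    y: np.ndarray                 # 0 = relaxed, 1 = stressed
    environment: str              # 'lab' or 'daily'

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if len(self.X) != len(self.y):
            raise ValueError("X and y length mismatch")

    def __len__(self) -> int:
        return len(self.X)

    def for_modality(self, modality: str) -> "LabeledDataset":
        """Restrict to a modality's columns, dropping rows with missing features."""
        cols = list(MODALITY_COLUMNS[modality])
        X = self.X[cols]
        keep = np.isfinite(X.to_numpy(dtype=float)).all(axis=1)
        return LabeledDataset(X[keep].reset_index(drop=True), self.y[keep], self.environment)


@dataclass
class EvalResult:
    """Accuracy, fold spread and confusion counts of one evaluated cell."""

    model_type: str
    eval_mode: str                      # 'cv10', 'split80' or 'transfer'
    classifier: str
    modality: str
    accuracy: float                     # %
    fold_sd: Optional[float]            # %, CV only
    confusion: np.ndarray               # 2x2, rows true (relaxed, stressed)
    n_train: int
    n_test: int
    selected_features: tuple[str, ...]
    y_true: np.ndarray
    y_pred: np.ndarray


def make_classifier(name: str, seed: int):
    """Classifier with the study's hyperparameters; library defaults elsewhere."""
    seed = int(seed) % (2**31)
    if name == "mlp":
        return MLPClassifier(hidden_layer_sizes=(5, 5), max_iter=500, random_state=seed)
    if name == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=3)
    if name == "svm":
        return SVC(kernel="rbf", random_state=seed)
    if name == "logreg":
        return LogisticRegression(max_iter=1000)  # predict() thresholds at 0.5
    raise ValueError(f"unknown classifier {name!r}")


# ---------------------------------------------------------------------------
# preparation primitives

def _abs_pointbiserial(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|Pearson correlation| of each column with the 0/1 label (0 if constant)."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = Xc.std(axis=0)
    sy = yc.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * yc[:, None]).mean(axis=0) / (sx * sy)
    r[~np.isfinite(r)] = 0.0
    return np.abs(r)


def _cfs_merit(subset: list[int], rcf: np.ndarray, rff: np.ndarray) -> float:
    """CFS merit: k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)."""
    k = len(subset)
    mean_cf = rcf[subset].mean()
    if k == 1:
        return float(mean_cf)
    pairs = [(i, j) for n, i in enumerate(subset) for j in subset[n + 1:]]
    mean_ff = float(np.mean([rff[i, j] for i, j in pairs]))
    return float(k * mean_cf / np.sqrt(k + k * (k - 1) * mean_ff))


def select_features(
    X: pd.DataFrame, y: np.ndarray, k: int, method: str = "correlation_rank"
) -> list[str]:
    """Choose ``k`` feature names on training data only.

    ``correlation_rank`` ranks by absolute point-biserial correlation with
    the binary label (ties broken by schema order); ``cfs_subset`` runs a
    greedy best-first search on the CFS merit, growing the subset to ``k``.
    """
    if len(np.unique(y)) < 2:
        raise ValueError("select_features requires both classes in the training data")
    if k < 1 or k > X.shape[1]:
        raise ValueError(f"k={k} outside [1, {X.shape[1]}]")
    Xv = X.to_numpy(dtype=float)
    rcf = _abs_pointbiserial(Xv, np.asarray(y, dtype=float))
    if method == "correlation_rank":
        order = np.argsort(-rcf, kind="stable")   # stable: ties keep schema order
        return [X.columns[i] for i in order[:k]]
    if method == "cfs_subset":
        with np.errstate(invalid="ignore", divide="ignore"):
            rff = np.abs(np.corrcoef(Xv, rowvar=False))
        rff[~np.isfinite(rff)] = 0.0
        chosen: list[int] = []
        remaining = list(range(X.shape[1]))
        while len(chosen) < k:
            merits = [(_cfs_merit(chosen + [j], rcf, rff), -j) for j in remaining]
            best = max(range(len(remaining)), key=lambda i: merits[i])
            chosen.append(remaining.pop(best))
        return [X.columns[i] for i in sorted(chosen, key=chosen.index)]
    raise ValueError(f"unknown selection method {method!r}")


def undersample(y: np.ndarray, seed: int | np.random.Generator) -> np.ndarray:
    """Row indices after exact-balance random undersampling of the majority.

    Minority rows are all kept; majority rows are uniformly sampled without
    replacement down to the minority count.  Returned indices are sorted,
    so original row order is preserved.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() == 0:
        raise ValueError("undersample requires rows from both classes")
    n_min = counts.min()
    keep: list[np.ndarray] = []
    for cls, cnt in zip(classes, counts):
        idx = np.flatnonzero(y == cls)
        if cnt > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))


@dataclass
class MinMaxParams:
    mins: np.ndarray
    scales: np.ndarray            # max - min; 0 for constant columns

    def apply(self, X: np.ndarray) -> np.ndarray:
        out = np.zeros_like(X, dtype=float)
        nz = self.scales != 0
        out[:, nz] = (X[:, nz] - self.mins[nz]) / self.scales[nz]
        return out


def normalize(train: np.ndarray, test: Optional[np.ndarray] = None):
    """Min-max scale to [0, 1] with parameters fit on train only.

    Test values may leave [0, 1]; constant training columns map to 0.
    Returns (train', test', params); test' is None when no test given.
    """
    train = np.asarray(train, dtype=float)
    params = MinMaxParams(mins=train.min(axis=0), scales=np.ptp(train, axis=0))
    test_out = params.apply(np.asarray(test, dtype=float)) if test is not None else None
    return params.apply(train), test_out, params


# ---------------------------------------------------------------------------
# fitting one cell

@dataclass
class FittedCell:
    features: list[str]
    scaler: MinMaxParams
    clf: object


def _fit(X: pd.DataFrame, y: np.ndarray, spec: ModelSpec, seed: int) -> FittedCell:
    """Undersample, select, normalize and fit on training rows only."""
    rng = np.random.default_rng(seed)
    idx = undersample(y, rng)
    Xb, yb = X.iloc[idx], y[idx]
    feats = select_features(Xb, yb, spec.k, spec.selection)
    Xs, _, scaler = normalize(Xb[feats].to_numpy(dtype=float))
    clf = make_classifier(spec.classifier, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(Xs, yb)
    return FittedCell(features=feats, scaler=scaler, clf=clf)


def _predict(cell: FittedCell, X: pd.DataFrame) -> np.ndarray:
    return cell.clf.predict(cell.scaler.apply(X[cell.features].to_numpy(dtype=float)))


def _accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return 100.0 * float(np.mean(y_true == y_pred))


# ---------------------------------------------------------------------------
# evaluation protocols

def evaluate_cv(
    ds: LabeledDataset,
    spec: ModelSpec,
    folds: int = 10,
    seed: int = 0,
    model_type: str = "",
    global_prep: bool = False,
) -> EvalResult:
    """Stratified k-fold cross-validation of one cell.

    By default undersampling, selection and normalization are re-fit
    inside every training fold.  ``global_prep`` instead performs them
    once globally before folding (the conventional order, which leaks
    test information into preparation).
    """
    data = ds.for_modality(spec.modality)
    classes, counts = np.unique(data.y, return_counts=True)
    if len(classes) < 2 or counts.min() < folds:
        raise ValueError(
            f"evaluate_cv needs >= {folds} rows per class; smallest class has "
            f"{0 if len(classes) < 2 else counts.min()}"
        )
    rng = np.random.default_rng(seed)
    X, y = data.X, data.y
    if global_prep:
        idx = undersample(y, rng)
        X, y = X.iloc[idx].reset_index(drop=True), y[idx]
        feats = select_features(X, y, spec.k, spec.selection)
        Xn, _, _ = normalize(X[feats].to_numpy(dtype=float))
        X = pd.DataFrame(Xn, columns=feats)

    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=int(rng.integers(2**31)))
    fold_acc, confs, feat_lists = [], [], []
    y_true_all, y_pred_all = [], []
    for tr_idx, te_idx in skf.split(X, y):
        fold_seed = int(rng.integers(2**31))
        if global_prep:
            clf = make_classifier(spec.classifier, fold_seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf.fit(X.iloc[tr_idx].to_numpy(dtype=float), y[tr_idx])
            y_pred = clf.predict(X.iloc[te_idx].to_numpy(dtype=float))
            feat_lists.append(tuple(X.columns))
        else:
            cell = _fit(X.iloc[tr_idx].reset_index(drop=True), y[tr_idx], spec, fold_seed)
            y_pred = _predict(cell, X.iloc[te_idx])
            feat_lists.append(tuple(cell.features))
        y_te = y[te_idx]
        fold_acc.append(_accuracy(y_te, y_pred))
        confs.append(confusion_matrix(y_te, y_pred, labels=[0, 1]))
        y_true_all.append(y_te)
        y_pred_all.append(y_pred)

    freq: dict[str, int] = {}
    for fl in feat_lists:
        for f in fl:
            freq[f] = freq.get(f, 0) + 1
    selected = tuple(sorted(freq, key=lambda f: (-freq[f], f)))
    return EvalResult(
        model_type=model_type, eval_mode=f"cv{folds}",
        classifier=spec.classifier, modality=spec.modality,
        accuracy=float(np.mean(fold_acc)),
        fold_sd=float(np.std(fold_acc, ddof=1)),
        confusion=np.sum(confs, axis=0),
        n_train=len(y) - len(y) // folds, n_test=len(y),
        selected_features=selected,
        y_true=np.concatenate(y_true_all), y_pred=np.concatenate(y_pred_all),
    )


def evaluate_split(
    ds: LabeledDataset,
    spec: ModelSpec,
    train_frac: float = 0.8,
    seed: int = 0,
    model_type: str = "",
) -> EvalResult:
    """Single stratified train/test split (80/20 by default)."""
    data = ds.for_modality(spec.modality)
    classes, counts = np.unique(data.y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("evaluate_split needs >= 2 rows per class")
    rng = np.random.default_rng(seed)
    tr_idx, te_idx = train_test_split(
        np.arange(len(data)), train_size=train_frac, stratify=data.y,
        random_state=int(rng.integers(2**31)),
    )
    cell = _fit(data.X.iloc[tr_idx].reset_index(drop=True), data.y[tr_idx],
                spec, int(rng.integers(2**31)))
    y_pred = _predict(cell, data.X.iloc[te_idx])
    y_te = data.y[te_idx]
    return EvalResult(
        model_type=model_type, eval_mode="split80",
        classifier=spec.classifier, modality=spec.modality,
        accuracy=_accuracy(y_te, y_pred), fold_sd=None,
        confusion=confusion_matrix(y_te, y_pred, labels=[0, 1]),
        n_train=len(tr_idx), n_test=len(te_idx),
        selected_features=tuple(cell.features),
        y_true=y_te, y_pred=y_pred,
    )


def evaluate_transfer(
    train_ds: LabeledDataset,
    test_ds: LabeledDataset,
    spec: ModelSpec,
    seed: int = 0,
    model_type: str = "",
) -> EvalResult:
    """Cross-environment evaluation: fit on one environment, score the other.

    Preparation (undersampling, selection, normalization) is fit on the
    training environment only; the fitted model never sees test labels.
    """
    if train_ds.environment == test_ds.environment:
        raise ValueError("evaluate_transfer requires disjoint environments")
    train = train_ds.for_modality(spec.modality)
    test = test_ds.for_modality(spec.modality)
    if len(test) == 0:
        raise ValueError("evaluate_transfer: empty test set")
    cell = _fit(train.X, train.y, spec, seed)
    y_pred = _predict(cell, test.X)
    return EvalResult(
        model_type=model_type, eval_mode="transfer",
        classifier=spec.classifier, modality=spec.modality,
        accuracy=_accuracy(test.y, y_pred), fold_sd=None,
        confusion=confusion_matrix(test.y, y_pred, labels=[0, 1]),
        n_train=len(train), n_test=len(test),
        selected_features=tuple(cell.features),
        y_true=test.y, y_pred=y_pred,
    )


# ---------------------------------------------------------------------------
# dataset assembly and the full matrix

def build_datasets(records: Sequence[SessionRecord]) -> dict[str, LabeledDataset]:
    """Materialize the three label/environment datasets from session records.

    ``lab_context`` uses the two-class known-context labels (recovery
    phases excluded); ``lab_selfreport`` and ``daily_selfreport`` use the
    binarized PSS-5 score.  Rows missing the chosen label are dropped.
    """
    frame = records_to_frame(records)
    feature_cols = list(MODALITY_COLUMNS["combined"])
    out: dict[str, LabeledDataset] = {}

    def make(sub: pd.DataFrame, label_col: str, env: str) -> Optional[LabeledDataset]:
        sub = sub[sub[label_col].isin(LABEL_CODES)]
        if len(sub) == 0:
            return None
        y = sub[label_col].map(LABEL_CODES).to_numpy(dtype=int)
        return LabeledDataset(sub[feature_cols].reset_index(drop=True), y, env)

    lab = frame[frame["environment"] == "lab"]
    daily = frame[frame["environment"] == "daily"]
    for key, sub, col, env in (
        ("lab_context", lab, "stress_context", "lab"),
        ("lab_selfreport", lab, "stress_selfreport", "lab"),
        ("daily_selfreport", daily, "stress_selfreport", "daily"),
    ):
        ds = make(sub, col, env)
        if ds is not None:
            out[key] = ds
        else:
            logger.warning("no rows with %s labels; %s dataset unavailable", col, key)
    return out


@dataclass(frozen=True)
class MatrixConfig:
    classifiers: tuple[str, ...] = CLASSIFIERS
    modalities: tuple[str, ...] = MODALITIES
    model_types: tuple[str, ...] = MODEL_TYPES
    folds: int = 10
    train_frac: float = 0.8
    selection: str = "correlation_rank"
    k_features: Optional[int] = None
    global_prep: bool = False
    pipeline: PipelineConfig = field(default_factory=lambda: DEFAULT_CONFIG)


#: (training dataset, testing dataset or None→CV/split) per model type
_MATRIX_PLAN = {
    "LLKC": ("lab_context", None),
    "LLSR": ("lab_selfreport", None),
    "DDSR": ("daily_selfreport", None),
    "LDKC": ("lab_context", "daily_selfreport"),
    "LDSR": ("lab_selfreport", "daily_selfreport"),
}


def matrix_from_records(
    records: Sequence[SessionRecord],
    config: MatrixConfig = MatrixConfig(),
    seed: int = 0,
) -> list[EvalResult]:
    """Evaluate every requested matrix cell on extracted session records.

    Within-environment model types are evaluated by both 10-fold CV and an
    80/20 split; cross-environment types by a single transfer evaluation.
    Cells whose label family or row counts make evaluation impossible are
    skipped with a logged reason.
    """
    datasets = build_datasets(records)
    rng = np.random.default_rng(seed)
    results: list[EvalResult] = []
    for model_type in config.model_types:
        train_key, test_key = _MATRIX_PLAN[model_type]
        for modality in config.modalities:
            for clf in config.classifiers:
                spec = ModelSpec(classifier=clf, modality=modality,
                                 k_features=config.k_features,
                                 selection=config.selection)
                cell_seed = int(rng.integers(2**31))
                try:
                    if test_key is None:
                        results.append(evaluate_cv(
                            datasets[train_key], spec, config.folds, cell_seed,
                            model_type, config.global_prep))
                        results.append(evaluate_split(
                            datasets[train_key], spec, config.train_frac,
                            cell_seed, model_type))
                    else:
                        results.append(evaluate_transfer(
                            datasets[train_key], datasets[test_key], spec,
                            cell_seed, model_type))
                except (KeyError, ValueError) as exc:
                    logger.warning("cell %s/%s/%s skipped: %s",
                                   model_type, modality, clf, exc)
    return results


def run_model_matrix(
    study: StudyDataset,
    config: MatrixConfig = MatrixConfig(),
    seed: int = 0,
) -> list[EvalResult]:
    """Full pipeline on a study: extract session records, evaluate all cells."""
    from .pipeline import extract_session_records

    records = extract_session_records(study, config.pipeline)
    return matrix_from_records(records, config, seed)


def results_frame(results: Sequence[EvalResult]) -> pd.DataFrame:
    """Tabular summary in the shape of the accuracy tables."""
    return pd.DataFrame([
        {
            "model_type": r.model_type,
            "eval_mode": r.eval_mode,
            "modality": r.modality,
            "classifier": r.classifier,
            "accuracy": r.accuracy,
            "fold_sd": r.fold_sd,
            "n_train": r.n_train,
            "n_test": r.n_test,
        }
        for r in results
    ])
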