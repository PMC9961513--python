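"""Dataset splitting, cross-validation and the three discriminant classifiers.

The calibration/prediction split is the deterministic Kennard-Stone max-min
design; cross-validation uses venetian blinds (row ``i`` of the stored dataset
order goes to fold ``i mod n_splits``).  PLS-DA is a NIPALS partial least
squares regression onto class-indicator columns with an arg-max assignment
rule; the RBF C-SVM and single-hidden-layer ANN routes operate on PLS-score
compressed inputs.  All preprocessing is (re)fitted strictly inside each
training partition — held-out rows never touch fitted state.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .exceptions import InputError
from .hypercube import SpectraTable
from .metrics import ClassMetrics, class_error, overall_accuracy, per_class_report
from .preprocess import PreprocessChain, make_chain

__all__ = [
    "SplitPlan",
    "CVPlan",
    "kennard_stone_split",
    "venetian_blinds",
    "class_indicators",
    "PLSDAModel",
    "plsda_fit",
    "plsda_cv",
    "PLSCompressor",
    "pls_compress",
    "SVMConfig",
    "ANNConfig",
    "svm_fit",
    "svm_predict",
    "ann_fit",
    "ann_predict",
    "ModelReport",
    "evaluate_model",
]


# ---------------------------------------------------------------------------
# splitting and cross-validation


@dataclass(frozen=True)
class SplitPlan:
    calibration_indices: np.ndarray
    prediction_indices: np.ndarray
    fraction: float

    def __post_init__(self):
        cal = np.asarray(self.calibration_indices, dtype=int)
        pred = np.asarray(self.prediction_indices, dtype=int)
        object.__setattr__(self, "calibration_indices", cal)
        object.__setattr__(self, "prediction_indices", pred)
        n = cal.size + pred.size
        union = np.sort(np.concatenate([cal, pred]))
        if not np.array_equal(union, np.arange(n)):
            raise InputError("calibration/prediction indices must partition 0..n-1")


@dataclass(frozen=True)
class CVPlan:
    """Venetian-blinds fold assignment over the stored dataset order."""

    n_splits: int
    assignment: np.ndarray

    def folds(self) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        for f in range(self.n_splits):
            val = np.flatnonzero(self.assignment == f)
            train = np.flatnonzero(self.assignment != f)
            if val.size:
                yield train, val


def venetian_blinds(n: int, n_splits: int = 10) -> CVPlan:
    """Row ``i`` belongs to fold ``i mod n_splits`` (one sample per blind)."""
    if n < 2 or n_splits < 2:
        raise InputError("venetian blinds needs n >= 2 and n_splits >= 2")
    return CVPlan(n_splits=n_splits, assignment=np.arange(n) % n_splits)


def kennard_stone_split(X, fraction: float = 0.95) -> SplitPlan:
    """Deterministic Kennard-Stone max-min calibration selection.

    The two most distant samples (Euclidean) seed the calibration set; each
    further pick maximises its minimum distance to the already-chosen set.
    The calibration size is ``ceil(fraction * n)``.  Ties break on the lowest
    index, so duplicate-heavy data still yields a reproducible plan.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if not 0.0 < fraction < 1.0:
        raise InputError("fraction must lie in (0, 1)")
    if n < 2:
        raise InputError("Kennard-Stone needs at least 2 samples")
    n_cal = int(min(max(math.ceil(fraction * n), 2), n - 1))
    D = cdist(X, X)
    if D.max() == 0.0:
        first, second = 0, 1
    else:
        flat = int(np.argmax(D))  # first occurrence = lowest (i, j) pair
        first, second = divmod(flat, n)
        if first > second:
            first, second = second, first
    selected = np.zeros(n, dtype=bool)
    selected[[first, second]] = True
    min_dist = np.minimum(D[first], D[second])
    order = [first, second]
    while len(order) < n_cal:
        masked = np.where(selected, -np.inf, min_dist)
        nxt = int(np.argmax(masked))
        selected[nxt] = True
        order.append(nxt)
        min_dist = np.minimum(min_dist, D[nxt])
    cal = np.flatnonzero(selected)
    pred = np.flatnonzero(~selected)
    return SplitPlan(cal, pred, fraction)


# ---------------------------------------------------------------------------
# PLS core (NIPALS, X-deflation only)


def class_indicators(y, classes: Sequence | None = None) -> tuple[np.ndarray, list]:
    """One-hot indicator matrix (one column per class) and the class order."""
    y = np.asarray(y)
    if classes is None:
        classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise InputError("need at least 2 classes")
    Y = np.column_stack([(y == c).astype(float) for c in classes])
    return Y, list(classes)


def _nipals(Xc, Yc, n_components, tol=1e-10, max_iter=500):
    """NIPALS PLS on centred X/Y; deflates X only.

    Returns (W, P, Q, T), possibly with fewer columns than requested when the
    residual X collapses.
    """
    Xd = Xc.copy()
    n, p = Xd.shape
    W = []
    P = []
    Q = []
    T = []
    for _ in range(n_components):
        col = int(np.argmax(np.einsum("ij,ij->j", Yc, Yc)))
        u = Yc[:, col].copy()
        if not np.any(u):
            break
        t = np.zeros(n)
        for _ in range(max_iter):
            w = Xd.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w /= nw
            t_new = Xd @ w
            q = Yc.T @ t_new / (t_new @ t_new)
            u = Yc @ q / (q @ q)
            if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t_new), 1e-30):
                t = t_new
                break
            t = t_new
        tt = t @ t
        if tt <= 1e-30:
            break
        p_load = Xd.T @ t / tt
        q = Yc.T @ t / tt
        Xd -= np.outer(t, p_load)
        W.append(w)
        P.append(p_load)
        Q.append(q)
        T.append(t)
    if not W:
        raise InputError("PLS found no usable component (X has no variance)")
    return (np.column_stack(W), np.column_stack(P), np.column_stack(Q), np.column_stack(T))


def _pls_rotations(W, P, a):
    """R such that scores of new centred data are X @ R (first ``a`` LVs)."""
    return W[:, :a] @ np.linalg.inv(P[:, :a].T @ W[:, :a])


class _PLSCore:
    """Fitted NIPALS state with per-LV prediction support."""

    def __init__(self, X, Y, n_components):
        X = np.asarray(X, float)
        Y = np.asarray(Y, float)
        n_components = int(min(n_components, max(X.shape[0] - 1, 1), X.shape[1]))
        self.x_mean = X.mean(axis=0)
        self.y_mean = Y.mean(axis=0)
        self.W, self.P, self.Q, self.T = _nipals(
            X - self.x_mean, Y - self.y_mean, n_components
        )
        self.n_components = self.W.shape[1]

    def predict_y(self, X, a: int | None = None) -> np.ndarray:
        a = self.n_components if a is None else min(a, self.n_components)
        R = _pls_rotations(self.W, self.P, a)
        scores = (np.asarray(X, float) - self.x_mean) @ R
        return scores @ self.Q[:, :a].T + self.y_mean

    def scores(self, X, a: int | None = None) -> np.ndarray:
        a = self.n_components if a is None else min(a, self.n_components)
        R = _pls_rotations(self.W, self.P, a)
        return (np.asarray(X, float) - self.x_mean) @ R


# ---------------------------------------------------------------------------
# PLS-DA


class PLSDAModel:
    """PLS-DA: NIPALS regression of class indicators on preprocessed spectra.

    The decision rule assigns each sample to the class whose predicted
    indicator is largest.  The preprocessing chain is fitted inside ``fit``,
    on calibration rows only.
    """

    def __init__(self, n_lv: int, chain: str | Sequence = ()):
        self.n_lv = int(n_lv)
        self.chain_spec = chain
        self.chain: PreprocessChain | None = None
        self.classes_: list | None = None
        self.core_: _PLSCore | None = None

    def fit(self, X_cal, y_cal) -> "PLSDAModel":
        Y, classes = class_indicators(y_cal)
        self.classes_ = classes
        self.chain = make_chain(self.chain_spec)
        Xp = self.chain.fit_apply(X_cal, Y - Y.mean(axis=0))
        if self.n_lv > min(Xp.shape[0] - 1, Xp.shape[1]):
            raise InputError(
                f"n_lv={self.n_lv} exceeds min(n-1, bands)="
                f"{min(Xp.shape[0] - 1, Xp.shape[1])}"
            )
        self.core_ = _PLSCore(Xp, Y, self.n_lv)
        return self

    def decision_values(self, X) -> np.ndarray:
        if self.core_ is None:
            raise InputError("model not fitted")
        return self.core_.predict_y(self.chain.apply(X))

    def predict(self, X) -> np.ndarray:
        values = self.decision_values(X)
        idx = np.argmax(values, axis=1)
        return np.asarray(self.classes_, dtype=object)[idx]

    @property
    def x_scores_(self) -> np.ndarray:
        return self.core_.T


def plsda_fit(X_cal, y_cal, n_lv: int, chain: str | Sequence = ()) -> PLSDAModel:
    return PLSDAModel(n_lv=n_lv, chain=chain).fit(X_cal, y_cal)


def plsda_cv(
    X_cal,
    y_cal,
    chain: str | Sequence,
    lv_grid: Sequence[int],
    cv: CVPlan,
) -> tuple[int, pd.DataFrame]:
    """Venetian-blinds CV over a grid of LV counts.

    Returns the selected LV count (minimum mean per-class CV error, ties going
    to fewer LVs) and the per-LV error table.  The chain and the PLS model are
    refitted inside every fold.
    """
    X_cal = np.asarray(X_cal, float)
    y_cal = np.asarray(y_cal)
    Yfull, classes = class_indicators(y_cal)
    lv_grid = sorted(set(int(a) for a in lv_grid))
    max_allowed = min(X_cal.shape[0] - X_cal.shape[0] // cv.n_splits - 1, X_cal.shape[1])
    usable = [a for a in lv_grid if a <= max_allowed]
    if len(usable) < len(lv_grid):
        warnings.warn(
            f"lv_grid trimmed to <= {max_allowed} (training-fold rank limit)",
            stacklevel=2,
        )
    if not usable:
        raise InputError("no usable LV counts in lv_grid")
    max_lv = max(usable)
    pooled = {a: np.empty(X_cal.shape[0], dtype=object) for a in usable}
    for train, val in cv.folds():
        Ytr, _ = class_indicators(y_cal[train], classes)
        fold_chain = make_chain(chain).fit(X_cal[train], Ytr - Ytr.mean(axis=0))
        Xtr = fold_chain.apply(X_cal[train])
        Xva = fold_chain.apply(X_cal[val])
        core = _PLSCore(Xtr, Ytr, max_lv)
        for a in usable:
            pred_idx = np.argmax(core.predict_y(Xva, a), axis=1)
            pooled[a][val] = np.asarray(classes, dtype=object)[pred_idx]
    rows = []
    for a in usable:
        report = per_class_report(y_cal, pooled[a], classes)
        rows.append({"n_lv": a, "cv_class_error": float(np.mean([m.class_error for m in report]))})
    table = pd.DataFrame(rows)
    best = table.loc[table["cv_class_error"].idxmin()]
    # idxmin returns the first minimum; grid is sorted so ties pick fewer LVs
    return int(best["n_lv"]), table


# ---------------------------------------------------------------------------
# PLS data compression for SVM / ANN


class PLSCompressor:
    """Project spectra onto the calibration PLS score space (x-block compression)."""

    def __init__(self, X_cal, y_cal, n_lv: int):
        Y, self.classes_ = class_indicators(y_cal)
        self.core_ = _PLSCore(np.asarray(X_cal, float), Y, n_lv)
        self.scores_ = self.core_.scores(X_cal)

    @property
    def n_lv(self) -> int:
        return self.core_.n_components

    def transform(self, X) -> np.ndarray:
        return self.core_.scores(X)


def pls_compress(X_cal, y_cal, n_lv: int) -> PLSCompressor:
    return PLSCompressor(X_cal, y_cal, n_lv)


# ---------------------------------------------------------------------------
# SVM / ANN on compressed scores


@dataclass(frozen=True)
class SVMConfig:
    C: float = 1.0
    gamma: float = 0.32
    n_compress_lv: int = 4

    def __post_init__(self):
        if self.C <= 0 or self.gamma <= 0:
            raise InputError("SVM requires C > 0 and gamma > 0")


@dataclass(frozen=True)
class ANNConfig:
    hidden_nodes: int = 10
    n_compress_lv: int = 4
    max_epochs: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.hidden_nodes < 1:
            raise InputError("ANN requires hidden_nodes >= 1")


def svm_fit(scores, y_cal, config: SVMConfig) -> SVC:
    """RBF soft-margin SVM on PLS scores (one-vs-one for multi-class)."""
    model = SVC(C=config.C, gamma=config.gamma, kernel="rbf")
    model.fit(np.asarray(scores, float), np.asarray(y_cal))
    return model


def svm_predict(model: SVC, scores) -> np.ndarray:
    return model.predict(np.asarray(scores, float))


def ann_fit(scores, y_cal, config: ANNConfig) -> MLPClassifier:
    """Single-hidden-layer network (logistic activation, full-batch L-BFGS)."""
    scores = np.asarray(scores, float)
    if not np.all(np.isfinite(scores)):
        raise InputError("ANN inputs must be finite")
    model = MLPClassifier(
        hidden_layer_sizes=(config.hidden_nodes,),
        activation="logistic",
        solver="lbfgs",
        max_iter=config.max_epochs,
        random_state=config.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings on tiny fixtures
        model.fit(scores, np.asarray(y_cal))
    return model


def ann_predict(model: MLPClassifier, scores) -> np.ndarray:
    return model.predict(np.asarray(scores, float))


# ---------------------------------------------------------------------------
# full evaluation (Cal / CV / Pred report)


@dataclass
class ModelReport:
    """Per-class sensitivities and class errors over the three phases."""

    classes: list
    table: pd.DataFrame
    overall_accuracy: float
    selected_n_lv: int | None = None
    details: dict = field(default_factory=dict)

    COLUMNS = [
        "class",
        "sensitivity_cal",
        "class_error_cal",
        "sensitivity_cv",
        "class_error_cv",
        "sensitivity_pred",
        "class_error_pred",
    ]

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            self.table.to_csv(fh, index=False, lineterminator="\n")
            fh.write(f"overall_accuracy,{self.overall_accuracy!r}\n")

    def to_dict(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "rows": self.table.to_dict(orient="records"),
            "overall_accuracy": self.overall_accuracy,
            "selected_n_lv": self.selected_n_lv,
            **self.details,
        }


def _fit_predict_route(model_spec: dict, X_tr, y_tr, X_list):
    """Fit one classifier route on (X_tr, y_tr); predict each matrix in X_list."""
    classifier = model_spec.get("classifier", "plsda")
    chain_spec = model_spec.get("chain", ())
    Ytr, classes = class_indicators(y_tr)
    fold_chain = make_chain(chain_spec).fit(X_tr, Ytr - Ytr.mean(axis=0))
    Xp = fold_chain.apply(X_tr)
    outs = []
    if classifier == "plsda":
        n_lv = int(model_spec.get("n_lv", 4))
        core = _PLSCore(Xp, Ytr, n_lv)
        for X in X_list:
            idx = np.argmax(core.predict_y(fold_chain.apply(X)), axis=1)
            outs.append(np.asarray(classes, dtype=object)[idx])
        return outs
    n_comp = int(model_spec.get("n_compress_lv", model_spec.get("n_lv", 4)))
    comp = PLSCompressor(Xp, y_tr, n_comp)
    if classifier == "csvm":
        cfg = SVMConfig(
            C=float(model_spec.get("C", 1.0)),
            gamma=float(model_spec.get("gamma", 0.32)),
            n_compress_lv=n_comp,
        )
        clf = svm_fit(comp.scores_, y_tr, cfg)
    elif classifier == "annda":
        cfg = ANNConfig(
            hidden_nodes=int(model_spec.get("hidden_nodes", 10)),
            n_compress_lv=n_comp,
            max_epochs=int(model_spec.get("max_epochs", 500)),
            seed=int(model_spec.get("seed", 0)),
        )
        clf = ann_fit(comp.scores_, y_tr, cfg)
    else:
        raise InputError(f"unknown classifier {classifier!r}")
    for X in X_list:
        outs.append(clf.predict(comp.transform(fold_chain.apply(X))))
    return outs


def _phase_metrics(y_true, y_pred, classes) -> list[ClassMetrics]:
    return per_class_report(y_true, y_pred, classes)


def evaluate_model(
    model_spec: dict,
    table: SpectraTable,
    split: SplitPlan,
    cv: CVPlan | None = None,
    target: str = "endophyte_status",
) -> ModelReport:
    """Calibration / cross-validation / prediction report for one model spec.

    ``model_spec`` keys: ``classifier`` (plsda | csvm | annda), ``chain``
    (preset name or step list), ``n_lv`` (int or "auto"), plus classifier
    specific parameters (C, gamma, hidden_nodes, seed, n_compress_lv).
    """
    X = table.X
    y = table.labels[target].to_numpy()
    cal_idx = split.calibration_indices
    pred_idx = split.prediction_indices
    X_cal, y_cal = X[cal_idx], y[cal_idx]
    X_pred, y_pred_true = X[pred_idx], y[pred_idx]
    if cv is None:
        cv = venetian_blinds(len(cal_idx))
    _, classes = class_indicators(y_cal)

    model_spec = dict(model_spec)
    selected_n_lv = None
    if model_spec.get("n_lv") == "auto":
        grid = model_spec.get("lv_grid", range(1, 21))
        selected_n_lv, _ = plsda_cv(X_cal, y_cal, model_spec.get("chain", ()), grid, cv)
        model_spec["n_lv"] = selected_n_lv

    # calibration (resubstitution) + held-out prediction from one fit
    cal_pred, pred_pred = _fit_predict_route(model_spec, X_cal, y_cal, [X_cal, X_pred])
    # cross-validation: full refit per fold, pooled predictions
    cv_pred = np.empty(len(cal_idx), dtype=object)
    for train, val in cv.folds():
        (out,) = _fit_predict_route(model_spec, X_cal[train], y_cal[train], [X_cal[val]])
        cv_pred[val] = out

    m_cal = _phase_metrics(y_cal, cal_pred, classes)
    m_cv = _phase_metrics(y_cal, cv_pred, classes)
    m_pred = _phase_metrics(y_pred_true, pred_pred, classes)

    rows = []
    for cls, a, b, c in zip(classes, m_cal, m_cv, m_pred):
        rows.append(
            {
                "class": cls,
                "sensitivity_cal": a.sensitivity,
                "class_error_cal": a.class_error,
                "sensitivity_cv": b.sensitivity,
                "class_error_cv": b.class_error,
                "sensitivity_pred": c.sensitivity,
                "class_error_pred": c.class_error,
            }
        )
    df = pd.DataFrame(rows, columns=ModelReport.COLUMNS)
    acc = overall_accuracy(
        [m.class_error for m in m_cv] + [m.class_error for m in m_pred]
    )
    return ModelReport(
        classes=classes,
        table=df,
        overall_accuracy=acc,
        selected_n_lv=selected_n_lv,
        details={"target": target, "model_spec": {k: v for k, v in model_spec.items()}},
    )
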