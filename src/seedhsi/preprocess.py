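"""Spectral pre-treatments composable into fit/apply chains.

Row-wise transforms (detrend, asymmetric weighted-least-squares baseline,
Savitzky-Golay derivatives, SNV, EMSC with a fixed reference) act on each
spectrum independently.  Fit-dependent transforms (mean centring, OSC, EMSC
with a calibration-mean reference) learn state on the calibration set and
replay it unchanged on held-out rows — never refit.

The six named presets ``pt1`` .. ``pt6`` are the pre-treatment combinations
used for model optimisation, e.g. ``pt6`` = detrend, baseline (order 2),
2nd derivative (order 2, 15 pt), EMSC, OSC, mean centre.
"""

from __future__ import annotations

import copy
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .exceptions import DegenerateFitError, InputError

__all__ = [
    "detrend",
    "wls_baseline",
    "sg_derivative",
    "snv",
    "DetrendStep",
    "WLSBaselineStep",
    "SGDerivativeStep",
    "SNVStep",
    "EMSCStep",
    "OSCStep",
    "MeanCenterStep",
    "PreprocessChain",
    "chain_fit",
    "make_chain",
    "PRESETS",
    "STEP_REGISTRY",
]


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2:
        raise InputError("spectra matrix must be 2-D (rows = spectra)")
    return X


# ---------------------------------------------------------------------------
# row-wise transforms


def detrend(X, order: int = 2) -> np.ndarray:
    """Subtract, per row, the least-squares polynomial of ``order`` in band index."""
    X = _as_matrix(X)
    n_bands = X.shape[1]
    if order < 1:
        raise InputError("detrend order must be >= 1")
    if order >= n_bands:
        raise InputError(f"detrend order {order} >= band count {n_bands}")
    t = np.linspace(-1.0, 1.0, n_bands)
    V = np.polynomial.polynomial.polyvander(t, order)
    # hat matrix of the polynomial basis; projection removes the fitted trend
    H = V @ np.linalg.pinv(V)
    return X - X @ H.T


def wls_baseline(
    X,
    order: int = 2,
    max_iter: int = 100,
    tol: float = 1e-6,
    above_weight: float = 0.001,
) -> np.ndarray:
    """Subtract an asymmetrically re-weighted polynomial baseline per row.

    Points above the current baseline are down-weighted to ``above_weight``
    (points below keep weight 1) and the weighted polynomial fit is repeated
    until the weight vector changes by less than ``tol`` or ``max_iter`` is
    reached.  Positive peaks therefore barely attract the baseline.
    """
    X = _as_matrix(X)
    if order < 0:
        raise InputError("baseline order must be >= 0")
    n_rows, n_bands = X.shape
    t = np.linspace(-1.0, 1.0, n_bands)
    V = np.polynomial.polynomial.polyvander(t, order)  # (bands, order+1)
    w = np.ones((n_rows, n_bands))
    baseline = np.zeros_like(X)
    for _ in range(max_iter):
        A = np.einsum("bi,rb,bj->rij", V, w, V)
        rhs = np.einsum("bi,rb->ri", V, w * X)
        coef = np.linalg.solve(A, rhs[..., None])[..., 0]
        baseline = coef @ V.T
        w_new = np.where(X > baseline, above_weight, 1.0)
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            break
        w = w_new
    return X - baseline


def sg_derivative(
    X, deriv_order: int, poly_order: int = 2, window: int = 15
) -> np.ndarray:
    """Savitzky-Golay derivative per row (band-index abscissa).

    Edges use a polynomial refit over the terminal window rather than padding,
    so derivatives of polynomials of degree <= ``poly_order`` are exact at
    interior points.
    """
    X = _as_matrix(X)
    if window % 2 == 0:
        raise InputError("window must be odd")
    if not (window > poly_order >= deriv_order):
        raise InputError("require window > poly_order >= deriv_order")
    if window > X.shape[1]:
        raise InputError(f"window {window} exceeds band count {X.shape[1]}")
    return savgol_filter(
        X, window_length=window, polyorder=poly_order, deriv=deriv_order,
        delta=1.0, axis=1, mode="interp",
    )


def snv(X) -> np.ndarray:
    """Standard normal variate: per row, subtract the mean and divide by the
    sample (n-1) standard deviation."""
    X = _as_matrix(X)
    sd = X.std(axis=1, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise InputError(f"SNV undefined for zero-variance row(s) {zero.tolist()}")
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


# ---------------------------------------------------------------------------
# step classes


class _Step:
    """Common fit/apply interface; row-wise steps have trivial fits."""

    name: str = ""
    requires_y: bool = False

    def fit(self, X, Y=None) -> "_Step":
        return self

    def apply(self, X) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def clone(self) -> "_Step":
        return copy.deepcopy(self)


class DetrendStep(_Step):
    name = "detrend"

    def __init__(self, order: int = 2):
        self.order = order

    def apply(self, X):
        return detrend(X, self.order)


class WLSBaselineStep(_Step):
    name = "wls_baseline"

    def __init__(self, order: int = 2, max_iter: int = 100, tol: float = 1e-6):
        self.order = order
        self.max_iter = max_iter
        self.tol = tol

    def apply(self, X):
        return wls_baseline(X, self.order, self.max_iter, self.tol)


class SGDerivativeStep(_Step):
    name = "sg_derivative"

    def __init__(self, deriv_order: int = 2, poly_order: int = 2, window: int = 15):
        self.deriv_order = deriv_order
        self.poly_order = poly_order
        self.window = window

    def apply(self, X):
        return sg_derivative(X, self.deriv_order, self.poly_order, self.window)


class SNVStep(_Step):
    name = "snv"

    def apply(self, X):
        return snv(X)


class EMSCStep(_Step):
    """Extended multiplicative scatter correction.

    Each row ``x`` is regressed as ``x ≈ a + b·m + Σ_j d_j·λ^j`` against the
    reference spectrum ``m`` (default: calibration-set mean) and a wavelength
    polynomial; the corrected row is ``(x - a - Σ d_j λ^j) / b``.
    """

    name = "emsc"

    def __init__(
        self,
        poly_order: int = 2,
        reference: np.ndarray | None = None,
        b_tol: float = 1e-8,
    ):
        self.poly_order = poly_order
        self.reference = None if reference is None else np.asarray(reference, float)
        self.b_tol = b_tol
        self._design: np.ndarray | None = None
        self._pinv: np.ndarray | None = None

    def fit(self, X, Y=None):
        X = _as_matrix(X)
        ref = self.reference if self.reference is not None else X.mean(axis=0)
        if ref.size != X.shape[1]:
            raise InputError("EMSC reference band count mismatch")
        t = np.linspace(-1.0, 1.0, X.shape[1])
        poly = np.polynomial.polynomial.polyvander(t, self.poly_order)  # incl. const
        self._design = np.column_stack([poly[:, :1], ref, poly[:, 1:]])
        self._pinv = np.linalg.pinv(self._design)
        self.reference = ref
        return self

    def apply(self, X):
        if self._pinv is None:
            raise InputError("EMSC step not fitted")
        X = _as_matrix(X)
        if X.shape[1] != self._design.shape[0]:
            raise InputError("EMSC band count mismatch at apply time")
        coefs = X @ self._pinv.T  # rows: (a, b, d_1..d_p)
        b = coefs[:, 1]
        if np.any(np.abs(b) < self.b_tol):
            bad = np.flatnonzero(np.abs(b) < self.b_tol)
            raise DegenerateFitError(
                f"EMSC multiplicative coefficient ~0 for row(s) {bad.tolist()}"
            )
        background = coefs[:, [0]] @ self._design[:, [0]].T
        if self.poly_order >= 1:
            background = background + coefs[:, 2:] @ self._design[:, 2:].T
        return (X - background) / b[:, None]


class OSCStep(_Step):
    """Orthogonal signal correction (NIPALS variant).

    Components of maximal X-variance whose scores are orthogonalized against
    the (column-centred) response Y are removed from X.  Stored weights and
    loadings deflate new data without refitting.
    """

    name = "osc"
    requires_y = True

    def __init__(self, n_components: int = 1, tol: float = 1e-10, max_iter: int = 500):
        if n_components < 1:
            raise InputError("OSC needs n_components >= 1")
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.x_mean_: np.ndarray | None = None
        self.weights_: list[np.ndarray] = []
        self.loadings_: list[np.ndarray] = []
        self.calibration_scores_: np.ndarray | None = None

    def fit(self, X, Y=None):
        if Y is None:
            raise InputError("OSC requires a response matrix Y at fit time")
        X = _as_matrix(X)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if Y.shape[0] != X.shape[0]:
            raise InputError("X and Y row counts differ")
        self.x_mean_ = X.mean(axis=0)
        Xc = X - self.x_mean_
        Yc = Y - Y.mean(axis=0)
        rank = np.linalg.matrix_rank(Xc)
        if self.n_components >= rank:
            raise InputError(
                f"OSC n_components={self.n_components} >= rank(X)={rank}"
            )
        Yp = np.linalg.pinv(Yc)
        self.weights_, self.loadings_ = [], []
        scores = []
        for _ in range(self.n_components):
            # dominant X direction
            u, s, vt = np.linalg.svd(Xc, full_matrices=False)
            t = u[:, 0] * s[0]
            for _ in range(self.max_iter):
                t_orth = t - Yc @ (Yp @ t)
                w, *_ = np.linalg.lstsq(Xc, t_orth, rcond=None)
                nw = np.linalg.norm(w)
                if nw == 0:
                    raise DegenerateFitError("OSC weight vector vanished")
                w /= nw
                t_new = Xc @ w
                if np.linalg.norm(t_new - t) <= self.tol * max(np.linalg.norm(t_new), 1e-30):
                    t = t_new
                    break
                t = t_new
            t = t - Yc @ (Yp @ t)  # exact orthogonality of stored scores
            tt = t @ t
            if tt == 0:
                raise DegenerateFitError("OSC score vector vanished")
            p = Xc.T @ t / tt
            Xc = Xc - np.outer(t, p)
            self.weights_.append(w)
            self.loadings_.append(p)
            scores.append(t)
        self.calibration_scores_ = np.column_stack(scores)
        return self

    def apply(self, X):
        if self.x_mean_ is None:
            raise InputError("OSC step not fitted")
        X = _as_matrix(X)
        Z = X - self.x_mean_
        for w, p in zip(self.weights_, self.loadings_):
            t = Z @ w
            Z = Z - np.outer(t, p)
        return Z + self.x_mean_


class MeanCenterStep(_Step):
    name = "mean_center"

    def __init__(self):
        self.means_: np.ndarray | None = None

    def fit(self, X, Y=None):
        self.means_ = _as_matrix(X).mean(axis=0)
        return self

    def apply(self, X):
        if self.means_ is None:
            raise InputError("mean_center step not fitted")
        X = _as_matrix(X)
        if X.shape[1] != self.means_.size:
            raise InputError("band count mismatch against fitted column means")
        return X - self.means_


STEP_REGISTRY = {
    "detrend": DetrendStep,
    "wls_baseline": WLSBaselineStep,
    "sg_derivative": SGDerivativeStep,
    "snv": SNVStep,
    "emsc": EMSCStep,
    "osc": OSCStep,
    "mean_center": MeanCenterStep,
}

# the six standard pre-treatment combinations
PRESETS: dict[str, list] = {
    "pt1": ["detrend", ("wls_baseline", {"order": 2}), "mean_center"],
    "pt2": [
        "detrend",
        ("wls_baseline", {"order": 2}),
        ("sg_derivative", {"deriv_order": 2, "poly_order": 2, "window": 15}),
        "mean_center",
    ],
    "pt3": [
        "detrend",
        ("wls_baseline", {"order": 2}),
        ("sg_derivative", {"deriv_order": 2, "poly_order": 2, "window": 15}),
        "emsc",
        "mean_center",
    ],
    "pt4": ["detrend", ("wls_baseline", {"order": 2}), "osc", "mean_center"],
    "pt5": [
        "detrend",
        ("wls_baseline", {"order": 2}),
        ("sg_derivative", {"deriv_order": 2, "poly_order": 2, "window": 15}),
        "osc",
        "mean_center",
    ],
    "pt6": [
        "detrend",
        ("wls_baseline", {"order": 2}),
        ("sg_derivative", {"deriv_order": 2, "poly_order": 2, "window": 15}),
        "emsc",
        "osc",
        "mean_center",
    ],
}


def _resolve_spec(spec) -> list[_Step]:
    if isinstance(spec, str):
        if spec not in PRESETS:
            raise InputError(f"unknown preset {spec!r}; known: {sorted(PRESETS)}")
        spec = PRESETS[spec]
    steps: list[_Step] = []
    for item in spec:
        if isinstance(item, _Step):
            steps.append(item.clone())
            continue
        if isinstance(item, str):
            name, params = item, {}
        elif isinstance(item, (tuple, list)) and len(item) == 2:
            name, params = item
        elif isinstance(item, dict):
            params = dict(item)
            name = params.pop("name")
        else:
            raise InputError(f"unrecognised step spec {item!r}")
        if name not in STEP_REGISTRY:
            raise InputError(f"unknown step {name!r}; known: {sorted(STEP_REGISTRY)}")
        steps.append(STEP_REGISTRY[name](**params))
    return steps


class PreprocessChain:
    """Ordered pre-treatment steps fitted on calibration data.

    ``fit`` runs the steps in order, each fitted on the output of its
    predecessors; ``apply`` replays the frozen states.  An empty chain is the
    identity.
    """

    def __init__(self, spec: str | Sequence = ()):
        self.spec = spec
        self.steps = _resolve_spec(spec)
        self.fitted = False

    @property
    def requires_y(self) -> bool:
        return any(step.requires_y for step in self.steps)

    def fit(self, X, Y=None) -> "PreprocessChain":
        if self.requires_y and Y is None:
            raise InputError("chain contains OSC but no Y was supplied")
        Z = _as_matrix(X)
        for step in self.steps:
            step.fit(Z, Y)
            Z = step.apply(Z)
        self.fitted = True
        return self

    def apply(self, X) -> np.ndarray:
        if not self.fitted:
            raise InputError("chain must be fitted before apply")
        Z = _as_matrix(X)
        for step in self.steps:
            Z = step.apply(Z)
        return Z

    def fit_apply(self, X, Y=None) -> np.ndarray:
        self.fit(X, Y)
        return self.apply(X)


def make_chain(spec: str | Sequence = ()) -> PreprocessChain:
    """Build an unfitted chain from a preset name or a list of step specs."""
    return PreprocessChain(spec)


def chain_fit(spec, X_cal, Y_cal=None) -> PreprocessChain:
    """Convenience: build and fit a chain in one call."""
    return make_chain(spec).fit(X_cal, Y_cal)
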