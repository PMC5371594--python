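"""Soft-margin SVM in the dual, linear multi-kernel combination, one-vs-one.

The binary classifier is the standard maximal-margin problem

    min_w,w0  1/2 ||w||^2 + C sum_i xi_i
    s.t.      y_i (w.x_i + w0) >= 1 - xi_i,

solved in its dual over a precomputed kernel (see :mod:`mklpet._smo`).  The
multi-kernel model evaluates a convex combination of per-region linear
kernels, k = sum_m q_m k_m with q on the simplex; the weights q are chosen
by grid search, never by gradient descent.

Class convention for the two-group task: non-idiopathic parkinsonism
(MSA and PSP pooled) is the positive class (+1), idiopathic PD the negative
class (-1), so "sensitivity" is the detection rate of atypical syndromes.
Decision values of exactly zero predict the positive class.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._smo import DEFAULT_TOL, solve_dual

#: class encoding of the binary idiopathic vs non-idiopathic task
POSITIVE_CLASS = "atypical"  # MSA u PSP
NEGATIVE_CLASS = "PD"

KKT_TOL = 1e-4


def linear_kernel(X: np.ndarray, Y: np.ndarray | None = None) -> np.ndarray:
    """Gram matrix of dot products; K[i, j] = x_i . y_j."""
    X = np.asarray(X, dtype=np.float64)
    Y = X if Y is None else np.asarray(Y, dtype=np.float64)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[1] != Y.shape[1]:
        raise ValueError("feature dimensions do not match")
    return X @ Y.T


def validate_weights(q: np.ndarray, n_kernels: int | None = None) -> np.ndarray:
    q = np.asarray(q, dtype=np.float64)
    if q.ndim != 1 or (n_kernels is not None and q.size != n_kernels):
        raise ValueError("kernel weight vector has wrong length")
    if np.any(q < 0):
        raise ValueError("kernel weights must be nonnegative")
    if abs(q.sum() - 1.0) > 1e-12:
        raise ValueError("kernel weights must sum to 1")
    return q


def combine_kernels(kernels: list[np.ndarray], q: np.ndarray) -> np.ndarray:
    """Weighted sum sum_m q_m K_m of same-shape kernel matrices."""
    q = validate_weights(q, len(kernels))
    shapes = {k.shape for k in kernels}
    if len(shapes) != 1:
        raise ValueError("all kernels must share one shape")
    out = np.zeros(kernels[0].shape)
    for qm, km in zip(q, kernels):
        out += qm * km
    return out


@dataclass
class SVMModel:
    """A trained binary SVM over a precomputed kernel.

    ``dual_coef`` holds alpha_i * y_i per training sample; the decision
    function on a test-by-train kernel is K_test @ dual_coef + bias.
    """

    alpha: np.ndarray
    y: np.ndarray
    bias: float
    C: float
    dual_objective: float
    label_map: dict[int, str] = field(
        default_factory=lambda: {-1: NEGATIVE_CLASS, +1: POSITIVE_CLASS}
    )
    kernel_name: str = "linear"

    @property
    def dual_coef(self) -> np.ndarray:
        return self.alpha * self.y

    @property
    def support_index(self) -> np.ndarray:
        return np.flatnonzero(self.alpha > 0)


def train_svm(
    K: np.ndarray,
    y: np.ndarray,
    C: float,
    tol: float = DEFAULT_TOL,
    label_map: dict[int, str] | None = None,
    check_kernel: bool = True,
) -> SVMModel:
    """Solve the dual on a precomputed kernel.

    ``y`` must be +/-1 with both classes present.  A kernel that is
    indefinite beyond tolerance gets a small diagonal ridge (with a warning).
    The bias is the mean of y_i - f_i over free support vectors
    (0 < alpha_i < C), or the feasible-interval midpoint if none are free.
    """
    K = np.asarray(K, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if K.ndim != 2 or K.shape[0] != K.shape[1] or K.shape[0] != y.size:
        raise ValueError("kernel must be square and match y")
    if C <= 0:
        raise ValueError("C must be positive")
    uniq = np.unique(y)
    if not np.array_equal(uniq, [-1.0, 1.0]):
        if uniq.size == 1:
            raise ValueError("training data contains a single class")
        raise ValueError("labels must be +/-1")
    if check_kernel:
        if np.max(np.abs(K - K.T)) > 1e-10:
            raise ValueError("kernel matrix is not symmetric")
        scale = max(1.0, float(np.abs(np.diag(K)).max()))
        min_eig = float(np.linalg.eigvalsh(K).min())
        if min_eig < -1e-8 * scale:
            warnings.warn(
                f"kernel indefinite (min eigenvalue {min_eig:.3g}); adding ridge",
                stacklevel=2,
            )
            K = K + (-min_eig + 1e-10 * scale) * np.eye(K.shape[0])

    alpha = solve_dual(K, y, C, tol=tol)
    f = K @ (alpha * y)
    free = (alpha > 1e-10 * C) & (alpha < C * (1 - 1e-10))
    if free.any():
        bias = float(np.mean(y[free] - f[free]))
    else:
        up = ((y > 0) & (alpha < C)) | ((y < 0) & (alpha > 0))
        lo = ((y > 0) & (alpha > 0)) | ((y < 0) & (alpha < C))
        hi = np.max(y[up] - f[up]) if up.any() else 0.0
        lo_v = np.min(y[lo] - f[lo]) if lo.any() else 0.0
        bias = float((hi + lo_v) / 2.0)
    obj = float(alpha.sum() - 0.5 * (alpha * y) @ f)
    return SVMModel(
        alpha=alpha,
        y=y,
        bias=bias,
        C=float(C),
        dual_objective=obj,
        label_map=label_map or {-1: NEGATIVE_CLASS, +1: POSITIVE_CLASS},
    )


def decision_values(model: SVMModel, K_test: np.ndarray) -> np.ndarray:
    """g(x) = sum_j alpha_j y_j K(x, x_j) + bias for each test row."""
    K_test = np.atleast_2d(np.asarray(K_test, dtype=np.float64))
    if K_test.shape[1] != model.alpha.size:
        raise ValueError("test kernel columns must match training samples")
    return K_test @ model.dual_coef + model.bias


def predict(model: SVMModel, K_test: np.ndarray) -> list[str]:
    """Class names by the side of the hyperplane; g == 0 maps to +1."""
    g = decision_values(model, K_test)
    return [model.label_map[+1] if gi >= 0 else model.label_map[-1] for gi in g]


def weight_vector(model: SVMModel, X_train: np.ndarray) -> np.ndarray:
    """Primal weights w = sum_i alpha_i y_i x_i of a linear-kernel model."""
    if model.kernel_name != "linear":
        raise ValueError("weight vector is only defined for linear kernels")
    X_train = np.asarray(X_train, dtype=np.float64)
    if X_train.shape[0] != model.alpha.size:
        raise ValueError("X_train rows must match training samples")
    return X_train.T @ model.dual_coef


@dataclass
class MKLModel:
    """Trained multi-kernel SVM: base SVM + simplex weights + feature refs."""

    svm: SVMModel
    q: np.ndarray
    blocks: list[tuple[str, str]]
    X_train_blocks: list[np.ndarray]

    def __post_init__(self) -> None:
        self.q = validate_weights(self.q, len(self.blocks))
        if len(self.X_train_blocks) != len(self.blocks):
            raise ValueError("one training feature block required per kernel")

    def test_kernel(self, X_test_blocks: list[np.ndarray]) -> np.ndarray:
        ks = [
            linear_kernel(Xt, Xtr)
            for Xt, Xtr in zip(X_test_blocks, self.X_train_blocks)
        ]
        return combine_kernels(ks, self.q)

    def decision_values(self, X_test_blocks: list[np.ndarray]) -> np.ndarray:
        return decision_values(self.svm, self.test_kernel(X_test_blocks))

    def predict(self, X_test_blocks: list[np.ndarray]) -> list[str]:
        return predict(self.svm, self.test_kernel(X_test_blocks))


def train_mkl(
    X_blocks: list[np.ndarray],
    y: np.ndarray,
    C: float,
    q: np.ndarray,
    blocks: list[tuple[str, str]] | None = None,
    label_map: dict[int, str] | None = None,
) -> MKLModel:
    """Train an SVM on the q-weighted combination of per-block linear kernels."""
    kernels = [linear_kernel(X) for X in X_blocks]
    K = combine_kernels(kernels, q)
    svm = train_svm(K, y, C, label_map=label_map)
    if blocks is None:
        blocks = [("", f"block{i}") for i in range(len(X_blocks))]
    return MKLModel(svm=svm, q=np.asarray(q, dtype=np.float64), blocks=blocks,
                    X_train_blocks=[np.asarray(X) for X in X_blocks])


@dataclass
class OvOEnsemble:
    """One binary MKL model per unordered class pair."""

    classes: list[str]
    models: dict[tuple[str, str], MKLModel]


def train_ovo(
    X_blocks: list[np.ndarray],
    labels: np.ndarray,
    C: float | dict[tuple[str, str], float],
    q: np.ndarray | dict[tuple[str, str], np.ndarray],
    classes: list[str] | None = None,
    blocks: list[tuple[str, str]] | None = None,
) -> OvOEnsemble:
    """One-against-one ensemble: each pairwise model sees only its two classes.

    ``C`` and ``q`` may be single values or per-pair dicts (keyed by the
    sorted class pair), e.g. from a per-pair grid search.
    """
    labels = np.asarray(labels)
    if classes is None:
        classes = sorted(np.unique(labels).tolist())
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    models = {}
    for a, b in itertools.combinations(classes, 2):
        idx = np.flatnonzero((labels == a) | (labels == b))
        if np.sum(labels[idx] == a) < 1 or np.sum(labels[idx] == b) < 1:
            raise ValueError(f"class pair ({a}, {b}) lacks samples")
        y = np.where(labels[idx] == b, 1.0, -1.0)  # later class is +1
        pair = (a, b)
        C_ab = C[pair] if isinstance(C, dict) else C
        q_ab = q[pair] if isinstance(q, dict) else q
        sub_blocks = [X[idx] for X in X_blocks]
        models[pair] = train_mkl(
            sub_blocks, y, C_ab, q_ab, blocks=blocks, label_map={-1: a, +1: b}
        )
    return OvOEnsemble(classes=classes, models=models)


def predict_ovo(ensemble: OvOEnsemble, X_test_blocks: list[np.ndarray]) -> list[str]:
    """Majority vote over pairwise models.

    Ties are broken by the largest sum of |decision value| over the wins of
    each tied class; a remaining exact tie falls back to class-name order.
    """
    n = X_test_blocks[0].shape[0]
    votes = {c: np.zeros(n) for c in ensemble.classes}
    strength = {c: np.zeros(n) for c in ensemble.classes}
    for (a, b), model in ensemble.models.items():
        g = model.decision_values(X_test_blocks)
        winners = np.where(g >= 0, b, a)
        for c in (a, b):
            won = winners == c
            votes[c][won] += 1
            strength[c][won] += np.abs(g[won])
    out = []
    for i in range(n):
        best = max(
            ensemble.classes,
            key=lambda c: (votes[c][i], strength[c][i], -ensemble.classes.index(c)),
        )
        out.append(best)
    return out
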