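"""Kernel SVM with median-heuristic RBF bandwidth, solved by decomposition.

The classifier is the multiclass hinge formulation

    minimize  t(w_n, xi_i) = 1/2 * sum_n ||w_n||^2 + (C/m) * sum_i xi_i
    s.t.      <x_i, w_{y_i}> - <x_i, w_n> >= b_i^n - xi_i,
              b_i^n = 1 - delta_{y_i, n}

with decision rule argmax_n <x, w_n>, used here with k = 2 classes
(tumor vs normal), C = 1, and the RBF kernel
K(x_i, x_j) = exp(-||x_i - x_j||^2 / sigma^2) whose bandwidth sigma^2 is the
median of all pairwise squared distances among the training spectra.

k = 2 reduction
---------------
With two classes the constraints only involve w = w_1 - w_2, and minimizing
||w_1||^2 + ||w_2||^2 at fixed difference gives w_1 = -w_2 = w/2.  The
problem becomes the standard bias-free soft-margin binary SVM

    minimize 1/2 ||w||^2 + C' * sum_i xi_i,   s_i <x_i, w> >= 1 - xi_i

with C' = 2C/m and s_i = +-1 (the factor 2 from ||w||^2/2 -> ||w||^2/4, the
1/m from the loss scaling above).  Its dual,

    max_alpha  sum_i alpha_i - 1/2 alpha' Q alpha,   0 <= alpha_i <= C',
    Q_ij = s_i s_j K(x_i, x_j),

has *no* equality constraint (the formulation carries no bias term), so the
decomposition solver can take exact Newton steps on one coordinate at a
time.  The working coordinate is the maximal KKT violator; convergence is
declared when the largest violation drops below a kernel-score tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist, pdist

__all__ = [
    "TrainingSet",
    "SVMModel",
    "median_sigma2",
    "rbf",
    "rbf_kernel",
    "train",
    "decision_values",
    "predict",
    "primal_objective",
    "save_model",
    "load_model",
]

#: KKT violation tolerance on kernel scores.
KKT_TOL = 1e-3
#: Cap on coordinate updates before the solver gives up.
MAX_UPDATES = 10_000_000


@dataclass
class TrainingSet:
    """Preprocessed spectra with class labels and per-row specimen provenance.

    ``y`` holds class labels as strings; the ordered class code sequence is
    their sorted unique set.  ``specimen_ids`` is needed so cross-validation
    can leave whole specimens out; ``pixels`` (optional) are the (row, col)
    source coordinates used for canonical ordering and leakage checks.
    """

    X: np.ndarray
    y: np.ndarray
    specimen_ids: np.ndarray
    pixels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y)
        self.specimen_ids = np.asarray(self.specimen_ids)
        if self.X.ndim != 2 or len(self.y) != len(self.X):
            raise ValueError("inconsistent training-set shapes")
        if len(self.specimen_ids) != len(self.X):
            raise ValueError("specimen_ids length mismatch")
        if self.pixels is not None:
            self.pixels = np.asarray(self.pixels, dtype=np.int64)
            key = np.rec.fromarrays(
                [self.specimen_ids, self.pixels[:, 0], self.pixels[:, 1]])
            if len(np.unique(key)) != len(key):
                raise ValueError("duplicate (specimen, pixel) training rows")

    @property
    def classes(self) -> tuple:
        return tuple(sorted(np.unique(self.y)))

    def __len__(self) -> int:
        return len(self.y)

    @staticmethod
    def concat(parts: list["TrainingSet"]) -> "TrainingSet":
        if not parts:
            raise ValueError("nothing to concatenate")
        pixels = None
        if all(p.pixels is not None for p in parts):
            pixels = np.vstack([p.pixels for p in parts])
        return TrainingSet(
            X=np.vstack([p.X for p in parts]),
            y=np.concatenate([p.y for p in parts]),
            specimen_ids=np.concatenate([p.specimen_ids for p in parts]),
            pixels=pixels,
        )

    def canonical_order(self) -> "TrainingSet":
        """Sort rows by (specimen, pixel row, pixel col): solver input order
        is then independent of how folds were assembled."""
        if self.pixels is None:
            keys = (np.arange(len(self)), self.specimen_ids)
        else:
            keys = (self.pixels[:, 1], self.pixels[:, 0], self.specimen_ids)
        order = np.lexsort(keys)
        return TrainingSet(self.X[order], self.y[order], self.specimen_ids[order],
                           None if self.pixels is None else self.pixels[order])

    def stratified_subsample(self, n_per_class: int, seed: int) -> "TrainingSet":
        """Optional seeded per-class subsample for very large pixel sets."""
        rng = np.random.default_rng(seed)
        keep = np.zeros(len(self), dtype=bool)
        for cls in self.classes:
            idx = np.nonzero(self.y == cls)[0]
            if len(idx) > n_per_class:
                idx = rng.choice(idx, size=n_per_class, replace=False)
            keep[idx] = True
        sel = np.nonzero(keep)[0]
        return TrainingSet(self.X[sel], self.y[sel], self.specimen_ids[sel],
                           None if self.pixels is None else self.pixels[sel])


def median_sigma2(X: np.ndarray) -> float:
    """Median-heuristic bandwidth: median of all pairwise squared distances.

    sigma^2 := median{ ||x_i - x_j||^2 : i < j }; an even pair count takes
    the mean of the two central values.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("median_sigma2 needs at least two rows")
    d2 = pdist(X, "sqeuclidean")
    med = float(np.median(d2))
    if med <= 0:
        raise ValueError("all pairwise distances are zero: bandwidth undefined")
    return med


def rbf(xi: np.ndarray, xj: np.ndarray, sigma2: float) -> float:
    """Gaussian kernel K(x_i, x_j) = exp(-||x_i - x_j||^2 / sigma^2)."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    d2 = float(np.sum((np.asarray(xi, float) - np.asarray(xj, float)) ** 2))
    return float(np.exp(-d2 / sigma2))


def rbf_kernel(A: np.ndarray, B: np.ndarray, sigma2: float) -> np.ndarray:
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    return np.exp(-cdist(A, B, "sqeuclidean") / sigma2)


@dataclass
class SVMModel:
    """Trained model: kernel expansion plus training diagnostics.

    ``dual_coef`` holds alpha_i * s_i per support vector, so the binary
    decision value is f(x) = sum_sv dual_coef_j K(x, sv_j) and the per-class
    scores of the two-class reduction are (+f/2, -f/2) in class order.
    ``xi`` are the training slacks, kept for diagnostics; ``w2`` is
    ||w||^2 = alpha' Q alpha at the solution.
    """

    support_vectors: np.ndarray
    dual_coef: np.ndarray
    sigma2: float
    C: float
    C_eff: float
    classes: tuple
    n_train: int
    xi: np.ndarray
    w2: float
    n_updates: int
    meta: dict = field(default_factory=dict)


def train(ts: TrainingSet, C: float = 1.0, sigma2: float | str = "median",
          c_mode: str = "per-sample", tol: float = KKT_TOL,
          max_updates: int = MAX_UPDATES) -> SVMModel:
    """Fit the two-class kernel SVM by maximal-violator coordinate decomposition.

    ``sigma2="median"`` applies the median heuristic to ``ts.X``.  With
    ``c_mode="per-sample"`` the slack penalty is C/m as in the multiclass
    hinge objective, so C = 1 means C' = 2/m in the binary reduction;
    ``c_mode="absolute"`` uses C' = C directly (the convention of most SVM
    libraries, provided for comparison).
    """
    ts = ts.canonical_order()
    classes = ts.classes
    if len(classes) != 2:
        raise ValueError(f"training requires exactly 2 classes, got {classes}")
    m = len(ts)
    if sigma2 == "median":
        sigma2 = median_sigma2(ts.X)
    sigma2 = float(sigma2)
    if c_mode == "per-sample":
        C_eff = 2.0 * C / m
    elif c_mode == "absolute":
        C_eff = float(C)
    else:
        raise ValueError(f"unknown c_mode {c_mode!r}")

    s = np.where(ts.y == classes[0], 1.0, -1.0)
    K = rbf_kernel(ts.X, ts.X, sigma2)
    diag = np.clip(np.diag(K), 1e-12, None)

    alpha = np.zeros(m)
    u = np.zeros(m)                       # u_i = f(x_i) = sum_j alpha_j s_j K_ij
    n_updates = 0
    while True:
        grad = 1.0 - s * u                # dual gradient dW/dalpha
        up = np.where(alpha < C_eff, grad, -np.inf)     # can increase
        down = np.where(alpha > 0.0, -grad, -np.inf)    # can decrease
        viol = np.maximum(up, down)
        i = int(np.argmax(viol))
        if viol[i] <= tol:
            break
        if n_updates >= max_updates:
            raise RuntimeError(
                f"solver did not converge within {max_updates} updates "
                f"(m={m}, max KKT violation={viol[i]:.3e}, tol={tol})"
            )
        new_ai = np.clip(alpha[i] + grad[i] / diag[i], 0.0, C_eff)
        delta = new_ai - alpha[i]
        alpha[i] = new_ai
        u += delta * s[i] * K[:, i]
        n_updates += 1

    xi = np.maximum(0.0, 1.0 - s * u)
    w2 = float(alpha @ (s * u))           # alpha' Q alpha
    sv = alpha > 0
    return SVMModel(
        support_vectors=ts.X[sv].copy(),
        dual_coef=(alpha * s)[sv],
        sigma2=sigma2,
        C=float(C),
        C_eff=float(C_eff),
        classes=classes,
        n_train=m,
        xi=xi,
        w2=w2,
        n_updates=n_updates,
        meta={"c_mode": c_mode, "tol": tol},
    )


def decision_values(model: SVMModel, X: np.ndarray) -> np.ndarray:
    """Per-class score matrix (n, 2): the arguments of the argmax decision rule.

    Scores come from the kernel expansion over the support vectors; in the
    two-class reduction w_1 = -w_2 = w/2, so the class scores are
    (+f(x)/2, -f(x)/2) with f(x) = sum_j dual_coef_j K(x, sv_j).
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.support_vectors.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model "
            f"dimension {model.support_vectors.shape[1]}"
        )
    f = rbf_kernel(X, model.support_vectors, model.sigma2) @ model.dual_coef
    return np.column_stack([f / 2.0, -f / 2.0])


def predict(model: SVMModel, X: np.ndarray) -> np.ndarray:
    """argmax of the class scores; an exact tie takes the first class code."""
    scores = decision_values(model, X)
    idx = np.argmax(scores, axis=1)       # first maximum on ties
    return np.asarray(model.classes)[idx]


def primal_objective(model: SVMModel) -> float:
    """Multiclass-hinge objective t = 1/4 ||w||^2 + (C/m) sum_i xi_i.

    (1/2)(||w_1||^2 + ||w_2||^2) = ||w||^2 / 4 under the k = 2 reduction.
    For ``c_mode="absolute"`` the slack weight is C'/2 so that the value
    stays comparable: t = primal of the binary problem divided by 2.
    """
    slack_weight = model.C_eff / 2.0
    return 0.25 * model.w2 + slack_weight * float(np.sum(model.xi))


_SCHEMA_VERSION = 1


def save_model(model: SVMModel, path: str | Path) -> Path:
    import json

    path = Path(path)
    np.savez_compressed(
        path,
        schema_version=_SCHEMA_VERSION,
        support_vectors=model.support_vectors,
        dual_coef=model.dual_coef,
        sigma2=model.sigma2,
        C=model.C,
        C_eff=model.C_eff,
        classes=np.asarray(model.classes),
        n_train=model.n_train,
        xi=model.xi,
        w2=model.w2,
        n_updates=model.n_updates,
        meta_json=json.dumps(model.meta),
    )
    return path


def load_model(path: str | Path) -> SVMModel:
    import json

    with np.load(path, allow_pickle=False) as z:
        if int(z["schema_version"]) != _SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema {int(z['schema_version'])}")
        return SVMModel(
            support_vectors=z["support_vectors"],
            dual_coef=z["dual_coef"],
            sigma2=float(z["sigma2"]),
            C=float(z["C"]),
            C_eff=float(z["C_eff"]),
            classes=tuple(str(c) for c in z["classes"]),
            n_train=int(z["n_train"]),
            xi=z["xi"],
            w2=float(z["w2"]),
            n_updates=int(z["n_updates"]),
            meta=json.loads(str(z["meta_json"])),
        )
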