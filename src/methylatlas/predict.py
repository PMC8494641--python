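"""Multi-task neural prediction of cell subtype and dissection region.

A two-hidden-layer network — input PCs → shared layer (1,000 units) → two
task branches (200 units each) → softmax heads for subtype and region —
trained with summed cross-entropies, dropout 0.5 on hidden layers, Adam,
10 epochs of minibatches of 100.  Spatial accuracy is scored exactly and
"fuzzily" (a prediction counts if it hits the true dissection region or an
anatomically adjacent one), and compared against the naive composition
baseline that guesses each subtype's modal region.  The network is a
self-contained numpy implementation (forward/backward passes and Adam),
keeping the package dependency-light and the arithmetic fully seedable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ModelSpec",
    "MultiTaskANN",
    "PredictionResult",
    "composition_baseline",
    "crossvalidate",
    "fit_baseline",
    "fit_multitask",
    "fuzzy_accuracy",
    "permutation_importance",
]


@dataclass
class ModelSpec:
    """Architecture and training hyperparameters (defaults as published)."""

    shared_width: int = 1000
    branch_width: int = 200
    dropout: float = 0.5
    epochs: int = 10
    batch_size: int = 100
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shared_width, self.branch_width) < 1:
            raise ValueError("layer widths must be positive")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")


def _one_hot(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(classes, y)
    out = np.zeros((len(y), len(classes)))
    out[np.arange(len(y)), idx] = 1.0
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, params: dict, lr: float):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict, b1=0.9, b2=0.999, eps=1e-8):
        self.t += 1
        for k in params:
            self.m[k] = b1 * self.m[k] + (1 - b1) * grads[k]
            self.v[k] = b2 * self.v[k] + (1 - b2) * grads[k] ** 2
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


class MultiTaskANN:
    """Shared trunk + two softmax heads, trained by backprop with Adam."""

    def __init__(self, n_inputs: int, subtype_classes, region_classes, spec: ModelSpec):
        self.spec = spec
        self.subtype_classes = np.asarray(subtype_classes)
        self.region_classes = np.asarray(region_classes)
        rng = np.random.default_rng(spec.seed)
        h, b = spec.shared_width, spec.branch_width

        def _init(n_in, n_out):
            return rng.normal(0, np.sqrt(2.0 / n_in), size=(n_in, n_out))

        self.params = {
            "W0": _init(n_inputs, h), "b0": np.zeros(h),
            "W1s": _init(h, b), "b1s": np.zeros(b),
            "W1r": _init(h, b), "b1r": np.zeros(b),
            "W2s": _init(b, len(self.subtype_classes)), "b2s": np.zeros(len(self.subtype_classes)),
            "W2r": _init(b, len(self.region_classes)), "b2r": np.zeros(len(self.region_classes)),
        }
        self._opt = _Adam(self.params, spec.learning_rate)
        self._rng = rng
        self.loss_history: list[float] = []

    def _forward(self, x, train=False):
        p = self.params
        drop = self.spec.dropout if train else 0.0

        def _dropout(a):
            if drop == 0:
                return a, None
            mask = (self._rng.random(a.shape) >= drop) / (1 - drop)
            return a * mask, mask

        z0 = x @ p["W0"] + p["b0"]
        a0 = np.maximum(z0, 0)
        a0d, m0 = _dropout(a0)
        zs = a0d @ p["W1s"] + p["b1s"]
        as_ = np.maximum(zs, 0)
        asd, ms = _dropout(as_)
        zr = a0d @ p["W1r"] + p["b1r"]
        ar = np.maximum(zr, 0)
        ard, mr = _dropout(ar)
        ps = _softmax(asd @ p["W2s"] + p["b2s"])
        pr = _softmax(ard @ p["W2r"] + p["b2r"])
        cache = (x, z0, a0d, m0, zs, asd, ms, zr, ard, mr, ps, pr)
        return ps, pr, cache

    def _backward(self, cache, ys, yr):
        p = self.params
        x, z0, a0d, m0, zs, asd, ms, zr, ard, mr, ps, pr = cache
        n = x.shape[0]
        g = {}
        ds = (ps - ys) / n
        g["W2s"] = asd.T @ ds
        g["b2s"] = ds.sum(axis=0)
        dr = (pr - yr) / n
        g["W2r"] = ard.T @ dr
        g["b2r"] = dr.sum(axis=0)

        das = ds @ p["W2s"].T
        if ms is not None:
            das *= ms
        das *= zs > 0
        g["W1s"] = a0d.T @ das
        g["b1s"] = das.sum(axis=0)
        dar = dr @ p["W2r"].T
        if mr is not None:
            dar *= mr
        dar *= zr > 0
        g["W1r"] = a0d.T @ dar
        g["b1r"] = dar.sum(axis=0)

        da0 = das @ p["W1s"].T + dar @ p["W1r"].T
        if m0 is not None:
            da0 *= m0
        da0 *= z0 > 0
        g["W0"] = x.T @ da0
        g["b0"] = da0.sum(axis=0)
        return g

    def fit(self, x: np.ndarray, subtype: np.ndarray, region: np.ndarray):
        ys = _one_hot(subtype, self.subtype_classes)
        yr = _one_hot(region, self.region_classes)
        n = x.shape[0]
        bs = self.spec.batch_size
        for _ in range(self.spec.epochs):
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                ps, pr, cache = self._forward(x[idx], train=True)
                loss = -np.mean(np.sum(ys[idx] * np.log(ps + 1e-12), axis=1))
                loss += -np.mean(np.sum(yr[idx] * np.log(pr + 1e-12), axis=1))
                epoch_loss += loss * len(idx)
                grads = self._backward(cache, ys[idx], yr[idx])
                self._opt.step(self.params, grads)
            self.loss_history.append(epoch_loss / n)
        return self

    def predict_proba(self, x: np.ndarray):
        ps, pr, _ = self._forward(x, train=False)
        return ps, pr

    def predict(self, x: np.ndarray):
        ps, pr = self.predict_proba(x)
        return (
            self.subtype_classes[ps.argmax(axis=1)],
            self.region_classes[pr.argmax(axis=1)],
        )


def fit_multitask(
    pcs: np.ndarray, subtype: np.ndarray, region: np.ndarray, spec: ModelSpec | None = None
) -> MultiTaskANN:
    """Train the multi-task network on PC features with both label sets."""
    spec = spec or ModelSpec()
    subtype = np.asarray(subtype)
    region = np.asarray(region)
    for name, y in (("subtype", subtype), ("region", region)):
        classes, counts = np.unique(y, return_counts=True)
        tiny = classes[counts < 2]
        if tiny.size:
            raise ValueError(f"{name} classes with < 2 examples: {list(tiny)}")
    model = MultiTaskANN(
        pcs.shape[1], np.unique(subtype), np.unique(region), spec
    )
    return model.fit(pcs, subtype, region)


@dataclass
class PredictionResult:
    subtype_pred: np.ndarray
    region_pred: np.ndarray
    subtype_proba: np.ndarray
    region_proba: np.ndarray
    subtype_accuracy: float
    region_accuracy: float
    fold: np.ndarray | None = None
    per_fold: list = field(default_factory=list)


def crossvalidate(
    pcs: np.ndarray,
    subtype: np.ndarray,
    region: np.ndarray,
    spec: ModelSpec | None = None,
    k: int = 5,
) -> PredictionResult:
    """Stratified k-fold out-of-fold predictions and exact accuracies."""
    spec = spec or ModelSpec()
    subtype = np.asarray(subtype)
    region = np.asarray(region)
    n = len(subtype)
    sub_classes = np.unique(subtype)
    reg_classes = np.unique(region)
    sub_pred = np.empty(n, dtype=sub_classes.dtype)
    reg_pred = np.empty(n, dtype=reg_classes.dtype)
    sub_proba = np.zeros((n, len(sub_classes)))
    reg_proba = np.zeros((n, len(reg_classes)))
    fold_of = np.empty(n, dtype=int)
    per_fold = []
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=spec.seed)
    for f, (tr, te) in enumerate(skf.split(pcs, subtype)):
        fold_spec = ModelSpec(**{**spec.__dict__, "seed": spec.seed + f})
        model = MultiTaskANN(pcs.shape[1], sub_classes, reg_classes, fold_spec)
        model.fit(pcs[tr], subtype[tr], region[tr])
        ps, pr = model.predict_proba(pcs[te])
        sub_proba[te] = ps
        reg_proba[te] = pr
        sub_pred[te] = sub_classes[ps.argmax(axis=1)]
        reg_pred[te] = reg_classes[pr.argmax(axis=1)]
        fold_of[te] = f
        per_fold.append(
            dict(
                fold=f,
                subtype_accuracy=float(np.mean(sub_pred[te] == subtype[te])),
                region_accuracy=float(np.mean(reg_pred[te] == region[te])),
            )
        )
    return PredictionResult(
        subtype_pred=sub_pred,
        region_pred=reg_pred,
        subtype_proba=sub_proba,
        region_proba=reg_proba,
        subtype_accuracy=float(np.mean(sub_pred == subtype)),
        region_accuracy=float(np.mean(reg_pred == region)),
        fold=fold_of,
        per_fold=per_fold,
    )


def fuzzy_accuracy(predicted, truth, neighbors: dict) -> float:
    """Fraction of predictions equal to truth or an adjacent region of it."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    known = set(neighbors)
    hits = 0
    for p, t in zip(predicted, truth):
        if p not in known and p != t:
            raise ValueError(f"unknown region in predictions: {p!r}")
        if p == t or p in neighbors.get(t, ()):  # own region always counts
            hits += 1
    return hits / len(truth)


def composition_baseline(subtype, region, neighbors: dict) -> float:
    """Fuzzy accuracy of guessing each subtype's modal dissection region."""
    subtype = np.asarray(subtype)
    region = np.asarray(region)
    guess = np.empty_like(region)
    for c in np.unique(subtype):
        mask = subtype == c
        vals, counts = np.unique(region[mask], return_counts=True)
        guess[mask] = vals[np.argmax(counts)]
    return fuzzy_accuracy(guess, region, neighbors)


def permutation_importance(
    model: MultiTaskANN,
    pcs: np.ndarray,
    labels: np.ndarray,
    task: str = "region",
    n_perm: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Mean accuracy drop when each PC column is shuffled across cells."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    head = 1 if task == "region" else 0
    base_pred = model.predict(pcs)[head]
    base_acc = np.mean(base_pred == labels)
    drops = np.zeros(pcs.shape[1])
    for j in range(pcs.shape[1]):
        accs = []
        for _ in range(n_perm):
            xp = pcs.copy()
            xp[:, j] = xp[rng.permutation(len(xp)), j]
            accs.append(np.mean(model.predict(xp)[head] == labels))
        drops[j] = base_acc - np.mean(accs)
    return drops


def fit_baseline(kind: str, pcs: np.ndarray, labels: np.ndarray, seed: int = 0):
    """Reference single-task models for the benchmark comparison."""
    if kind == "logistic":
        clf = LogisticRegression(max_iter=2000, random_state=seed)
    elif kind == "random_forest":
        clf = RandomForestClassifier(n_estimators=1000, random_state=seed, n_jobs=1)
    else:
        raise ValueError(f"unknown baseline {kind!r}")
    return clf.fit(pcs, labels)
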