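"""Two-class linear discriminant and small feed-forward neural network.

Both models consume the 5-feature vectors, standardize them by training-set
statistics stored on the model, and emit a score in [0, 1] where higher
means deleterious. Ties at exactly 0.5 classify deleterious — the
recall-favoring convention matching the method's high-recall operating
point.

The network is the classic fully connected architecture for this problem:
5 input nodes, hidden layers of 10 and 5 nodes, 2 output nodes (deleterious,
benign), logistic sigmoid activations, sum-of-squares loss, weights
initialized uniformly in [-0.5, 0.5] — the era-typical simulator defaults.
Training is full-batch standard backpropagation (StdBP) or resilient
backpropagation (Rprop) with the canonical constants η+ = 1.2, η- = 0.5,
Δ0 = 0.1, Δmax = 50, Δmin = 1e-6 and sign-dependent per-weight step sizes
with weight backtracking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .profile_io import BENIGN, DELETERIOUS

DEFAULT_LAYERS = (5, 10, 5, 2)


def labels_to_bool(labels: Sequence[str]) -> np.ndarray:
    """Map 'benign'/'deleterious' strings to a boolean deleterious mask."""
    lab = np.asarray(labels)
    bad = set(np.unique(lab)) - {BENIGN, DELETERIOUS}
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    return lab == DELETERIOUS


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _mcc_bool(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(np.sum(y_true & y_pred))
    tn = int(np.sum(~y_true & ~y_pred))
    fp = int(np.sum(~y_true & y_pred))
    fn = int(np.sum(y_true & ~y_pred))
    denom = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom**0.5


@dataclass(frozen=True)
class Prediction:
    """A score in [0, 1] and its thresholded class call."""

    score: float
    label: str

    @classmethod
    def from_score(cls, score: float, threshold: float = 0.5) -> "Prediction":
        return cls(score=float(score),
                   label=DELETERIOUS if score >= threshold else BENIGN)


@dataclass
class Standardizer:
    """Per-feature z-scaling by stored training statistics."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        mean = X.mean(axis=0)
        std = X.std(axis=0, ddof=1)
        std = np.where(std == 0, 1.0, std)  # constant feature: pass through
        return cls(mean=mean, std=std)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.std


# ---------------------------------------------------------------------------
# Linear discriminant
# ---------------------------------------------------------------------------


@dataclass
class LDAModel:
    """Fisher discriminant with pooled within-class covariance.

    The direction is w ∝ S_pooled^{-1} (μ_del - μ_ben) on standardized
    features, so a higher projection means deleterious; the decision
    threshold sits at the midpoint of the projected class means, and the
    reported score is the logistic of the signed margin.
    """

    weights: np.ndarray
    threshold: float
    standardizer: Standardizer
    mean_del: float = 0.0
    mean_ben: float = 0.0

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        Z = self.standardizer.transform(np.atleast_2d(X))
        return Z @ self.weights - self.threshold

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(self.decision_values(X))

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> list[Prediction]:
        return [Prediction.from_score(s, threshold) for s in self.predict_scores(X)]

    # -- persistence -------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "model": "lda",
                "weights": self.weights.tolist(),
                "threshold": self.threshold,
                "standardizer": {
                    "mean": self.standardizer.mean.tolist(),
                    "std": self.standardizer.std.tolist(),
                },
                "projected_means": {"deleterious": self.mean_del,
                                    "benign": self.mean_ben},
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "LDAModel":
        d = json.loads(text)
        if d.get("model") != "lda":
            raise ValueError(f"not an LDA model file: {d.get('model')!r}")
        return cls(
            weights=np.array(d["weights"]),
            threshold=float(d["threshold"]),
            standardizer=Standardizer(
                mean=np.array(d["standardizer"]["mean"]),
                std=np.array(d["standardizer"]["std"]),
            ),
            mean_del=float(d["projected_means"]["deleterious"]),
            mean_ben=float(d["projected_means"]["benign"]),
        )


def lda_train(X: np.ndarray, labels: Sequence[str]) -> LDAModel:
    """Fit the two-class Fisher discriminant.

    A ridge ε = 1e-6·trace(S)/d is added to the pooled covariance so that
    collinear or constant features cannot make it singular.
    """
    X = np.asarray(X, dtype=float)
    y = labels_to_bool(labels)
    if y.all() or not y.any():
        raise ValueError("LDA needs both classes present")
    std = Standardizer.fit(X)
    Z = std.transform(X)
    zd, zb = Z[y], Z[~y]
    mu_d, mu_b = zd.mean(axis=0), zb.mean(axis=0)
    n_d, n_b = len(zd), len(zb)
    d = Z.shape[1]
    S = (
        np.cov(zd, rowvar=False, ddof=1) * (n_d - 1)
        + np.cov(zb, rowvar=False, ddof=1) * (n_b - 1)
    ) / (n_d + n_b - 2)
    S = np.atleast_2d(S)
    S = S + np.eye(d) * (1e-6 * np.trace(S) / d)
    w = np.linalg.solve(S, mu_d - mu_b)
    proj_d = float(mu_d @ w)
    proj_b = float(mu_b @ w)
    return LDAModel(
        weights=w,
        threshold=(proj_d + proj_b) / 2.0,
        standardizer=std,
        mean_del=proj_d,
        mean_ben=proj_b,
    )


# ---------------------------------------------------------------------------
# Feed-forward network
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    algorithm: str = "rprop"  # or "stdbp"
    learning_rate: float = 0.2  # StdBP only
    eta_plus: float = 1.2
    eta_minus: float = 0.5
    delta_init: float = 0.1
    delta_max: float = 50.0
    delta_min: float = 1e-6
    max_epochs: int = 300
    patience: int = 100  # epochs without validation-MCC improvement
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.eta_minus < 1.0 < self.eta_plus:
            raise ValueError("need eta_minus < 1 < eta_plus")
        if not self.delta_min < self.delta_init < self.delta_max:
            raise ValueError("need delta_min < delta_init < delta_max")
        if self.algorithm not in ("rprop", "stdbp"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")


@dataclass
class NeuralNet:
    """Fully connected logistic-sigmoid network, 2 output nodes.

    Output node 0 codes deleterious, node 1 benign; the prediction score is
    o_del / (o_del + o_ben), 0.5 when both outputs vanish.
    """

    layers: tuple[int, ...] = DEFAULT_LAYERS
    weights: list[np.ndarray] = field(default_factory=list)
    biases: list[np.ndarray] = field(default_factory=list)
    standardizer: Optional[Standardizer] = None
    seed: Optional[int] = None

    @classmethod
    def initialize(cls, layers: tuple[int, ...] = DEFAULT_LAYERS,
                   seed: int = 0) -> "NeuralNet":
        rng = np.random.default_rng(seed)
        weights = [
            rng.uniform(-0.5, 0.5, size=(layers[i], layers[i + 1]))
            for i in range(len(layers) - 1)
        ]
        biases = [
            rng.uniform(-0.5, 0.5, size=layers[i + 1])
            for i in range(len(layers) - 1)
        ]
        return cls(layers=tuple(layers), weights=weights, biases=biases, seed=seed)

    def _forward(self, Z: np.ndarray) -> list[np.ndarray]:
        acts = [Z]
        for W, b in zip(self.weights, self.biases):
            acts.append(_sigmoid(acts[-1] @ W + b))
        return acts

    def raw_outputs(self, X: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(X, dtype=float))
        if self.standardizer is not None:
            Z = self.standardizer.transform(Z)
        if Z.shape[1] != self.layers[0]:
            raise ValueError(
                f"expected {self.layers[0]} input features, got {Z.shape[1]}"
            )
        return self._forward(Z)[-1]

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        out = self.raw_outputs(X)
        o_del, o_ben = out[:, 0], out[:, 1]
        total = o_del + o_ben
        with np.errstate(invalid="ignore"):
            scores = np.where(total > 0, o_del / np.where(total > 0, total, 1.0), 0.5)
        return scores

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> list[Prediction]:
        return [Prediction.from_score(s, threshold) for s in self.predict_scores(X)]

    def copy_weights(self) -> tuple[list[np.ndarray], list[np.ndarray]]:
        return [W.copy() for W in self.weights], [b.copy() for b in self.biases]

    # -- persistence -------------------------------------------------------
    def to_json(self) -> str:
        d = {
            "model": "nn",
            "layers": list(self.layers),
            "weights": [W.tolist() for W in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "seed": self.seed,
        }
        if self.standardizer is not None:
            d["standardizer"] = {
                "mean": self.standardizer.mean.tolist(),
                "std": self.standardizer.std.tolist(),
            }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "NeuralNet":
        d = json.loads(text)
        if d.get("model") != "nn":
            raise ValueError(f"not a neural-net model file: {d.get('model')!r}")
        std = None
        if "standardizer" in d:
            std = Standardizer(
                mean=np.array(d["standardizer"]["mean"]),
                std=np.array(d["standardizer"]["std"]),
            )
        return cls(
            layers=tuple(d["layers"]),
            weights=[np.array(W) for W in d["weights"]],
            biases=[np.array(b) for b in d["biases"]],
            standardizer=std,
            seed=d.get("seed"),
        )


@dataclass
class TrainingLog:
    sse: list[float] = field(default_factory=list)
    val_mcc: list[float] = field(default_factory=list)
    step_min: list[float] = field(default_factory=list)
    step_max: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_mcc: float = -np.inf


def _gradients(
    net: NeuralNet, Z: np.ndarray, T: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray], float]:
    """Full-batch SSE gradients via backpropagation; returns (dW, db, sse)."""
    acts = net._forward(Z)
    out = acts[-1]
    err = out - T
    sse = float((err**2).sum())
    delta = 2.0 * err * out * (1.0 - out)
    dWs: list[np.ndarray] = [None] * len(net.weights)  # type: ignore[list-item]
    dbs: list[np.ndarray] = [None] * len(net.biases)  # type: ignore[list-item]
    for layer in range(len(net.weights) - 1, -1, -1):
        dWs[layer] = acts[layer].T @ delta
        dbs[layer] = delta.sum(axis=0)
        if layer > 0:
            a = acts[layer]
            delta = (delta @ net.weights[layer].T) * a * (1.0 - a)
    return dWs, dbs, sse


def nn_train(
    net: NeuralNet,
    X: np.ndarray,
    labels: Sequence[str],
    val_X: np.ndarray,
    val_labels: Sequence[str],
    cfg: TrainConfig = TrainConfig(),
) -> tuple[NeuralNet, TrainingLog]:
    """Train with StdBP or Rprop; return the best-validation-MCC snapshot.

    Targets are the one-hot class codes. After every epoch the validation
    MCC at threshold 0.5 is evaluated and the weight snapshot maximizing it
    is the one returned (the training log records the full trajectory).
    Fully deterministic given the net's initial weights and the data.
    """
    X = np.asarray(X, dtype=float)
    y = labels_to_bool(labels)
    std = Standardizer.fit(X)
    net = replace(
        net,
        weights=[W.copy() for W in net.weights],
        biases=[b.copy() for b in net.biases],
        standardizer=std,
    )
    Z = std.transform(X)
    T = np.column_stack([y.astype(float), (~y).astype(float)])
    val_y = labels_to_bool(val_labels)

    log = TrainingLog()
    best_weights = net.copy_weights()

    if cfg.algorithm == "rprop":
        steps_W = [np.full_like(W, cfg.delta_init) for W in net.weights]
        steps_b = [np.full_like(b, cfg.delta_init) for b in net.biases]
        prev_gW = [np.zeros_like(W) for W in net.weights]
        prev_gb = [np.zeros_like(b) for b in net.biases]
        prev_dW = [np.zeros_like(W) for W in net.weights]
        prev_db = [np.zeros_like(b) for b in net.biases]
        prev_sse = np.inf

    stale = 0
    for epoch in range(cfg.max_epochs):
        dWs, dbs, sse = _gradients(net, Z, T)
        if not np.isfinite(sse):
            raise FloatingPointError(f"training diverged at epoch {epoch}")
        log.sse.append(sse)

        if cfg.algorithm == "stdbp":
            for W, b, dW, db in zip(net.weights, net.biases, dWs, dbs):
                W -= cfg.learning_rate * dW
                b -= cfg.learning_rate * db
            log.step_min.append(cfg.learning_rate)
            log.step_max.append(cfg.learning_rate)
        else:  # Rprop with weight backtracking
            lo, hi = np.inf, -np.inf
            for i in range(len(net.weights)):
                for params, grads, prev_g, steps, prev_upd in (
                    (net.weights[i], dWs[i], prev_gW[i], steps_W[i], prev_dW[i]),
                    (net.biases[i], dbs[i], prev_gb[i], steps_b[i], prev_db[i]),
                ):
                    sign = prev_g * grads
                    inc = sign > 0
                    dec = sign < 0
                    steps[inc] = np.minimum(steps[inc] * cfg.eta_plus, cfg.delta_max)
                    steps[dec] = np.maximum(steps[dec] * cfg.eta_minus, cfg.delta_min)
                    update = -np.sign(grads) * steps
                    # backtracking: revert the last move where the gradient
                    # flipped sign, but only if the error grew
                    if sse > prev_sse:
                        update[dec] = -prev_upd[dec]
                    else:
                        update[dec] = 0.0
                    grads = grads.copy()
                    grads[dec] = 0.0  # skip adaptation next epoch
                    params += update
                    prev_upd[...] = update
                    prev_g[...] = grads
                    lo = min(lo, float(steps.min()))
                    hi = max(hi, float(steps.max()))
            prev_sse = sse
            log.step_min.append(lo)
            log.step_max.append(hi)

        val_pred = net.predict_scores(val_X) >= 0.5
        mcc = _mcc_bool(val_y, val_pred)
        log.val_mcc.append(mcc)
        if mcc > log.best_val_mcc:
            log.best_val_mcc = mcc
            log.best_epoch = epoch
            best_weights = net.copy_weights()
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break

    net.weights, net.biases = best_weights
    return net, log


# ---------------------------------------------------------------------------
# Consensus combiners
# ---------------------------------------------------------------------------


def consensus(
    predictions: Sequence[Sequence[Prediction]], mode: str = "majority"
) -> list[str]:
    """Combine aligned prediction lists from several models into one call set.

    majority — deleterious iff more than half the models vote deleterious,
    with even splits breaking toward deleterious; union — deleterious iff
    any model votes deleterious.
    """
    if len(predictions) < 2:
        raise ValueError("consensus needs at least 2 predictors")
    lengths = {len(p) for p in predictions}
    if len(lengths) != 1:
        raise ValueError(f"prediction lists are misaligned: lengths {sorted(lengths)}")
    if mode not in ("majority", "union"):
        raise ValueError(f"unknown consensus mode {mode!r}")
    n_models = len(predictions)
    out = []
    for votes in zip(*predictions):
        n_del = sum(v.label == DELETERIOUS for v in votes)
        if mode == "union":
            call = DELETERIOUS if n_del > 0 else BENIGN
        else:
            # strict majority, with even-split ties breaking deleterious
            call = DELETERIOUS if 2 * n_del >= n_models else BENIGN
        out.append(call)
    return out


def load_model(text: str):
    """Load a persisted model of either kind from its JSON text."""
    kind = json.loads(text).get("model")
    if kind == "lda":
        return LDAModel.from_json(text)
    if kind == "nn":
        return NeuralNet.from_json(text)
    raise ValueError(f"unknown model kind {kind!r}")
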