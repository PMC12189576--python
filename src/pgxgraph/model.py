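"""Medication-usage predictors: GCN, dense network and logistic baseline.

All predictors are scikit-learn style estimators mapping a patient dosage
matrix (patients x genotype features) to independent per-medication usage
probabilities, trained with minibatch Adam on a multilabel binary
cross-entropy loss (sum over medications, mean over patients) and selected at
the epoch with the lowest validation loss.

The graph model follows a three-step architecture: (1) node embeddings from
stacked graph convolutions ``H^{l+1} = sigma(S H^l W^l)`` over the normalized
operator ``S = D_hat^{-1/2}(A+I)D_hat^{-1/2}`` with identity input features,
so only graph structure informs the embeddings; (2) a genotype-weighted
aggregation ``Z_i = sum_j G_ij * H[feature_j]`` producing one embedding per
patient; (3) a feed-forward head with a terminal sigmoid per medication. The
GCN layers and the head are updated jointly end-to-end. The randomized-graph
control is the identical model trained on a degree-preserving rewiring of the
graph, isolating the contribution of the specific graph wiring.
"""

from __future__ import annotations

import copy
import json
import math

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator

from ._nn import Adam, bce_loss, glorot, relu, sigmoid
from .kg import KnowledgeGraph, NormalizedAdjacency, graph_operator, randomize_graph

__all__ = [
    "gcn_forward",
    "aggregate_patient_embedding",
    "bce_loss",
    "split_sizes",
    "stratified_split",
    "LogisticUsageClassifier",
    "DenseUsageClassifier",
    "GCNUsageClassifier",
    "build_model",
    "train",
]

_ACTIVATIONS = {"relu": relu, "identity": lambda x: x, "tanh": np.tanh}


# ---------------------------------------------------------------------------
# functional pieces


def gcn_forward(S, weights: list[np.ndarray], activation: str = "relu") -> np.ndarray:
    """Stacked graph convolutions with identity input features.

    Computes ``H^{l+1} = sigma(S H^l W^l)`` starting from ``H^0 = I``; the
    first product therefore reduces to ``S @ W^0`` and no dense N x N feature
    matrix is ever materialized. Returns the final-layer node embeddings.
    """
    if isinstance(S, NormalizedAdjacency):
        S = S.S
    act = _ACTIVATIONS[activation] if isinstance(activation, str) else activation
    n = S.shape[0]
    H: np.ndarray | None = None
    for layer, W in enumerate(weights):
        d_in = n if H is None else H.shape[1]
        if W.shape[0] != d_in:
            raise ValueError(
                f"layer {layer}: weight rows {W.shape[0]} != input width {d_in}"
            )
        H = act(S @ W if H is None else S @ (H @ W))
    if H is None:
        raise ValueError("at least one weight matrix required")
    return np.asarray(H)


def aggregate_patient_embedding(H_features: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Genotype-weighted sum of feature-node embeddings: ``Z = G @ H_features``.

    ``H_features`` rows must align with the feature columns of ``G``; accepts
    a single patient vector or a batch.
    """
    H_features = np.asarray(H_features, dtype=np.float64)
    G = np.asarray(G, dtype=np.float64)
    if G.shape[-1] != H_features.shape[0]:
        raise ValueError(
            f"feature length mismatch: G has {G.shape[-1]},"
            f" embeddings have {H_features.shape[0]} rows"
        )
    return G @ H_features


# ---------------------------------------------------------------------------
# stratified multilabel splitting


def split_sizes(n: int, fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)) -> tuple[int, int, int]:
    """Train/validation/test counts for ``n`` samples.

    Validation and test counts round up (ceiling); training takes the
    remainder.
    """
    f_train, f_val, f_test = fractions
    if min(fractions) <= 0 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    n_val = math.ceil(f_val * n)
    n_test = math.ceil(f_test * n)
    n_train = n - n_val - n_test
    if n_train <= 0:
        raise ValueError(f"too few samples ({n}) for fractions {fractions}")
    return n_train, n_val, n_test


def stratified_split(
    labels,
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Iteratively stratified train/validation/test partition of all samples.

    Labels rarest first: samples carrying the currently rarest unassigned
    label go to the split with the greatest remaining demand for that label
    (ties broken by remaining capacity, then at random), keeping each
    medication's prevalence balanced across splits. Label-free samples fill
    remaining capacity at the end. Reproducible under a fixed seed.
    """
    Y = np.asarray(getattr(labels, "values", labels), dtype=np.float64)
    if Y.ndim != 2:
        raise ValueError("labels must be 2-D (patients x medications)")
    n, k = Y.shape
    sizes = split_sizes(n, fractions)
    rng = np.random.default_rng(seed)

    capacity = np.array(sizes, dtype=np.int64)
    # fractional per-split demand for each label
    desired = np.outer(np.array(sizes) / n, Y.sum(axis=0))  # 3 x k
    label_sets = [set(np.flatnonzero(Y[:, j])) for j in range(k)]
    few = [j for j in range(k) if 0 < len(label_sets[j]) < 3]
    if few:
        import warnings

        warnings.warn(
            f"{len(few)} label(s) have fewer users than splits; best-effort placement",
            stacklevel=2,
        )
    assignment = np.full(n, -1, dtype=np.int64)
    unassigned = set(range(n))

    while True:
        remaining = [(len(label_sets[j]), j) for j in range(k) if label_sets[j]]
        if not remaining:
            break
        _, j = min(remaining)
        members = sorted(label_sets[j])
        rng.shuffle(members)
        for i in members:
            open_splits = np.flatnonzero(capacity > 0)
            d = desired[open_splits, j]
            best = open_splits[d == d.max()]
            if len(best) > 1:
                c = capacity[best]
                best = best[c == c.max()]
            s = int(rng.choice(best))
            assignment[i] = s
            capacity[s] -= 1
            unassigned.discard(i)
            for jj in np.flatnonzero(Y[i]):
                desired[s, jj] -= 1.0
                label_sets[jj].discard(i)

    rest = sorted(unassigned)
    rng.shuffle(rest)
    for i in rest:
        open_splits = np.flatnonzero(capacity > 0)
        c = capacity[open_splits]
        best = open_splits[c == c.max()]
        s = int(rng.choice(best))
        assignment[i] = s
        capacity[s] -= 1

    return tuple(np.sort(np.flatnonzero(assignment == s)) for s in range(3))


# ---------------------------------------------------------------------------
# estimators


class _MultilabelNetClassifier(BaseEstimator):
    """Shared minibatch-Adam training loop with validation-loss model selection.

    Subclasses implement ``_init_params`` / ``_forward`` / ``_backward`` over
    a named parameter dict; gradients are analytic. Training runs until the
    epoch budget or until ``patience`` epochs pass without a validation-loss
    improvement, and the returned model is the checkpoint with the minimum
    validation loss (``best_epoch_``, 1-based).
    """

    def __init__(self, lr=1e-3, max_epochs=200, patience=20, batch_size=4096,
                 validation_fraction=0.1, random_state=0):
        self.lr = lr
        self.max_epochs = max_epochs
        self.patience = patience
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # subclass API -------------------------------------------------------
    def _init_params(self, rng, n_features, n_labels) -> dict[str, np.ndarray]:
        raise NotImplementedError

    def _forward(self, params, X):
        """Return (logits, cache)."""
        raise NotImplementedError

    def _backward(self, params, cache, d_logits) -> dict[str, np.ndarray]:
        raise NotImplementedError

    def _prepare_fit(self, rng) -> None:
        """Hook run once before parameter initialization."""

    # --------------------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(getattr(X, "values", X), dtype=np.float64)
        y = np.asarray(getattr(y, "values", y), dtype=np.float64)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y row counts differ")
        rng = np.random.default_rng(self.random_state)
        self._prepare_fit(rng)

        if X_val is None:
            frac = self.validation_fraction
            tr, va, _ = stratified_split(
                y, (1.0 - 1.5 * frac, frac, frac / 2.0),
                seed=int(rng.integers(2**31 - 1)),
            )
            tr = np.sort(np.concatenate([tr, _]))
            X, X_val, y, y_val = X[tr], X[va], y[tr], y[va]
        else:
            X_val = np.asarray(getattr(X_val, "values", X_val), dtype=np.float64)
            y_val = np.asarray(getattr(y_val, "values", y_val), dtype=np.float64)

        n, p = X.shape
        k = y.shape[1]
        self.n_features_in_ = p
        self.n_labels_ = k
        params = self._init_params(rng, p, k)
        opt = Adam(params, lr=self.lr)

        history = {"train_loss": [], "val_loss": []}
        best_loss, best_epoch, best_params = np.inf, -1, None
        stale = 0
        for epoch in range(1, self.max_epochs + 1):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                logits, cache = self._forward(params, X[idx])
                probs = sigmoid(logits)
                d_logits = (probs - y[idx]) / len(idx)
                grads = self._backward(params, cache, d_logits)
                opt.step(params, grads)

            train_loss = bce_loss(y, sigmoid(self._forward(params, X)[0]))
            val_loss = bce_loss(y_val, sigmoid(self._forward(params, X_val)[0]))
            if not (np.isfinite(train_loss) and np.isfinite(val_loss)):
                raise FloatingPointError(f"training diverged (NaN loss) at epoch {epoch}")
            history["train_loss"].append(train_loss)
            history["val_loss"].append(val_loss)
            if val_loss < best_loss - 1e-12:
                best_loss, best_epoch = val_loss, epoch
                best_params = {k_: v.copy() for k_, v in params.items()}
                stale = 0
            else:
                stale += 1
                if stale >= self.patience:
                    break

        self.params_ = best_params if best_params is not None else params
        self.history_ = history
        self.best_epoch_ = best_epoch
        self.best_val_loss_ = float(best_loss)
        return self

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(getattr(X, "values", X), dtype=np.float64)
        logits, _ = self._forward(self.params_, X)
        return logits

    def predict_proba(self, X) -> np.ndarray:
        return sigmoid(self.decision_function(X))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(np.int64)

    # checkpointing ------------------------------------------------------

    def save(self, weights_path, history_path=None) -> None:
        np.savez(weights_path, **self.params_)
        if history_path is not None:
            meta = {
                "class": type(self).__name__,
                "params": {k: v for k, v in self.get_params().items()
                           if isinstance(v, (int, float, str, type(None)))},
                "history": self.history_,
                "best_epoch": self.best_epoch_,
                "best_val_loss": self.best_val_loss_,
            }
            with open(history_path, "w") as fh:
                json.dump(meta, fh, indent=2)

    def load_weights(self, weights_path) -> "_MultilabelNetClassifier":
        with np.load(weights_path) as z:
            self.params_ = {k: z[k] for k in z.files}
        return self


class LogisticUsageClassifier(_MultilabelNetClassifier):
    """Unregularized multilabel logistic regression (the linear baseline)."""

    def _init_params(self, rng, p, k):
        return {"W": np.zeros((p, k)), "b": np.zeros(k)}

    def _forward(self, params, X):
        return X @ params["W"] + params["b"], {"X": X}

    def _backward(self, params, cache, d_logits):
        X = cache["X"]
        return {"W": X.T @ d_logits, "b": d_logits.sum(axis=0)}


class DenseUsageClassifier(_MultilabelNetClassifier):
    """Feed-forward multilabel network on raw dosages (the DNN comparator)."""

    def __init__(self, hidden=(256, 64), lr=1e-3, max_epochs=200, patience=20,
                 batch_size=4096, validation_fraction=0.1, random_state=0):
        super().__init__(lr=lr, max_epochs=max_epochs, patience=patience,
                         batch_size=batch_size,
                         validation_fraction=validation_fraction,
                         random_state=random_state)
        self.hidden = hidden

    def _init_params(self, rng, p, k):
        dims = [p, *self.hidden, k]
        params = {}
        for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            params[f"W{i}"] = glorot(rng, a, b)
            params[f"b{i}"] = np.zeros(b)
        self._depth = len(dims) - 1
        return params

    def _forward(self, params, X):
        depth = len([k_ for k_ in params if k_.startswith("W")])
        acts = [X]
        pres = []
        h = X
        for i in range(depth):
            z = h @ params[f"W{i}"] + params[f"b{i}"]
            pres.append(z)
            h = relu(z) if i < depth - 1 else z
            acts.append(h)
        return h, {"acts": acts, "pres": pres, "depth": depth}

    def _backward(self, params, cache, d_logits):
        acts, pres, depth = cache["acts"], cache["pres"], cache["depth"]
        grads = {}
        delta = d_logits
        for i in reversed(range(depth)):
            grads[f"W{i}"] = acts[i].T @ delta
            grads[f"b{i}"] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ params[f"W{i}"].T) * (pres[i - 1] > 0)
        return grads


class GCNUsageClassifier(_MultilabelNetClassifier):
    """Graph-convolutional medication-usage predictor.

    Parameters
    ----------
    graph : KnowledgeGraph
        The knowledge graph whose variant/haplotype nodes correspond to the
        columns of the dosage matrix.
    feature_ids : list of str
        Node id per dosage column, in column order.
    n_layers, embedding_dim : int
        Number of graph-convolution layers and final embedding width F.
    head_hidden : tuple of int
        Hidden widths of the classifier head (terminal layer is linear with
        one sigmoid output per medication).
    randomize : bool
        Train on a degree-preserving rewiring of the graph instead (the
        randomized-graph ablation control).
    """

    def __init__(self, graph=None, feature_ids=None, n_layers=2, embedding_dim=64,
                 head_hidden=(64,), randomize=False, randomize_mode="degree-preserving",
                 lr=1e-3, max_epochs=200, patience=20, batch_size=4096,
                 validation_fraction=0.1, random_state=0):
        super().__init__(lr=lr, max_epochs=max_epochs, patience=patience,
                         batch_size=batch_size,
                         validation_fraction=validation_fraction,
                         random_state=random_state)
        self.graph = graph
        self.feature_ids = feature_ids
        self.n_layers = n_layers
        self.embedding_dim = embedding_dim
        self.head_hidden = head_hidden
        self.randomize = randomize
        self.randomize_mode = randomize_mode

    def _prepare_fit(self, rng):
        if self.graph is None or self.feature_ids is None:
            raise ValueError("GCN models require a graph and feature_ids")
        graph = self.graph
        if self.randomize:
            graph = randomize_graph(graph, mode=self.randomize_mode,
                                    seed=int(rng.integers(2**31 - 1)))
        self.graph_used_ = graph
        op = graph_operator(graph)
        self.S_ = sp.csr_matrix(op.S)
        index = graph.node_index
        missing = [f for f in self.feature_ids if f not in index]
        if missing:
            raise ValueError(f"{len(missing)} feature ids missing from graph,"
                             f" e.g. {missing[:3]}")
        self.feature_rows_ = np.array([index[f] for f in self.feature_ids])

    def _init_params(self, rng, p, k):
        if p != len(self.feature_ids):
            raise ValueError("dosage columns do not match feature_ids length")
        n = self.S_.shape[0]
        dims = [n] + [self.embedding_dim] * self.n_layers
        params = {}
        for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            params[f"G{i}"] = glorot(rng, a, b)
        head_dims = [self.embedding_dim, *self.head_hidden, k]
        for i, (a, b) in enumerate(zip(head_dims[:-1], head_dims[1:])):
            params[f"W{i}"] = glorot(rng, a, b)
            params[f"b{i}"] = np.zeros(b)
        return params

    def _forward(self, params, X):
        S = self.S_
        n_gcn = len([k_ for k_ in params if k_.startswith("G")])
        pres, acts = [], []
        H = None
        for i in range(n_gcn):
            W = params[f"G{i}"]
            z = S @ W if H is None else S @ (H @ W)
            pres.append(z)
            H = relu(z)
            acts.append(H)
        Hf = H[self.feature_rows_]
        Z = X @ Hf  # genotype-weighted aggregation
        depth = len([k_ for k_ in params if k_.startswith("W")])
        head_pres, head_acts = [], [Z]
        h = Z
        for i in range(depth):
            z = h @ params[f"W{i}"] + params[f"b{i}"]
            head_pres.append(z)
            h = relu(z) if i < depth - 1 else z
            head_acts.append(h)
        cache = {"X": X, "pres": pres, "acts": acts, "Hf": Hf,
                 "head_pres": head_pres, "head_acts": head_acts,
                 "depth": depth, "n_gcn": n_gcn}
        return h, cache

    def _backward(self, params, cache, d_logits):
        S = self.S_
        grads = {}
        depth, n_gcn = cache["depth"], cache["n_gcn"]
        delta = d_logits
        for i in reversed(range(depth)):
            grads[f"W{i}"] = cache["head_acts"][i].T @ delta
            grads[f"b{i}"] = delta.sum(axis=0)
            delta = delta @ params[f"W{i}"].T
            if i > 0:
                delta = delta * (cache["head_pres"][i - 1] > 0)
        dZ = delta  # gradient w.r.t. patient embeddings
        dHf = cache["X"].T @ dZ
        dH = np.zeros((S.shape[0], dHf.shape[1]))
        np.add.at(dH, self.feature_rows_, dHf)
        for i in reversed(range(n_gcn)):
            dz = dH * (cache["pres"][i] > 0)
            # S is symmetric, so S^T @ x == S @ x
            if i == 0:
                grads[f"G{i}"] = S @ dz
            else:
                H_prev = cache["acts"][i - 1]
                Sdz = S @ dz
                grads[f"G{i}"] = H_prev.T @ Sdz
                dH = Sdz @ params[f"G{i}"].T
        return grads

    def node_embeddings(self) -> np.ndarray:
        """Final-layer embeddings of all graph nodes under the fitted weights."""
        n_gcn = len([k_ for k_ in self.params_ if k_.startswith("G")])
        weights = [self.params_[f"G{i}"] for i in range(n_gcn)]
        return gcn_forward(self.S_, weights, activation="relu")


# ---------------------------------------------------------------------------
# factory and training wrapper

MODEL_KINDS = ("baseline", "dnn", "gcn", "gcn-random")


def build_model(kind: str, graph: KnowledgeGraph | None = None,
                feature_ids: list[str] | None = None, random_state: int = 0,
                **kwargs) -> _MultilabelNetClassifier:
    """Construct one of the compared predictors by name."""
    if kind == "baseline":
        return LogisticUsageClassifier(random_state=random_state, **kwargs)
    if kind == "dnn":
        return DenseUsageClassifier(random_state=random_state, **kwargs)
    if kind in ("gcn", "gcn-random"):
        if graph is None or feature_ids is None:
            raise ValueError(f"model kind {kind!r} requires a graph and feature_ids")
        return GCNUsageClassifier(graph=graph, feature_ids=feature_ids,
                                  randomize=(kind == "gcn-random"),
                                  random_state=random_state, **kwargs)
    raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")


def train(predictor, X, y, splits, config: dict | None = None):
    """Fit on the train split with validation-loss checkpoint selection.

    ``splits`` is the (train, validation, test) index triple from
    :func:`stratified_split`; the test indices are untouched. Returns
    ``(fitted predictor, history dict)``.
    """
    X = np.asarray(getattr(X, "values", X), dtype=np.float64)
    y = np.asarray(getattr(y, "values", y), dtype=np.float64)
    tr, va, _ = splits
    if config:
        predictor = copy.deepcopy(predictor).set_params(**config)
    predictor.fit(X[tr], y[tr], X_val=X[va], y_val=y[va])
    return predictor, predictor.history_
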