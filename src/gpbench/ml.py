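"""Machine-learning genomic predictors behind a uniform predict contract.

Four regressors: random forests (bagged trees with per-split feature
subsampling), gradient-boosted trees with early stopping on a held-out
fraction of the training data, a two-hidden-layer perceptron, and a
one-dimensional convolutional network over the SNP axis.  The neural
networks are plain numpy implementations trained by mini-batch SGD with
momentum, l2 weight decay and inverted dropout, so a fixed seed gives
bit-identical training runs in single-threaded mode.  Trees see raw
0/1/2 codes (scale-invariant); the networks standardize inputs and the
response internally and return predictions on the original scale.

Default hyperparameters are the tuned values of the benchmarked study
conditions: RF ntree=500 / mtry=min(2000, m) / nodesize=5; boosting
learning rate 0.10, depth 3, 80% bagging, 50-round early stopping; MLP
units (64, 32) with ReLU then softplus ("softReLU" = softplus
log(1+e^x)), dropout (0.1, 0.1), SGD lr 0.01, momentum 0.5, weight decay
1e-5, batch 32, 200 epochs; CNN with 16 length-5 stride-3 filters,
max-pool 2/2, dropout 0.3, a 32-unit softplus dense layer and a softplus
unit before the linear output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "RFConfig",
    "GBConfig",
    "MLPConfig",
    "CNNConfig",
    "FittedSKModel",
    "FittedNet",
    "fit_random_forest",
    "fit_gradient_boosting",
    "fit_mlp",
    "fit_cnn",
    "tune_hyperparameters",
    "RF_PRESET_GRID",
    "MLP_PRESET_GRID",
]


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass
class RFConfig:
    ntree: int = 500
    mtry: int | None = None  # default min(2000, m), resolved at fit time
    nodesize: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")


@dataclass
class GBConfig:
    learning_rate: float = 0.10
    max_depth: int = 3
    subsample: float = 0.80
    early_stopping_rounds: int = 50
    max_trees: int = 5000
    validation_fraction: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.learning_rate <= 1.0):
            raise ValueError("learning_rate must be in [0, 1]")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in (0, 1)")


@dataclass
class MLPConfig:
    hidden_units: tuple[int, ...] = (64, 32)
    activations: tuple[str, ...] = ("relu", "softrelu")
    dropout: tuple[float, ...] = (0.1, 0.1)
    learning_rate: float = 0.01
    momentum: float = 0.5
    weight_decay: float = 1e-5
    batch_size: int = 32
    epochs: int = 200
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (len(self.hidden_units) == len(self.activations) == len(self.dropout)):
            raise ValueError("hidden_units, activations and dropout must have equal length")


@dataclass
class CNNConfig:
    n_filters: int = 16
    kernel: int = 5
    conv_stride: int = 3
    pool: int = 2
    pool_stride: int = 2
    dropout_pool: float = 0.3
    fc_units: int = 32
    dropout_fc: float = 0.3
    learning_rate: float = 0.01
    momentum: float = 0.5
    weight_decay: float = 1e-5
    batch_size: int = 64
    epochs: int = 200
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.kernel, self.conv_stride, self.pool, self.pool_stride) < 1:
            raise ValueError("kernel/stride values must be positive")

    def conv_len(self, m: int) -> int:
        return (m - self.kernel) // self.conv_stride + 1

    def pool_len(self, m: int) -> int:
        return (self.conv_len(m) - self.pool) // self.pool_stride + 1


# ---------------------------------------------------------------------------
# fitted handles
# ---------------------------------------------------------------------------


@dataclass
class FittedSKModel:
    model: object
    oob_mse: float | None = None
    best_iteration: int | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.model.predict(np.asarray(X, dtype=np.float64)))


@dataclass
class FittedNet:
    params: dict[str, np.ndarray]
    forward: callable = field(repr=False)
    x_mean: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    x_sd: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    y_mean: float = 0.0
    y_sd: float = 1.0
    history: pd.DataFrame | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        Z = (X - self.x_mean) / self.x_sd
        out = self.forward(self.params, Z)
        return self.y_mean + self.y_sd * out


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------


def fit_random_forest(y_train, X_train, config: RFConfig | None = None) -> FittedSKModel:
    """Bagged regression trees with mtry-feature splits and OOB error."""
    config = config or RFConfig()
    X = np.asarray(X_train, dtype=np.float64)
    y = np.asarray(y_train, dtype=np.float64)
    m = X.shape[1]
    mtry = min(2000, m) if config.mtry is None else config.mtry
    if mtry > m:
        raise ValueError(f"mtry={mtry} exceeds number of features m={m}")
    rf = RandomForestRegressor(
        n_estimators=config.ntree,
        max_features=mtry,
        min_samples_leaf=config.nodesize,
        bootstrap=True,
        oob_score=True,
        random_state=config.seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    oob_pred = rf.oob_prediction_
    oob_mse = float(np.mean((y - oob_pred) ** 2))
    return FittedSKModel(model=rf, oob_mse=oob_mse)


def fit_gradient_boosting(y_train, X_train, config: GBConfig | None = None) -> FittedSKModel:
    """Gradient-boosted depth-limited trees (xgboost) with early stopping.

    A fixed ``validation_fraction`` of the training data is held out for
    early stopping; boosting stops once held-out MSE has not improved for
    ``early_stopping_rounds`` rounds, and the best iteration is retained.
    """
    import xgboost as xgb

    config = config or GBConfig()
    X = np.asarray(X_train, dtype=np.float64)
    y = np.asarray(y_train, dtype=np.float64)
    n = len(y)
    n_val = max(1, int(round(n * config.validation_fraction)))
    if n - n_val < 2:
        raise ValueError("training set too small for the early-stopping holdout")
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]

    if config.learning_rate == 0.0:
        # degenerate limit: no update ever happens; predict the base score
        base = float(np.mean(y[tr_idx]))
        class _Const:
            def predict(self, X):  # noqa: ANN001
                return np.full(len(X), base)
        return FittedSKModel(model=_Const(), best_iteration=0)

    model = xgb.XGBRegressor(
        n_estimators=config.max_trees,
        learning_rate=config.learning_rate,
        max_depth=config.max_depth,
        subsample=config.subsample,
        early_stopping_rounds=config.early_stopping_rounds,
        eval_metric="rmse",
        random_state=config.seed,
        n_jobs=1,
        tree_method="hist",
        verbosity=0,
    )
    model.fit(X[tr_idx], y[tr_idx], eval_set=[(X[val_idx], y[val_idx])], verbose=False)
    best = getattr(model, "best_iteration", None)
    return FittedSKModel(model=model, best_iteration=best)


# ---------------------------------------------------------------------------
# numpy neural networks
# ---------------------------------------------------------------------------


def _act(name: str, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Activation value and derivative."""
    if name == "relu":
        out = np.maximum(x, 0.0)
        return out, (x > 0).astype(np.float64)
    if name in ("softrelu", "softplus"):
        out = np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)  # stable softplus
        return out, 1.0 / (1.0 + np.exp(-x))
    if name == "linear":
        return x, np.ones_like(x)
    raise ValueError(f"unknown activation {name!r}")


def _standardize_xy(X, y):
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0)
    x_sd[x_sd == 0] = 1.0
    y_mean = float(y.mean())
    y_sd = float(y.std()) or 1.0
    return (X - x_mean) / x_sd, (y - y_mean) / y_sd, x_mean, x_sd, y_mean, y_sd


def _sgd_step(params, grads, velocity, lr, momentum, weight_decay):
    for k in params:
        velocity[k] = momentum * velocity[k] - lr * (grads[k] + weight_decay * params[k])
        params[k] += velocity[k]


def _val_split(n, frac, rng):
    n_val = int(round(n * frac))
    perm = rng.permutation(n)
    return perm[n_val:], perm[:n_val]


def fit_mlp(y_train, X_train, config: MLPConfig | None = None) -> FittedNet:
    """Two-hidden-layer perceptron trained by mini-batch SGD.

    Minimizes (1/2n) sum (y - yhat)^2 plus l2 penalties on all weights
    and biases (weight decay).  The per-epoch train/validation MSE curve
    (standardized scale) is retained on the fitted handle for
    overfitting inspection.
    """
    config = config or MLPConfig()
    Z, yz, x_mean, x_sd, y_mean, y_sd = _standardize_xy(X_train, y_train)
    n, m = Z.shape
    rng = np.random.default_rng(config.seed)
    sizes = (m, *config.hidden_units, 1)
    acts = (*config.activations, "linear")

    params: dict[str, np.ndarray] = {}
    for layer, (fan_in, fan_out) in enumerate(zip(sizes[:-1], sizes[1:])):
        scale = np.sqrt(2.0 / fan_in)
        params[f"W{layer}"] = rng.normal(0.0, scale, size=(fan_in, fan_out))
        params[f"b{layer}"] = np.zeros(fan_out)
    n_layers = len(sizes) - 1

    def forward_inference(p, X):
        h = X
        for layer in range(n_layers):
            z = h @ p[f"W{layer}"] + p[f"b{layer}"]
            h, _ = _act(acts[layer], z)
        return h[:, 0]

    tr_idx, val_idx = _val_split(n, config.validation_fraction, rng)
    if len(tr_idx) == 0:
        tr_idx = np.arange(n)
        val_idx = np.empty(0, dtype=int)

    velocity = {k: np.zeros_like(v) for k, v in params.items()}
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(tr_idx))
        batch_sse = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = tr_idx[order[start : start + config.batch_size]]
            Xb, yb = Z[batch], yz[batch]
            # forward with caches
            hs = [Xb]
            caches = []
            h = Xb
            for layer in range(n_layers):
                z = h @ params[f"W{layer}"] + params[f"b{layer}"]
                h, dh = _act(acts[layer], z)
                mask = None
                if layer < n_layers - 1 and config.dropout[layer] > 0:
                    keep = 1.0 - config.dropout[layer]
                    mask = (rng.random(h.shape) < keep) / keep
                    h = h * mask
                caches.append((dh, mask))
                hs.append(h)
            pred = hs[-1][:, 0]
            if not np.isfinite(pred).all():
                raise FloatingPointError(f"NaN loss at epoch {epoch}")
            batch_sse += float(np.sum((pred - yb) ** 2))
            grads = {}
            delta = ((pred - yb) / len(yb))[:, None]
            for layer in range(n_layers - 1, -1, -1):
                dh, mask = caches[layer]
                if mask is not None:
                    delta = delta * mask
                delta = delta * dh
                grads[f"W{layer}"] = hs[layer].T @ delta
                grads[f"b{layer}"] = delta.sum(axis=0)
                if layer:
                    delta = delta @ params[f"W{layer}"].T
            _sgd_step(params, grads, velocity, config.learning_rate,
                      config.momentum, config.weight_decay)
        # running train MSE over the epoch's batches (pre-update, with dropout)
        tr_mse = batch_sse / len(tr_idx)
        val_mse = (
            float(np.mean((forward_inference(params, Z[val_idx]) - yz[val_idx]) ** 2))
            if len(val_idx)
            else np.nan
        )
        history.append((epoch, tr_mse, val_mse))

    hist = pd.DataFrame(history, columns=["epoch", "train_mse", "val_mse"])
    return FittedNet(
        params=params, forward=forward_inference,
        x_mean=x_mean, x_sd=x_sd, y_mean=y_mean, y_sd=y_sd, history=hist,
    )


def fit_cnn(y_train, X_train, config: CNNConfig | None = None) -> FittedNet:
    """One-dimensional CNN over the SNP axis.

    conv(16 filters, kernel 5, stride 3) + ReLU -> max-pool(2, stride 2)
    -> dropout -> dense(32) softplus -> dropout -> dense(1) softplus ->
    linear output.
    """
    config = config or CNNConfig()
    Z, yz, x_mean, x_sd, y_mean, y_sd = _standardize_xy(X_train, y_train)
    n, m = Z.shape
    T = config.conv_len(m)
    P = config.pool_len(m)
    if T < 1 or P < 1:
        raise ValueError(f"conv/pool geometry underflows for m={m}")
    F, K = config.n_filters, config.kernel
    rng = np.random.default_rng(config.seed)

    params = {
        "Wc": rng.normal(0.0, np.sqrt(2.0 / K), size=(K, F)),
        "bc": np.zeros(F),
        "W1": rng.normal(0.0, np.sqrt(2.0 / (P * F)), size=(P * F, config.fc_units)),
        "b1": np.zeros(config.fc_units),
        "W2": rng.normal(0.0, np.sqrt(2.0 / config.fc_units), size=(config.fc_units, 1)),
        # softplus bottleneck: start the unit in its responsive region and the
        # output weight at unity, else the scalar path can begin near-dead
        "b2": np.full(1, 0.5),
        "W3": np.ones((1, 1)),
        "b3": np.zeros(1),
    }

    win_idx = (np.arange(T)[:, None] * config.conv_stride + np.arange(K)[None, :])  # (T, K)
    pool_idx = np.arange(P)[:, None] * config.pool_stride + np.arange(config.pool)[None, :]

    contiguous_pool = config.pool == config.pool_stride

    def conv_forward(p, X):
        Xw = X[:, win_idx]  # (n, T, K)
        z = Xw @ p["Wc"] + p["bc"]  # (n, T, F)
        a = np.maximum(z, 0.0)
        if contiguous_pool:
            win = a[:, : P * config.pool, :].reshape(len(X), P, config.pool, F)
        else:
            win = a[:, pool_idx, :]  # (n, P, pool, F)
        arg = win.argmax(axis=2)
        pooled = np.take_along_axis(win, arg[:, :, None, :], axis=2)[:, :, 0, :]
        return Xw, z, a, arg, pooled

    def head_forward(p, flat):
        z1 = flat @ p["W1"] + p["b1"]
        a1, d1 = _act("softrelu", z1)
        z2 = a1 @ p["W2"] + p["b2"]
        a2, d2 = _act("softrelu", z2)
        out = a2 @ p["W3"] + p["b3"]
        return out[:, 0], (z1, a1, d1, z2, a2, d2)

    def forward_inference(p, X):
        *_, pooled = conv_forward(p, X)
        flat = pooled.reshape(len(X), -1)
        return head_forward(p, flat)[0]

    tr_idx, val_idx = _val_split(n, config.validation_fraction, rng)
    if len(tr_idx) == 0:
        tr_idx = np.arange(n)
        val_idx = np.empty(0, dtype=int)
    velocity = {k: np.zeros_like(v) for k, v in params.items()}
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(tr_idx))
        batch_sse = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = tr_idx[order[start : start + config.batch_size]]
            Xb, yb = Z[batch], yz[batch]
            nb = len(yb)
            Xw, zc, ac, arg, pooled = conv_forward(params, Xb)
            keep_p = 1.0 - config.dropout_pool
            mask_p = (rng.random(pooled.shape) < keep_p) / keep_p if config.dropout_pool else None
            pooled_d = pooled * mask_p if mask_p is not None else pooled
            flat = pooled_d.reshape(nb, -1)
            z1 = flat @ params["W1"] + params["b1"]
            a1, d1 = _act("softrelu", z1)
            keep_f = 1.0 - config.dropout_fc
            mask_f = (rng.random(a1.shape) < keep_f) / keep_f if config.dropout_fc else None
            a1_d = a1 * mask_f if mask_f is not None else a1
            z2 = a1_d @ params["W2"] + params["b2"]
            a2, d2 = _act("softrelu", z2)
            pred = (a2 @ params["W3"] + params["b3"])[:, 0]
            if not np.isfinite(pred).all():
                raise FloatingPointError(f"NaN loss at epoch {epoch}")
            batch_sse += float(np.sum((pred - yb) ** 2))

            grads = {}
            dout = ((pred - yb) / nb)[:, None]
            grads["W3"] = a2.T @ dout
            grads["b3"] = dout.sum(axis=0)
            da2 = dout @ params["W3"].T
            dz2 = da2 * d2
            grads["W2"] = a1_d.T @ dz2
            grads["b2"] = dz2.sum(axis=0)
            da1 = dz2 @ params["W2"].T
            if mask_f is not None:
                da1 = da1 * mask_f
            dz1 = da1 * d1
            grads["W1"] = flat.T @ dz1
            grads["b1"] = dz1.sum(axis=0)
            dflat = dz1 @ params["W1"].T
            dpooled = dflat.reshape(nb, P, F)
            if mask_p is not None:
                dpooled = dpooled * mask_p
            # route pooled gradient back to the argmax conv outputs
            dac = np.zeros_like(ac)  # (nb, T, F)
            # scatter: for each (i, p_out, f), position pool_idx[p_out, arg]
            t_positions = np.take_along_axis(
                np.broadcast_to(pool_idx[None, :, :, None], (nb, P, config.pool, F)),
                arg[:, :, None, :],
                axis=2,
            )[:, :, 0, :]  # (nb, P, F)
            i_idx = np.repeat(np.arange(nb), P * F)
            f_idx = np.tile(np.arange(F), nb * P)
            if config.pool <= config.pool_stride:  # windows disjoint: no collisions
                dac[i_idx, t_positions.ravel(), f_idx] = dpooled.ravel()
            else:
                np.add.at(dac, (i_idx, t_positions.ravel(), f_idx), dpooled.ravel())
            dzc = dac * (zc > 0)
            grads["Wc"] = np.einsum("ntk,ntf->kf", Xw, dzc)
            grads["bc"] = dzc.sum(axis=(0, 1))
            _sgd_step(params, grads, velocity, config.learning_rate,
                      config.momentum, config.weight_decay)
        tr_mse = batch_sse / len(tr_idx)
        val_mse = (
            float(np.mean((forward_inference(params, Z[val_idx]) - yz[val_idx]) ** 2))
            if len(val_idx)
            else np.nan
        )
        history.append((epoch, tr_mse, val_mse))

    hist = pd.DataFrame(history, columns=["epoch", "train_mse", "val_mse"])
    return FittedNet(
        params=params, forward=forward_inference,
        x_mean=x_mean, x_sd=x_sd, y_mean=y_mean, y_sd=y_sd, history=hist,
    )


# ---------------------------------------------------------------------------
# hyperparameter search
# ---------------------------------------------------------------------------

# the grids explored when tuning at full scale
RF_PRESET_GRID = {"ntree": [200, 500, 1000], "mtry": [500, 1000, 2000, 5000]}
MLP_PRESET_GRID = {
    "batch_size": [32, 64, 128, 256],
    "epochs": [50, 100, 200, 500, 1000],
    "learning_rate": [0.001, 0.01, 0.1, 0.2, 0.3],
    "weight_decay": [1e-5, 1e-4, 1e-3, 1e-2],
}

_FITTERS = {
    "rf": (fit_random_forest, RFConfig),
    "gb": (fit_gradient_boosting, GBConfig),
    "mlp": (fit_mlp, MLPConfig),
    "cnn": (fit_cnn, CNNConfig),
}


def _expand_grid(grid) -> list[dict]:
    if isinstance(grid, dict):
        keys = list(grid)
        return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]
    return [dict(g) for g in grid]


def tune_hyperparameters(method: str, grid, y, X, scheme: str = "cv5", seed: int = 0):
    """Exhaustive grid search; returns (best config, score table).

    ``scheme='oob'`` scores random forests by out-of-bag MSE; ``'cv5'``
    scores any method by five-fold cross-validated MSE.  The score table
    has one row per configuration.
    """
    if method not in _FITTERS:
        raise ValueError(f"unknown method {method!r}")
    combos = _expand_grid(grid)
    if not combos:
        raise ValueError("grid is empty")
    fitter, cfg_cls = _FITTERS[method]
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, m = X.shape
    rows = []
    for combo in combos:
        params = dict(combo)
        if method == "rf" and "mtry" in params:
            params["mtry"] = min(params["mtry"], m)
        cfg = cfg_cls(**params, seed=seed) if "seed" not in params else cfg_cls(**params)
        if scheme == "oob":
            if method != "rf":
                raise ValueError("scheme 'oob' applies to random forests only")
            fitted = fitter(y, X, cfg)
            mse = fitted.oob_mse
        elif scheme == "cv5":
            if n < 5:
                raise ValueError("cv5 scheme needs at least 5 records")
            rng = np.random.default_rng(seed)
            folds = rng.permutation(n) % 5
            errs = []
            for f in range(5):
                te = folds == f
                fitted = fitter(y[~te], X[~te], cfg)
                errs.append(np.mean((fitted.predict(X[te]) - y[te]) ** 2))
            mse = float(np.mean(errs))
        else:
            raise ValueError("scheme must be 'oob' or 'cv5'")
        rows.append({**combo, "mse": mse})
    table = pd.DataFrame(rows)
    best = combos[int(table["mse"].idxmin())]
    params = dict(best)
    if method == "rf" and "mtry" in params:
        params["mtry"] = min(params["mtry"], m)
    best_cfg = cfg_cls(**params, seed=seed) if "seed" not in params else cfg_cls(**params)
    return best_cfg, table
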