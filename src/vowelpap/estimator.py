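"""Two-step stacked regression of PAP diameter from acoustic features.

Six-fold cross-validation; in each fold four base regressors (linear,
random forest, multilayer perceptron, 1-D convolutional network) are
trained on the training folds, and a random-forest combiner merges their
outputs.  The combiner is trained on *inner* out-of-fold predictions of
the base models inside each training split, so no test-fold information
ever reaches a fitted model.  Performance is reported as RMSE (mm) and the
Pearson correlation between pooled out-of-fold predictions and measured
PAP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.compose import TransformedTargetRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LinearRegression
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

N_FOLDS = 6
MODEL_NAMES = ("linear", "random_forest", "ann", "cnn")
RF_TREES = 500


# ---------------------------------------------------------------------------
# Fold construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    n_samples: int
    assignment: np.ndarray      # fold index 0..n_folds-1 per sample
    mode: str                   # "by_observation" | "by_participant"
    n_folds: int = N_FOLDS

    def split(self):
        for k in range(self.n_folds):
            test = np.flatnonzero(self.assignment == k)
            train = np.flatnonzero(self.assignment != k)
            yield train, test


def make_folds(
    n: int,
    mode: str = "by_observation",
    seed: int = 0,
    groups: Optional[Sequence] = None,
    n_folds: int = N_FOLDS,
) -> FoldPlan:
    """Assign samples to cross-validation folds.

    ``by_observation`` deals shuffled samples round-robin, so fold sizes
    differ by at most one (n = 150 gives exactly 25 test samples per fold).
    ``by_participant`` deals shuffled participants instead, so no
    participant's vowels ever span folds (the leakage-safe alternative);
    it requires ``groups``.
    """
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} samples, got {n}")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    if mode == "by_observation":
        order = rng.permutation(n)
        assignment[order] = np.arange(n) % n_folds
    elif mode == "by_participant":
        if groups is None:
            raise ValueError("by_participant mode requires groups")
        groups = np.asarray(groups)
        uniq = np.unique(groups)
        order = rng.permutation(len(uniq))
        fold_of = {g: i % n_folds for i, g in enumerate(uniq[order])}
        assignment = np.array([fold_of[g] for g in groups])
    else:
        raise ValueError(f"unknown fold mode {mode!r}")
    return FoldPlan(n_samples=n, assignment=assignment, mode=mode, n_folds=n_folds)


# ---------------------------------------------------------------------------
# 1-D convolutional regressor (numpy, Adam, early stopping)
# ---------------------------------------------------------------------------

def _sliding(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, L) -> (N, C, L-k+1, k) windows."""
    return np.lib.stride_tricks.sliding_window_view(x, k, axis=2)


class CNNRegressor(BaseEstimator, RegressorMixin):
    """Small 1-D convolutional network treating the 106-feature vector as an
    ordered sequence: two conv blocks (16 then 32 channels, kernel 5, max
    pool 2) and a dense head, trained with Adam and early stopping on an
    inner validation split.  Inputs are expected pre-standardized."""

    def __init__(self, channels=(16, 32), kernel=5, hidden=32,
                 lr=3e-3, max_epochs=150, patience=15, val_fraction=0.1,
                 batch_size=64, random_state=0):
        self.channels = channels
        self.kernel = kernel
        self.hidden = hidden
        self.lr = lr
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.batch_size = batch_size
        self.random_state = random_state

    # -- forward / backward -------------------------------------------------
    def _forward(self, x, params, cache=None):
        w1, b1, w2, b2, w3, b3, w4, b4 = params
        k = self.kernel
        a1 = np.einsum("nclk,ock->nol", _sliding(x, k), w1, optimize=True) + b1[None, :, None]
        r1 = np.maximum(a1, 0.0)
        L1 = (r1.shape[2] // 2) * 2
        p1v = r1[:, :, :L1].reshape(r1.shape[0], r1.shape[1], -1, 2)
        p1 = p1v.max(axis=3)
        a2 = np.einsum("nclk,ock->nol", _sliding(p1, k), w2, optimize=True) + b2[None, :, None]
        r2 = np.maximum(a2, 0.0)
        L2 = (r2.shape[2] // 2) * 2
        p2v = r2[:, :, :L2].reshape(r2.shape[0], r2.shape[1], -1, 2)
        p2 = p2v.max(axis=3)
        flat = p2.reshape(p2.shape[0], -1)
        a3 = flat @ w3 + b3
        r3 = np.maximum(a3, 0.0)
        out = (r3 @ w4 + b4).ravel()
        if cache is not None:
            cache.update(x=x, a1=a1, r1=r1, p1v=p1v, p1=p1, a2=a2, r2=r2,
                         p2v=p2v, p2=p2, flat=flat, a3=a3, r3=r3)
        return out

    def _backward(self, dout, params, cache):
        w1, b1, w2, b2, w3, b3, w4, b4 = params
        k = self.kernel
        n = len(dout)
        dout = dout.reshape(-1, 1)
        dw4 = cache["r3"].T @ dout
        db4 = dout.sum(axis=0)
        dr3 = dout @ w4.T
        da3 = dr3 * (cache["a3"] > 0)
        dw3 = cache["flat"].T @ da3
        db3 = da3.sum(axis=0)
        dflat = da3 @ w3.T
        dp2 = dflat.reshape(cache["p2"].shape)
        # unpool 2: route gradient to the max element of each pair
        dp2v = np.zeros_like(cache["p2v"])
        arg2 = cache["p2v"].argmax(axis=3)
        np.put_along_axis(dp2v, arg2[..., None], dp2[..., None], axis=3)
        dr2 = np.zeros_like(cache["r2"])
        L2 = dp2v.shape[2] * 2
        dr2[:, :, :L2] = dp2v.reshape(dr2.shape[0], dr2.shape[1], L2)
        da2 = dr2 * (cache["a2"] > 0)
        dw2 = np.einsum("nclk,nol->ock", _sliding(cache["p1"], k), da2, optimize=True)
        db2 = da2.sum(axis=(0, 2))
        pad = np.pad(da2, ((0, 0), (0, 0), (k - 1, k - 1)))
        dp1 = np.einsum("nolk,ock->ncl", _sliding(pad, k), w2[:, :, ::-1], optimize=True)
        dp1v = np.zeros_like(cache["p1v"])
        arg1 = cache["p1v"].argmax(axis=3)
        np.put_along_axis(dp1v, arg1[..., None], dp1[..., None], axis=3)
        dr1 = np.zeros_like(cache["r1"])
        L1 = dp1v.shape[2] * 2
        dr1[:, :, :L1] = dp1v.reshape(dr1.shape[0], dr1.shape[1], L1)
        da1 = dr1 * (cache["a1"] > 0)
        dw1 = np.einsum("nclk,nol->ock", _sliding(cache["x"], k), da1, optimize=True)
        db1 = da1.sum(axis=(0, 2))
        grads = [dw1, db1, dw2, db2, dw3, db3, dw4, db4]
        return [g / n for g in grads]

    # -- training -----------------------------------------------------------
    #: shortest input the two conv/pool blocks can digest; narrower inputs
    #: are zero-padded on the right
    MIN_INPUT_LEN = 20

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        rng = np.random.default_rng(self.random_state)
        self.y_mean_ = float(y.mean())
        self.y_sd_ = float(y.std()) or 1.0
        yt = (y - self.y_mean_) / self.y_sd_
        self.pad_ = max(0, self.MIN_INPUT_LEN - X.shape[1])
        if self.pad_:
            X = np.pad(X, ((0, 0), (0, self.pad_)))
        x = X[:, None, :]

        c1, c2 = self.channels
        k = self.kernel
        L = X.shape[1]
        L1 = (L - k + 1) // 2
        L2 = (L1 - k + 1) // 2
        flat_dim = c2 * L2

        def he(*shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        params = [
            he(c1, 1, k, fan_in=k), np.zeros(c1),
            he(c2, c1, k, fan_in=c1 * k), np.zeros(c2),
            he(flat_dim, self.hidden, fan_in=flat_dim), np.zeros(self.hidden),
            he(self.hidden, 1, fan_in=self.hidden), np.zeros(1),
        ]

        n = len(y)
        n_val = max(1, int(round(self.val_fraction * n))) if n >= 10 else 0
        order = rng.permutation(n)
        val_idx, tr_idx = order[:n_val], order[n_val:]
        xv, yv = x[val_idx], yt[val_idx]
        xt, ytr = x[tr_idx], yt[tr_idx]

        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        best_loss, best_params, since_best, t = np.inf, [p.copy() for p in params], 0, 0
        for epoch in range(self.max_epochs):
            perm = rng.permutation(len(ytr))
            for start in range(0, len(ytr), self.batch_size):
                idx = perm[start:start + self.batch_size]
                cache: dict = {}
                pred = self._forward(xt[idx], params, cache)
                grads = self._backward(2.0 * (pred - ytr[idx]), params, cache)
                t += 1
                for i, g in enumerate(grads):
                    m[i] = beta1 * m[i] + (1 - beta1) * g
                    v[i] = beta2 * v[i] + (1 - beta2) * g * g
                    mh = m[i] / (1 - beta1**t)
                    vh = v[i] / (1 - beta2**t)
                    params[i] -= self.lr * mh / (np.sqrt(vh) + eps)
            monitor_x, monitor_y = (xv, yv) if n_val else (xt, ytr)
            loss = float(np.mean((self._forward(monitor_x, params) - monitor_y) ** 2))
            if loss < best_loss - 1e-6:
                best_loss = loss
                best_params = [p.copy() for p in params]
                since_best = 0
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
        self.params_ = best_params
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=np.float64)
        if self.pad_:
            X = np.pad(X, ((0, 0), (0, self.pad_)))
        return self._forward(X[:, None, :], self.params_) * self.y_sd_ + self.y_mean_


# ---------------------------------------------------------------------------
# Step 1 / step 2 fitting
# ---------------------------------------------------------------------------

def _check_finite(X: np.ndarray) -> None:
    bad = np.flatnonzero(np.isinf(X).any(axis=0))
    if len(bad):
        raise ValueError(f"non-finite feature values in columns {bad.tolist()}")


def _base_models(seed: int) -> Dict[str, Pipeline]:
    """The four step-1 regressors: missing values are median-imputed and
    features standardized inside each pipeline (training-fold statistics
    only); the forest needs neither but gets the imputer."""
    ss = np.random.SeedSequence(seed).generate_state(4)
    pre = lambda: [("impute", SimpleImputer(strategy="median")),
                   ("scale", StandardScaler())]
    return {
        "linear": Pipeline(pre() + [("model", LinearRegression())]),
        "random_forest": Pipeline(
            [("impute", SimpleImputer(strategy="median")),
             ("model", RandomForestRegressor(
                 n_estimators=RF_TREES, random_state=int(ss[1] % 2**31), n_jobs=1))]),
        # targets standardized so the network trains on unit scale
        "ann": Pipeline(pre() + [("model", TransformedTargetRegressor(
            regressor=MLPRegressor(
                hidden_layer_sizes=(64, 32), max_iter=500, early_stopping=True,
                validation_fraction=0.1, n_iter_no_change=30,
                random_state=int(ss[2] % 2**31)),
            transformer=StandardScaler()))]),
        "cnn": Pipeline(pre() + [("model", CNNRegressor(
            random_state=int(ss[3] % 2**31)))]),
    }


def fit_step1(X: np.ndarray, y: np.ndarray, seed: int = 0) -> Dict[str, Pipeline]:
    """Fit the four base regressors on one training split."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < 20:
        raise ValueError("need at least 20 training samples")
    _check_finite(X)
    models = _base_models(seed)
    for model in models.values():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # MLP convergence chatter
            model.fit(X, y)
    return models


def fit_step2(oof_predictions: np.ndarray, y: np.ndarray, seed: int = 0
              ) -> RandomForestRegressor:
    """Fit the random-forest combiner on step-1 out-of-fold predictions."""
    oof_predictions = np.asarray(oof_predictions, dtype=float)
    y = np.asarray(y, dtype=float)
    if oof_predictions.ndim != 2 or oof_predictions.shape[1] != len(MODEL_NAMES):
        raise ValueError(
            f"expected {len(MODEL_NAMES)} prediction columns, got shape "
            f"{oof_predictions.shape}"
        )
    if oof_predictions.shape[0] != len(y):
        raise ValueError("prediction rows misaligned with targets")
    # a 4-input meta-learner overfits at unlimited depth; coarse leaves keep
    # it close to a smoothed weighting of the base models
    rf = RandomForestRegressor(n_estimators=RF_TREES, min_samples_leaf=10,
                               random_state=int(seed % 2**31), n_jobs=1)
    rf.fit(oof_predictions, y)
    return rf


def evaluate(y_true: np.ndarray, y_pred: np.ndarray) -> Tuple[float, float]:
    """(RMSE in mm, Pearson r); r is NaN with a warning for constant
    predictions."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    rmse = float(np.sqrt(np.mean((y_pred - y_true) ** 2)))
    if np.ptp(y_pred) == 0:
        warnings.warn("constant predictions: correlation undefined")
        return rmse, float("nan")
    r = float(np.corrcoef(y_true, y_pred)[0, 1])
    return rmse, r


# ---------------------------------------------------------------------------
# Full stacked cross-validation
# ---------------------------------------------------------------------------

@dataclass
class EstimationResult:
    """Per-sample out-of-fold predictions and metrics for the four base
    models and the stacked combiner."""

    fold_plan: FoldPlan
    predictions: Dict[str, np.ndarray]          # model -> pooled OOF preds
    y: np.ndarray
    per_fold: pd.DataFrame = field(default_factory=pd.DataFrame)

    def overall(self, model: str = "stacked") -> Tuple[float, float]:
        return evaluate(self.y, self.predictions[model])

    def metrics_table(self) -> pd.DataFrame:
        """Model x (fold-wise RMSE mean+-SD, overall RMSE, fold-wise r
        mean+-SD, overall r) summary."""
        rows = []
        for model in [*MODEL_NAMES, "stacked"]:
            sub = self.per_fold[self.per_fold["model"] == model]
            rmse, r = self.overall(model)
            rows.append({
                "model": model,
                "foldwise_rmse_mean": sub["rmse"].mean(),
                "foldwise_rmse_sd": sub["rmse"].std(ddof=1),
                "overall_rmse": rmse,
                "foldwise_r_mean": sub["r"].mean(),
                "foldwise_r_sd": sub["r"].std(ddof=1),
                "overall_r": r,
            })
        return pd.DataFrame(rows)


def stacked_cv(
    X: np.ndarray,
    y: np.ndarray,
    fold_plan: Optional[FoldPlan] = None,
    seed: int = 0,
    mode: str = "by_observation",
    groups: Optional[Sequence] = None,
    inner_folds: int = 5,
) -> EstimationResult:
    """Six-fold cross-validated two-step stacked estimation.

    Step 1: per outer fold, the four base models are fitted on the training
    folds and predict the held-out fold, giving pooled out-of-fold base
    predictions for every sample.  Step 2: for each fold, the combiner is
    trained on the out-of-fold predictions of all *other* folds and applied
    to that fold's predictions, so neither step ever sees its evaluation
    fold's targets.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_finite(X)
    ss = np.random.SeedSequence(seed)
    fold_seed, model_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    if fold_plan is None:
        fold_plan = make_folds(len(y), mode=mode, seed=fold_seed, groups=groups)

    preds = {m: np.full(len(y), np.nan) for m in [*MODEL_NAMES, "stacked"]}
    fold_rows = []
    oof = np.full((len(y), len(MODEL_NAMES)), np.nan)
    for k, (train, test) in enumerate(fold_plan.split()):
        models = fit_step1(X[train], y[train], seed=model_seed + 7 * k)
        for j, name in enumerate(MODEL_NAMES):
            oof[test, j] = models[name].predict(X[test])
            preds[name][test] = oof[test, j]
            rmse, r = evaluate(y[test], oof[test, j])
            fold_rows.append({"model": name, "fold": k + 1, "rmse": rmse, "r": r})

    for k, (train, test) in enumerate(fold_plan.split()):
        combiner = fit_step2(oof[train], y[train], seed=model_seed + 13 * k)
        preds["stacked"][test] = combiner.predict(oof[test])
        rmse, r = evaluate(y[test], preds["stacked"][test])
        fold_rows.append({"model": "stacked", "fold": k + 1, "rmse": rmse, "r": r})

    return EstimationResult(fold_plan=fold_plan, predictions=preds, y=y,
                            per_fold=pd.DataFrame(fold_rows))
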