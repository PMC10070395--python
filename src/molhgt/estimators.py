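"""Scikit-learn style estimators wrapping the heterogeneous graph transformer.

``HGTRegressor`` and ``HGTClassifier`` take a sequence of SMILES strings as
``X`` and a label vector/matrix as ``y`` (NaN marks missing labels in the
multi-task case). They follow the sklearn contract — ``get_params`` /
``set_params``, fitted attributes with trailing underscores — so they
compose with pipelines and model selection utilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin

from . import model as M
from .autodiff import Tensor, concat
from .chemgraph import build_hetero_graph
from .metrics import UndefinedMetricError, masked_loss, rmse, roc_auc
from .nn import Adam, iter_params

__all__ = ["HGTRegressor", "HGTClassifier"]


def _macro_auc(labels: np.ndarray, mask: np.ndarray, scores: np.ndarray) -> float:
    """Macro-average ROC-AUC over tasks where both classes are observed."""
    values = []
    for j in range(labels.shape[1]):
        obs = mask[:, j]
        if not obs.any():
            continue
        try:
            values.append(roc_auc(labels[obs, j], scores[obs, j]))
        except UndefinedMetricError:
            continue
    if not values:
        raise UndefinedMetricError("no task had both classes observed")
    return float(np.mean(values))


class _HGTBase(BaseEstimator):
    _task_type = ""

    def __init__(self, hidden_dim=300, num_heads=4, depth=3, dropout=0.1,
                 sigma="softmax", value_source="node", variant="full",
                 junction_membership="all", learning_rate=1e-3, lr_schedule="constant",
                 batch_size=32, max_epochs=100, patience=20, tol=0.0,
                 clip_norm=5.0, random_state=0, verbose=0):
        self.hidden_dim = hidden_dim
        self.num_heads = num_heads
        self.depth = depth
        self.dropout = dropout
        self.sigma = sigma
        self.value_source = value_source
        self.variant = variant
        self.junction_membership = junction_membership
        self.learning_rate = learning_rate
        self.lr_schedule = lr_schedule
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.tol = tol
        self.clip_norm = clip_norm
        self.random_state = random_state
        self.verbose = verbose

    # -- helpers -------------------------------------------------------------
    def _make_config(self) -> M.ModelConfig:
        views = tuple(
            v for v in ("alpha", "beta", "gamma") if v in M.VARIANT_VIEWS[self.variant]
        )
        return M.ModelConfig(
            hidden_dim=self.hidden_dim,
            num_heads=self.num_heads,
            depth=self.depth,
            dropout=self.dropout,
            sigma=self.sigma,
            value_source=self.value_source,
            views_enabled=views,
            fusion_variant=self.variant,
            junction_membership=self.junction_membership,
            seed=self.random_state,
        )

    def _compile(self, X) -> list[M.CompiledGraph]:
        cache: dict[str, M.CompiledGraph] = getattr(self, "_graph_cache", {})
        graphs = []
        for smi in X:
            if smi not in cache:
                cache[smi] = M.compile_graph(
                    build_hetero_graph(smi, membership=self.junction_membership)
                )
            graphs.append(cache[smi])
        self._graph_cache = cache
        return graphs

    @staticmethod
    def _as_2d(y) -> tuple[np.ndarray, np.ndarray]:
        y = np.asarray(y, dtype=np.float64)
        if y.ndim == 1:
            y = y[:, None]
        mask = ~np.isnan(y)
        return np.where(mask, y, 0.0), mask

    def _batch_scores(self, graphs, training: bool, rng=None) -> Tensor:
        rows = [
            M.forward(g, self.params_, self.config_, training=training, rng=rng)[0]
            for g in graphs
        ]
        return concat(rows, axis=0)

    def _encode(self, y: np.ndarray, mask: np.ndarray) -> np.ndarray:
        return y

    def _validation_score(self, graphs, labels, mask) -> float:
        """Higher is better (regression returns negative RMSE)."""
        scores = self._batch_scores(graphs, training=False).data
        if self._task_type == "classification":
            return _macro_auc(labels, mask, scores)
        scores = self._decode(scores)
        return -rmse(scores[mask], labels[mask])

    def _decode(self, scores: np.ndarray) -> np.ndarray:
        return scores

    # -- sklearn API -----------------------------------------------------------
    def fit(self, X, y, X_valid=None, y_valid=None):
        """Train with Adam on mini-batches of the masked multi-task loss.

        If a validation set is given, training early-stops on the validation
        metric (macro ROC-AUC / negative RMSE) with the configured patience
        and the best parameters are restored.
        """
        X = list(X)
        labels, mask = self._as_2d(y)
        if len(X) != len(labels):
            raise ValueError("X and y length mismatch")
        self.n_tasks_ = labels.shape[1]
        self.config_ = self._make_config()
        self._fit_scaling(labels, mask)
        target = self._encode(labels, mask)

        graphs = self._compile(X)
        self.params_ = M.init_params(self.config_, self.n_tasks_)
        optimizer = Adam(self.params_, lr=self.learning_rate, clip_norm=self.clip_norm)
        rng = np.random.default_rng(self.random_state + 1)

        has_valid = X_valid is not None and len(X_valid) > 0
        if has_valid:
            v_labels, v_mask = self._as_2d(y_valid)
            v_graphs = self._compile(list(X_valid))

        n = len(X)
        best_score, best_state, patience_left = -np.inf, None, self.patience
        self.loss_history_, self.valid_history_ = [], []
        self.best_epoch_ = 0
        for epoch in range(self.max_epochs):
            if self.lr_schedule == "cosine":  # decay to 0 over max_epochs
                optimizer.lr = self.learning_rate * 0.5 * (
                    1.0 + np.cos(np.pi * epoch / max(1, self.max_epochs))
                )
            elif self.lr_schedule == "tail":  # hold, then decay over the last quarter
                hold = int(0.75 * self.max_epochs)
                if epoch >= hold:
                    frac = (epoch - hold) / max(1, self.max_epochs - hold)
                    optimizer.lr = self.learning_rate * (1.0 - 0.95 * frac)
                else:
                    optimizer.lr = self.learning_rate
            elif self.lr_schedule == "warm_tail":  # warmup, hold, long decay
                warm = max(1, int(0.1 * self.max_epochs))
                hold = int(0.6 * self.max_epochs)
                if epoch < warm:
                    optimizer.lr = self.learning_rate * (0.1 + 0.9 * epoch / warm)
                elif epoch < hold:
                    optimizer.lr = self.learning_rate
                else:
                    frac = (epoch - hold) / max(1, self.max_epochs - hold)
                    optimizer.lr = self.learning_rate * (1.0 - 0.98 * frac)
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                scores = self._batch_scores([graphs[i] for i in idx], training=True, rng=rng)
                loss = masked_loss(scores, target[idx], mask[idx], self._task_type)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(f"non-finite loss at epoch {epoch}")
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
                epoch_loss += float(loss.data) * len(idx)
            self.loss_history_.append(epoch_loss / n)
            if self.verbose:
                print(f"epoch {epoch}: train loss {self.loss_history_[-1]:.5f}")
            if not has_valid and self.loss_history_[-1] <= min(self.loss_history_):
                # keep the best-train-loss parameters (training can destabilize late)
                best_state = {path: p.data.copy() for path, p in iter_params(self.params_)}
                self.best_epoch_ = epoch
            if self.tol and self.loss_history_[-1] < self.tol:
                break  # training loss converged
            if has_valid:
                try:
                    score = self._validation_score(v_graphs, v_labels, v_mask)
                except UndefinedMetricError:
                    score = -np.inf
                self.valid_history_.append(score)
                if score > best_score:
                    best_score, patience_left, self.best_epoch_ = score, self.patience, epoch
                    best_state = {
                        path: p.data.copy() for path, p in iter_params(self.params_)
                    }
                else:
                    patience_left -= 1
                    if patience_left <= 0:
                        break
        if best_state is not None:
            for path, p in iter_params(self.params_):
                p.data = best_state[path]
            if has_valid:
                self.best_valid_score_ = best_score
        return self

    def _fit_scaling(self, labels, mask) -> None:
        pass

    def decision_function(self, X):
        self._check_fitted()
        graphs = self._compile(list(X))
        return self._batch_scores(graphs, training=False).data

    def embed(self, X) -> np.ndarray:
        """Molecule embeddings Z, one row per input SMILES."""
        self._check_fitted()
        out = []
        for g in self._compile(list(X)):
            _, emb = M.forward(g, self.params_, self.config_, training=False)
            out.append(emb.Z.data[0])
        return np.asarray(out)

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")

    def save(self, path) -> None:
        self._check_fitted()
        M.save_checkpoint(path, self.params_, self.config_, self.n_tasks_,
                          meta=self._checkpoint_meta())

    def _checkpoint_meta(self) -> dict:
        return {"task_type": self._task_type}

    def _load_from(self, path):
        params, config, n_tasks, meta = M.load_checkpoint(path)
        self.params_, self.config_, self.n_tasks_ = params, config, n_tasks
        return meta


class HGTRegressor(_HGTBase, RegressorMixin):
    """Molecular property regression (RMSE-style tasks).

    Targets are standardized per task during training and mapped back at
    prediction time, so reported errors are on the original label scale.
    """

    _task_type = "regression"

    def _fit_scaling(self, labels, mask) -> None:
        means, scales = [], []
        for j in range(labels.shape[1]):
            obs = labels[mask[:, j], j]
            means.append(obs.mean() if obs.size else 0.0)
            scales.append(max(obs.std(), 1e-8) if obs.size else 1.0)
        self.y_mean_ = np.asarray(means)
        self.y_scale_ = np.asarray(scales)

    def _encode(self, y, mask):
        return np.where(mask, (y - self.y_mean_) / self.y_scale_, 0.0)

    def _decode(self, scores):
        return scores * self.y_scale_ + self.y_mean_

    def predict(self, X) -> np.ndarray:
        raw = self.decision_function(X)
        out = self._decode(raw)
        return out[:, 0] if self.n_tasks_ == 1 else out

    def save(self, path) -> None:
        self._check_fitted()
        M.save_checkpoint(
            path, self.params_, self.config_, self.n_tasks_,
            meta={"task_type": self._task_type,
                  "y_mean": self.y_mean_.tolist(), "y_scale": self.y_scale_.tolist()},
        )

    @classmethod
    def load(cls, path) -> "HGTRegressor":
        est = cls()
        meta = est._load_from(path)
        est.y_mean_ = np.asarray(meta["y_mean"])
        est.y_scale_ = np.asarray(meta["y_scale"])
        return est


class HGTClassifier(_HGTBase, ClassifierMixin):
    """Binary (possibly multi-task) molecular property classification.

    The head emits raw scores; ``predict_proba`` applies the logistic
    sigmoid, ``predict`` thresholds at 0.5. Missing labels (NaN in ``y``)
    are masked out of the loss.
    """

    _task_type = "classification"

    def fit(self, X, y, X_valid=None, y_valid=None):
        labels, mask = self._as_2d(y)
        observed = labels[mask]
        if not np.isin(observed, (0.0, 1.0)).all():
            raise ValueError("classification labels must be 0/1 (NaN for missing)")
        self.classes_ = np.array([0, 1])
        return super().fit(X, y, X_valid=X_valid, y_valid=y_valid)

    def predict_proba(self, X) -> np.ndarray:
        """Positive-class probability per task; for a single task the usual
        sklearn two-column layout is returned."""
        scores = self.decision_function(X)
        proba = 1.0 / (1.0 + np.exp(-scores))
        if self.n_tasks_ == 1:
            return np.column_stack([1.0 - proba[:, 0], proba[:, 0]])
        return proba

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        pred = (scores >= 0.0).astype(int)
        return pred[:, 0] if self.n_tasks_ == 1 else pred

    @classmethod
    def load(cls, path) -> "HGTClassifier":
        est = cls()
        est._load_from(path)
        est.classes_ = np.array([0, 1])
        return est
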