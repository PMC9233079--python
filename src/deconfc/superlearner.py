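"""Cross-validated super learner (stacked ensemble) estimators.

The super learner fits a library of candidate learners, obtains
out-of-fold predictions for each via V-fold cross-validation, and
chooses convex combination weights minimizing the cross-validated risk
— squared error for continuous targets, negative Bernoulli
log-likelihood for binary targets.  The weight problem is solved over
the probability simplex, so the ensemble's cross-validated risk can
never exceed that of any single library member (up to solver
tolerance).  Learners are refit on the full data for prediction.

`SuperLearnerRegressor` and `SuperLearnerClassifier` follow the
scikit-learn estimator protocol (``fit``/``predict``,
``get_params``/``set_params``, trailing-underscore fitted attributes)
and accept any library of scikit-learn compatible estimators;
:func:`default_library` builds the standard library used by the
pipeline: intercept-only, GLM, lasso, additive splines, a
piecewise-linear spline+lasso learner in the MARS family, forward
stepwise (with and without pairwise interactions), random forest and
gradient boosting — plus ridge and support-vector regression for
continuous outcomes.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.dummy import DummyClassifier, DummyRegressor
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import (
    LassoCV,
    LinearRegression,
    LogisticRegression,
    LogisticRegressionCV,
    RidgeCV,
)
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler
from sklearn.svm import SVR

__all__ = [
    "make_folds",
    "default_library",
    "SuperLearnerRegressor",
    "SuperLearnerClassifier",
    "StepwiseGLM",
]

PROB_CLIP = 1e-3          # binomial ensemble predictions clipped to [eps, 1-eps]
_SOLVER_TOL = 1e-10


def make_folds(
    n: int, v: int, seed: int = 0, stratify_on: np.ndarray | None = None
) -> np.ndarray:
    """Assign ``n`` indices to ``v`` cross-validation folds.

    Folds have near-equal size; with ``stratify_on`` (binary labels)
    the per-fold label counts differ by at most one.
    """
    if not 2 <= v <= n:
        raise ValueError(f"need 2 <= v <= n, got v={v}, n={n}")
    idx = np.arange(n)
    if stratify_on is not None:
        splitter = StratifiedKFold(n_splits=v, shuffle=True, random_state=seed)
        splits = splitter.split(idx[:, None], np.asarray(stratify_on))
    else:
        splitter = KFold(n_splits=v, shuffle=True, random_state=seed)
        splits = splitter.split(idx[:, None])
    folds = np.empty(n, dtype=int)
    for f, (_, test) in enumerate(splits):
        folds[test] = f
    return folds


class StepwiseGLM(BaseEstimator):
    """Greedy forward-stepwise GLM selected by BIC.

    Starts from the intercept-only model and adds, one at a time, the
    column (optionally including pairwise interaction columns) that
    most reduces BIC, stopping when no addition improves it.
    """

    def __init__(self, task: str = "gaussian", interactions: bool = False,
                 max_terms: int | None = None):
        self.task = task
        self.interactions = interactions
        self.max_terms = max_terms

    def _candidates(self, X: np.ndarray) -> np.ndarray:
        if not self.interactions:
            return X
        n, p = X.shape
        cols = [X]
        for i in range(p):
            for j in range(i + 1, p):
                cols.append((X[:, i] * X[:, j])[:, None])
        return np.hstack(cols)

    def _bic(self, Z: np.ndarray, y: np.ndarray) -> tuple[float, object]:
        n = len(y)
        k = Z.shape[1] + 1
        if self.task == "gaussian":
            model = LinearRegression()
            model.fit(Z, y)
            rss = float(np.sum((y - model.predict(Z)) ** 2))
            rss = max(rss, 1e-12)
            return n * np.log(rss / n) + k * np.log(n), model
        model = LogisticRegression(C=np.inf, max_iter=500)
        model.fit(Z, y)
        p = np.clip(model.predict_proba(Z)[:, 1], 1e-12, 1 - 1e-12)
        ll = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
        return -2 * ll + k * np.log(n), model

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        C = self._candidates(X)
        n, p = C.shape
        self._n_input_cols_ = X.shape[1]
        selected: list[int] = []
        # intercept-only baseline
        if self.task == "gaussian":
            best_bic = n * np.log(max(np.var(y) * n, 1e-12) / n) + np.log(n)
        else:
            pbar = np.clip(y.mean(), 1e-12, 1 - 1e-12)
            ll0 = n * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar))
            best_bic = -2 * ll0 + np.log(n)
        best_model = None
        max_terms = self.max_terms or min(p, max(2, n // 10))
        while len(selected) < max_terms:
            gains = []
            for j in range(p):
                if j in selected:
                    continue
                try:
                    bic, model = self._bic(C[:, selected + [j]], y)
                except Exception:
                    continue
                gains.append((bic, j, model))
            if not gains:
                break
            bic, j, model = min(gains, key=lambda t: t[0])
            if bic >= best_bic - 1e-9:
                break
            best_bic, best_model = bic, model
            selected.append(j)
        self.selected_ = selected
        self.model_ = best_model
        if self.task == "gaussian":
            self.intercept_only_ = float(np.mean(y)) if best_model is None else None
        else:
            self.intercept_only_ = float(np.mean(y)) if best_model is None else None
        return self

    def _transform(self, X) -> np.ndarray:
        C = self._candidates(np.asarray(X, dtype=float))
        return C[:, self.selected_]

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if self.model_ is None:
            return np.full(X.shape[0], self.intercept_only_)
        Z = self._transform(X)
        if self.task == "gaussian":
            return self.model_.predict(Z)
        return self.model_.predict_proba(Z)[:, 1]

    def predict_proba(self, X):
        p = self.predict(X)
        return np.column_stack([1 - p, p])


def default_library(task: str, fast: bool = False) -> list[tuple[str, BaseEstimator]]:
    """The standard learner library.

    ``task`` is ``'gaussian'`` or ``'binomial'``.  ``fast=True`` keeps
    only the cheap parametric members (mean, GLM, lasso, additive
    splines) for simulation studies.
    """
    if task not in ("gaussian", "binomial"):
        raise ValueError(f"task must be 'gaussian' or 'binomial', got {task!r}")
    gauss = task == "gaussian"
    spline = SplineTransformer(n_knots=5, degree=3, knots="uniform")
    spline_lin = SplineTransformer(n_knots=5, degree=1, knots="uniform")
    if gauss:
        lib = [
            ("mean", DummyRegressor(strategy="mean")),
            ("glm", LinearRegression()),
            ("lasso", make_pipeline(StandardScaler(), LassoCV(cv=5))),
            ("gam", make_pipeline(clone(spline), RidgeCV())),
        ]
        if not fast:
            lib += [
                ("mars", make_pipeline(clone(spline_lin), LassoCV(cv=5))),
                ("step", StepwiseGLM(task="gaussian")),
                ("step_interactions", StepwiseGLM(task="gaussian", interactions=True)),
                ("ridge", make_pipeline(StandardScaler(), RidgeCV())),
                ("rf", RandomForestRegressor(n_estimators=200)),
                ("xgboost", _xgb("gaussian")),
                ("svm", make_pipeline(StandardScaler(), SVR())),
            ]
        return lib
    logit = lambda **kw: LogisticRegression(max_iter=1000, **kw)
    l1cv = lambda: LogisticRegressionCV(
        l1_ratios=(1.0,), solver="liblinear", cv=5,
        scoring="neg_log_loss", use_legacy_attributes=False,
    )
    lib = [
        ("mean", DummyClassifier(strategy="prior")),
        ("glm", logit(C=np.inf)),
        ("lasso", make_pipeline(StandardScaler(), l1cv())),
        ("gam", make_pipeline(clone(spline), logit(C=1.0))),
    ]
    if not fast:
        lib += [
            ("mars", make_pipeline(clone(spline_lin), l1cv())),
            ("step", StepwiseGLM(task="binomial")),
            ("step_interactions", StepwiseGLM(task="binomial", interactions=True)),
            ("rf", RandomForestClassifier(n_estimators=200)),
            ("xgboost", _xgb("binomial")),
        ]
    return lib


def _xgb(task: str):
    from xgboost import XGBClassifier, XGBRegressor

    kw = dict(n_estimators=100, max_depth=3, learning_rate=0.1, verbosity=0,
              n_jobs=1, tree_method="hist")
    return XGBRegressor(**kw) if task == "gaussian" else XGBClassifier(**kw)


def _solve_simplex_weights(Z: np.ndarray, y: np.ndarray, loss: str) -> np.ndarray:
    """Convex weights minimizing CV risk over the probability simplex."""
    n, L = Z.shape
    if L == 1:
        return np.array([1.0])

    if loss == "gaussian":
        def objective(w):
            r = Z @ w - y
            return float(r @ r) / n, 2.0 * (Z.T @ r) / n
    else:
        def objective(w):
            p = np.clip(Z @ w, 1e-12, 1 - 1e-12)
            nll = -float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))) / n
            grad = -(Z.T @ (y / p - (1 - y) / (1 - p))) / n
            return nll, grad

    w0 = np.full(L, 1.0 / L)
    res = minimize(
        objective, w0, jac=True, method="SLSQP",
        bounds=[(0.0, 1.0)] * L,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                      "jac": lambda w: np.ones_like(w)}],
        options={"maxiter": 500, "ftol": _SOLVER_TOL},
    )
    w = np.clip(res.x, 0.0, None)
    s = w.sum()
    w = np.full(L, 1.0 / L) if s <= 0 else w / s
    # polish: compare with vertices, keep the best (guards solver stalls)
    risks = [objective(np.eye(L)[j])[0] for j in range(L)]
    if objective(w)[0] > min(risks) + 1e-12:
        w = np.eye(L)[int(np.argmin(risks))]
    return w


class _BaseSuperLearner(BaseEstimator):
    _task = "gaussian"

    def __init__(self, library=None, v: int = 10, seed: int = 0,
                 stratify: bool = False, fast: bool = False):
        self.library = library
        self.v = v
        self.seed = seed
        self.stratify = stratify
        self.fast = fast

    # -- helpers -----------------------------------------------------
    def _resolve_library(self):
        lib = self.library
        if lib is None:
            lib = default_library(self._task, fast=self.fast)
        if not lib:
            raise ValueError("library must be nonempty")
        names = [name for name, _ in lib]
        if len(set(names)) != len(names):
            raise ValueError("learner names must be unique")
        return lib

    def _seeded_clone(self, est, offset: int):
        est = clone(est)
        params = est.get_params()
        rs = {k: int(self.seed * 1000 + offset) % (2**31 - 1)
              for k in params if k == "random_state" or k.endswith("__random_state")}
        if rs:
            est.set_params(**rs)
        return est

    def _learner_predict(self, est, X: np.ndarray) -> np.ndarray:
        if self._task == "binomial" and hasattr(est, "predict_proba"):
            p = est.predict_proba(X)
            return p[:, 1] if p.ndim == 2 else np.asarray(p)
        return np.asarray(est.predict(X), dtype=float)

    @staticmethod
    def _check_X_y(X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(X) != len(y):
            raise ValueError("X and y have different lengths")
        if not np.isfinite(X).all() or not np.isfinite(y).all():
            raise ValueError("X and y must not contain missing/non-finite values")
        return X, y

    # -- protocol ----------------------------------------------------
    def fit(self, X, y):
        X, y = self._check_X_y(X, y)
        lib = self._resolve_library()
        n = len(y)
        v = min(self.v, n)
        strat = y if (self._task == "binomial" and self.stratify) else None
        self.folds_ = make_folds(n, v, seed=self.seed, stratify_on=strat)

        cv_pred = np.full((n, len(lib)), np.nan)
        ok = np.ones(len(lib), dtype=bool)
        for f in range(v):
            test = self.folds_ == f
            train = ~test
            for j, (name, est) in enumerate(lib):
                if not ok[j]:
                    continue
                try:
                    m = self._seeded_clone(est, offset=j * 97 + f)
                    m.fit(X[train], y[train])
                    cv_pred[test, j] = self._learner_predict(m, X[test])
                except Exception as exc:  # learner dropped, weights renormalized
                    warnings.warn(f"learner {name!r} failed in CV and was dropped: {exc}")
                    ok[j] = False
        if not ok.any():
            raise RuntimeError("all learners failed during cross-validation")
        lib = [lib[j] for j in np.flatnonzero(ok)]
        cv_pred = cv_pred[:, ok]
        if self._task == "binomial":
            cv_pred = np.clip(cv_pred, PROB_CLIP, 1 - PROB_CLIP)

        if self._task == "gaussian":
            self.cv_risk_ = np.mean((cv_pred - y[:, None]) ** 2, axis=0)
        else:
            self.cv_risk_ = -np.mean(
                y[:, None] * np.log(cv_pred) + (1 - y[:, None]) * np.log(1 - cv_pred),
                axis=0,
            )
        self.weights_ = _solve_simplex_weights(cv_pred, y, self._task)
        self.learner_names_ = [name for name, _ in lib]
        self.cv_predictions_ = cv_pred

        self.learners_ = []
        kept = []
        for j, (name, est) in enumerate(lib):
            try:
                m = self._seeded_clone(est, offset=j * 97 + 1009)
                m.fit(X, y)
                self.learners_.append(m)
                kept.append(j)
            except Exception as exc:
                warnings.warn(f"learner {name!r} failed on refit and was dropped: {exc}")
        if not self.learners_:
            raise RuntimeError("all learners failed on the full data")
        kept = np.asarray(kept, dtype=int)
        w = self.weights_[kept]
        self.weights_ = w / w.sum() if w.sum() > 0 else np.full(len(w), 1 / len(w))
        self.learner_names_ = [lib[j][0] for j in kept]
        self.cv_risk_ = self.cv_risk_[kept]
        self.n_features_in_ = X.shape[1]
        return self

    def _combine(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1] if X.ndim == 2 else 'wrong'} features, "
                f"expected {self.n_features_in_}"
            )
        if X.shape[0] == 0:
            return np.empty(0)
        preds = np.column_stack([self._learner_predict(m, X) for m in self.learners_])
        if self._task == "binomial":
            preds = np.clip(preds, PROB_CLIP, 1 - PROB_CLIP)
        return preds @ self.weights_

    def summary(self) -> dict:
        """Weights and CV risks, exportable as JSON."""
        return {
            "task": self._task,
            "learners": self.learner_names_,
            "weights": np.asarray(self.weights_).tolist(),
            "cv_risk": np.asarray(self.cv_risk_).tolist(),
        }


class SuperLearnerRegressor(_BaseSuperLearner, RegressorMixin):
    """Super learner for continuous targets (squared-error risk)."""

    _task = "gaussian"

    def predict(self, X):
        return self._combine(X)


class SuperLearnerClassifier(_BaseSuperLearner):
    """Super learner for binary targets (negative log-likelihood risk).

    ``predict_proba`` returns the clipped ensemble probability of the
    positive class (two-column array, sklearn layout).
    """

    _task = "binomial"

    def fit(self, X, y):
        y = np.asarray(y).ravel()
        classes = np.unique(y)
        if classes.size != 2 or not set(classes.tolist()) <= {0, 1, 0.0, 1.0}:
            raise ValueError("y must contain both classes, coded 0/1")
        self.classes_ = np.array([0, 1])
        return super().fit(X, y)

    def predict_proba(self, X):
        p = np.clip(self._combine(X), PROB_CLIP, 1 - PROB_CLIP)
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self._combine(X) >= 0.5).astype(int)
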