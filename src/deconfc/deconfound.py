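"""Doubly robust estimation of the deconfounded group difference.

The target parameter is, per edge,

    psi = E{ E(Y | A=1, Delta=1, W) | A=1 } - E{ E(Y | A=0, Delta=1, W) | A=0 },

the ASD-TD difference of outcome-regression means integrated over each
diagnosis group's *full* covariate distribution — usable and unusable
participants alike — rather than over the usable cases only (the naive
comparison).  Under mean exchangeability, positivity and consistency
this equals the group difference in the hypothetical world where every
child passes motion QC.

Estimation proceeds in three steps: (1) a super-learner propensity
model g(A, W) = P(Delta=1 | A, W) fit on all rows; (2) a super-learner
outcome model Q(A, W) = E(Y | Delta=1, A, W) fit on usable rows and
predicted for everyone; (3) a per-group mean combining both.  Three
combiners are provided:

* ``aipw`` — augmented inverse-probability weighting, the sample mean
  of ``Delta/g (Y - Q) + Q``;
* ``tmle`` — targeted minimum loss: an intercept fluctuation of Q
  weighted by ``Delta/g`` so the efficient-influence-function equation
  is solved exactly, then the mean of the fluctuated Q;
* ``drtmle`` — doubly robust TMLE: additionally estimates the
  reduced-dimension nuisances E[Delta | Q] and E[Y - Q | Delta=1, g]
  by univariate local-linear regression and iterates extra fluctuation
  steps until the two associated correction equations are also solved,
  giving valid influence-function inference when one nuisance model is
  inconsistent.

Standard errors come from the empirical variance of the efficient
influence function; group differences are compared with independent
z-statistics, optionally averaged over repeated cross-validation seeds,
with Benjamini-Hochberg control across edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import expit, logit
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .superlearner import (
    PROB_CLIP,
    SuperLearnerClassifier,
    SuperLearnerRegressor,
)

__all__ = [
    "GroupMeanEstimate",
    "build_design",
    "fit_propensity",
    "fit_outcome",
    "aipw_group_mean",
    "tmle_group_mean",
    "drtmle_group_mean",
    "group_difference_z",
    "naive_difference_z",
    "bh_adjust",
    "DeconfoundedGroupDifference",
]


@dataclass(frozen=True)
class GroupMeanEstimate:
    """A deconfounded (or naive) group mean with influence-function SE."""

    psi: float
    se: float
    estimator: str
    group: int
    n: int


# ---------------------------------------------------------------------------
# design helpers and nuisance fits
# ---------------------------------------------------------------------------

def build_design(predictors: pd.DataFrame) -> np.ndarray:
    """Numeric design matrix: categoricals one-hot (first level dropped)."""
    X = pd.get_dummies(predictors, drop_first=True, dtype=float)
    return X.to_numpy(dtype=float)


def fit_propensity(
    X: np.ndarray,
    delta: np.ndarray,
    library=None,
    v: int = 10,
    seed: int = 0,
    fast: bool = True,
):
    """Super-learner propensity fit; returns (g, diagnostics, model).

    ``g`` are in-sample propensities clipped to ``[eps, 1-eps]``;
    diagnostics report the propensity range (positivity check) and the
    cross-validated AUC of the ensemble.
    """
    delta = np.asarray(delta).ravel().astype(int)
    if len(np.unique(delta)) < 2:
        raise ValueError("delta has a single class; nothing to model")
    sl = SuperLearnerClassifier(library=library, v=v, seed=seed, fast=fast)
    sl.fit(X, delta)
    g = sl.predict_proba(X)[:, 1]
    cv_ens = np.clip(sl.cv_predictions_ @ sl.weights_, PROB_CLIP, 1 - PROB_CLIP)
    diagnostics = {
        "min_propensity": float(g.min()),
        "max_propensity": float(g.max()),
        "n_clipped": int(np.sum((g <= PROB_CLIP) | (g >= 1 - PROB_CLIP))),
        "cv_auc": float(roc_auc_score(delta, cv_ens)),
    }
    if diagnostics["n_clipped"]:
        warnings.warn(
            f"{diagnostics['n_clipped']} propensities at the clipping bound "
            f"({PROB_CLIP}); possible positivity violation"
        )
    return g, diagnostics, sl


def fit_outcome(
    X: np.ndarray,
    delta: np.ndarray,
    y: np.ndarray,
    library=None,
    v: int = 10,
    seed: int = 0,
    fast: bool = True,
):
    """Super-learner outcome fit on usable rows; predicts every row."""
    delta = np.asarray(delta).ravel().astype(int)
    y = np.asarray(y, dtype=float).ravel()
    use = delta == 1
    if use.sum() < 4:
        raise ValueError(f"only {int(use.sum())} usable rows; cannot fit outcome model")
    if np.isnan(y[use]).any():
        raise ValueError("usable rows contain missing outcomes")
    sl = SuperLearnerRegressor(library=library, v=min(v, int(use.sum())), seed=seed,
                               fast=fast)
    sl.fit(X[use], y[use])
    q = sl.predict(X)
    return q, sl


# ---------------------------------------------------------------------------
# group-mean combiners
# ---------------------------------------------------------------------------

def _check_group_inputs(y, delta, g, q, mask):
    y = np.asarray(y, dtype=float).ravel()
    delta = np.asarray(delta).ravel().astype(int)
    g = np.asarray(g, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    mask = np.asarray(mask, dtype=bool).ravel()
    if not mask.any():
        raise ValueError("group mask selects no rows")
    if np.any(g <= 0) or np.any(g > 1):
        raise ValueError("propensities must lie in (0, 1]")
    y, delta, g, q = (a[mask] for a in (y, delta, g, q))
    y0 = np.where(delta == 1, y, 0.0)
    if np.isnan(y0).any():
        raise ValueError("usable rows contain missing outcomes")
    return y0, delta, g, q


def aipw_group_mean(y, delta, g, q, mask, group: int = 1) -> GroupMeanEstimate:
    """Augmented IPW mean of one diagnosis group."""
    y0, delta, g, q = _check_group_inputs(y, delta, g, q, mask)
    integrand = delta / g * (y0 - q) + q
    psi = float(integrand.mean())
    se = float(integrand.std(ddof=1) / np.sqrt(len(integrand)))
    return GroupMeanEstimate(psi=psi, se=se, estimator="aipw", group=group,
                             n=len(integrand))


def tmle_group_mean(y, delta, g, q, mask, group: int = 1) -> GroupMeanEstimate:
    """TMLE mean: weighted intercept fluctuation of Q, then plug-in."""
    y0, delta, g, q = _check_group_inputs(y, delta, g, q, mask)
    w = delta / g
    if w.sum() > 0:
        eps = float(np.sum(w * (y0 - q)) / w.sum())
    else:
        eps = 0.0
    q_star = q + eps
    psi = float(q_star.mean())
    eif = w * (y0 - q_star) + q_star - psi
    se = float(eif.std(ddof=1) / np.sqrt(len(eif)))
    return GroupMeanEstimate(psi=psi, se=se, estimator="tmle", group=group, n=len(eif))


def _local_linear(x_train, y_train, x_eval, bandwidth, exclude_self=False):
    """Gaussian-kernel local-linear regression at ``x_eval`` (vectorized).

    With ``exclude_self`` the i-th evaluation ignores the i-th training
    point (requires ``x_eval is x_train``), giving leave-one-out fits.
    """
    x = np.asarray(x_train, float)
    y = np.asarray(y_train, float)
    e = np.asarray(x_eval, float)
    out = np.empty(len(e))
    ybar = y.mean()
    chunk = max(1, int(2e6 // max(len(x), 1)))
    for start in range(0, len(e), chunk):
        ec = e[start:start + chunk]
        u = (x[None, :] - ec[:, None]) / bandwidth
        w = np.exp(-0.5 * u * u)
        if exclude_self:
            for k in range(len(ec)):
                w[k, start + k] = 0.0
        sw = w.sum(axis=1)
        ok = sw > 1e-300
        xm = np.divide(w @ x, sw, out=np.zeros_like(sw), where=ok)
        ym = np.divide(w @ y, sw, out=np.zeros_like(sw), where=ok)
        sxx = w @ (x * x) - sw * xm * xm
        sxy = w @ (x * y) - sw * xm * ym
        beta = np.divide(sxy, sxx, out=np.zeros_like(sxx), where=sxx > 1e-12)
        vals = ym + beta * (ec - xm)
        vals[~ok] = ybar
        out[start:start + chunk] = vals
    return out


_CV_BANDWIDTH_FACTORS = (0.1, 0.2, 0.5, 1.0, 2.0)
_CV_MAX_POINTS = 400


def _smooth(x_train, y_train, x_eval) -> np.ndarray:
    """Univariate nonparametric regression, LOO-CV bandwidth.

    Bandwidth is chosen by leave-one-out squared error over a small
    multiplicative grid around the n^(-1/5) reference rate (a random
    subsample of at most 400 points keeps selection O(1) in n).  Falls
    back to the global mean when the regressor is (nearly) constant,
    which also makes the no-missingness case exact.
    """
    x_train = np.asarray(x_train, float)
    y_train = np.asarray(y_train, float)
    sd = x_train.std()
    if sd <= 1e-12 or len(x_train) < 5:
        return np.full(len(x_eval), y_train.mean())
    n = len(x_train)
    if n > _CV_MAX_POINTS:
        sub = np.random.default_rng(0).choice(n, _CV_MAX_POINTS, replace=False)
        xs, ys = x_train[sub], y_train[sub]
    else:
        xs, ys = x_train, y_train
    best_bw, best_err = None, np.inf
    for c in _CV_BANDWIDTH_FACTORS:
        bw = c * sd * n ** (-0.2)
        pred = _local_linear(xs, ys, xs, bw, exclude_self=True)
        err = float(np.sum((ys - pred) ** 2))
        if err < best_err:
            best_err, best_bw = err, bw
    return _local_linear(x_train, y_train, np.asarray(x_eval, float), best_bw)


def drtmle_group_mean(
    y, delta, g, q, mask, group: int = 1,
    tol: float | None = None, max_iter: int = 10, g_trunc: float = 0.01,
) -> GroupMeanEstimate:
    """Doubly robust TMLE mean of one diagnosis group.

    Iterates (a) a logistic fluctuation of g with clever covariate
    ``Qr(g)/g``, where ``Qr`` is the local-linear regression of the
    outcome residual on g among usable rows, and (b) a weighted linear
    fluctuation of Q solving the estimating equations associated with
    the directions ``1/g`` and ``(gr(Q) - g)/(g gr(Q))``, where ``gr``
    is the local-linear regression of Delta on Q — implemented as a
    ``Delta/g``-weighted regression on the bounded directions
    ``[1, (gr - g)/gr]`` so low-propensity unusable rows cannot drive
    the fluctuated Q to extremes.  Iteration stops when the efficient
    influence function and both extra correction terms have empirical
    mean below ``tol``.

    ``tol`` defaults to the sampling-scale criterion 1/(sqrt(n) log n):
    the extra equations involve re-estimated nonparametric nuisances,
    so driving them below sampling noise is neither possible nor
    useful.  Propensities are truncated at ``g_trunc`` (default 0.01)
    to bound the fluctuation covariates.
    """
    y0, delta, g, q = _check_group_inputs(y, delta, g, q, mask)
    n = len(y0)
    if tol is None:
        tol = 1.0 / (np.sqrt(n) * np.log(n))
    g = np.clip(g, g_trunc, 1.0)
    use = delta == 1

    def equations(g, q, qr, gr):
        e1 = np.mean(delta / g * (y0 - q))
        e2 = np.mean((delta - g) / g * qr)
        e3 = np.mean(delta * (gr - g) / (g * gr) * (y0 - q))
        return e1, e2, e3

    qr = gr = None
    for _ in range(max_iter):
        qr = _smooth(g[use], (y0 - q)[use], g)
        gr = np.clip(_smooth(q, delta.astype(float), q), g_trunc, 1.0)
        if np.max(np.abs(equations(g, q, qr, gr))) <= tol:
            break

        # (a) fluctuate g along clever covariate Qr/g
        h1 = qr / g
        if np.max(np.abs(h1)) > 1e-12 and 0 < delta.sum() < n:
            lo = logit(np.clip(g, g_trunc, 1 - g_trunc))

            def score(eps):
                return float(np.sum((delta - expit(lo + eps * h1)) * h1))

            s0 = score(0.0)
            if abs(s0) > 1e-12:
                span = 1.0 / max(np.max(np.abs(h1)), 1e-8)
                a, b = -span, span
                for _ in range(60):
                    if score(a) * score(b) <= 0:
                        break
                    a, b = 2 * a, 2 * b
                if score(a) * score(b) <= 0:
                    eps = brentq(score, a, b, xtol=1e-12)
                    g = np.clip(expit(lo + eps * h1), g_trunc, 1.0)

        # (b) fluctuate Q: weighted form of the fluctuation along 1/g
        # and (gr - g)/(g gr) — regress the residual on the bounded
        # directions [1, (gr - g)/gr] with weights delta/g, which
        # solves the same two estimating equations without sending the
        # fluctuated Q to extremes on low-propensity unusable rows
        gr = np.clip(_smooth(q, delta.astype(float), q), g_trunc, 1.0)
        m3 = (gr - g) / gr
        D = np.column_stack([np.ones(n), m3])
        w = (delta / g)[use]
        sw = np.sqrt(w)[:, None]
        coef, *_ = np.linalg.lstsq(sw * D[use], np.sqrt(w) * (y0 - q)[use],
                                   rcond=None)
        q = q + D @ coef
    else:
        qr = _smooth(g[use], (y0 - q)[use], g)
        gr = np.clip(_smooth(q, delta.astype(float), q), g_trunc, 1.0)
        resid = equations(g, q, qr, gr)
        if np.max(np.abs(resid)) > 10 * tol:
            raise RuntimeError(
                "drtmle targeting did not converge; residual estimating "
                f"equations {tuple(float(r) for r in resid)}"
            )

    integrand = delta / g * (y0 - q) + q
    psi = float(integrand.mean())
    eif = integrand - psi
    se = float(eif.std(ddof=1) / np.sqrt(n))
    return GroupMeanEstimate(psi=psi, se=se, estimator="drtmle", group=group, n=n)


_GROUP_MEANS = {
    "aipw": aipw_group_mean,
    "tmle": tmle_group_mean,
    "drtmle": drtmle_group_mean,
}


# ---------------------------------------------------------------------------
# z statistics and multiplicity
# ---------------------------------------------------------------------------

def group_difference_z(est1: GroupMeanEstimate, est0: GroupMeanEstimate):
    """Independent-groups z for psi_1 - psi_0 (negative z: ASD < TD)."""
    if est1.estimator != est0.estimator:
        raise ValueError("estimates come from different estimators")
    diff = est1.psi - est0.psi
    se = float(np.sqrt(est1.se**2 + est0.se**2))
    z = diff / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return diff, se, float(z), p


def naive_difference_z(y, delta, a):
    """Usable-case group-mean difference with Welch-form SE."""
    y = np.asarray(y, float).ravel()
    delta = np.asarray(delta).ravel().astype(int)
    a = np.asarray(a).ravel().astype(int)
    out = {}
    for grp in (1, 0):
        sel = (a == grp) & (delta == 1)
        if sel.sum() < 2:
            raise ValueError(f"fewer than 2 usable rows in group {grp}")
        yy = y[sel]
        out[grp] = (float(yy.mean()), float(yy.std(ddof=1) / np.sqrt(len(yy))), len(yy))
    diff = out[1][0] - out[0][0]
    se = float(np.sqrt(out[1][1] ** 2 + out[0][1] ** 2))
    z = diff / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return diff, se, float(z), p


def naive_group_mean(y, delta, a, group: int) -> GroupMeanEstimate:
    """Usable-case sample mean of one group (the naive comparator)."""
    y = np.asarray(y, float).ravel()
    sel = (np.asarray(a).ravel() == group) & (np.asarray(delta).ravel() == 1)
    yy = y[sel]
    if len(yy) < 2:
        raise ValueError(f"fewer than 2 usable rows in group {group}")
    return GroupMeanEstimate(
        psi=float(yy.mean()), se=float(yy.std(ddof=1) / np.sqrt(len(yy))),
        estimator="naive", group=group, n=len(yy),
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# the full per-cohort estimator
# ---------------------------------------------------------------------------

class DeconfoundedGroupDifference(BaseEstimator):
    """Edgewise deconfounded ASD-TD differences, sklearn-style.

    Parameters
    ----------
    estimator : 'drtmle' | 'tmle' | 'aipw'
        Group-mean combiner (the naive comparator is always reported).
    propensity_library, outcome_library : optional learner libraries
        ``(name, estimator)`` pairs; None uses the package default
        (the fast parametric subset, suited to simulation studies).
    v : folds for the super learners.
    n_seeds : number of cross-validation seeds; per-edge z-statistics
        are averaged across seeds.
    fdr_levels : FDR thresholds reported in the results table.

    After ``fit(X, y)`` — ``X`` a DataFrame with columns ``A`` and
    ``delta`` plus predictors, ``y`` an (n,) or (n, n_edges) outcome
    array with NaN where unusable — the fitted attributes hold a
    per-edge results table (``results_``), the propensity diagnostics
    (``diagnostics_``) and the per-seed manifest (``manifest_``).
    """

    def __init__(self, estimator: str = "drtmle", propensity_library=None,
                 outcome_library=None, v: int = 10, seed: int = 0,
                 n_seeds: int = 1, fdr_levels: tuple = (0.2, 0.05),
                 fast: bool = True, max_seed_failures: float = 0.1):
        self.estimator = estimator
        self.propensity_library = propensity_library
        self.outcome_library = outcome_library
        self.v = v
        self.seed = seed
        self.n_seeds = n_seeds
        self.fdr_levels = fdr_levels
        self.fast = fast
        self.max_seed_failures = max_seed_failures

    def _run_one_seed(self, X, a, delta, Y, seed):
        g, diag, _ = fit_propensity(
            X, delta, library=self.propensity_library, v=self.v, seed=seed,
            fast=self.fast,
        )
        combine = _GROUP_MEANS[self.estimator]
        rows = []
        for e in range(Y.shape[1]):
            y = Y[:, e]
            q, _ = fit_outcome(
                X, delta, y, library=self.outcome_library, v=self.v,
                seed=seed + 7919 * (e + 1), fast=self.fast,
            )
            est1 = combine(y, delta, g, q, a == 1, group=1)
            est0 = combine(y, delta, g, q, a == 0, group=0)
            diff, se, z, p = group_difference_z(est1, est0)
            rows.append((est1.psi, est0.psi, diff, se, z))
        arr = np.asarray(rows)
        return arr, diag

    def fit(self, X: pd.DataFrame, y: np.ndarray):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a DataFrame with 'A' and 'delta' columns")
        for col in ("A", "delta"):
            if col not in X.columns:
                raise ValueError(f"X is missing required column {col!r}")
        if self.estimator not in _GROUP_MEANS:
            raise ValueError(f"unknown estimator {self.estimator!r}")
        a = X["A"].to_numpy(int)
        delta = X["delta"].to_numpy(int)
        predictors = X.drop(columns=["delta"])
        design = build_design(predictors)
        Y = np.asarray(y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]

        per_seed = []
        diags = []
        failures = 0
        for s in range(self.n_seeds):
            seed = self.seed + 104729 * s
            try:
                arr, diag = self._run_one_seed(design, a, delta, Y, seed)
            except Exception as exc:
                failures += 1
                warnings.warn(f"seed {seed} failed: {exc}")
                if failures > max(self.max_seed_failures * self.n_seeds, 0):
                    raise RuntimeError(
                        f"{failures}/{self.n_seeds} seeds failed; aborting"
                    ) from exc
                continue
            per_seed.append(arr)
            diags.append(diag)
        stacked = np.stack(per_seed)          # (seeds, edges, 5)
        z_mean = stacked[:, :, 4].mean(axis=0)
        p = 2.0 * stats.norm.sf(np.abs(z_mean))
        q = bh_adjust(p)

        res = pd.DataFrame({
            "edge": np.arange(Y.shape[1]),
            "psi_asd": stacked[:, :, 0].mean(axis=0),
            "psi_td": stacked[:, :, 1].mean(axis=0),
            "difference": stacked[:, :, 2].mean(axis=0),
            "se": stacked[:, :, 3].mean(axis=0),
            "z": z_mean,
            "p": p,
            "q": q,
            "sign": np.where(z_mean < 0, "ASD<TD", "ASD>TD"),
        })
        for lvl in self.fdr_levels:
            res[f"significant_fdr_{lvl}"] = q <= lvl

        naive = []
        for e in range(Y.shape[1]):
            naive.append(naive_difference_z(Y[:, e], delta, a))
        naive = np.asarray(naive)
        res["naive_difference"] = naive[:, 0]
        res["naive_z"] = naive[:, 2]
        res["naive_p"] = naive[:, 3]
        res["naive_q"] = bh_adjust(naive[:, 3])

        self.results_ = res
        self.diagnostics_ = {
            "min_propensity": min(d["min_propensity"] for d in diags),
            "cv_auc_mean": float(np.mean([d["cv_auc"] for d in diags])),
            "n_seeds_completed": len(per_seed),
        }
        self.manifest_ = {"seeds": [self.seed + 104729 * s for s in range(self.n_seeds)],
                          "per_seed_diagnostics": diags}
        self.z_per_seed_ = stacked[:, :, 4]
        return self

    def run_multiseed(self, X, y):
        """Fit and return the per-edge results table."""
        return self.fit(X, y).results_
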