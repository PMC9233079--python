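"""Selection-bias diagnostics: who gets excluded, and does it matter?

Motion QC deletes scans non-randomly: symptom severity, age and
cognitive ability all predict both head motion and scan usability.
This module quantifies that selection with three tools:

* univariate penalized-spline GAMs of exclusion probability (logit
  link) or mean framewise displacement (identity link) on a phenotype,
  with the smoothing parameter chosen by restricted maximum likelihood
  (REML) under the random-effects view of the spline coefficients;
* one-sided Mann-Whitney U tests comparing included and excluded
  participants phenotype by phenotype, with rank-biserial-style effect
  sizes r = |Z|/sqrt(N);
* a Pearson chi-square (Yates-corrected for 2x2) comparing exclusion
  proportions between diagnosis groups.

Families of tests are adjusted with Benjamini-Hochberg FDR; family
membership is explicit in the report tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.gam.api import BSplines

from .deconfound import bh_adjust

__all__ = [
    "SmoothFit",
    "TestResult",
    "exclusion_curve",
    "fd_association",
    "included_excluded_test",
    "exclusion_chi_square",
    "phenotype_fc_screen",
    "diagnostics_report",
]


@dataclass(frozen=True)
class SmoothFit:
    """A fitted univariate penalized-spline smooth."""

    covariate: str
    link: str                   # 'logit' or 'identity'
    grid: np.ndarray            # evaluation grid (observed range only)
    fitted: np.ndarray          # smooth on the grid, response scale
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    edf: float                  # effective degrees of freedom of the smooth
    lam: float                  # REML-selected penalty
    p_value: float              # test of no association


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    q: float | None
    effect_size_r: float | None
    direction: str | None


# ---------------------------------------------------------------------------
# penalized-spline GAM with REML smoothing
# ---------------------------------------------------------------------------

_DF_BASIS = 10          # cubic B-spline basis dimension per smooth


def _pirls_fit(B, S, y, lam, family, max_iter=100, tol=1e-10):
    """Penalized IRLS for an intercept + smooth model at fixed lambda.

    Returns (beta, eta, mu, w, A_inv) where A = X'WX + lam*S_full.
    """
    n, p = B.shape
    X = np.column_stack([np.ones(n), B])
    S_full = np.zeros((p + 1, p + 1))
    S_full[1:, 1:] = S
    if family == "gaussian":
        A = X.T @ X + lam * S_full
        beta = np.linalg.solve(A, X.T @ y)
        eta = X @ beta
        return beta, eta, eta, np.ones(n), np.linalg.inv(A)
    # binomial with logit link
    mu = np.clip((y + 0.5) / 2.0, 0.01, 0.99)
    eta = np.log(mu / (1 - mu))
    beta = np.zeros(p + 1)
    for _ in range(max_iter):
        w = mu * (1 - mu)
        z = eta + (y - mu) / w
        A = X.T @ (w[:, None] * X) + lam * S_full
        beta_new = np.linalg.solve(A, X.T @ (w * z))
        eta = X @ beta_new
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    w = mu * (1 - mu)
    A = X.T @ (w[:, None] * X) + lam * S_full
    return beta, eta, mu, w, np.linalg.inv(A)


def _log_det_pseudo(S, lam):
    """log |lam * S|_+ over the positive eigenvalues of S."""
    ev = np.linalg.eigvalsh(S)
    pos = ev[ev > ev.max() * 1e-10]
    return float(np.sum(np.log(lam * pos)))


def _reml_criterion(B, S, y, lam, family):
    """Negative restricted log-likelihood (up to constants)."""
    n, p = B.shape
    beta, eta, mu, w, _ = _pirls_fit(B, S, y, lam, family)
    X = np.column_stack([np.ones(n), B])
    S_full = np.zeros((p + 1, p + 1))
    S_full[1:, 1:] = S
    pen = float(beta @ (S_full @ beta))
    A = X.T @ (w[:, None] * X) + lam * S_full
    sign, logdet_A = np.linalg.slogdet(A)
    logdet_S = _log_det_pseudo(S, lam)
    null_dim = (p + 1) - np.linalg.matrix_rank(S)
    if family == "gaussian":
        rss = float(np.sum((y - eta) ** 2))
        phi = (rss + lam * pen) / max(n - null_dim, 1)
        return (
            0.5 * (rss + lam * pen) / phi
            + 0.5 * (n - null_dim) * np.log(2 * np.pi * phi)
            + 0.5 * logdet_A - 0.5 * (p + 1 - null_dim) * np.log(phi)
            - 0.5 * logdet_S
        )
    # working-model Laplace/PQL approximation, scale fixed at 1
    z = eta + (y - mu) / w
    rss_w = float(np.sum(w * (z - eta) ** 2))
    return 0.5 * (rss_w + lam * pen) + 0.5 * logdet_A - 0.5 * logdet_S


def _fit_pgam(x, y, family, covariate="x", n_grid=100):
    """Fit y ~ intercept + spline(x), REML-selected penalty."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if len(x) != len(y):
        raise ValueError("x and y have different lengths")
    if len(x) < 30:
        raise ValueError(f"need >= 30 observations, got {len(x)}")
    if x.std() <= 1e-12:
        raise ValueError(f"covariate {covariate!r} is constant")
    if family == "binomial" and len(np.unique(y)) < 2:
        raise ValueError("response has a single class")

    bs = BSplines(x[:, None], df=[_DF_BASIS], degree=[3], include_intercept=False)
    B = bs.basis
    S = bs.penalty_matrices[0]

    from scipy.optimize import minimize_scalar
    res = minimize_scalar(
        lambda loglam: _reml_criterion(B, S, y, np.exp(loglam), family),
        bounds=(-8.0, 18.0), method="bounded",
        options={"xatol": 1e-2},
    )
    lam = float(np.exp(res.x))

    n, p = B.shape
    beta, eta, mu, w, A_inv = _pirls_fit(B, S, y, lam, family)
    X = np.column_stack([np.ones(n), B])
    F = A_inv @ (X.T @ (w[:, None] * X))      # smoother/shrinkage matrix
    edf_total = float(np.trace(F))
    edf_smooth = edf_total - 1.0
    # alternative edf accounting for smoothing-parameter uncertainty
    edf1_smooth = float(2.0 * np.trace(F) - np.trace(F @ F)) - 1.0
    if family == "gaussian":
        rss = float(np.sum((y - eta) ** 2))
        phi = rss / max(n - edf_total, 1.0)
    else:
        phi = 1.0
    V = phi * A_inv                           # Bayesian posterior covariance

    # Wald test of the smooth block on its leading eigen-directions,
    # with test dof tied to the effective degrees of freedom
    bsm = beta[1:]
    Vsm = V[1:, 1:]
    ev, U = np.linalg.eigh(Vsm)
    order = np.argsort(ev)[::-1]
    ev, U = ev[order], U[:, order]
    t = U.T @ bsm

    def wald_stat(df: float) -> float:
        k = int(np.floor(df))
        frac = df - k
        s = float(np.sum(t[:k] ** 2 / ev[:k]))
        if frac > 1e-8 and k < len(ev):
            s += frac * float(t[k] ** 2 / ev[k])
        return s

    if family == "gaussian":
        df = float(min(max(edf1_smooth, 1.0), p))
        p_value = float(stats.f.sf(wald_stat(df) / df, df, max(n - edf_total, 1.0)))
    else:
        r = int(min(max(np.round(edf_smooth), 1), p))
        p_value = float(stats.chi2.sf(wald_stat(float(r)), r))

    grid = np.linspace(x.min(), x.max(), n_grid)
    Bg = bs.transform(grid[:, None])
    Xg = np.column_stack([np.ones(n_grid), Bg])
    eta_g = Xg @ beta
    se_g = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, V, Xg), 0.0))
    lo, hi = eta_g - 1.96 * se_g, eta_g + 1.96 * se_g
    if family == "binomial":
        inv = lambda v: 1.0 / (1.0 + np.exp(-v))
        fitted, lo, hi = inv(eta_g), inv(lo), inv(hi)
        link = "logit"
    else:
        fitted, link = eta_g, "identity"
    return SmoothFit(
        covariate=covariate, link=link, grid=grid, fitted=fitted,
        ci_lower=lo, ci_upper=hi, edf=edf_smooth, lam=lam, p_value=p_value,
    )


def exclusion_curve(x, delta, covariate: str = "x") -> SmoothFit:
    """Penalized-spline logistic smooth of exclusion (1 - delta) on x."""
    delta = np.asarray(delta).ravel().astype(int)
    excluded = 1 - delta
    return _fit_pgam(x, excluded, "binomial", covariate=covariate)


def fd_association(x, mean_fd, covariate: str = "x") -> SmoothFit:
    """Gaussian penalized-spline smooth of mean FD on a phenotype."""
    return _fit_pgam(x, mean_fd, "gaussian", covariate=covariate)


def phenotype_fc_screen(x, edges, covariate: str = "x") -> np.ndarray:
    """Per-edge GAM p-values of adjusted connectivity on one phenotype.

    A pile-up of small p-values across edges indicates the phenotype
    carries connectivity signal, hence that usability selection on the
    phenotype can bias naive group comparisons.
    """
    edges = np.asarray(edges, float)
    if edges.ndim == 1:
        edges = edges[:, None]
    return np.array([
        _fit_pgam(x, edges[:, e], "gaussian", covariate=covariate).p_value
        for e in range(edges.shape[1])
    ])


# ---------------------------------------------------------------------------
# rank tests and contingency tests
# ---------------------------------------------------------------------------

def included_excluded_test(
    x_included, x_excluded, direction: str = "less"
) -> TestResult:
    """One-sided Mann-Whitney U comparing included vs excluded values.

    ``direction`` is the alternative for the *included* sample
    ('less': included stochastically smaller).  Effect size is
    r = |Z|/sqrt(N) with Z the tie-corrected normal deviate and N the
    combined sample size.
    """
    xi = np.asarray(x_included, float).ravel()
    xe = np.asarray(x_excluded, float).ravel()
    if xi.size == 0 or xe.size == 0:
        raise ValueError("both samples must be nonempty")
    if direction not in ("less", "greater"):
        raise ValueError("direction must be 'less' or 'greater'")
    res = stats.mannwhitneyu(xi, xe, alternative=direction, method="auto")
    n1, n2 = len(xi), len(xe)
    n = n1 + n2
    # tie-corrected normal deviate for the effect size
    mu_u = n1 * n2 / 2.0
    pooled = np.concatenate([xi, xe])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1.0)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1.0) - tie_term)
    z = 0.0 if sigma2 <= 0 else (res.statistic - mu_u) / np.sqrt(sigma2)
    r = abs(z) / np.sqrt(n)
    return TestResult(
        statistic=float(res.statistic), p=float(res.pvalue), q=None,
        effect_size_r=float(r), direction=direction,
    )


def exclusion_chi_square(table, correction: bool = True) -> TestResult:
    """Pearson chi-square on a 2x2 usable-by-group table (Yates default)."""
    tab = np.asarray(table, float)
    if tab.shape != (2, 2):
        raise ValueError(f"table must be 2x2, got {tab.shape}")
    if np.any(tab < 0):
        raise ValueError("counts must be >= 0")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    res = stats.chi2_contingency(tab, correction=correction)
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue),
                      q=None, effect_size_r=None, direction=None)


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def diagnostics_report(
    subjects: pd.DataFrame,
    delta: np.ndarray,
    mean_fd: np.ndarray,
    phenotypes: tuple = ("ados", "srs", "inattention", "hyperactivity",
                         "motor_overflow", "age", "gai"),
) -> pd.DataFrame:
    """Assemble the selection-bias report (one row per test).

    Families: ``exclusion_gam`` (seven smooths of exclusion, one per
    phenotype; ADOS restricted to the ASD group), ``fd_gam`` (seven
    smooths of mean FD), and ``included_vs_excluded`` (thirteen
    one-sided Mann-Whitney tests: seven in the ASD group, six in the
    TD group, where ADOS is not administered).  BH adjustment is
    applied within each family.
    """
    delta = np.asarray(delta).ravel().astype(int)
    mean_fd = np.asarray(mean_fd, float).ravel()
    a = subjects["A"].to_numpy(int)
    rows = []

    def subset_for(ph):
        if ph == "ados":          # ADOS only administered in the ASD group
            return a == 1
        return np.ones(len(a), bool)

    for family, fit in (("exclusion_gam", exclusion_curve), ("fd_gam", fd_association)):
        fam_rows = []
        for ph in phenotypes:
            sel = subset_for(ph)
            x = subjects.loc[sel, ph].to_numpy(float)
            resp = delta[sel] if family == "exclusion_gam" else mean_fd[sel]
            try:
                sf = fit(x, resp, covariate=ph)
                fam_rows.append({"family": family, "test": ph,
                                 "statistic": sf.edf, "p": sf.p_value,
                                 "effect_size_r": None, "direction": None})
            except ValueError:
                continue
        ps = bh_adjust([r["p"] for r in fam_rows]) if fam_rows else []
        for r_, q in zip(fam_rows, ps):
            r_["q"] = float(q)
        rows.extend(fam_rows)

    fam_rows = []
    # severity measures: included hypothesized lower; age/GAI: higher
    direction_of = {ph: "less" for ph in phenotypes}
    direction_of.update({"age": "greater", "gai": "greater"})
    for grp in (1, 0):
        for ph in phenotypes:
            if ph == "ados" and grp == 0:
                continue
            sel = a == grp
            xi = subjects.loc[sel & (delta == 1), ph].to_numpy(float)
            xe = subjects.loc[sel & (delta == 0), ph].to_numpy(float)
            if xi.size == 0 or xe.size == 0:
                continue
            tr = included_excluded_test(xi, xe, direction=direction_of[ph])
            fam_rows.append({
                "family": "included_vs_excluded",
                "test": f"{ph}_{'asd' if grp else 'td'}",
                "statistic": tr.statistic, "p": tr.p,
                "effect_size_r": tr.effect_size_r, "direction": tr.direction,
            })
    ps = bh_adjust([r["p"] for r in fam_rows]) if fam_rows else []
    for r_, q in zip(fam_rows, ps):
        r_["q"] = float(q)
    rows.extend(fam_rows)
    return pd.DataFrame(rows)
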