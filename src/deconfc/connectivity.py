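"""Edgewise functional-connectivity outcomes from component timecourses.

Partial correlations among ICA component timecourses are estimated by
ridge-regularized inversion of the sample correlation matrix:
``Theta = (R + rho I)^-1`` and ``p_ij = -theta_ij / sqrt(theta_ii
theta_jj)``.  The regularization (default rho = 1) stabilizes the
inverse when the number of frames is modest relative to the number of
components.  Edges between *signal* components are Fisher
z-transformed and flattened in a fixed lower-triangle order to form
each subject's outcome vector; with 18 signal components this yields
153 edges.

Before group analysis, each edge is adjusted for scanner motion and
sampling-design covariates: per edge, an OLS fit on mean FD, max FD,
the count of low-FD frames, sex, race, socioeconomic status and
diagnosis; the adjusted outcome is the residual plus the fitted
intercept and the subject's own diagnosis term, which removes nuisance
mean effects while preserving the group difference exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ridge_partial_correlation",
    "fisher_z_edges",
    "edge_labels",
    "AdjustmentModel",
    "adjust_residuals",
]


def ridge_partial_correlation(timecourses: np.ndarray, rho: float = 1.0) -> np.ndarray:
    """Ridge-regularized partial correlation matrix of column variables.

    Parameters
    ----------
    timecourses : array, shape (n_frames, K)
    rho : ridge penalty added to the diagonal of the sample
        correlation matrix before inversion.

    Returns
    -------
    K x K symmetric matrix with unit diagonal.
    """
    tc = np.asarray(timecourses, dtype=float)
    if tc.ndim != 2 or tc.shape[0] < 2 or tc.shape[1] < 2:
        raise ValueError(f"timecourses must be n_frames x K with n>=2, K>=2, got {tc.shape}")
    if rho < 0:
        raise ValueError(f"rho must be >= 0, got {rho}")
    sd = tc.std(axis=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0).tolist()
        raise ValueError(f"constant columns {bad} have undefined correlation")
    r = np.corrcoef(tc, rowvar=False)
    theta = np.linalg.inv(r + rho * np.eye(r.shape[0]))
    d = np.sqrt(np.diag(theta))
    p = -theta / np.outer(d, d)
    np.fill_diagonal(p, 1.0)
    # enforce exact symmetry against inversion round-off
    return (p + p.T) / 2.0


def edge_labels(signal_indices: np.ndarray) -> list[tuple[int, int]]:
    """Fixed edge ordering: lower-triangle row-major, reported as (i, j), i < j.

    Traversal visits rows of the signal-submatrix lower triangle in
    order (pair (s1,s0), (s2,s0), (s2,s1), ...), the order obtained by
    flattening the lower triangle row by row.
    """
    idx = np.asarray(signal_indices, dtype=int)
    if idx.size < 2:
        raise ValueError("need at least 2 signal components")
    if len(set(idx.tolist())) != idx.size:
        raise ValueError("signal_indices must be unique")
    labels = []
    for r in range(1, idx.size):
        for c in range(r):
            i, j = idx[c], idx[r]
            labels.append((int(min(i, j)), int(max(i, j))))
    return labels


def fisher_z_edges(partial_corr: np.ndarray, signal_indices: np.ndarray) -> np.ndarray:
    """Fisher z of signal-signal partial correlations in the fixed order."""
    p = np.asarray(partial_corr, dtype=float)
    idx = np.asarray(signal_indices, dtype=int)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("partial_corr must be square")
    if idx.max() >= p.shape[0] or idx.min() < 0:
        raise ValueError("signal_indices out of range")
    sub = p[np.ix_(idx, idx)]
    tri = sub[np.tril_indices(idx.size, k=-1)]
    if np.any(np.abs(tri) >= 1.0):
        raise ValueError("|partial correlation| >= 1 gives infinite Fisher z")
    return np.arctanh(tri)


@dataclass(frozen=True)
class AdjustmentModel:
    """Per-edge OLS coefficients of the nuisance-adjustment fit."""

    columns: list[str]           # design column names incl. intercept
    coef: np.ndarray             # n_columns x n_edges
    diagnosis_column: str        # name of the diagnosis dummy

    def to_dict(self) -> dict:
        return {
            "columns": self.columns,
            "diagnosis_column": self.diagnosis_column,
            "coef": self.coef.tolist(),
        }


def _adjustment_design(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Build the adjustment design matrix.

    Reference levels: female (sex), AfricanAmerican (race) and Autism
    (diagnosis), so the dummies are sex_M, race one-hots against
    AfricanAmerican, and diagnosis_TD.
    """
    req = {"mean_fd", "max_fd", "n_frames_below", "sex", "race", "ses", "A"}
    missing = req - set(covariates.columns)
    if missing:
        raise ValueError(f"adjustment covariates missing columns: {sorted(missing)}")
    n = len(covariates)
    cols: list[str] = ["intercept"]
    mats = [np.ones(n)]
    for c in ("mean_fd", "max_fd", "n_frames_below", "ses"):
        cols.append(c)
        mats.append(covariates[c].to_numpy(float))
    cols.append("sex_M")
    mats.append((covariates["sex"].astype(str) == "M").to_numpy(float))
    races = sorted(set(covariates["race"].astype(str)) - {"AfricanAmerican"})
    for lvl in races:
        cols.append(f"race_{lvl}")
        mats.append((covariates["race"].astype(str) == lvl).to_numpy(float))
    cols.append("diagnosis_TD")
    mats.append((covariates["A"].to_numpy(int) == 0).astype(float))
    return np.column_stack(mats), cols


def adjust_residuals(
    edges: np.ndarray, covariates: pd.DataFrame
) -> tuple[np.ndarray, AdjustmentModel]:
    """Remove motion/design nuisance means from each edge.

    Fits, per edge, OLS of the edge value on mean FD, max FD, low-FD
    frame count, sex, race, SES and diagnosis (usable subjects only;
    rows must already be restricted).  Returns the adjusted edge table
    (residual + intercept + subject's diagnosis term) and the fitted
    model.  The adjustment leaves the ASD-TD mean difference of every
    edge unchanged.
    """
    y = np.asarray(edges, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if y.shape[0] != len(covariates):
        raise ValueError("edges and covariates have different row counts")
    x, cols = _adjustment_design(covariates)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name columns whose removal restores full rank
        collinear = []
        for j in range(x.shape[1]):
            keep = [k for k in range(x.shape[1]) if k != j]
            if np.linalg.matrix_rank(x[:, keep]) == rank:
                collinear.append(cols[j])
        raise ValueError(f"adjustment design is rank deficient; collinear columns: {collinear}")
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    j_int = cols.index("intercept")
    j_dx = cols.index("diagnosis_TD")
    add_back = coef[j_int][None, :] + np.outer(x[:, j_dx], coef[j_dx])
    adjusted = resid + add_back
    model = AdjustmentModel(columns=cols, coef=coef, diagnosis_column="diagnosis_TD")
    return adjusted, model
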