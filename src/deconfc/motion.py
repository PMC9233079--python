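"""Framewise displacement and motion-based scan usability rules.

A realignment trace is the standard 6-column rigid-body parameter
series (x, y, z translations in mm; pitch, roll, yaw rotations in
radians) at a fixed repetition time.  Framewise displacement (FD)
follows the Power convention: the sum of absolute frame-to-frame
changes of the six parameters, rotations converted to arc length at an
assumed 50 mm head radius.

Two usability rules are implemented.  The *lenient* rule drops frames
whose frame-to-frame translation exceeds 3 mm or rotation exceeds 3
degrees on any axis and requires at least 5 minutes of continuous
surviving data.  The *strict* rule requires mean FD of at most 0.2 mm
and at least 5 minutes of frames with FD of at most 0.25 mm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ScanQC",
    "framewise_displacement",
    "evaluate_lenient",
    "evaluate_strict",
    "motion_summaries",
    "qc_scan",
    "select_best_scan",
    "read_realignment",
]

FIVE_MINUTES_S = 300.0
LENIENT_TRANSLATION_MM = 3.0
LENIENT_ROTATION_RAD = np.deg2rad(3.0)
STRICT_MEAN_FD_MM = 0.2
STRICT_FRAME_FD_MM = 0.25


@dataclass(frozen=True)
class ScanQC:
    """Per-scan motion summaries and usability flags."""

    fd: np.ndarray
    tr: float
    mean_fd: float
    max_fd: float
    n_frames_below: int        # frames with FD < 0.25 mm
    usable_lenient: bool
    usable_strict: bool
    longest_run_s: float       # lenient rule's longest surviving run


def _validate_trace(trace: np.ndarray, tr: float) -> np.ndarray:
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise ValueError(f"trace must be n_frames x 6, got shape {trace.shape}")
    if trace.shape[0] < 2:
        raise ValueError("trace must have at least 2 frames")
    if tr <= 0:
        raise ValueError(f"tr must be > 0, got {tr}")
    if not np.isfinite(trace).all():
        raise ValueError("trace contains non-finite values")
    return trace


def framewise_displacement(trace: np.ndarray, radius: float = 50.0) -> np.ndarray:
    """Power FD series in mm; the first frame is 0 by convention."""
    trace = _validate_trace(trace, tr=1.0)
    diffs = np.abs(np.diff(trace, axis=0))
    fd = diffs[:, :3].sum(axis=1) + radius * diffs[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def evaluate_lenient(trace: np.ndarray, tr: float) -> tuple[bool, float]:
    """Apply the lenient rule; returns (usable, longest_run_seconds).

    A transition whose jump exceeds 3 mm translation or 3 deg rotation
    on any single axis breaks the series; usability requires the
    longest unbroken segment to span at least 300 s of frames.
    """
    trace = _validate_trace(trace, tr)
    diffs = np.abs(np.diff(trace, axis=0))
    bad_jump = (
        (diffs[:, :3] > LENIENT_TRANSLATION_MM).any(axis=1)
        | (diffs[:, 3:] > LENIENT_ROTATION_RAD).any(axis=1)
    )
    longest = run = 1
    for bad in bad_jump:
        run = 1 if bad else run + 1
        longest = max(longest, run)
    longest_s = longest * tr
    return longest_s >= FIVE_MINUTES_S, float(longest_s)


def evaluate_strict(fd: np.ndarray, tr: float) -> bool:
    """Strict rule: mean FD <= 0.2 mm and >= 300 s of frames with FD <= 0.25 mm."""
    fd = np.asarray(fd, dtype=float)
    if fd.ndim != 1 or fd.size == 0:
        raise ValueError("fd must be a nonempty 1-D series")
    if tr <= 0:
        raise ValueError(f"tr must be > 0, got {tr}")
    clean_s = (fd <= STRICT_FRAME_FD_MM).sum() * tr
    # exclusion requires the mean to exceed 0.2 mm, so a scan at the
    # boundary stays usable; the epsilon absorbs summation round-off
    return bool(fd.mean() <= STRICT_MEAN_FD_MM + 1e-12 and clean_s >= FIVE_MINUTES_S)


def motion_summaries(fd: np.ndarray) -> dict[str, float]:
    """Motion covariates for the adjustment model.

    Keys match the adjustment-model design columns: ``mean_fd``,
    ``max_fd`` and ``n_frames_below`` (count of frames with
    FD strictly below 0.25 mm).
    """
    fd = np.asarray(fd, dtype=float)
    if fd.ndim != 1 or fd.size == 0:
        raise ValueError("fd must be a nonempty 1-D series")
    return {
        "mean_fd": float(fd.mean()),
        "max_fd": float(fd.max()),
        "n_frames_below": int((fd < STRICT_FRAME_FD_MM).sum()),
    }


def qc_scan(trace: np.ndarray, tr: float, radius: float = 50.0) -> ScanQC:
    """Evaluate both usability rules and summarize one scan."""
    fd = framewise_displacement(trace, radius=radius)
    summ = motion_summaries(fd)
    lenient, longest_s = evaluate_lenient(trace, tr)
    return ScanQC(
        fd=fd,
        tr=tr,
        mean_fd=summ["mean_fd"],
        max_fd=summ["max_fd"],
        n_frames_below=summ["n_frames_below"],
        usable_lenient=lenient,
        usable_strict=evaluate_strict(fd, tr),
        longest_run_s=longest_s,
    )


def select_best_scan(scans: list[ScanQC], criterion: str = "lenient") -> int | None:
    """Index of the passing scan with the lowest mean FD; None if none pass."""
    if not scans:
        raise ValueError("scans must be nonempty")
    if criterion not in ("lenient", "strict"):
        raise ValueError(f"criterion must be 'lenient' or 'strict', got {criterion!r}")
    attr = "usable_lenient" if criterion == "lenient" else "usable_strict"
    passing = [i for i, s in enumerate(scans) if getattr(s, attr)]
    if not passing:
        return None
    return min(passing, key=lambda i: scans[i].mean_fd)


def read_realignment(path: str | Path) -> np.ndarray:
    """Read an SPM-style rp_*.txt file (6 whitespace-delimited columns)."""
    arr = np.loadtxt(path)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 columns, got shape {arr.shape}")
    return arr


def qc_table(traces: list[np.ndarray], tr: float) -> pd.DataFrame:
    """Run :func:`qc_scan` over traces and tabulate the ScanQC fields."""
    rows = []
    for i, t in enumerate(traces):
        s = qc_scan(t, tr)
        rows.append({
            "scan": i, "mean_fd": s.mean_fd, "max_fd": s.max_fd,
            "n_frames_below": s.n_frames_below,
            "usable_lenient": s.usable_lenient, "usable_strict": s.usable_strict,
            "longest_run_s": s.longest_run_s,
        })
    return pd.DataFrame(rows)
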