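"""Fiber-photometry processing: isosbestic detrending and event-aligned
z-scoring.

The 405 nm isosbestic control channel is fitted onto the 465 nm calcium
signal by least squares (affine), removing photobleaching and shared motion
artifacts; dF/F = (signal - fit) / fit. Event-aligned responses are binned at
0.5 s over a -5..+5 s window and z-scored against the 5 s pre-event baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PhotometryTrace:
    """Two-channel recording at a fixed sampling rate (Hz)."""

    time: np.ndarray
    signal_465: np.ndarray
    control_405: np.ndarray
    rate: float

    def __post_init__(self):
        if not (len(self.time) == len(self.signal_465) == len(self.control_405)):
            raise ValueError("channel lengths differ")
        if self.rate <= 0:
            raise ValueError("sampling rate must be > 0")


@dataclass
class AlignedResponse:
    """Event x bin z-score matrix with bin centers (s, event-relative)."""

    z: np.ndarray  # events x bins; NaN rows mark invalid events
    bin_centers: np.ndarray
    valid: np.ndarray  # per-event bool
    events: np.ndarray  # event times actually used


def detrend(trace: PhotometryTrace, mode: str = "dff") -> np.ndarray:
    """Fit control affinely onto signal and return dF/F.

    fit = a * control + b minimizing ||signal - fit||^2 (closed-form normal
    equations); dF/F = (signal - fit) / fit, with fit <= 0 samples masked NaN.
    ``mode='residual'`` returns signal - fit instead. A constant control
    channel degrades to an intercept-only fit with a warning.
    """
    if trace.time[-1] - trace.time[0] < 10.0:
        raise ValueError("need at least 10 s of data to detrend")
    s, c = np.asarray(trace.signal_465, float), np.asarray(trace.control_405, float)
    if np.ptp(c) == 0:
        warnings.warn("constant control channel; fitting intercept only")
        fit = np.full_like(s, s.mean())
    else:
        A = np.column_stack([c, np.ones_like(c)])
        coef, *_ = np.linalg.lstsq(A, s, rcond=None)
        fit = A @ coef
    if mode == "residual":
        return s - fit
    if mode != "dff":
        raise ValueError(f"unknown mode {mode!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = (s - fit) / fit
    dff[fit <= 0] = np.nan
    return dff


def detrend_coefficients(trace: PhotometryTrace) -> tuple[float, float]:
    """The fitted (a, b) of fit = a * control + b (for inspection/tests)."""
    c, s = np.asarray(trace.control_405, float), np.asarray(trace.signal_465, float)
    A = np.column_stack([c, np.ones_like(c)])
    coef, *_ = np.linalg.lstsq(A, s, rcond=None)
    return float(coef[0]), float(coef[1])


def event_zscore(
    dff: np.ndarray,
    time: np.ndarray,
    events: np.ndarray,
    pre: float = 5.0,
    post: float = 5.0,
    bin_width: float = 0.5,
) -> AlignedResponse:
    """Bin dF/F around each event and z-score against the pre-event baseline.

    Bins are aligned to event time; per event, z = (bin mean - baseline mean)
    / baseline sd over the ``pre``-period bins. Events without a full window
    are dropped with a warning; a zero baseline sd marks the event invalid
    (NaN row).
    """
    time = np.asarray(time, float)
    dt = float(np.median(np.diff(time)))
    n_pre = int(round(pre / bin_width))
    n_post = int(round(post / bin_width))
    n_bins = n_pre + n_post
    edges = np.arange(-n_pre, n_post + 1) * bin_width
    centers = (edges[:-1] + edges[1:]) / 2

    kept, rows, valid = [], [], []
    for ev in np.asarray(events, float):
        if ev - pre < time[0] - dt / 2 or ev + post > time[-1] + dt / 2:
            warnings.warn(f"event at t={ev:.2f}s lacks a full window; dropped")
            continue
        rel = time - ev
        binned = np.empty(n_bins)
        for i in range(n_bins):
            m = (rel >= edges[i]) & (rel < edges[i + 1])
            binned[i] = np.nanmean(dff[m]) if m.any() else np.nan
        base = binned[:n_pre]
        mu, sd = np.nanmean(base), np.nanstd(base, ddof=0)
        if not np.isfinite(sd) or sd == 0:
            rows.append(np.full(n_bins, np.nan))
            valid.append(False)
        else:
            rows.append((binned - mu) / sd)
            valid.append(True)
        kept.append(ev)
    z = np.vstack(rows) if rows else np.empty((0, n_bins))
    return AlignedResponse(
        z=z, bin_centers=centers, valid=np.asarray(valid, bool), events=np.asarray(kept)
    )


def paired_pre_post_test(resp: AlignedResponse) -> tuple[float, float]:
    """Paired t test of per-event mean post z versus mean pre z (utility)."""
    from scipy import stats

    z = resp.z[resp.valid]
    n_pre = (resp.bin_centers < 0).sum()
    pre_m, post_m = z[:, :n_pre].mean(axis=1), z[:, n_pre:].mean(axis=1)
    t, p = stats.ttest_rel(post_m, pre_m)
    return float(t), float(p)


def response_table(resp: AlignedResponse) -> pd.DataFrame:
    """z matrix as a tidy DataFrame (events x bin centers)."""
    return pd.DataFrame(
        resp.z, index=[f"event{i}" for i in range(resp.z.shape[0])],
        columns=[f"{c:+.2f}s" for c in resp.bin_centers],
    )
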