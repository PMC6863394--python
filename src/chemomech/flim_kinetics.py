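"""FLIM-FRET biosensor kinetics.

A FRET biosensor's donor fluorescence lifetime τ_sensor drops when the
sensor is active; with a time-matched donor-only control τ_donor the FRET
efficiency is E = 1 − τ_sensor/τ_donor, computed pointwise against the
control's value at the same time index (ratio normalization, never baseline
subtraction).  After a stimulus at t = 0 the activity peaks at the first
post-stimulus frame (30 s) and relaxes; the deactivation is summarised by

* ΔE at 30 s relative to the pre-stimulus baseline (mean over −300..0 s),
* a mono-exponential fit y = a + b·e^{−c(t−t₀)} on the decay window with
  half-time t½ = ln 2 / c,
* a biphasic comparison: independent fits on the full post-peak window and
  on the early (first 5 min) window, whose disagreement flags a biphasic
  deactivation,
* per-cell half-time distributions for group comparisons.

Acquisition has an early phase (30-s frames for 5 min) and a late phase
(60-s frames for 30 min) separated by a 60-s operator gap; the gap is
missing data and is never interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "FretTrace",
    "DecayFit",
    "fret_efficiency",
    "delta_fret",
    "fit_decay",
    "biphasic_compare",
    "per_cell_halftimes",
]


@dataclass
class FretTrace:
    """FRET-efficiency time series of one cell (t in seconds, stimulus at 0)."""

    cell_id: object
    t: np.ndarray
    e: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.e = np.asarray(self.e, dtype=float)
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")


@dataclass
class DecayFit:
    """Mono-exponential deactivation fit y = a + b·e^{−c(t−t₀)}.

    ``t_half = ln 2 / c`` for accepted fits; ``accepted`` is False on
    non-convergence, non-positive rate, or an implausible half-time.
    """

    a: float
    b: float
    c: float
    t_half: float
    window: tuple[float, float]
    rms_residual: float
    n_points: int
    accepted: bool
    reason: str = ""


# ---------------------------------------------------------------------------
# efficiency and stimulus-locked change
# ---------------------------------------------------------------------------

def fret_efficiency(sensor: pd.DataFrame, donor_control: pd.DataFrame,
                    cell_id: object = 0, grid_tol: float = 1.0,
                    interpolate: bool = False) -> FretTrace:
    """E(t) = 1 − τ_sensor(t)/τ_donor(t), pointwise against the control.

    Both tables need columns ``t_s, tau_ns`` on a shared grid (within
    ``grid_tol`` seconds); with ``interpolate=True`` the control is
    linearly interpolated onto the sensor grid instead.  Non-positive
    control lifetimes are an error.
    """
    s = sensor.sort_values("t_s")
    d = donor_control.sort_values("t_s")
    t = s["t_s"].to_numpy(dtype=float)
    tau_s = s["tau_ns"].to_numpy(dtype=float)
    td = d["t_s"].to_numpy(dtype=float)
    tau_d = d["tau_ns"].to_numpy(dtype=float)

    if len(td) == len(t) and np.allclose(td, t, atol=grid_tol):
        tau_d_matched = tau_d
    elif interpolate:
        tau_d_matched = np.interp(t, td, tau_d)
    else:
        raise ValueError("sensor and control sampling grids differ; "
                         "pass interpolate=True to resample the control")
    if np.any(tau_d_matched <= 0):
        raise ValueError("control lifetimes must be > 0")
    return FretTrace(cell_id=cell_id, t=t, e=1.0 - tau_s / tau_d_matched)


def delta_fret(trace: FretTrace, peak_time: float = 30.0,
               baseline_window: tuple[float, float] = (-300.0, 0.0)) -> float:
    """ΔE at the post-stimulus peak relative to the pre-stimulus baseline.

    Baseline is the mean of E over samples with t in ``baseline_window``
    (inclusive).  A missing sample at ``peak_time`` is an error — no silent
    nearest-neighbour substitution.
    """
    b0, b1 = baseline_window
    base = trace.e[(trace.t >= b0) & (trace.t <= b1)]
    if base.size == 0:
        raise ValueError("no samples in the baseline window")
    at_peak = np.isclose(trace.t, peak_time)
    if not at_peak.any():
        raise ValueError(f"no sample at t = {peak_time} s")
    return float(trace.e[at_peak][0] - base.mean())


# ---------------------------------------------------------------------------
# exponential deactivation fitting
# ---------------------------------------------------------------------------

_HALF_TIME_RANGE = (10.0, 1.0e4)   # s, plausibility bounds for accepted fits


def fit_decay(trace: FretTrace, window: tuple[float, float] = (30.0, 1800.0)
              ) -> DecayFit:
    """Nonlinear least-squares fit of y = a + b·e^{−c(t−t₀)} on a window.

    ``t₀`` is the window start (the post-stimulus maximum, 30 s by
    default).  Initialization: a₀ = last value, b₀ = first − last, c₀ from
    a log-linear fit of (y − a₀).  Fits that fail to converge, return
    c ≤ 0, or land outside the plausible half-time range are flagged
    rejected rather than silently returned.
    """
    t0, t1 = window
    sel = (trace.t >= t0) & (trace.t <= t1)
    t = trace.t[sel]
    y = trace.e[sel]
    if t.size < 5:
        raise ValueError(f"window [{t0}, {t1}] has {t.size} samples (need >= 5)")
    if np.ptp(y) == 0:
        return DecayFit(float(y[0]), 0.0, np.nan, np.nan, window, 0.0,
                        int(t.size), False, "constant data (no decay)")

    a0 = float(y[-1])
    b0 = float(y[0] - y[-1])
    resid = y - a0
    pos = resid > 0 if b0 >= 0 else resid < 0
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos] - t0, np.log(np.abs(resid[pos])), 1)[0]
        c0 = max(-slope, 1e-5)
    else:
        c0 = 1.0 / max(t1 - t0, 1.0)

    def model(tt, a, b, c):
        return a + b * np.exp(-c * (tt - t0))

    try:
        popt, _ = curve_fit(model, t, y, p0=(a0, b0, c0), maxfev=10000)
    except (RuntimeError, ValueError):
        return DecayFit(np.nan, np.nan, np.nan, np.nan, window, np.nan,
                        int(t.size), False, "non-convergence")
    a, b, c = (float(v) for v in popt)
    rms = float(np.sqrt(np.mean((model(t, a, b, c) - y) ** 2)))
    if c <= 0:
        return DecayFit(a, b, c, np.nan, window, rms, int(t.size),
                        False, "non-positive rate")
    t_half = float(np.log(2.0) / c)
    lo, hi = _HALF_TIME_RANGE
    if not (lo < t_half < hi):
        return DecayFit(a, b, c, t_half, window, rms, int(t.size),
                        False, f"half-time {t_half:.1f} s outside ({lo}, {hi})")
    return DecayFit(a, b, c, t_half, window, rms, int(t.size), True)


def biphasic_compare(trace: FretTrace,
                     full_window: tuple[float, float] = (30.0, 1800.0),
                     early_window: tuple[float, float] = (30.0, 300.0)
                     ) -> dict:
    """Independent fits on the full and early decay windows.

    A single-exponential decay gives statistically indistinguishable
    half-times in both windows; a fast-plus-slow (biphasic) decay makes the
    early-window half-time shorter.  Returns both fits, each window's
    amplitude-normalized RMS residual, and the half-time comparison.
    """
    full = fit_decay(trace, full_window)
    early = fit_decay(trace, early_window)
    out = {"full": full, "early": early}
    for name, f in (("full", full), ("early", early)):
        out[f"{name}_norm_residual"] = (f.rms_residual / abs(f.b)
                                        if f.accepted and f.b != 0 else np.nan)
    out["early_faster"] = (early.accepted and full.accepted
                          and early.t_half < full.t_half)
    return out


def per_cell_halftimes(traces: list[FretTrace],
                       window: tuple[float, float] = (30.0, 1800.0)
                       ) -> tuple[pd.DataFrame, dict]:
    """Half-time of the deactivation fit for each individual cell.

    Returns ``(table, summary)``: the table has one row per cell with its
    fit parameters and acceptance status; the summary gives quantiles of
    accepted half-times and the rejection count.  At least 2 accepted fits
    are required.
    """
    rows = []
    for tr in traces:
        f = fit_decay(tr, window)
        rows.append({"cell": tr.cell_id, "a": f.a, "b": f.b, "c": f.c,
                     "t_half_s": f.t_half, "accepted": f.accepted,
                     "reason": f.reason})
    table = pd.DataFrame(rows)
    ok = table.loc[table["accepted"], "t_half_s"]
    if len(ok) < 2:
        raise ValueError(f"only {len(ok)} accepted fits (need >= 2)")
    summary = {
        "n_accepted": int(len(ok)),
        "n_rejected": int((~table["accepted"]).sum()),
        "median_t_half_s": float(ok.median()),
        "q25_t_half_s": float(ok.quantile(0.25)),
        "q75_t_half_s": float(ok.quantile(0.75)),
    }
    return table, summary
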