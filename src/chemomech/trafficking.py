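"""Receptor-trafficking quantifications.

Four independent assays of receptor fate after ligand stimulation:

* **Internalization** — the fraction of a tagged receptor's fluorescence at
  the plasma membrane, expressed as a percentage of its value at stimulus
  time (:func:`surface_fraction`).
* **Recycling / degradation** — capture-ELISA chase series of a cleavably
  biotinylated receptor pool.  In the recycling assay, receptors that
  return to the surface have their biotin cleaved by the second
  reducing-agent (MesNa) step, so the captured signal is the
  internalized-not-yet-recycled pool and the recycled percentage *rises* as
  the signal falls: recycled% = 100·(s0 − s(t))/s0.  The degradation assay
  reports the surviving pool directly: remaining% = 100·s(t)/s0.
* **Colocalization** — Pearson correlation of two channels over a fixed
  ROI box centred on the cell, after rolling-ball background subtraction.
* **Ligand consumption** — LC-MS peak areas of each lysophosphatidic-acid
  species normalized to a spiked internal standard (LPA 17:0), optionally
  with a first-order consumption fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ColocInput",
    "surface_fraction",
    "recycling_percent",
    "degradation_percent",
    "subtract_background",
    "pearson_colocalization",
    "normalize_lipid",
]


# ---------------------------------------------------------------------------
# internalization
# ---------------------------------------------------------------------------

def surface_fraction(trace: pd.DataFrame) -> pd.DataFrame:
    """Membrane fluorescence as % of its initial membrane fraction.

    ``trace`` needs columns ``t_min, membrane_intensity, total_intensity``
    with the first sample at t = 0.  The per-frame membrane fraction
    membrane/total is normalized to its value at t = 0:
    f(t) = 100 · (membrane(t)/total(t)) / (membrane(0)/total(0)).
    Monotonicity is not assumed (receptors can recycle back).
    """
    tr = trace.sort_values("t_min")
    t = tr["t_min"].to_numpy(dtype=float)
    mem = tr["membrane_intensity"].to_numpy(dtype=float)
    tot = tr["total_intensity"].to_numpy(dtype=float)
    if t[0] != 0:
        raise ValueError("first sample must be at t = 0")
    if np.any(tot <= 0):
        raise ValueError("total intensities must be > 0")
    if mem[0] <= 0:
        raise ValueError("zero membrane signal at t = 0")
    frac = mem / tot
    return pd.DataFrame({"t_min": t, "surface_percent": 100.0 * frac / frac[0]})


# ---------------------------------------------------------------------------
# capture-ELISA recycling and degradation
# ---------------------------------------------------------------------------

def _check_series(series: pd.DataFrame, s0: float) -> np.ndarray:
    sig = series["signal"].to_numpy(dtype=float)
    if s0 <= 0:
        raise ValueError("s0 must be > 0")
    if np.any(sig < 0):
        raise ValueError("signals must be >= 0")
    return sig


def recycling_percent(series: pd.DataFrame, s0: float | None = None,
                      tolerance: float = 0.05) -> pd.DataFrame:
    """% of the internalized pool recycled at each chase time.

    The captured signal is the internalized-not-recycled pool, so
    recycled% = 100·(s0 − s(t))/s0.  ``s0`` defaults to the signal at the
    earliest chase time.  Values are clamped to [0, 100]; signals exceeding
    s0 by more than ``tolerance``·s0 trigger a warning before clamping.
    """
    series = series.sort_values("t_min")
    if s0 is None:
        s0 = float(series["signal"].iloc[0])
    sig = _check_series(series, s0)
    if np.any(sig > s0 * (1.0 + tolerance)):
        warnings.warn("signal exceeds s0 beyond noise tolerance; clamping")
    pct = 100.0 * (s0 - sig) / s0
    return pd.DataFrame({"t_min": series["t_min"].to_numpy(dtype=float),
                         "recycled_percent": np.clip(pct, 0.0, 100.0),
                         "recycled_percent_raw": pct})


def degradation_percent(series: pd.DataFrame, s0: float | None = None,
                        tolerance: float = 0.05) -> pd.DataFrame:
    """% of receptors remaining at each chase time: 100·s(t)/s0."""
    series = series.sort_values("t_min")
    if s0 is None:
        s0 = float(series["signal"].iloc[0])
    sig = _check_series(series, s0)
    if np.any(sig > s0 * (1.0 + tolerance)):
        warnings.warn("signal exceeds s0 beyond noise tolerance; clamping")
    pct = 100.0 * sig / s0
    return pd.DataFrame({"t_min": series["t_min"].to_numpy(dtype=float),
                         "remaining_percent": np.clip(pct, 0.0, 100.0),
                         "remaining_percent_raw": pct})


# ---------------------------------------------------------------------------
# colocalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColocInput:
    """Two-channel ROI specification for Pearson colocalization.

    ``center`` is the cell centre in µm; a ``roi_size`` × ``roi_size`` µm
    box (15×15 µm default) is placed over it.  ``background_radius`` (px)
    sets the rolling-ball radius for background subtraction; 0 disables it.
    """

    channel1: np.ndarray
    channel2: np.ndarray
    center: tuple[float, float]
    pixel_size: float
    roi_size: float = 15.0
    background_radius: int = 50


def subtract_background(image: np.ndarray, radius: int = 50) -> np.ndarray:
    """Rolling-ball background subtraction.

    Estimates a smooth background surface (everywhere ≤ the image) with a
    ball of the given pixel radius and subtracts it; the result is
    non-negative.  The radius should exceed the size of the features of
    interest — that choice is the caller's responsibility.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    from skimage.restoration import rolling_ball
    img = np.asarray(image, dtype=float)
    bg = rolling_ball(img, radius=radius)
    return img - bg


def pearson_colocalization(inp: ColocInput) -> float:
    """Pearson correlation of two channels over the ROI pixels.

    Background is rolling-ball-subtracted from each channel first (when
    ``background_radius`` > 0); no intensity thresholding is applied.
    Returns NaN (undefined) when either channel has zero variance in the
    ROI.
    """
    ch1 = np.asarray(inp.channel1, dtype=float)
    ch2 = np.asarray(inp.channel2, dtype=float)
    if ch1.shape != ch2.shape:
        raise ValueError("channels must share a shape")
    half_px = int(round(inp.roi_size / 2.0 / inp.pixel_size))
    cx, cy = (int(round(c / inp.pixel_size)) for c in inp.center)
    y0, y1 = cy - half_px, cy + half_px
    x0, x1 = cx - half_px, cx + half_px
    if y0 < 0 or x0 < 0 or y1 > ch1.shape[0] or x1 > ch1.shape[1]:
        raise ValueError("ROI extends outside the image")
    if inp.background_radius > 0:
        ch1 = subtract_background(ch1, inp.background_radius)
        ch2 = subtract_background(ch2, inp.background_radius)
    a = ch1[y0:y1, x0:x1].ravel()
    b = ch2[y0:y1, x0:x1].ravel()
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero variance in ROI: Pearson R undefined")
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


# ---------------------------------------------------------------------------
# lipid consumption
# ---------------------------------------------------------------------------

def normalize_lipid(series: pd.DataFrame, fit_decay_rate: bool = False
                    ) -> pd.DataFrame | tuple[pd.DataFrame, dict]:
    """Internal-standard-normalized lipid abundance over time.

    ``series`` needs columns ``t_h, peak_area, internal_standard_area``;
    the normalized abundance is peak_area / internal_standard_area per time
    point.  With ``fit_decay_rate`` a log-linear first-order consumption
    fit is added, returning ``(table, {"rate_per_h", "half_life_h"})`` —
    flagged exploratory: it assumes simple exponential consumption.
    """
    req = ("t_h", "peak_area", "internal_standard_area")
    missing = [c for c in req if c not in series.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    s = series.sort_values("t_h")
    is_area = s["internal_standard_area"].to_numpy(dtype=float)
    if np.any(is_area <= 0) or s["internal_standard_area"].isna().any():
        raise ValueError("internal-standard area must be present and > 0 "
                         "for every time point")
    table = pd.DataFrame({
        "t_h": s["t_h"].to_numpy(dtype=float),
        "normalized_abundance": s["peak_area"].to_numpy(dtype=float) / is_area,
    })
    if not fit_decay_rate:
        return table
    ratio = table["normalized_abundance"].to_numpy()
    if np.any(ratio <= 0):
        raise ValueError("cannot log-fit non-positive abundances")
    slope, _ = np.polyfit(table["t_h"].to_numpy(), np.log(ratio), 1)
    rate = -float(slope)
    fit = {"rate_per_h": rate,
           "half_life_h": float(np.log(2) / rate) if rate > 0 else float("inf"),
           "exploratory": True}
    return table, fit
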