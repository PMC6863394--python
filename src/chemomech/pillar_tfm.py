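"""Micropillar traction-force microscopy.

Cells plated on arrays of flexible PDMS micropillars bend each pillar they
pull on; for small deflections a pillar is a cantilevered cylinder and the
tip force is ``F = k · δ`` with the Euler–Bernoulli bending stiffness
``k = 3EI/L³`` (``I = πD⁴/64``).  The pipeline here is:

1. :func:`bending_stiffness` — k from the pillar geometry.
2. :func:`detect_pillars` — sub-pixel pillar centres on the equilibrium
   (cell-free) reference image, snapped to a best-fit square lattice.
3. :func:`register_drift` / :func:`correct_drift` — translation-only stage
   drift registration against the first frame.
4. :func:`pillar_displacement` — per-pillar deflection versus the
   equilibrium reference by windowed normalized cross-correlation with a
   quadratic sub-pixel peak fit.
5. :func:`traction_forces` and :func:`cell_mean_traction` — forces and the
   per-cell summary (mean force over a chosen pillar subset and time
   window).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import match_template, peak_local_max
from skimage.registration import phase_cross_correlation

__all__ = [
    "PillarGeometry",
    "PillarGrid",
    "TractionRecord",
    "bending_stiffness",
    "detect_pillars",
    "register_drift",
    "correct_drift",
    "focus_scores",
    "pillar_displacement",
    "traction_forces",
    "cell_mean_traction",
]


class DetectionError(RuntimeError):
    """Pillar detection failed."""


@dataclass(frozen=True)
class PillarGeometry:
    """Physical description of one pillar in a square array.

    diameter and height in µm, Young's modulus in MPa, pitch
    (centre-to-centre) in µm.
    """

    diameter: float
    height: float
    youngs_modulus: float
    pitch: float

    def validate(self) -> None:
        if min(self.diameter, self.height, self.youngs_modulus, self.pitch) <= 0:
            raise ValueError("all geometry parameters must be > 0")
        if self.diameter >= self.pitch:
            raise ValueError("diameter must be smaller than pitch")


@dataclass
class PillarGrid:
    """Detected pillar lattice: sub-pixel equilibrium centres.

    ``centres`` has shape (n, 2) as (x, y) pixels; ``pixel_size`` is in
    µm/pixel.  ``rotation`` is the fitted lattice rotation in radians and
    ``n_dropped`` counts detections discarded as off-lattice outliers.
    """

    centres: np.ndarray
    pixel_size: float
    pitch_px: float
    rotation: float
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.centres)


@dataclass
class TractionRecord:
    """Per-cell traction summary: mean force over pillars and time."""

    cell_id: object
    mean_force_nN: float
    n_pillars: int
    time_span_h: float
    condition: str = ""
    warning: str = ""


# ---------------------------------------------------------------------------
# beam theory
# ---------------------------------------------------------------------------

def bending_stiffness(geom: PillarGeometry) -> float:
    """Cantilever tip stiffness k = 3EI/L³ in nN/µm.

    The pillar is treated as a cylindrical cantilever loaded at the tip,
    with second moment of area I = πD⁴/64.  With D, L in µm and E in MPa
    (1 MPa = 10³ nN/µm²) the result is in nN/µm directly.
    """
    geom.validate()
    inertia = np.pi * geom.diameter**4 / 64.0          # µm⁴
    e_nn_um2 = geom.youngs_modulus * 1.0e3             # MPa -> nN/µm²
    return float(3.0 * e_nn_um2 * inertia / geom.height**3)


# ---------------------------------------------------------------------------
# pillar detection on the equilibrium image
# ---------------------------------------------------------------------------

def _refine_centroid(image: np.ndarray, y: float, x: float, radius: int,
                     n_iter: int = 3) -> tuple[float, float]:
    """Iterative intensity centroid in a square window, background-floored."""
    for _ in range(n_iter):
        yi, xi = int(round(y)), int(round(x))
        y0, y1 = yi - radius, yi + radius + 1
        x0, x1 = xi - radius, xi + radius + 1
        if y0 < 0 or x0 < 0 or y1 > image.shape[0] or x1 > image.shape[1]:
            break
        win = image[y0:y1, x0:x1] - image[y0:y1, x0:x1].min()
        total = win.sum()
        if total <= 0:
            break
        yy, xx = np.mgrid[y0:y1, x0:x1]
        y, x = float((yy * win).sum() / total), float((xx * win).sum() / total)
    return y, x


def detect_pillars(reference: np.ndarray, geom: PillarGeometry,
                   pixel_size: float, min_intensity: float | None = None
                   ) -> PillarGrid:
    """Locate pillar centres on the equilibrium image and fit the lattice.

    Local maxima are refined to sub-pixel intensity centroids, a square
    lattice at the expected pitch is fitted (rotation + origin), and
    detections more than 20% of a pitch off-lattice are dropped with a
    count in the result.
    """
    geom.validate()
    ref = np.asarray(reference, dtype=float)
    pitch_px = geom.pitch / pixel_size
    if min_intensity is None:
        lo, hi = ref.min(), ref.max()
        if hi <= lo:
            raise DetectionError("blank reference image")
        min_intensity = lo + 0.3 * (hi - lo)
    peaks = peak_local_max(ref, min_distance=max(1, int(pitch_px * 0.6)),
                           threshold_abs=min_intensity, exclude_border=False)
    if len(peaks) < 4:
        raise DetectionError(f"only {len(peaks)} pillars found (need >= 4)")

    radius = max(2, int(round(pitch_px / 2)) - 1)
    centres = np.array([_refine_centroid(ref, py, px, radius)[::-1]
                        for py, px in peaks])        # (x, y)

    # lattice rotation from nearest-neighbour vectors folded into [0, 90°)
    from scipy.spatial import cKDTree
    tree = cKDTree(centres)
    d, idx = tree.query(centres, k=2)
    nn_vec = centres[idx[:, 1]] - centres
    ang = np.mod(np.arctan2(nn_vec[:, 1], nn_vec[:, 0]), np.pi / 2)
    # circular mean on the 4-fold-symmetric angle
    rot = float(np.angle(np.exp(4j * ang).mean()) / 4.0)
    pitch_est = float(np.median(d[:, 1]))

    c, s = np.cos(rot), np.sin(rot)
    basis = np.array([[c, -s], [s, c]]) * pitch_est
    origin = centres[0]
    ij = np.round(np.linalg.solve(basis, (centres - origin).T).T)
    snapped = origin + ij @ basis.T
    off = np.linalg.norm(centres - snapped, axis=1)
    keep = off <= 0.2 * pitch_est
    n_dropped = int((~keep).sum())
    if keep.sum() < 4:
        raise DetectionError("fewer than 4 on-lattice pillars")

    # refine origin and lattice vectors by least squares over the kept
    # detections, then snap: averaging over all pillars suppresses the
    # per-centroid noise, so the equilibrium positions carry far less noise
    # than any single detection
    ij_k, cen_k = ij[keep], centres[keep]
    design = np.column_stack([np.ones(len(ij_k)), ij_k])   # [1, i, j]
    coef, *_ = np.linalg.lstsq(design, cen_k, rcond=None)  # rows: O, b1, b2
    snapped_k = design @ coef
    b1, b2 = coef[1], coef[2]
    rot = float(np.arctan2(b1[1], b1[0]))
    pitch_fit = float((np.linalg.norm(b1) + np.linalg.norm(b2)) / 2.0)
    return PillarGrid(centres=snapped_k, pixel_size=pixel_size,
                      pitch_px=pitch_fit, rotation=rot, n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# drift registration
# ---------------------------------------------------------------------------

def register_drift(stack: np.ndarray, upsample_factor: int = 100) -> np.ndarray:
    """Per-frame rigid translation (dx, dy) of each frame relative to frame 0.

    Whole-image phase cross-correlation with sub-pixel refinement.  A
    returned shift of (dx, dy) means the frame content moved by +dx right
    and +dy down with respect to the first frame.  Degenerate (constant)
    frames get zero shift with a warning.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a stack with >= 2 frames")
    shifts = np.zeros((stack.shape[0], 2))
    ref = stack[0]
    for f in range(1, stack.shape[0]):
        if stack[f].std() == 0 or ref.std() == 0:
            warnings.warn(f"frame {f}: constant image, assuming zero drift")
            continue
        (dy, dx), _, _ = phase_cross_correlation(ref, stack[f],
                                                 upsample_factor=upsample_factor)
        # phase_cross_correlation returns the shift that maps moving -> ref
        shifts[f] = (-dx, -dy)
    return shifts


def correct_drift(stack: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    """Shift every frame back by its registered drift (spline interpolation)."""
    stack = np.asarray(stack, dtype=float)
    out = stack.copy()
    for f in range(1, stack.shape[0]):
        dx, dy = shifts[f]
        if dx or dy:
            out[f] = ndimage.shift(stack[f], (-dy, -dx), order=3, mode="nearest")
    return out


def focus_scores(stack: np.ndarray) -> np.ndarray:
    """Per-frame intensity variance, a simple focus-quality score.

    Out-of-focus frames blur the pillar spots and lose variance; frames
    scoring below a caller-chosen threshold should be excluded from
    displacement analysis.
    """
    stack = np.asarray(stack, dtype=float)
    return stack.var(axis=(1, 2))


# ---------------------------------------------------------------------------
# sub-pixel pillar displacement
# ---------------------------------------------------------------------------

def _mean_template(ref_img: np.ndarray, grid: PillarGrid, half: int
                   ) -> np.ndarray:
    """Phase-aligned mean pillar template from the equilibrium image.

    Each in-bounds pillar window is Fourier-shifted so its (lattice-snapped)
    centre sits exactly at the window centre, then averaged.  Averaging over
    the whole array suppresses the reference image's pixel noise, so a
    displacement measurement carries essentially only the moving frame's
    noise.
    """
    acc = np.zeros((2 * half + 1, 2 * half + 1))
    n = 0
    for cx, cy in grid.centres:
        xi, yi = int(round(cx)), int(round(cy))
        if (yi - half < 0 or xi - half < 0 or yi + half + 1 > ref_img.shape[0]
                or xi + half + 1 > ref_img.shape[1]):
            continue
        win = ref_img[yi - half:yi + half + 1, xi - half:xi + half + 1]
        phase = (cy - yi, cx - xi)
        if max(abs(p) for p in phase) > 1e-9:
            win = np.fft.ifft2(ndimage.fourier_shift(np.fft.fft2(win),
                                                     (-phase[0], -phase[1]))).real
        acc += win
        n += 1
    if n == 0:
        raise ValueError("no pillar window fits inside the reference image")
    return acc / n


def _quadratic_peak_2d(corr: np.ndarray, peak: tuple[int, int]
                       ) -> tuple[float, float]:
    """Sub-pixel peak by least-squares 2-D quadratic on the 3×3 neighbourhood."""
    py, px = peak
    c = corr[py - 1:py + 2, px - 1:px + 2].astype(float)
    yy, xx = np.mgrid[-1:2, -1:2]
    design = np.column_stack([np.ones(9), xx.ravel(), yy.ravel(),
                              xx.ravel() ** 2, yy.ravel() ** 2,
                              (xx * yy).ravel()])
    _, ax, ay, axx, ayy, axy = np.linalg.lstsq(design, c.ravel(), rcond=None)[0]
    hess = np.array([[2 * axx, axy], [axy, 2 * ayy]])
    if np.linalg.det(hess) <= 0:          # not a proper maximum
        return float(py), float(px)
    ox, oy = np.linalg.solve(hess, [-ax, -ay])
    ox, oy = np.clip([ox, oy], -1.0, 1.0)
    return py + float(oy), px + float(ox)


def _refine_peak_continuous(search: np.ndarray, tmpl: np.ndarray,
                            peak: tuple[int, int],
                            start: tuple[float, float]
                            ) -> tuple[float, float]:
    """Refine a correlation peak by maximizing the continuous NCC.

    The normalized correlation at fractional shift (u, v) around the
    integer peak equals the Pearson correlation between the window at the
    peak and the template Fourier-shifted by (u, v); maximizing that
    continuous function removes the bias a 3×3 quadratic fit keeps at
    half-pixel offsets.
    """
    from scipy.optimize import minimize

    py, px = peak
    win = search[py:py + tmpl.shape[0], px:px + tmpl.shape[1]]
    w = win - win.mean()
    wn = np.linalg.norm(w)
    if wn == 0:
        return float(py), float(px)
    ft = np.fft.fft2(tmpl)

    def neg_ncc(uv: np.ndarray) -> float:
        shifted = np.fft.ifft2(ndimage.fourier_shift(ft, (uv[0], uv[1]))).real
        s = shifted - shifted.mean()
        sn = np.linalg.norm(s)
        return 0.0 if sn == 0 else -float((w * s).sum() / (wn * sn))

    res = minimize(neg_ncc, x0=[start[0], start[1]], method="Nelder-Mead",
                   options={"xatol": 1e-3, "fatol": 1e-12, "maxiter": 60})
    dy, dx = np.clip(res.x, -1.0, 1.0)
    return py + float(dy), px + float(dx)


def _locate_spot(image: np.ndarray, tmpl: np.ndarray,
                 centre: tuple[int, int], half: int, max_shift: int
                 ) -> tuple[float, float, float] | None:
    """Locate the template in ``image`` near an integer ``centre`` (x, y).

    Normalized cross-correlation over a ±``max_shift`` search, quadratic
    3×3 peak estimate, then continuous NCC refinement.  Returns the
    absolute sub-pixel position (x, y) and the correlation peak height, or
    None when the search window leaves the image.
    """
    xi, yi = centre
    Y0, Y1 = yi - half - max_shift, yi + half + max_shift + 1
    X0, X1 = xi - half - max_shift, xi + half + max_shift + 1
    if Y0 < 0 or X0 < 0 or Y1 > image.shape[0] or X1 > image.shape[1]:
        return None
    search = image[Y0:Y1, X0:X1]
    corr = match_template(search, tmpl, pad_input=False)
    py, px = np.unravel_index(np.argmax(corr), corr.shape)
    if 0 < py < corr.shape[0] - 1 and 0 < px < corr.shape[1] - 1:
        sy, sx = _quadratic_peak_2d(corr, (py, px))
        sy, sx = _refine_peak_continuous(search, tmpl, (py, px),
                                         (sy - py, sx - px))
    else:
        sy, sx = float(py), float(px)
    return (xi + sx - max_shift, yi + sy - max_shift, float(corr[py, px]))


def pillar_displacement(stack: np.ndarray, grid: PillarGrid,
                        window: int = 9, max_shift: int | None = None,
                        reference_frame: int = 0,
                        frames: np.ndarray | None = None,
                        pillars: np.ndarray | None = None) -> pd.DataFrame:
    """Per-pillar, per-frame deflection from the equilibrium position.

    A phase-aligned mean pillar template is built from the equilibrium
    reference frame (see :func:`_mean_template`).  For every pillar and
    frame, the neighbourhood of the pillar's equilibrium position is
    cross-correlated (normalized) against the template; the correlation
    peak, refined by a quadratic fit on its 3×3 neighbourhood, locates the
    pillar, and subtracting the lattice-snapped equilibrium centre gives
    the deflection in µm.  ``window`` must stay below the lattice pitch in
    pixels so each window sees one pillar.  Pillars whose search window
    overlaps the image border are flagged ``excluded`` with NaN values.
    ``frames`` / ``pillars`` restrict the computation to subsets (all by
    default).  For deflections approaching half the pitch, choose
    ``window`` small enough that the neighbouring pillar stays outside the
    matched window (e.g. 7 px at a 10 px pitch).

    Returns a table with columns ``pillar, frame, dx_um, dy_um,
    magnitude_um, quality, excluded`` (``quality`` is the correlation peak
    height).
    """
    stack = np.asarray(stack, dtype=float)
    if window >= grid.pitch_px:
        raise ValueError("window must be smaller than the pitch in pixels")
    if max_shift is None:
        # deflections beyond half the pitch are ambiguous anyway; +1 keeps a
        # half-pitch peak off the correlation-map edge
        max_shift = int(np.ceil(grid.pitch_px / 2.0)) + 1
    half = window // 2
    tmpl = _mean_template(stack[reference_frame], grid, half)
    frame_idx = range(stack.shape[0]) if frames is None else frames
    pillar_idx = range(len(grid.centres)) if pillars is None else pillars

    rows = []
    for pid in pillar_idx:
        cx, cy = grid.centres[pid]
        xi, yi = int(round(cx)), int(round(cy))
        Y0, Y1 = yi - half - max_shift, yi + half + max_shift + 1
        X0, X1 = xi - half - max_shift, xi + half + max_shift + 1
        if Y0 < 0 or X0 < 0 or Y1 > stack.shape[1] or X1 > stack.shape[2]:
            for f in frame_idx:
                rows.append((pid, f, np.nan, np.nan, np.nan, np.nan, True))
            continue
        for f in frame_idx:
            found = _locate_spot(stack[f], tmpl, (xi, yi), half, max_shift)
            if found is None:
                rows.append((pid, f, np.nan, np.nan, np.nan, np.nan, True))
                continue
            fx, fy, quality = found
            # recentre on the estimate and repeat with a tight search: once
            # the spot sits near the window centre the match is unbiased
            xj, yj = int(round(fx)), int(round(fy))
            if (xj, yj) != (xi, yi):
                again = _locate_spot(stack[f], tmpl, (xj, yj), half, 2)
                if again is not None:
                    fx, fy, quality = again
            dx_px = fx - cx
            dy_px = fy - cy
            rows.append((pid, f, dx_px * grid.pixel_size, dy_px * grid.pixel_size,
                         float(np.hypot(dx_px, dy_px)) * grid.pixel_size,
                         quality, False))
    return pd.DataFrame(rows, columns=["pillar", "frame", "dx_um", "dy_um",
                                       "magnitude_um", "quality", "excluded"])


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------

def traction_forces(field: pd.DataFrame, k: float) -> pd.DataFrame:
    """Convert deflections to forces: F = k·δ elementwise (nN).

    Adds ``fx_nN, fy_nN, force_nN`` columns to a displacement table.
    """
    if k <= 0:
        raise ValueError("stiffness k must be > 0")
    out = field.copy()
    out["fx_nN"] = k * out["dx_um"]
    out["fy_nN"] = k * out["dy_um"]
    out["force_nN"] = k * out["magnitude_um"]
    return out


def cell_mean_traction(forces: pd.DataFrame, pillar_subset: list[int],
                       time_window: tuple[float, float],
                       frame_interval_h: float,
                       cell_id: object = 0, condition: str = "",
                       min_window_h: float = 1.5) -> TractionRecord:
    """Mean traction force of one cell: average per-pillar per-frame force
    magnitude over the given pillar subset and time window (hours).

    Windows shorter than ``min_window_h`` are allowed but flagged with a
    warning in the returned record.
    """
    if not pillar_subset:
        raise ValueError("pillar_subset must be nonempty")
    t0, t1 = time_window
    span = t1 - t0
    warning = ""
    if span < min_window_h:
        warning = (f"time window {span:.2f} h shorter than the "
                   f"{min_window_h:.2f} h minimum")
        warnings.warn(warning)
    sel = forces[forces["pillar"].isin(pillar_subset) & ~forces["excluded"]]
    t = sel["frame"] * frame_interval_h
    sel = sel[(t >= t0) & (t <= t1)]
    if sel.empty:
        raise ValueError("no force samples in the requested window")
    return TractionRecord(cell_id=cell_id,
                          mean_force_nN=float(sel["force_nN"].mean()),
                          n_pillars=sel["pillar"].nunique(),
                          time_span_h=span, condition=condition,
                          warning=warning)
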