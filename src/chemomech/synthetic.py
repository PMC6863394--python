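"""Synthetic data generators with known ground truth.

Every analysis stage in this package consumes one of five input classes:
cell tracks, micropillar image stacks, SHG-like collagen z-stacks,
FLIM-FRET lifetime traces, and capture-ELISA chase series.  The generators
here emulate each class with fully known ground-truth parameters so that
every downstream quantification can be validated by parameter recovery,
without any real microscopy data.

All randomness funnels through one ``numpy.random.Generator`` seeded per
call; no global state is touched, and a fixed seed reproduces outputs
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "TrackSimConfig",
    "PillarSimConfig",
    "FlimSimConfig",
    "ElisaSimConfig",
    "simulate_tracks",
    "simulate_pillar_stack",
    "simulate_shg_texture",
    "simulate_flim_traces",
    "simulate_elisa",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# ---------------------------------------------------------------------------
# Cell tracks: biased random walk sampled like a chemotaxis-chamber movie
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrackSimConfig:
    """Biased-random-walk track generator settings.

    Cells take one step per imaging frame.  Step headings are drawn from a
    von Mises distribution centred on ``gradient_angle`` with concentration
    ``bias_kappa`` (0 = unbiased, isotropic walk); step lengths are
    log-normal with mean ``mean_step`` and coefficient of variation
    ``step_cv`` (positive support, heavy-ish tail, like real cell speeds).

    Defaults mirror a 48 h chemotaxis-chamber experiment imaged every
    30 min.
    """

    n_cells: int = 50
    frame_interval: float = 30.0   # minutes
    duration: float = 48.0         # hours
    mean_step: float = 6.0         # µm per frame (~12 µm/h)
    step_cv: float = 0.5
    bias_kappa: float = 0.0        # von Mises concentration, >= 0
    gradient_angle: float = 0.0    # radians, direction of increasing attractant
    start_spread: float = 100.0    # µm, half-width of random start box
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ConfigError("n_cells must be >= 1")
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval must be > 0")
        if self.duration <= 0:
            raise ConfigError("duration must be > 0")
        if self.mean_step <= 0:
            raise ConfigError("mean_step must be > 0")
        if self.step_cv < 0:
            raise ConfigError("step_cv must be >= 0")
        if self.bias_kappa < 0:
            raise ConfigError("bias_kappa must be >= 0")


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and CV."""
    sigma2 = np.log(1.0 + cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def simulate_tracks(cfg: TrackSimConfig) -> pd.DataFrame:
    """Simulate biased-random-walk tracks for ``cfg.n_cells`` cells.

    Returns a long-format table with columns
    ``track_id, frame, t_min, x_um, y_um`` (one row per cell per frame),
    the same layout the track readers expect.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_frames = int(round(cfg.duration * 60.0 / cfg.frame_interval)) + 1
    n_steps = n_frames - 1
    if n_steps < 1:
        raise ConfigError("duration/frame_interval give fewer than 2 frames")

    starts = rng.uniform(-cfg.start_spread, cfg.start_spread, size=(cfg.n_cells, 2))
    if cfg.bias_kappa == 0:
        angles = rng.uniform(-np.pi, np.pi, size=(cfg.n_cells, n_steps))
    else:
        angles = rng.vonmises(cfg.gradient_angle, cfg.bias_kappa,
                              size=(cfg.n_cells, n_steps))
    if cfg.step_cv == 0:
        lengths = np.full((cfg.n_cells, n_steps), cfg.mean_step)
    else:
        mu, sigma = _lognormal_params(cfg.mean_step, cfg.step_cv)
        lengths = rng.lognormal(mu, sigma, size=(cfg.n_cells, n_steps))

    dx = lengths * np.cos(angles)
    dy = lengths * np.sin(angles)
    x = np.concatenate([starts[:, :1], starts[:, :1] + np.cumsum(dx, axis=1)], axis=1)
    y = np.concatenate([starts[:, 1:], starts[:, 1:] + np.cumsum(dy, axis=1)], axis=1)

    frames = np.arange(n_frames)
    out = pd.DataFrame({
        "track_id": np.repeat(np.arange(cfg.n_cells), n_frames),
        "frame": np.tile(frames, cfg.n_cells),
        "t_min": np.tile(frames * cfg.frame_interval, cfg.n_cells),
        "x_um": x.ravel(),
        "y_um": y.ravel(),
    })
    return out


# ---------------------------------------------------------------------------
# Micropillar arrays: Gaussian spots on a square lattice with known shifts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PillarSimConfig:
    """Synthetic micropillar-array movie settings.

    Pillars are rendered as isotropic Gaussian spots on a square lattice of
    pitch ``pitch`` µm.  Frame 0 is the undisplaced equilibrium reference;
    each later frame first applies the whole-field ``global_drift`` (pixels
    per frame, cumulative) and then the per-pillar ``displacement_map``
    (µm).  The true displacements are returned alongside the stack for
    recovery tests.
    """

    pitch: float = 1.0             # µm, centre-to-centre
    pillar_sigma: float = 0.15     # µm, Gaussian spot sigma
    n_rows: int = 10
    n_cols: int = 10
    pixel_size: float = 0.1        # µm / pixel
    n_frames: int = 2
    margin: float = 1.0            # µm blank border around the lattice
    displacement_map: dict[int, tuple[float, float]] = field(default_factory=dict)
    global_drift: tuple[float, float] = (0.0, 0.0)   # pixels per frame (dx, dy)
    noise_sd: float = 0.0          # additive Gaussian, intensity units (peak = 1)
    rotation: float = 0.0          # radians, lattice rotation
    seed: int = 0

    def validate(self) -> None:
        if self.pitch <= 2.0 * self.pillar_sigma:
            raise ConfigError("pitch must exceed 2*pillar_sigma")
        if self.pixel_size <= 0:
            raise ConfigError("pixel_size must be > 0")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ConfigError("need at least one pillar")
        if self.n_frames < 1:
            raise ConfigError("n_frames must be >= 1")
        for pid, (dx, dy) in self.displacement_map.items():
            if np.hypot(dx, dy) > self.pitch / 2.0:
                raise ConfigError(
                    f"pillar {pid}: displacement {np.hypot(dx, dy):.3f} µm exceeds "
                    f"half the pitch ({self.pitch / 2.0:.3f} µm); pillar identity "
                    "would be ambiguous"
                )


def _lattice_positions_um(cfg: PillarSimConfig) -> np.ndarray:
    """Equilibrium pillar centres in µm, shape (n_pillars, 2) as (x, y)."""
    jj, ii = np.meshgrid(np.arange(cfg.n_cols), np.arange(cfg.n_rows))
    x = cfg.margin + jj.ravel() * cfg.pitch
    y = cfg.margin + ii.ravel() * cfg.pitch
    pos = np.column_stack([x, y])
    if cfg.rotation != 0.0:
        c, s = np.cos(cfg.rotation), np.sin(cfg.rotation)
        centre = pos.mean(axis=0)
        pos = (pos - centre) @ np.array([[c, -s], [s, c]]).T + centre
    return pos


def _render_spots(centres_px: np.ndarray, shape: tuple[int, int],
                  sigma_px: float) -> np.ndarray:
    """Sum of unit-peak Gaussian spots at sub-pixel centres (x, y) in pixels."""
    img = np.zeros(shape, dtype=np.float64)
    yy = np.arange(shape[0])[:, None]
    xx = np.arange(shape[1])[None, :]
    half = int(np.ceil(5 * sigma_px))
    for cx, cy in centres_px:
        x0, x1 = max(0, int(cx) - half), min(shape[1], int(cx) + half + 1)
        y0, y1 = max(0, int(cy) - half), min(shape[0], int(cy) + half + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        sub = np.exp(-((xx[:, x0:x1] - cx) ** 2 + (yy[y0:y1, :] - cy) ** 2)
                     / (2 * sigma_px**2))
        img[y0:y1, x0:x1] += sub
    return img


def simulate_pillar_stack(cfg: PillarSimConfig) -> tuple[np.ndarray, dict]:
    """Render a pillar movie and its ground truth.

    Returns ``(stack, truth)`` where ``stack`` has shape
    ``(n_frames, H, W)`` with frame 0 the equilibrium reference, and
    ``truth`` holds the equilibrium centres (pixels), per-frame cumulative
    drift (pixels), and the per-pillar displacements (µm) applied in every
    frame after the first.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    centres_um = _lattice_positions_um(cfg)
    extent = centres_um.max(axis=0) + cfg.margin
    shape = (int(np.ceil(extent[1] / cfg.pixel_size)) + 1,
             int(np.ceil(extent[0] / cfg.pixel_size)) + 1)
    sigma_px = cfg.pillar_sigma / cfg.pixel_size

    disp_um = np.zeros_like(centres_um)
    for pid, (dx, dy) in cfg.displacement_map.items():
        disp_um[pid] = (dx, dy)

    frames = []
    drift = np.zeros((cfg.n_frames, 2))
    for f in range(cfg.n_frames):
        centres = centres_um.copy()
        if f > 0:
            centres = centres + disp_um
        centres_px = centres / cfg.pixel_size
        if f > 0:
            drift[f] = np.asarray(cfg.global_drift) * f
            centres_px = centres_px + drift[f]
        img = _render_spots(centres_px, shape, sigma_px)
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, size=shape)
        frames.append(img)

    truth = {
        "centres_px": centres_um / cfg.pixel_size,
        "displacement_um": disp_um,
        "drift_px": drift,
        "pixel_size": cfg.pixel_size,
        "pitch": cfg.pitch,
    }
    return np.stack(frames), truth


# ---------------------------------------------------------------------------
# SHG-like collagen textures
# ---------------------------------------------------------------------------

def simulate_shg_texture(mode: Literal["homogeneous", "fibrous"],
                         size: int = 256, seed: int = 0,
                         n_slices: int = 5,
                         mean_intensity: float = 120.0) -> tuple[np.ndarray, np.ndarray]:
    """Generate a synthetic collagen-like z-stack plus its foreground mask.

    ``homogeneous`` produces a nearly uniform foreground with fine
    low-amplitude speckle (a featureless, even layer); ``fibrous`` produces
    high-contrast oriented line structures — bright fibres over dim gaps —
    resembling fibrillar collagen.  Both are embedded on a dark background
    with matched foreground mean intensity, so texture differences are not
    mean-intensity differences.

    Returns ``(zstack, mask)`` with ``zstack`` of shape
    ``(n_slices, size, size)`` in [0, 255] and ``mask`` the true foreground.
    """
    if size < 64:
        raise ConfigError("size must be >= 64")
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size]
    # round-ish foreground blob covering the image centre
    cx = cy = size / 2.0
    r = size * 0.42
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 < r**2

    slices = []
    for _ in range(n_slices):
        if mode == "homogeneous":
            # even layer: small-amplitude fine speckle around the mean
            tex = gaussian_filter(rng.normal(size=(size, size)), 1.5)
            amplitude = 8.0
        elif mode == "fibrous":
            # long oriented streaks: bright fibres over dim gaps, with a
            # wide continuous intensity spread
            tex = gaussian_filter(rng.normal(size=(size, size)), (12.0, 1.0))
            amplitude = 45.0
        else:
            raise ConfigError(f"unknown mode {mode!r}")
        tex = (tex - tex[mask].mean()) / tex[mask].std()
        img = np.zeros((size, size))
        img[mask] = mean_intensity + amplitude * tex[mask]
        img += rng.normal(0.0, 2.0, size=img.shape) * ~mask  # faint background noise
        slices.append(np.clip(img, 0, 255))
    return np.stack(slices), mask


# ---------------------------------------------------------------------------
# FLIM-FRET lifetime traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlimSimConfig:
    """Step-then-exponential-decay FRET trace generator.

    True FRET efficiency sits at ``e_baseline`` before the stimulus, steps
    to ``e_peak`` at t = 30 s after stimulation, then relaxes back to
    ``e_baseline`` exponentially at ``decay_rate``.  The sensor's donor
    lifetime is ``tau_donor * (1 - E(t))`` plus Gaussian noise; a
    time-matched donor-only control at constant ``tau_donor`` (plus noise)
    is generated on the same grid.

    The sampling grid reproduces a two-phase live acquisition: baseline
    every 30 s for 5 min before the stimulus, an early phase every 30 s for
    5 min, a 60 s operator gap, then a late phase every 60 s for 30 min.
    """

    tau_donor: float = 4.0         # ns (donor-only control lifetime)
    e_baseline: float = 0.15
    e_peak: float = 0.30
    decay_rate: float = np.log(2) / 600.0   # 1/s  (t_half = 600 s)
    noise_sd: float = 0.0          # ns, on lifetimes
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.e_baseline <= self.e_peak < 1.0):
            raise ConfigError("need 0 <= e_baseline <= e_peak < 1")
        if self.tau_donor <= 0:
            raise ConfigError("tau_donor must be > 0")
        if self.decay_rate < 0:
            raise ConfigError("decay_rate must be >= 0")


def flim_time_grid() -> np.ndarray:
    """Two-phase acquisition grid in seconds relative to the stimulus.

    Baseline −300..0 s at 30 s; early phase 30..300 s at 30 s; a 60 s gap;
    late phase 360..2100 s at 60 s (the gap is real missing data, never
    interpolated).
    """
    baseline = np.arange(-300, 1, 30)
    early = np.arange(30, 301, 30)
    late = np.arange(360, 2101, 60)
    return np.concatenate([baseline, early, late]).astype(float)


def true_efficiency(t: np.ndarray, cfg: FlimSimConfig) -> np.ndarray:
    """Ground-truth E(t): step to e_peak at t = 30 s then exponential decay."""
    t = np.asarray(t, dtype=float)
    e = np.full_like(t, cfg.e_baseline)
    post = t >= 30.0
    amp = cfg.e_peak - cfg.e_baseline
    e[post] = cfg.e_baseline + amp * np.exp(-cfg.decay_rate * (t[post] - 30.0))
    return e


def simulate_flim_traces(cfg: FlimSimConfig, n_cells: int = 1
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate sensor and time-matched donor-control lifetime tables.

    Returns ``(sensor, donor)`` DataFrames with columns
    ``cell, t_s, tau_ns`` on the shared two-phase grid.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    t = flim_time_grid()
    e = true_efficiency(t, cfg)

    rows_s, rows_d = [], []
    for cell in range(n_cells):
        tau_s = cfg.tau_donor * (1.0 - e)
        tau_d = np.full_like(t, cfg.tau_donor)
        if cfg.noise_sd > 0:
            tau_s = tau_s + rng.normal(0.0, cfg.noise_sd, size=t.shape)
            tau_d = tau_d + rng.normal(0.0, cfg.noise_sd, size=t.shape)
        rows_s.append(pd.DataFrame({"cell": cell, "t_s": t, "tau_ns": tau_s}))
        rows_d.append(pd.DataFrame({"cell": cell, "t_s": t, "tau_ns": tau_d}))
    return pd.concat(rows_s, ignore_index=True), pd.concat(rows_d, ignore_index=True)


# ---------------------------------------------------------------------------
# Capture-ELISA recycling / degradation series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElisaSimConfig:
    """Two-compartment receptor chase generator.

    The internalized biotinylated pool (initial signal ``s0``) loses
    receptors to recycling at ``k_rec`` and to degradation at ``k_deg``
    (both first order, per minute).  The recycling assay's captured signal
    is the internalized-not-yet-recycled pool,
    ``S(t) = s0·exp(−(k_rec+k_deg)·t)``; the degradation assay measures the
    surviving pool ``s0·exp(−k_deg·t)``.  Noise is multiplicative
    log-normal with coefficient of variation ``noise_cv`` (plate-reader
    signals are positive and scale-proportional).
    """

    s0: float = 1.0
    k_rec: float = np.log(2) / 15.0    # 1/min
    k_deg: float = np.log(2) / 60.0    # 1/min
    chase_times: tuple[float, ...] = (0.0, 4.0, 8.0, 15.0, 30.0)
    noise_cv: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.s0 <= 0:
            raise ConfigError("s0 must be > 0")
        if self.k_rec < 0 or self.k_deg < 0:
            raise ConfigError("rates must be >= 0")


def simulate_elisa(cfg: ElisaSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate noisy recycling and degradation chase series.

    Returns ``(recycling, degradation)`` DataFrames with columns
    ``t_min, signal`` sharing ``cfg.chase_times``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    t = np.asarray(cfg.chase_times, dtype=float)

    def noisy(values: np.ndarray) -> np.ndarray:
        if cfg.noise_cv == 0:
            return values
        mu, sigma = _lognormal_params(1.0, cfg.noise_cv)
        return values * rng.lognormal(mu, sigma, size=values.shape)

    rec = cfg.s0 * np.exp(-(cfg.k_rec + cfg.k_deg) * t)
    deg = cfg.s0 * np.exp(-cfg.k_deg * t)
    recycling = pd.DataFrame({"t_min": t, "signal": noisy(rec)})
    degradation = pd.DataFrame({"t_min": t, "signal": noisy(deg)})
    return recycling, degradation
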