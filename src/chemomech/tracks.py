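"""Chemotaxis statistics on cell tracks.

A *track* is the time-stamped 2-D trajectory of one cell, manually or
automatically tracked from a chemotaxis-chamber movie.  This module applies
the inclusion rules used for chamber experiments (only cells that start on
the chamber bridge count, cells are censored once they leave it, dying
cells are excluded), then computes the chemotactic index Cosθ, cell speed,
rose/spider summaries, and the Rayleigh test for directionality.

Conventions: angles are mathematical (counterclockwise from +x, radians);
the gradient angle points toward increasing chemoattractant.  Image-origin
(y-down) data should be loaded with ``flip_y=True``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

__all__ = [
    "Track",
    "GradientSpec",
    "TrackFilterSpec",
    "ChemotaxisSummary",
    "load_tracks",
    "filter_tracks",
    "chemotactic_index",
    "track_speed",
    "rayleigh_test",
    "rose_histogram",
    "spider_coordinates",
    "cohort_summary",
]

REQUIRED_COLUMNS = ("track_id", "frame", "t_min", "x_um", "y_um")


class TrackFormatError(ValueError):
    """Malformed track table."""


@dataclass
class Track:
    """One cell's ordered, time-stamped positions (t in minutes, x/y in µm)."""

    track_id: object
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __len__(self) -> int:
        return len(self.t)

    @property
    def net_displacement(self) -> np.ndarray:
        return np.array([self.x[-1] - self.x[0], self.y[-1] - self.y[0]])


@dataclass(frozen=True)
class GradientSpec:
    """Direction of increasing chemoattractant, radians CCW from +x."""

    angle: float = 0.0

    @property
    def unit_vector(self) -> np.ndarray:
        return np.array([np.cos(self.angle), np.sin(self.angle)])


@dataclass
class TrackFilterSpec:
    """Cohort inclusion rules for chamber experiments.

    ``start_region`` is the bridge polygon in µm; tracks must start inside
    it, and with ``censor_on_exit`` each track is truncated at its first
    exit.  ``excluded_ids`` drops cells flagged by the experimenter (e.g.
    dying cells); tracks shorter than ``min_points`` after truncation are
    removed.
    """

    start_region: Polygon | None = None
    censor_on_exit: bool = True
    excluded_ids: set = field(default_factory=set)
    min_points: int = 2

    def __post_init__(self) -> None:
        if self.start_region is not None and not self.start_region.is_valid:
            raise ValueError("start_region polygon must be simple and closed")
        if self.min_points < 2:
            raise ValueError("min_points must be >= 2")


@dataclass
class ChemotaxisSummary:
    """Cohort-level chemotaxis statistics (one Cosθ and speed per cell)."""

    per_cell: pd.DataFrame          # track_id, cos_theta, speed_um_h, angle
    n: int
    n_excluded_undefined: int
    mean_cos_theta: float
    sem_cos_theta: float
    mean_speed: float
    sem_speed: float
    resultant_length: float
    rayleigh_z: float
    rayleigh_p: float


# ---------------------------------------------------------------------------
# loading and filtering
# ---------------------------------------------------------------------------

def load_tracks(table: pd.DataFrame | str, flip_y: bool = False) -> list[Track]:
    """Build :class:`Track` objects from a long-format table (or CSV path).

    Rows are grouped by ``track_id`` and sorted by time.  Duplicate
    (track_id, frame) pairs and non-numeric coordinates are format errors.
    With ``flip_y`` the y axis is negated, converting image-origin (y-down)
    coordinates to the mathematical convention used throughout.
    """
    if isinstance(table, str):
        table = pd.read_csv(table)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise TrackFormatError(f"missing required columns: {missing}")

    for col in ("t_min", "x_um", "y_um"):
        vals = pd.to_numeric(table[col], errors="coerce")
        if vals.isna().any():
            bad = table.loc[vals.isna(), "track_id"].unique()
            raise TrackFormatError(
                f"non-numeric {col} in track(s) {list(bad)!r}")
    table = table.assign(**{c: pd.to_numeric(table[c]) for c in ("t_min", "x_um", "y_um")})

    tracks = []
    for tid, grp in table.groupby("track_id", sort=True):
        if grp["frame"].duplicated().any():
            raise TrackFormatError(f"duplicate frame in track {tid!r}")
        grp = grp.sort_values("t_min")
        if not np.all(np.diff(grp["t_min"].to_numpy()) > 0):
            raise TrackFormatError(f"non-increasing timestamps in track {tid!r}")
        y = grp["y_um"].to_numpy(dtype=float)
        tracks.append(Track(track_id=tid,
                            t=grp["t_min"].to_numpy(dtype=float),
                            x=grp["x_um"].to_numpy(dtype=float),
                            y=-y if flip_y else y))
    return tracks


def filter_tracks(tracks: list[Track], spec: TrackFilterSpec
                  ) -> tuple[list[Track], Counter]:
    """Apply cohort inclusion rules; returns surviving tracks and an audit log.

    The audit :class:`~collections.Counter` tallies removals by reason:
    ``excluded_id``, ``start_outside``, ``too_short`` (and ``kept``).
    """
    kept: list[Track] = []
    audit: Counter = Counter()
    for tr in tracks:
        if tr.track_id in spec.excluded_ids:
            audit["excluded_id"] += 1
            continue
        if spec.start_region is not None:
            if not spec.start_region.covers(Point(tr.x[0], tr.y[0])):
                audit["start_outside"] += 1
                continue
            if spec.censor_on_exit:
                inside = np.fromiter(
                    (spec.start_region.covers(Point(px, py))
                     for px, py in zip(tr.x, tr.y)), dtype=bool, count=len(tr))
                exits = np.flatnonzero(~inside)
                if exits.size:
                    k = exits[0]           # keep points before first exit
                    tr = Track(tr.track_id, tr.t[:k], tr.x[:k], tr.y[:k])
        if len(tr) < spec.min_points:
            audit["too_short"] += 1
            continue
        kept.append(tr)
        audit["kept"] += 1
    return kept, audit


# ---------------------------------------------------------------------------
# per-cell statistics
# ---------------------------------------------------------------------------

def chemotactic_index(track: Track, gradient: GradientSpec,
                      mode: str = "net") -> float:
    """Chemotactic index Cosθ of one cell.

    ``mode="net"`` (default): cosine of the angle between the cell's net
    displacement (end − start) and the gradient direction — one value per
    cell, as plotted in per-cell scatter summaries.  ``mode="per_step"``:
    mean of per-step cosines over steps with nonzero length.

    Returns ``nan`` when the index is undefined (zero net displacement, or
    no nonzero steps); callers should exclude and report such cells.
    """
    if len(track) < 2:
        raise ValueError("track needs at least 2 points")
    g = gradient.unit_vector
    if mode == "net":
        d = track.net_displacement
        norm = np.hypot(*d)
        if norm == 0:
            return float("nan")
        return float(d @ g / norm)
    if mode == "per_step":
        dx = np.diff(track.x)
        dy = np.diff(track.y)
        norms = np.hypot(dx, dy)
        ok = norms > 0
        if not ok.any():
            return float("nan")
        return float(np.mean((dx[ok] * g[0] + dy[ok] * g[1]) / norms[ok]))
    raise ValueError(f"unknown mode {mode!r}")


def track_speed(track: Track) -> float:
    """Mean speed in µm/h: total path length over elapsed time."""
    if len(track) < 2:
        raise ValueError("track needs at least 2 points")
    elapsed_min = track.t[-1] - track.t[0]
    if elapsed_min <= 0:
        raise ValueError("zero elapsed time")
    path = float(np.sum(np.hypot(np.diff(track.x), np.diff(track.y))))
    return path / (elapsed_min / 60.0)


# ---------------------------------------------------------------------------
# circular statistics
# ---------------------------------------------------------------------------

def rayleigh_test(angles: np.ndarray) -> tuple[float, float, float]:
    """Rayleigh test of circular uniformity.

    Returns ``(r_bar, Z, p)`` with mean resultant length
    R̄ = |n⁻¹ Σ e^{iθ}|, statistic Z = n·R̄², and the standard series
    approximation p = exp(√(1+4n+4(n²−(nR̄)²)) − (1+2n)), clamped to (0, 1].
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size < 3 or not np.all(np.isfinite(angles)):
        raise ValueError("need at least 3 finite angles")
    n = angles.size
    c = np.cos(angles).sum()
    s = np.sin(angles).sum()
    r_bar = np.hypot(c, s) / n
    z = n * r_bar**2
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n**2 - (n * r_bar) ** 2))
               - (1.0 + 2.0 * n))
    p = float(min(max(p, np.finfo(float).tiny), 1.0))
    return float(r_bar), float(z), p


def rose_histogram(angles: np.ndarray, n_bins: int = 12
                   ) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Equal-width angular histogram over [0, 2π) plus the resultant vector.

    Returns ``(counts, bin_edges, (r_bar, mean_angle))``.
    """
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    angles = np.mod(np.asarray(angles, dtype=float), 2 * np.pi)
    edges = np.linspace(0.0, 2 * np.pi, n_bins + 1)
    counts, _ = np.histogram(angles, bins=edges)
    c = np.cos(angles).sum()
    s = np.sin(angles).sum()
    n = max(angles.size, 1)
    return counts, edges, (float(np.hypot(c, s) / n), float(np.arctan2(s, c)))


def spider_coordinates(tracks: list[Track]) -> list[Track]:
    """Translate every track so its first point is the origin (shape kept)."""
    return [Track(tr.track_id, tr.t.copy(), tr.x - tr.x[0], tr.y - tr.y[0])
            for tr in tracks]


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

def cohort_summary(tracks: list[Track], gradient: GradientSpec,
                   mode: str = "net") -> ChemotaxisSummary:
    """Per-cell Cosθ and speed with cohort mean ± SEM and the Rayleigh test.

    The Rayleigh test is run on per-cell net-displacement angles (one angle
    per cell — cells, not steps, are the unit of directionality).  Cells
    with an undefined index (zero net displacement) are excluded from the
    cohort statistics and counted in ``n_excluded_undefined``.
    """
    if not tracks:
        raise ValueError("need at least one track")
    rows = []
    for tr in tracks:
        ct = chemotactic_index(tr, gradient, mode=mode)
        d = tr.net_displacement
        rows.append({
            "track_id": tr.track_id,
            "cos_theta": ct,
            "speed_um_h": track_speed(tr),
            "net_angle": np.arctan2(d[1], d[0]) if np.hypot(*d) > 0 else np.nan,
        })
    per_cell = pd.DataFrame(rows)
    valid = per_cell.dropna(subset=["cos_theta"])
    n = len(valid)
    if n == 0:
        raise ValueError("no track has a defined chemotactic index")
    ct = valid["cos_theta"].to_numpy()
    sp = valid["speed_um_h"].to_numpy()
    sem = lambda v: float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0

    ang = valid["net_angle"].dropna().to_numpy()
    if ang.size >= 3:
        r_bar, z, p = rayleigh_test(ang)
    else:
        r_bar, z, p = float("nan"), float("nan"), float("nan")

    return ChemotaxisSummary(
        per_cell=per_cell,
        n=n,
        n_excluded_undefined=len(per_cell) - n,
        mean_cos_theta=float(ct.mean()),
        sem_cos_theta=sem(ct),
        mean_speed=float(sp.mean()),
        sem_speed=sem(sp),
        resultant_length=r_bar,
        rayleigh_z=z,
        rayleigh_p=p,
    )
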