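"""Fixed-kernel home-range estimation.

Estimates the utilization distribution (UD) of an animal from telemetry
relocations with an isotropic Gaussian kernel and a single global
("fixed") bandwidth, extracts nested isopleths (the smallest-area region
containing p% of the UD mass) at 1% resolution, and selects the bandwidth
multiplier by cohesion/extent criteria: starting from the smallest
candidate multiplier of the reference bandwidth, accept the first UD whose
90th/95th isopleths neither fragment into many pieces nor extend far
beyond the relocation data, falling back to the reference bandwidth
itself.

Coordinates are projected metres throughout; densities are per m^2.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from typing import Iterable, Sequence
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "TelemetryTrack",
    "UtilizationDistribution",
    "IsoplethSet",
    "reference_bandwidth",
    "estimate_ud",
    "isopleths",
    "select_bandwidth",
    "ud_at",
    "isopleth_percentile_at",
    "period_relocations",
    "PERIODS",
]

#: Named estimation periods (month, day) boundaries, inclusive.
#: The annual period spans a study year (1 Oct - 30 Sep); the seasonal
#: periods exclude the 16 Mar - 31 May reproductive window.
PERIODS = ("Annual", "FallWinter", "Summer")

#: Minimum relocations for a seasonal UD (annual floor is lower).
MIN_RELOCATIONS_SEASONAL = 25
MIN_RELOCATIONS_ANNUAL = 5


@dataclass
class TelemetryTrack:
    """One animal's relocations and tracking window.

    Parameters
    ----------
    animal_id : str
    sex : {"F", "M"}
    tracking_start, tracking_end : datetime.date
        The period the animal was actively tracked (collar on, alive).
    relocations : pandas.DataFrame
        Columns ``date`` (datetime64), ``x``, ``y`` (metres).
    """

    animal_id: str
    sex: str
    tracking_start: dt.date
    tracking_end: dt.date
    relocations: pd.DataFrame

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        req = {"date", "x", "y"}
        if not req.issubset(self.relocations.columns):
            raise ValueError(f"relocations must have columns {sorted(req)}")

    @property
    def n(self) -> int:
        return len(self.relocations)

    def points(self) -> np.ndarray:
        """Relocation coordinates as an (n, 2) float array."""
        return self.relocations[["x", "y"]].to_numpy(dtype=float)


def _in_period(dates: pd.Series, period: str) -> np.ndarray:
    d = pd.to_datetime(dates)
    m, day = d.dt.month.to_numpy(), d.dt.day.to_numpy()
    fallwinter = (m >= 10) | (m <= 2) | ((m == 3) & (day <= 15))
    summer = (m >= 6) & (m <= 9)
    if period == "FallWinter":
        return fallwinter
    if period == "Summer":
        return summer
    if period == "Annual":
        return np.ones(len(d), dtype=bool)
    raise ValueError(f"unknown period {period!r}")


def period_relocations(track: TelemetryTrack, period: str) -> pd.DataFrame:
    """Relocations of `track` falling in the named period.

    ``Annual`` keeps everything; the two seasonal periods keep only their
    own dates, implicitly dropping the 16 Mar - 31 May window.
    """
    mask = _in_period(track.relocations["date"], period)
    return track.relocations.loc[mask].reset_index(drop=True)


def reference_bandwidth(points: np.ndarray) -> float:
    """Bivariate-normal reference bandwidth (metres).

    h_ref = sqrt((s_x^2 + s_y^2) / 2) * n^(-1/6)

    with s_x, s_y the marginal sample standard deviations. This is the
    plug-in rule that is optimal for an underlying bivariate normal and
    is the conventional starting point that candidate multipliers scale.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = pts.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points for a reference bandwidth")
    sx, sy = pts[:, 0].std(ddof=1), pts[:, 1].std(ddof=1)
    if sx == 0.0 and sy == 0.0:
        raise ValueError("degenerate variance: all points identical")
    return float(np.sqrt((sx**2 + sy**2) / 2.0) * n ** (-1.0 / 6.0))


@dataclass
class UtilizationDistribution:
    """A gridded kernel utilization distribution.

    ``density[iy, ix]`` is the estimated density (per m^2) at the cell
    centre ``(x0 + (ix + 0.5) * cell, y0 + (iy + 0.5) * cell)``; the row
    index runs with increasing y. ``x0, y0`` is the lower-left corner of
    the grid.
    """

    animal_id: str
    period: str
    x0: float
    y0: float
    cell: float
    density: np.ndarray
    bandwidth: float
    multiplier: float
    n_points: int

    @property
    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.density.shape[1]) + 0.5) * self.cell

    @property
    def y_centers(self) -> np.ndarray:
        return self.y0 + (np.arange(self.density.shape[0]) + 0.5) * self.cell

    def mass(self) -> float:
        """Total probability mass by cell summation (should be ~1)."""
        return float(self.density.sum() * self.cell**2)


def estimate_ud(
    track: TelemetryTrack | np.ndarray,
    bandwidth: float,
    cell: float | None = None,
    period: str = "Annual",
    margin_bandwidths: float = 4.0,
    min_relocations: int | None = None,
) -> UtilizationDistribution:
    """Fixed-kernel UD from relocations.

    density(x) = (1/n) * sum_j N(x; x_j, h^2 I)

    The grid extends ``margin_bandwidths * h`` beyond the data bounding
    box on every side so that cell summation captures the full kernel
    mass (4 bandwidths keeps the truncated mass below 1e-3), and the cell
    size defaults to h/4 (a resolution guard rejects cells coarser than
    h/2).
    """
    if isinstance(track, TelemetryTrack):
        rel = period_relocations(track, period)
        floor = min_relocations
        if floor is None:
            floor = (
                MIN_RELOCATIONS_ANNUAL
                if period == "Annual"
                else MIN_RELOCATIONS_SEASONAL
            )
        if len(rel) < floor:
            raise ValueError(
                f"{track.animal_id}/{period}: {len(rel)} relocations "
                f"< required floor {floor}"
            )
        pts = rel[["x", "y"]].to_numpy(dtype=float)
        animal_id, sex_n = track.animal_id, len(rel)
    else:
        pts = np.asarray(track, dtype=float)
        animal_id, sex_n = "", len(pts)

    h = float(bandwidth)
    if not h > 0:
        raise ValueError("bandwidth must be positive")
    if cell is None:
        cell = h / 4.0
    if cell > h / 2.0:
        raise ValueError(
            f"cell size {cell:.1f} m too coarse for bandwidth {h:.1f} m; "
            f"need cell <= {h / 2.0:.1f} m"
        )

    margin = margin_bandwidths * h
    xmin, ymin = pts.min(axis=0) - margin
    xmax, ymax = pts.max(axis=0) + margin
    nx = int(np.ceil((xmax - xmin) / cell))
    ny = int(np.ceil((ymax - ymin) / cell))
    gx = xmin + (np.arange(nx) + 0.5) * cell
    gy = ymin + (np.arange(ny) + 0.5) * cell

    # Separable Gaussian: density = Ky @ Kx.T / (n * 2*pi*h^2)
    kx = np.exp(-0.5 * ((gx[:, None] - pts[None, :, 0]) / h) ** 2)
    ky = np.exp(-0.5 * ((gy[:, None] - pts[None, :, 1]) / h) ** 2)
    dens = (ky @ kx.T) / (len(pts) * 2.0 * np.pi * h**2)

    return UtilizationDistribution(
        animal_id=animal_id,
        period=period,
        x0=float(xmin),
        y0=float(ymin),
        cell=float(cell),
        density=dens,
        bandwidth=h,
        multiplier=np.nan,
        n_points=sex_n,
    )


@dataclass
class IsoplethSet:
    """Density thresholds, areas and fragment counts by isopleth percentile.

    ``threshold(p)`` is the smallest density level such that cells at or
    above it hold at least p% of the total mass; ``area(p)`` is the grid
    area of those cells in hectares; ``fragments(p)`` counts 4-connected
    components of the region.
    """

    percentiles: tuple[int, ...]
    thresholds: dict[int, float] = field(repr=False)
    areas_ha: dict[int, float] = field(repr=False)
    fragment_counts: dict[int, int] = field(repr=False)

    def threshold(self, p: int) -> float:
        return self.thresholds[p]

    def area(self, p: int) -> float:
        return self.areas_ha[p]

    def fragments(self, p: int) -> int:
        return self.fragment_counts[p]


_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def isopleths(
    ud: UtilizationDistribution, percentiles: Iterable[int] = range(1, 100)
) -> IsoplethSet:
    """Extract isopleth thresholds/areas/fragment counts from a UD grid.

    Mass is accumulated over cells sorted by decreasing density; the
    threshold for p is the density of the first cell at which cumulative
    mass reaches p% (so the region's mass overshoots p% by at most one
    cell's mass -- the "1% accuracy" convention at usual resolutions).
    """
    percentiles = tuple(int(p) for p in percentiles)
    if not percentiles:
        raise ValueError("no percentiles requested")
    if min(percentiles) < 1 or max(percentiles) > 99:
        raise ValueError("percentiles must lie in [1, 99]")
    dens = ud.density
    if dens.size == 0 or dens.sum() <= 0:
        raise ValueError("empty utilization distribution")

    flat = np.sort(dens.ravel())[::-1]
    cum = np.cumsum(flat)
    total = cum[-1]
    thresholds: dict[int, float] = {}
    areas: dict[int, float] = {}
    frags: dict[int, int] = {}
    for p in percentiles:
        idx = int(np.searchsorted(cum, (p / 100.0) * total, side="left"))
        idx = min(idx, len(flat) - 1)
        thr = float(flat[idx])
        mask = dens >= thr
        thresholds[p] = thr
        areas[p] = float(mask.sum() * ud.cell**2 / 1e4)
        frags[p] = int(ndimage.label(mask, structure=_FOUR_CONN)[1])
    return IsoplethSet(percentiles, thresholds, areas, frags)


def ud_at(ud: UtilizationDistribution, points: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of the UD at arbitrary points.

    Points beyond the grid get density 0. A query exactly on a grid node
    returns the stored value.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    interp = RegularGridInterpolator(
        (ud.y_centers, ud.x_centers),
        ud.density,
        method="linear",
        bounds_error=False,
        fill_value=0.0,
    )
    out = interp(np.column_stack([pts[:, 1], pts[:, 0]]))
    return out if np.asarray(points).ndim == 2 else float(out[0])


def isopleth_percentile_at(
    ud: UtilizationDistribution,
    isos: IsoplethSet,
    point: Sequence[float],
    truncate_at: int | None = 90,
) -> int | None:
    """Smallest isopleth percentile whose region contains `point`.

    Returns ``None`` ("outside") when the density at the point falls
    below the truncation isopleth's threshold (default the 90%, the
    conventional maximum home-range extent beyond which kernel tails are
    unreliable). Requires `isos` computed at 1% steps.
    """
    d = float(ud_at(ud, np.asarray(point, dtype=float)))
    if truncate_at is not None and d < isos.threshold(truncate_at):
        return None
    for p in sorted(isos.percentiles):
        if d >= isos.threshold(p):
            return p
    return None


def select_bandwidth(
    track: TelemetryTrack | np.ndarray,
    multipliers: Sequence[float] = (0.6, 0.7, 0.8, 0.9),
    fallback: float = 1.0,
    period: str = "Annual",
    cell: float | None = None,
    max_fragments: int = 3,
    extent_margin: float = 2.0,
    apply_criteria: bool = True,
    min_relocations: int | None = None,
) -> tuple[float, UtilizationDistribution, pd.DataFrame]:
    """Pick the smallest bandwidth multiplier passing cohesion/extent tests.

    The reference bandwidth oversmooths, so candidate multipliers are
    tried in ascending order and the first one wins whose UD satisfies

    * cohesion -- the 90th and 95th isopleths have at most
      `max_fragments` 4-connected fragments each, and
    * extent -- the 95th isopleth's bounding box exceeds the relocation
      bounding box by at most ``extent_margin * h`` on every side.

    If none passes, the reference bandwidth (multiplier `fallback`) is
    used. Returns (multiplier, UD, per-multiplier diagnostics).
    """
    if list(multipliers) != sorted(multipliers):
        raise ValueError("multipliers must be sorted ascending")
    if isinstance(track, TelemetryTrack):
        pts = period_relocations(track, period)[["x", "y"]].to_numpy(dtype=float)
    else:
        pts = np.asarray(track, dtype=float)
    h_ref = reference_bandwidth(pts)
    data_min, data_max = pts.min(axis=0), pts.max(axis=0)

    rows = []
    chosen: tuple[float, UtilizationDistribution] | None = None
    for m in list(multipliers) + [fallback]:
        h = m * h_ref
        ud = estimate_ud(
            track, h, cell=cell, period=period, min_relocations=min_relocations
        )
        ud.multiplier = m
        isos = isopleths(ud, (90, 95))
        frag = max(isos.fragments(90), isos.fragments(95))
        mask95 = ud.density >= isos.threshold(95)
        iy, ix = np.nonzero(mask95)
        bb_min = np.array(
            [ud.x_centers[ix.min()] - ud.cell / 2, ud.y_centers[iy.min()] - ud.cell / 2]
        )
        bb_max = np.array(
            [ud.x_centers[ix.max()] + ud.cell / 2, ud.y_centers[iy.max()] + ud.cell / 2]
        )
        overshoot = float(
            max(np.max(data_min - bb_min), np.max(bb_max - data_max))
        )
        cohesive = frag <= max_fragments
        contained = overshoot <= extent_margin * h
        passes = (not apply_criteria) or (cohesive and contained)
        rows.append(
            dict(
                multiplier=m,
                bandwidth=h,
                fragments=frag,
                overshoot_m=overshoot,
                cohesive=cohesive,
                contained=contained,
                selected=False,
            )
        )
        if chosen is None and (passes or m == fallback):
            chosen = (m, ud)
            rows[-1]["selected"] = True
    assert chosen is not None
    diag = pd.DataFrame(rows)
    return chosen[0], chosen[1], diag
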