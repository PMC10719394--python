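"""Eutrophication change-assessment statistics on gridded scenario differences.

Vertical integrals/averages over fixed depth windows, scenario differencing,
normalized Bightwide % change with interannual SEM, inshore/offshore band
statistics, "considerable value" areas (|delta| beyond a threshold, default
10 mmol m-2 d-1), distance-from-coast cross sections and mean vertical
profiles.

Sign convention for the normalized change: per year,
``100 * (scenario - ANTH) / (ANTH - CTRL)`` — nutrient-reduction scenarios
yield negative values.  Bightwide means are area-weighted (a plain-mean
toggle is provided).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from eutroscen.grid import Grid


class WindowError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


def _layer_window_weights(grid: Grid, window: Tuple[float, float]) -> np.ndarray:
    """Per-layer thickness (m) of overlap with the depth window, shape (nz,)."""
    top, bot = window
    edges = grid.z_edges()
    if top < 0 or bot <= top:
        raise WindowError(f"bad depth window {window}")
    if top >= edges[-1]:
        raise WindowError(f"window {window} lies below the deepest layer edge {edges[-1]}")
    lo = np.clip(edges[:-1], top, bot)
    hi = np.clip(edges[1:], top, bot)
    return hi - lo


def integrate_vertical(field: np.ndarray, grid: Grid, window: Tuple[float, float] = (0.0, 100.0)) -> np.ndarray:
    """Thickness-weighted vertical integral over the window (rate -> mmol m-2 d-1).

    ``field`` is (..., nz, ny, nx) with NaN below bottom; partial layers are
    weighted by their overlap with the window, and columns shallower than the
    window integrate down to bathymetry.  Land columns return NaN.
    """
    field = np.asarray(field, dtype=float)
    w = _layer_window_weights(grid, window)
    wfull = w.reshape((-1, 1, 1))
    wet = np.isfinite(field)
    contrib = np.where(wet, field, 0.0) * wfull
    out = contrib.sum(axis=-3)
    any_wet = wet.any(axis=-3)
    return np.where(any_wet, out, np.nan)


def average_vertical(field: np.ndarray, grid: Grid, window: Tuple[float, float] = (0.0, 200.0)) -> np.ndarray:
    """Thickness-weighted vertical mean over the window (same units as field).

    The companion integral form is ``integrate_vertical`` with the same
    window; both presentations are standard for respiration maps.
    """
    field = np.asarray(field, dtype=float)
    w = _layer_window_weights(grid, window).reshape((-1, 1, 1))
    wet = np.isfinite(field)
    num = (np.where(wet, field, 0.0) * w).sum(axis=-3)
    den = (np.where(wet, 1.0, 0.0) * w).sum(axis=-3)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def annual_means(time_index, series: np.ndarray, year_end_month: int = 10) -> Tuple[np.ndarray, np.ndarray]:
    """Group a time series into Nov-Oct years (year labelled by its ending year).

    Returns (year_labels, annual_mean_values).
    """
    months = np.asarray(time_index.month)
    years = np.asarray(time_index.year)
    label = np.where(months > year_end_month, years + 1, years)
    uniq = np.unique(label)
    means = np.array([np.nanmean(series[label == y]) for y in uniq])
    return uniq, means


@dataclass
class NormalizedChange:
    """Bightwide normalized % change with interannual spread."""

    mean_pct: float
    sem_pct: Optional[float]
    per_year_pct: np.ndarray
    n_years: int


def normalized_change(
    scenario_series: np.ndarray,
    anth_series: np.ndarray,
    ctrl_series: np.ndarray,
    denominator_floor: float = 1e-12,
) -> NormalizedChange:
    """Per year, 100 * (S - ANTH)/(ANTH - CTRL); mean and SEM over years.

    Years where |ANTH - CTRL| < floor are masked.  SEM = sd / sqrt(n) is
    reported as None when fewer than two usable years remain.
    """
    s = np.atleast_1d(np.asarray(scenario_series, dtype=float))
    a = np.atleast_1d(np.asarray(anth_series, dtype=float))
    c = np.atleast_1d(np.asarray(ctrl_series, dtype=float))
    if not (s.shape == a.shape == c.shape):
        raise AlignmentError("scenario/ANTH/CTRL series must share length")
    denom = a - c
    ok = np.abs(denom) >= denominator_floor
    vals = np.full(s.shape, np.nan)
    vals[ok] = 100.0 * (s[ok] - a[ok]) / denom[ok]
    usable = vals[np.isfinite(vals)]
    n = usable.size
    mean = float(np.mean(usable)) if n else float("nan")
    sem = float(np.std(usable, ddof=1) / np.sqrt(n)) if n >= 2 else None
    return NormalizedChange(mean_pct=mean, sem_pct=sem, per_year_pct=vals, n_years=n)


def bightwide_mean(field2d: np.ndarray, grid: Grid, area_weighted: bool = True) -> float:
    """Domain mean of a 2-D diagnostic over ocean cells (area-weighted by default)."""
    valid = np.isfinite(field2d) & ~grid.land_mask
    if not valid.any():
        return float("nan")
    if area_weighted:
        w = grid.cell_area[valid]
        return float(np.sum(field2d[valid] * w) / np.sum(w))
    return float(np.mean(field2d[valid]))


@dataclass
class BandStats:
    """Inshore/offshore statistics of a scenario-difference map."""

    band: str
    mean_decline: float  # area-weighted mean of -delta (signed)
    p95_decline: float  # 95th pct of positive declines, area-weighted quantile
    area_above_km2: float  # delta > +threshold
    area_below_km2: float  # delta < -threshold
    band_area_km2: float


def _band_masks(grid: Grid, band_km: float) -> Tuple[np.ndarray, np.ndarray]:
    if grid.dist_coast is None:
        raise AlignmentError("grid has no dist_coast; provide land in the grid")
    ocean = ~grid.land_mask
    inshore = ocean & (grid.dist_coast <= band_km)
    offshore = ocean & (grid.dist_coast > band_km)
    return inshore, offshore


def weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Weighted empirical quantile, linear interpolation; reduces to the
    standard (n-1)-spacing linear quantile for equal weights."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        return float("nan")
    order = np.argsort(v)
    v, w = v[order], w[order]
    cw = np.cumsum(w)
    total = cw[-1]
    if v.size == 1 or total == w[-1]:
        return float(v[-1]) if v.size == 1 else float(np.interp(q, [0, 1], [v[0], v[-1]]))
    pos = (cw - w) / (total - w[-1])
    pos = np.clip(pos, 0.0, 1.0)
    return float(np.interp(q, pos, v))


def considerable_area(
    delta: np.ndarray,
    grid: Grid,
    threshold: float = 10.0,
    band_km: float = 15.0,
) -> Tuple[BandStats, BandStats]:
    """Areas (km^2) with delta strictly beyond +-threshold, split inshore/offshore."""
    if delta.shape != grid.shape:
        raise AlignmentError("delta map does not match the grid")
    out = []
    for name, mask in zip(("inshore", "offshore"), _band_masks(grid, band_km)):
        sel = mask & np.isfinite(delta)
        area = grid.cell_area / 1e6
        out.append(
            BandStats(
                band=name,
                mean_decline=_area_mean(-delta, sel, area),
                p95_decline=_decline_p95(delta, sel, area),
                area_above_km2=float(area[sel & (delta > threshold)].sum()),
                area_below_km2=float(area[sel & (delta < -threshold)].sum()),
                band_area_km2=float(area[sel].sum()),
            )
        )
    return tuple(out)


def _area_mean(field: np.ndarray, sel: np.ndarray, area: np.ndarray) -> float:
    if not sel.any():
        return float("nan")
    return float(np.sum(field[sel] * area[sel]) / np.sum(area[sel]))


def _decline_p95(delta: np.ndarray, sel: np.ndarray, area: np.ndarray) -> float:
    declines = -delta
    pos = sel & (declines > 0)
    if not pos.any():
        return float("nan")
    return weighted_quantile(declines[pos], area[pos], 0.95)


def band_stats(delta: np.ndarray, grid: Grid, band_km: float = 15.0) -> BandStats:
    """Inshore-band statistics: signed area-weighted mean decline and the 95th
    percentile of the decline-magnitude distribution (declines only)."""
    if delta.shape != grid.shape:
        raise AlignmentError("delta map does not match the grid")
    inshore, _ = _band_masks(grid, band_km)
    sel = inshore & np.isfinite(delta)
    if not sel.any():
        raise AlignmentError("empty inshore band")
    area = grid.cell_area / 1e6
    return BandStats(
        band="inshore",
        mean_decline=_area_mean(-delta, sel, area),
        p95_decline=_decline_p95(delta, sel, area),
        area_above_km2=float("nan"),
        area_below_km2=float("nan"),
        band_area_km2=float(area[sel].sum()),
    )


@dataclass
class CrossSection:
    """Alongshore-averaged (depth x distance-from-coast) section."""

    bin_edges_km: np.ndarray
    z_centers: np.ndarray
    section: np.ndarray  # (nz_window, nbins), NaN for empty bins
    profile: np.ndarray  # (nz_window,) Bightwide mean per layer


def cross_section(
    delta3d: np.ndarray,
    grid: Grid,
    bins_km: Optional[Sequence[float]] = None,
    window: Tuple[float, float] = (0.0, 200.0),
) -> CrossSection:
    """Mean over all columns per distance-from-coast bin, per depth layer.

    ``delta3d`` is (nz, ny, nx).  Default bins: 5 km from 0 to 150 km.
    """
    if delta3d.shape[1:] != grid.shape:
        raise AlignmentError("field does not match the grid")
    edges = np.asarray(bins_km if bins_km is not None else np.arange(0.0, 155.0, 5.0), dtype=float)
    in_window = (grid.z_centers >= window[0]) & (grid.z_centers <= window[1])
    zsel = np.nonzero(in_window)[0]
    sub = delta3d[zsel]
    if grid.dist_coast is None:
        raise AlignmentError("grid has no dist_coast")
    dist = grid.dist_coast
    ocean = ~grid.land_mask
    nb = edges.size - 1
    section = np.full((zsel.size, nb), np.nan)
    idx = np.digitize(dist, edges) - 1
    for b in range(nb):
        cols = ocean & (idx == b)
        if not cols.any():
            continue
        vals = sub[:, cols]
        with np.errstate(invalid="ignore"):
            any_fin = np.isfinite(vals).any(axis=1)
            section[any_fin, b] = np.nanmean(vals[any_fin], axis=1)
    flat = sub[:, ocean]
    profile = np.full(zsel.size, np.nan)
    fin = np.isfinite(flat).any(axis=1)
    profile[fin] = np.nanmean(flat[fin], axis=1)
    return CrossSection(
        bin_edges_km=edges, z_centers=grid.z_centers[zsel], section=section, profile=profile
    )
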