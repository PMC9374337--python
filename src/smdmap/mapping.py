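"""Per-pixel diffusion maps and per-region diffusion estimates."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import DEFAULT_DT, DEFAULT_R_MAX, DisplacementFitResults, DisplacementModel
from .segmentation import CellRecord, RegionPartition, _point_columns

PIXEL_SIZES = (50, 100, 150, 200)

__all__ = ["DiffusionMap", "RegionFits", "fit_pixel_map", "fit_regions", "PIXEL_SIZES"]


@dataclass
class DiffusionMap:
    """Grid of per-pixel diffusion estimates over a cell's bounding box.

    ``d`` and ``k`` hold per-pixel estimates (NaN where the pixel had
    fewer than ``min_per_pixel`` displacements); ``counts`` the per-pixel
    displacement counts. ``complete`` is True when every occupied pixel
    could be fitted; otherwise ``recommended_pixel_size`` suggests the
    next larger size from the standard ladder.
    """

    pixel_size_nm: float
    x_min_nm: float
    y_min_nm: float
    d: np.ndarray
    k: np.ndarray
    counts: np.ndarray
    min_per_pixel: int
    dt: float
    r_max: float
    background: bool
    complete: bool
    recommended_pixel_size: float | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.d.shape

    def fitted_values(self) -> np.ndarray:
        return self.d[np.isfinite(self.d)]


def fit_pixel_map(
    cell: CellRecord | pd.DataFrame,
    pixel_size: float = 100.0,
    min_per_pixel: int = 10,
    dt: float | None = None,
    r_max: float = DEFAULT_R_MAX,
    background: bool = True,
) -> DiffusionMap:
    """Bin displacements by origin into a pixel grid and fit each pixel.

    Each displacement contributes to exactly one pixel, the one containing
    its origin. Pixels with at least ``min_per_pixel`` displacements are
    fitted independently by maximum likelihood; the rest stay missing. If
    any occupied pixel is below the threshold the map is incomplete and
    the next larger standard pixel size is recommended.
    """
    df = cell.displacements if isinstance(cell, CellRecord) else cell
    if df.empty:
        raise ValueError("no displacements to map")
    if dt is None:
        dt = df.attrs.get("dt", DEFAULT_DT)
    xc, yc = _point_columns(df)
    x = df[xc].to_numpy(float)
    y = df[yc].to_numpy(float)
    r = df["r_nm"].to_numpy(float)
    x0, y0 = x.min(), y.min()
    nx = max(int(np.floor((x.max() - x0) / pixel_size)) + 1, 1)
    ny = max(int(np.floor((y.max() - y0) / pixel_size)) + 1, 1)
    ix = np.minimum(((x - x0) / pixel_size).astype(int), nx - 1)
    iy = np.minimum(((y - y0) / pixel_size).astype(int), ny - 1)
    flat = ix * ny + iy
    counts = np.bincount(flat, minlength=nx * ny).reshape(nx, ny)
    d_grid = np.full((nx, ny), np.nan)
    k_grid = np.full((nx, ny), np.nan)
    order = np.argsort(flat, kind="stable")
    flat_sorted, r_sorted = flat[order], r[order]
    uniq, starts = np.unique(flat_sorted, return_index=True)
    for u, chunk in zip(uniq, np.split(r_sorted, starts[1:])):
        if chunk.size < min_per_pixel:
            continue
        res = DisplacementModel(chunk, dt=dt, r_max=r_max, background=background).fit()
        if res.converged:
            d_grid[u // ny, u % ny] = res.d
            k_grid[u // ny, u % ny] = res.k
    complete = not np.any((counts > 0) & (counts < min_per_pixel))
    recommended = None
    if not complete:
        larger = [p for p in PIXEL_SIZES if p > pixel_size]
        recommended = float(larger[0]) if larger else None
    return DiffusionMap(
        pixel_size_nm=float(pixel_size),
        x_min_nm=float(x0),
        y_min_nm=float(y0),
        d=d_grid,
        k=k_grid,
        counts=counts,
        min_per_pixel=min_per_pixel,
        dt=float(dt),
        r_max=float(r_max),
        background=background,
        complete=complete,
        recommended_pixel_size=recommended,
    )


@dataclass
class RegionFits:
    """Per-region MLE fits for one cell (None where a region was excluded)."""

    center: DisplacementFitResults | None
    left_pole: DisplacementFitResults | None
    right_pole: DisplacementFitResults | None
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def valid(self) -> bool:
        """At least the center and one pole fitted and converged."""
        poles = [f for f in (self.left_pole, self.right_pole) if f is not None]
        return self.center is not None and len(poles) > 0

    def pole_center_ratio(self) -> float:
        """mean(available pole D) / center D; NaN when invalid."""
        if not self.valid:
            return float("nan")
        poles = [f.d for f in (self.left_pole, self.right_pole) if f is not None]
        return float(np.mean(poles) / self.center.d)


def fit_regions(
    partition: RegionPartition,
    dt: float | None = None,
    r_max: float = DEFAULT_R_MAX,
    min_per_region: int = 100,
    background: bool = True,
) -> RegionFits:
    """Fit each region of a partition that has enough displacements.

    Regions with fewer than ``min_per_region`` displacements are excluded
    (too few data points give region estimates with errors beyond ~10%),
    as are non-converged fits; exclusion reasons are recorded.
    """
    fits: dict[str, DisplacementFitResults | None] = {}
    excluded: dict[str, str] = {}
    for name, df in (
        ("center", partition.center),
        ("left_pole", partition.left_pole),
        ("right_pole", partition.right_pole),
    ):
        if len(df) < min_per_region:
            fits[name] = None
            excluded[name] = f"only {len(df)} displacements (< {min_per_region})"
            continue
        use_dt = dt if dt is not None else df.attrs.get("dt", DEFAULT_DT)
        res = DisplacementModel(
            df["r_nm"].to_numpy(), dt=use_dt, r_max=r_max, background=background
        ).fit()
        if not res.converged:
            fits[name] = None
            excluded[name] = "fit did not converge"
        else:
            fits[name] = res
    return RegionFits(
        center=fits["center"],
        left_pole=fits["left_pole"],
        right_pole=fits["right_pole"],
        excluded=excluded,
    )
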