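"""File formats, pipeline configuration and the end-to-end pipeline.

Canonical on-disk formats are plain text:

* localizations — CSV/TSV with columns ``frame, x_nm, y_nm`` (extra
  columns such as ``truth_id`` are preserved);
* displacements — CSV with ``origin_x_nm, origin_y_nm, r_nm, couple``;
* diffusion maps — a TSV grid of per-pixel D values (NaN for missing)
  plus a JSON sidecar with the grid metadata and count matrix;
* cells — a JSON index (id, angle, geometry, QC) plus one displacement
  CSV per cell.

Coordinates in files are nm, continuous, y increasing upward.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .displacements import extract_displacements, filter_displacements
from .mapping import DiffusionMap, RegionFits, fit_regions
from .segmentation import (
    CellRecord,
    VoronoiParams,
    cluster_cells,
    partition_regions,
    qc_filter,
    rotate_to_major_axis,
)

__all__ = [
    "SchemaError",
    "PipelineConfig",
    "PipelineResult",
    "read_localizations",
    "write_localizations",
    "read_displacements",
    "write_displacements",
    "read_map",
    "write_map",
    "read_cells",
    "write_cells",
    "run_pipeline",
]


class SchemaError(ValueError):
    """A required column is missing or a file is malformed."""


def _sep_for(path: Path) -> str:
    return "\t" if Path(path).suffix.lower() in {".tsv", ".tab"} else ","


def _require(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")


def read_localizations(path) -> pd.DataFrame:
    """Read a localization table (CSV/TSV: frame, x_nm, y_nm[, extras])."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path))
    except pd.errors.ParserError as err:
        raise SchemaError(f"{path}: malformed file: {err}") from err
    _require(df, ["frame", "x_nm", "y_nm"], path)
    bad = df.index[~np.isfinite(df[["x_nm", "y_nm"]]).all(axis=1)]
    if len(bad):
        raise SchemaError(
            f"{path}: non-finite coordinates at data row(s) {list(bad[:5] + 2)}"
        )
    df["frame"] = df["frame"].astype(int)
    if (df["frame"] < 0).any():
        raise SchemaError(f"{path}: negative frame indices")
    return df


def write_localizations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep=_sep_for(Path(path)), index=False)


def read_displacements(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    _require(df, ["origin_x_nm", "origin_y_nm", "r_nm", "couple"], path)
    return df


def write_displacements(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep=_sep_for(Path(path)), index=False)


def write_map(dmap: DiffusionMap, path) -> None:
    """Write a diffusion map as a TSV grid plus a JSON metadata sidecar."""
    path = Path(path)
    np.savetxt(path, dmap.d, delimiter="\t", fmt="%.6g")
    meta = {
        "pixel_size_nm": dmap.pixel_size_nm,
        "x_min_nm": dmap.x_min_nm,
        "y_min_nm": dmap.y_min_nm,
        "min_per_pixel": dmap.min_per_pixel,
        "dt": dmap.dt,
        "r_max": dmap.r_max,
        "background": dmap.background,
        "complete": dmap.complete,
        "recommended_pixel_size": dmap.recommended_pixel_size,
        "counts": dmap.counts.tolist(),
        "k": [[None if not np.isfinite(v) else v for v in row] for row in dmap.k],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_map(path) -> DiffusionMap:
    path = Path(path)
    d = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    k = np.array(
        [[np.nan if v is None else v for v in row] for row in meta["k"]], dtype=float
    )
    return DiffusionMap(
        pixel_size_nm=meta["pixel_size_nm"],
        x_min_nm=meta["x_min_nm"],
        y_min_nm=meta["y_min_nm"],
        d=d,
        k=k,
        counts=np.array(meta["counts"], dtype=int),
        min_per_pixel=meta["min_per_pixel"],
        dt=meta["dt"],
        r_max=meta["r_max"],
        background=meta["background"],
        complete=meta["complete"],
        recommended_pixel_size=meta["recommended_pixel_size"],
    )


def write_cells(cells: list[CellRecord], out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index = []
    for cell in cells:
        index.append(
            {
                "id": cell.id,
                "rotation_angle_rad": cell.rotation_angle,
                "length_um": cell.length_um,
                "width_um": cell.width_um,
                "qc_pass": cell.qc_pass,
                "qc_reason": cell.qc_reason,
                "n_displacements": cell.n_displacements,
            }
        )
        cell.displacements.to_csv(out_dir / f"cell_{cell.id:04d}.csv", index=False)
    (out_dir / "cells.json").write_text(json.dumps(index, indent=1))


def read_cells(out_dir) -> list[CellRecord]:
    out_dir = Path(out_dir)
    index = json.loads((out_dir / "cells.json").read_text())
    cells = []
    for rec in index:
        df = pd.read_csv(out_dir / f"cell_{rec['id']:04d}.csv")
        cells.append(
            CellRecord(
                id=rec["id"],
                displacements=df,
                rotation_angle=rec["rotation_angle_rad"],
                length_um=rec["length_um"],
                width_um=rec["width_um"],
                qc_pass=rec["qc_pass"],
                qc_reason=rec["qc_reason"],
            )
        )
    return cells


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds and defaults of the analysis pipeline.

    The defaults are the reference operating point: 1.5-ms lag, 600-nm
    pairing/truncation radius, 20%-length pole regions, per-cell QC range
    of 2,000–20,000 displacements, at least 100 displacements per region
    and 10 per map pixel, 45 displacements per pixel for a map pixel to be
    considered well determined (SD below ~15%).
    """

    dt: float = 1.5e-3
    r_max: float = 600.0
    phase: int = 0
    pixel_sizes: tuple[int, ...] = (50, 100, 150, 200)
    pole_fraction: float = 0.20
    min_displacements: int = 2000
    max_displacements: int = 20000
    min_per_region: int = 100
    min_per_pixel: int = 10
    map_quality_threshold: int = 45
    background: bool = True
    cluster_max_area_factor: float = 2.0
    cluster_min_size: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "dt": self.dt, "r_max": self.r_max,
            "min_per_region": self.min_per_region,
            "min_per_pixel": self.min_per_pixel,
            "min_displacements": self.min_displacements,
            "max_displacements": self.max_displacements,
            "map_quality_threshold": self.map_quality_threshold,
            "cluster_min_size": self.cluster_min_size,
            "cluster_max_area_factor": self.cluster_max_area_factor,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.pole_fraction < 0.5:
            raise ValueError("pole_fraction must lie in (0, 0.5)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pixel_sizes"] = list(self.pixel_sizes)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "pixel_sizes" in data:
            data["pixel_sizes"] = tuple(data["pixel_sizes"])
        return cls(**data)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    """Bundle produced by :func:`run_pipeline`."""

    cells: list[CellRecord]
    region_fits: pd.DataFrame
    manifest: dict
    ok: bool

    def write(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_cells(self.cells, out_dir / "cells")
        self.region_fits.to_csv(out_dir / "region_fits.csv", index=False)
        (out_dir / "manifest.json").write_text(json.dumps(self.manifest, indent=1))


def _region_rows(cell_id: int, fits: RegionFits) -> list[dict]:
    rows = []
    for region, res in (
        ("center", fits.center),
        ("left_pole", fits.left_pole),
        ("right_pole", fits.right_pole),
    ):
        rows.append(
            {
                "cell_id": cell_id,
                "region": region,
                "d_um2s": res.d if res else np.nan,
                "k_nm2": res.k if res else np.nan,
                "se_d": res.se_d if res else np.nan,
                "n": res.n if res else 0,
                "converged": bool(res.converged) if res else False,
                "excluded_reason": fits.excluded.get(region, ""),
            }
        )
    return rows


def run_pipeline(
    config: PipelineConfig,
    localizations: pd.DataFrame,
    out_dir=None,
    manual_flags: dict[int, str] | None = None,
) -> PipelineResult:
    """Run the experimental-style analysis chain on a localization table.

    Stages: frame pairing and all-pairs peak matching, r filtering,
    Voronoi cell detection on displacement origins, rotation onto the
    major axis, QC by displacement count, pole/center partitioning and
    per-region MLE fits (background slope fitted freely by default).
    Deterministic for a fixed config; emits a manifest recording the
    config hash and per-stage outcomes.
    """
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "python": platform.python_version(),
        "stages": [],
    }
    cells: list[CellRecord] = []
    rows: list[dict] = []

    def stage(name: str, **info) -> None:
        manifest["stages"].append({"stage": name, **info})

    if localizations.empty:
        stage("extract", status="empty input")
        return PipelineResult(
            cells=[], region_fits=pd.DataFrame(), manifest=manifest, ok=False
        )
    try:
        disp = extract_displacements(localizations, phase=config.phase, r_max=config.r_max)
        disp = filter_displacements(disp, r_max=config.r_max)
        stage("extract", n_displacements=len(disp))
        clusters = cluster_cells(
            disp,
            VoronoiParams(
                max_area_factor=config.cluster_max_area_factor,
                min_cluster_size=config.cluster_min_size,
            ),
        )
        stage("cluster", n_clusters=len(clusters))
        cells = [rotate_to_major_axis(c, cell_id=i) for i, c in enumerate(clusters)]
        kept = qc_filter(
            cells,
            min_disp=config.min_displacements,
            max_disp=config.max_displacements,
            manual_flags=manual_flags,
        )
        stage("qc", n_kept=len(kept), n_rejected=len(cells) - len(kept))
        for cell in kept:
            part = partition_regions(cell, pole_fraction=config.pole_fraction)
            fits = fit_regions(
                part,
                dt=config.dt,
                r_max=config.r_max,
                min_per_region=config.min_per_region,
                background=config.background,
            )
            rows.extend(_region_rows(cell.id, fits))
        stage("fit_regions", n_cells=len(kept))
    except Exception as err:  # noqa: BLE001 — manifest records the failure point
        stage("failure", error=f"{type(err).__name__}: {err}")
        result = PipelineResult(
            cells=cells, region_fits=pd.DataFrame(rows), manifest=manifest, ok=False
        )
        if out_dir is not None:
            result.write(out_dir)
        return result

    result = PipelineResult(
        cells=cells,
        region_fits=pd.DataFrame(rows),
        manifest=manifest,
        ok=len(rows) > 0,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result
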