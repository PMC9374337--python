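"""Synthetic-data generation: confined random walks and localization streams.

This module produces every input the analysis pipeline consumes:

* Brownian trajectories confined to a reflective spherocylinder, observed
  as discrete steps (a particle-based Brownian dynamics run);
* lag-subsampled planar displacements (pairing the position at step ``i``
  with the position at step ``i + lag``, exploiting the Markov property of
  the random walk);
* stroboscopic localization streams in the odd/even frame-couple convention,
  with localization noise and uniformly distributed spurious co-detections
  (the origin of the linear background term in the displacement density);
* cell populations of varying geometry and diffusivity;
* synthetic protein panels with a known diffusion–mass power law.

All randomness flows from explicit integer seeds; outputs are reproducible
bit-for-bit for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import Spherocylinder

__all__ = [
    "SimulationConfig",
    "StreamConfig",
    "ConfigurationError",
    "simulate_confined_walk",
    "extract_lag_displacements",
    "synthesize_localization_stream",
    "generate_cell_population",
    "generate_protein_panel",
]

NM_PER_UM = 1000.0


class ConfigurationError(ValueError):
    """Raised for inconsistent simulation or stream configurations."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one confined random-walk simulation.

    Defaults follow the reference protocol: 0.1-ms steps for a total of
    2 s, so that pairing each step with the step 15 rows later yields
    1.5-ms displacements.
    """

    d_sim: float
    dt_sim: float = 1e-4
    total_time: float = 2.0
    n_particles: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_sim < 0:
            raise ConfigurationError("d_sim must be >= 0")
        if self.dt_sim <= 0 or self.total_time <= 0:
            raise ConfigurationError("dt_sim and total_time must be > 0")
        if self.n_particles < 1:
            raise ConfigurationError("n_particles must be >= 1")
        steps = self.total_time / self.dt_sim
        if abs(steps - round(steps)) > 1e-9:
            raise ConfigurationError(
                "total_time must be an integer multiple of dt_sim"
            )

    @property
    def n_steps(self) -> int:
        return int(round(self.total_time / self.dt_sim))


def _walk(
    geom: Spherocylinder,
    start: np.ndarray,
    n_steps: int,
    step_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Propagate particles for ``n_steps``; returns (n_steps, n, 3) in μm."""
    pos = np.array(start, dtype=float, copy=True)
    out = np.empty((n_steps,) + pos.shape)
    for i in range(n_steps):
        if step_sd > 0:
            pos = geom.reflect(pos + rng.normal(0.0, step_sd, size=pos.shape))
        out[i] = pos
    return out


def simulate_confined_walk(
    config: SimulationConfig, geom: Spherocylinder
) -> pd.DataFrame:
    """Simulate Brownian motion inside a reflective spherocylinder.

    Particles start uniformly distributed inside the compartment. Each
    step displaces every coordinate by an independent normal draw with
    SD ``sqrt(2 * d_sim * dt_sim)``; steps ending outside the compartment
    are folded back by specular reflection. Rows record the positions
    after steps ``1..N`` (no t=0 row), so ``N = total_time / dt_sim`` rows
    are returned per particle.

    Returns
    -------
    pandas.DataFrame
        Columns ``step`` (1-based), ``particle`` (0-based), ``x``, ``y``,
        ``z`` in micrometers, sorted by step then particle.
    """
    rng = np.random.default_rng(config.seed)
    start = geom.sample_uniform(config.n_particles, rng)
    step_sd = float(np.sqrt(2.0 * config.d_sim * config.dt_sim))
    traj = _walk(geom, start, config.n_steps, step_sd, rng)
    n_steps, n_particles = traj.shape[:2]
    df = pd.DataFrame(
        {
            "step": np.repeat(np.arange(1, n_steps + 1), n_particles),
            "particle": np.tile(np.arange(n_particles), n_steps),
            "x": traj[:, :, 0].ravel(),
            "y": traj[:, :, 1].ravel(),
            "z": traj[:, :, 2].ravel(),
        }
    )
    df.attrs["dt_sim"] = config.dt_sim
    df.attrs["d_sim"] = config.d_sim
    return df


def _traj_to_array(traj: pd.DataFrame) -> np.ndarray:
    """Reshape a trajectory table to (n_steps, n_particles, 3) in μm."""
    n_particles = int(traj["particle"].max()) + 1
    n_steps = len(traj) // n_particles
    if n_steps * n_particles != len(traj):
        raise ValueError("trajectory table is ragged")
    order = np.lexsort((traj["particle"].to_numpy(), traj["step"].to_numpy()))
    xyz = traj[["x", "y", "z"]].to_numpy()[order]
    return xyz.reshape(n_steps, n_particles, 3)


def extract_lag_displacements(traj: pd.DataFrame, lag_steps: int) -> pd.DataFrame:
    """Pair each recorded position with the position ``lag_steps`` later.

    Because the random walk is a Markov process, every row can serve as a
    displacement origin; a table of ``N`` rows per particle yields
    ``N - lag_steps`` displacements per particle.

    Returns
    -------
    pandas.DataFrame
        Columns ``origin_x_nm``, ``origin_y_nm``, ``r_nm``, ``couple``
        (the 1-based origin step), ``particle``, plus ``dx_nm``/``dy_nm``
        components for vector-level checks.
    """
    if lag_steps < 1:
        raise ValueError("lag_steps must be >= 1")
    arr = _traj_to_array(traj)
    if arr.shape[0] <= lag_steps:
        raise ValueError(
            f"need more than {lag_steps} rows per particle, got {arr.shape[0]}"
        )
    origin = arr[:-lag_steps, :, :2]
    end = arr[lag_steps:, :, :2]
    delta = (end - origin) * NM_PER_UM
    n_pairs, n_particles = origin.shape[:2]
    out = pd.DataFrame(
        {
            "origin_x_nm": origin[:, :, 0].ravel() * NM_PER_UM,
            "origin_y_nm": origin[:, :, 1].ravel() * NM_PER_UM,
            "r_nm": np.sqrt((delta**2).sum(axis=2)).ravel(),
            "couple": np.repeat(np.arange(1, n_pairs + 1), n_particles),
            "particle": np.tile(np.arange(n_particles), n_pairs),
            "dx_nm": delta[:, :, 0].ravel(),
            "dy_nm": delta[:, :, 1].ravel(),
        }
    )
    dt_sim = traj.attrs.get("dt_sim")
    if dt_sim is not None:
        out.attrs["dt"] = dt_sim * lag_steps
    return out


@dataclass(frozen=True)
class StreamConfig:
    """Parameters of a synthetic stroboscopic localization stream.

    ``false_pair_rate`` is the expected number of spurious co-detections
    per frame couple per cell; each co-detection contributes one uniformly
    placed point in each frame of the couple, which is what produces the
    linear-in-r background of all-pairs distances. ``loc_noise_sd`` is the
    isotropic localization error (default 20 nm, a typical single-molecule
    localization precision). ``pole_slowdown`` optionally scales the
    diffusivity of emitters whose displacement originates in the outer
    ``pole_fraction`` of the cell length, to emulate genuinely slower
    diffusion at the poles.
    """

    loc_noise_sd: float = 20.0
    false_pair_rate: float = 0.0
    frames_per_cell: int = 8000
    emitters_per_couple: int = 1
    dt_sub: float = 1e-4
    n_sub: int = 15
    pole_slowdown: float = 1.0
    pole_fraction: float = 0.2
    phase: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loc_noise_sd < 0 or self.false_pair_rate < 0:
            raise ConfigurationError("rates and noise must be >= 0")
        if self.frames_per_cell < 2:
            raise ConfigurationError("frames_per_cell must be >= 2")
        if self.phase not in (0, 1):
            raise ConfigurationError("phase must be 0 or 1")
        if not (0 < self.pole_slowdown <= np.inf):
            raise ConfigurationError("pole_slowdown must be > 0")


def cell_layout(cells: list[tuple[Spherocylinder, float]], gap: float = 2.0) -> np.ndarray:
    """Cell-center x positions (μm) placing cells in a row with ``gap`` μm spacing."""
    centers = []
    cursor = 0.0
    for geom, _ in cells:
        centers.append(cursor + geom.total_length / 2.0)
        cursor += geom.total_length + gap
    return np.asarray(centers)


def synthesize_localization_stream(
    cells: list[tuple[Spherocylinder, float]],
    stream: StreamConfig,
) -> pd.DataFrame:
    """Emit a frame-indexed localization table for a field of synthetic cells.

    True emitters appear once per frame couple: a start position drawn from
    the stationary (uniform) distribution in the first frame and the
    position reached after ``n_sub`` reflected sub-steps (1.5 ms by
    default) in the second frame, both perturbed by Gaussian localization
    noise. Spurious co-detections are uniform over each cell's projected
    footprint. Ground-truth pairing labels are retained: ``truth_id >= 0``
    marks the two localizations of one true emitter, ``truth_id = -1``
    marks spurious points.

    Returns
    -------
    pandas.DataFrame
        Columns ``frame``, ``x_nm``, ``y_nm``, ``truth_id``, ``cell_id``.
        Cell centers (nm) are stored in ``df.attrs["cell_centers_nm"]``.
    """
    rng = np.random.default_rng(stream.seed)
    centers = cell_layout(cells)
    n_couples = (stream.frames_per_cell - stream.phase) // 2
    frames_first = stream.phase + 2 * np.arange(n_couples)

    recs: list[pd.DataFrame] = []
    truth_counter = 0
    for cell_id, ((geom, d_sim), cx) in enumerate(zip(cells, centers)):
        half_l = geom.total_length / 2.0
        pole_cut = half_l - stream.pole_fraction * geom.total_length
        for _ in range(stream.emitters_per_couple):
            start = geom.sample_uniform(n_couples, rng)
            d_eff = np.full(n_couples, d_sim)
            if stream.pole_slowdown != 1.0:
                in_pole = np.abs(start[:, 0]) >= pole_cut
                d_eff[in_pole] = d_sim * stream.pole_slowdown
            end = start.copy()
            for _ in range(stream.n_sub):
                sd = np.sqrt(2.0 * d_eff * stream.dt_sub)
                end = geom.reflect(end + rng.normal(size=end.shape) * sd[:, None])
            ids = truth_counter + np.arange(n_couples)
            truth_counter += n_couples
            for frames, pos in ((frames_first, start), (frames_first + 1, end)):
                xy = pos[:, :2] * NM_PER_UM
                xy = xy + rng.normal(0.0, stream.loc_noise_sd, size=xy.shape)
                recs.append(
                    pd.DataFrame(
                        {
                            "frame": frames,
                            "x_nm": xy[:, 0] + cx * NM_PER_UM,
                            "y_nm": xy[:, 1],
                            "truth_id": ids,
                            "cell_id": cell_id,
                        }
                    )
                )
        if stream.false_pair_rate > 0:
            n_false = rng.poisson(stream.false_pair_rate, size=(n_couples, 2))
            total = int(n_false.sum())
            pts = geom.sample_footprint(total, rng) * NM_PER_UM
            frame_idx = np.repeat(
                np.stack([frames_first, frames_first + 1], axis=1).ravel(),
                n_false.ravel(),
            )
            recs.append(
                pd.DataFrame(
                    {
                        "frame": frame_idx,
                        "x_nm": pts[:, 0] + cx * NM_PER_UM,
                        "y_nm": pts[:, 1],
                        "truth_id": -1,
                        "cell_id": cell_id,
                    }
                )
            )
    out = pd.concat(recs, ignore_index=True)
    out = out.sort_values(["frame", "x_nm"], kind="stable").reset_index(drop=True)
    out.attrs["cell_centers_nm"] = centers * NM_PER_UM
    out.attrs["dt"] = stream.dt_sub * stream.n_sub
    return out


def generate_cell_population(
    diameter_range: tuple[float, float] = (0.2, 2.34),
    length_range: tuple[float, float] = (1.1, 3.64),
    d_range: tuple[float, float] = (0.5, 20.0),
    n_cells: int = 40,
    seed: int = 0,
) -> list[tuple[Spherocylinder, float]]:
    """Sample a heterogeneous population of cells.

    Diameters, end-to-end lengths and diffusion coefficients are drawn
    uniformly within the given ranges; geometries with
    ``total_length < diameter`` are rejected and redrawn so every cell is
    a valid spherocylinder.
    """
    for lo, hi in (diameter_range, length_range, d_range):
        if lo > hi:
            raise ConfigurationError("ranges must be ordered (lo <= hi)")
    if n_cells < 1:
        raise ConfigurationError("n_cells must be >= 1")
    if length_range[1] < diameter_range[0]:
        raise ConfigurationError(
            "infeasible ranges: every sampled length would be below the "
            "smallest diameter"
        )
    rng = np.random.default_rng(seed)
    cells: list[tuple[Spherocylinder, float]] = []
    while len(cells) < n_cells:
        diam = rng.uniform(*diameter_range)
        length = rng.uniform(*length_range)
        d_sim = rng.uniform(*d_range)
        if length < diam:
            continue
        cells.append((Spherocylinder(radius=diam / 2.0, total_length=length), d_sim))
    return cells


def generate_protein_panel(
    alpha: float = 68.0,
    beta: float = -0.54,
    n: int = 10,
    rel_noise: float = 0.1,
    seed: int = 0,
    mass_range: tuple[float, float] = (25.0, 320.0),
) -> pd.DataFrame:
    """Synthesize a protein panel with a known diffusion–mass power law.

    Complex masses are log-uniform over ``mass_range`` (kDa); the true
    diffusion coefficient is ``alpha * M**beta`` perturbed by multiplicative
    lognormal noise with relative SD ``rel_noise`` (median-preserving).
    The generating parameters are retained in ``df.attrs``.
    """
    if n < 3:
        raise ConfigurationError("n must be >= 3")
    if rel_noise < 0:
        raise ConfigurationError("rel_noise must be >= 0")
    if beta >= 0:
        import warnings

        warnings.warn(
            "beta >= 0: diffusion increasing with mass is physically unusual",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    mass = np.exp(rng.uniform(np.log(mass_range[0]), np.log(mass_range[1]), size=n))
    d_true = alpha * mass**beta
    sigma = np.sqrt(np.log1p(rel_noise**2))
    d_obs = d_true * np.exp(rng.normal(0.0, sigma, size=n)) if sigma > 0 else d_true
    df = pd.DataFrame(
        {
            "name": [f"syn{i:02d}" for i in range(n)],
            "complex_mass_kda": mass,
            "d_true_um2s": d_true,
            "d_um2s": d_obs,
        }
    )
    df.attrs.update({"alpha": alpha, "beta": beta, "rel_noise": rel_noise})
    return df
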