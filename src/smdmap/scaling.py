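"""Protein-panel statistics: mass scaling, correlations and viscosity.

The downstream questions of an SMdM experiment: does the apparent
diffusion coefficient scale with the mass of the diffusing complex
(``D = alpha * M_complex**beta``), with protein abundance, or with the
number of interaction partners ("loneliness")? And what effective
("perceived") viscosity does each complex experience, under a
Stokes-Einstein picture with a mass-derived hydrodynamic radius?
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

MEOS32_MASS_KDA = 25.7
BOLTZMANN_J_PER_K = 1.380649e-23
AVOGADRO = 6.02214076e23

__all__ = [
    "ProteinRecord",
    "complex_mass",
    "loneliness",
    "interactors_per_molecule",
    "spearman",
    "PowerLawModel",
    "PowerLawResults",
    "fit_power_law",
    "pole_center_ratio",
    "PoleCenterEnsemble",
    "ViscosityModel",
    "perceived_viscosity",
    "two_sample_rank_test",
    "normality_test",
    "f_test_nested",
]


@dataclass
class ProteinRecord:
    """One tagged construct: masses, state, abundance and measured mobility.

    ``tag_mw`` defaults to the mEos3.2 fluorescent tag (25.7 kDa); for a
    free-tag construct set ``monomer_mw = 0``. The complex mass assumes
    every subunit of the oligomer carries one tag.
    """

    name: str
    monomer_mw: float
    tag_mw: float = MEOS32_MASS_KDA
    oligomeric_state: int = 1
    abundance: float | None = None
    interactor_abundance_sum: float | None = None
    loneliness: float | None = None
    d_center_mean: float | None = None
    d_center_sd: float | None = None
    heterologous: bool = False

    @property
    def complex_mass(self) -> float:
        return complex_mass(self)


def complex_mass(record: ProteinRecord) -> float:
    """Mass of the diffusing assembly, kDa.

    ``(monomer_mw + tag_mw) * oligomeric_state``: the tagged-subunit mass
    times the number of subunits, assuming all subunits are tagged.
    """
    if record.oligomeric_state < 1:
        raise ValueError("oligomeric_state must be >= 1")
    if record.monomer_mw < 0 or record.tag_mw < 0:
        raise ValueError("masses must be non-negative")
    return (record.monomer_mw + record.tag_mw) * record.oligomeric_state


def loneliness(abundance: float, interactor_sum: float) -> float:
    """Copy number of the protein divided by the summed copies of its
    known binary interaction partners.

    A loneliness of 10 means ten copies of the protein per interactor
    copy; 0.1 means ten interactor copies per protein copy. Undefined
    (NaN) when no interactor copies are recorded.
    """
    if abundance <= 0:
        raise ValueError("abundance must be > 0")
    if interactor_sum < 0:
        raise ValueError("interactor_sum must be >= 0")
    if interactor_sum == 0:
        return float("nan")
    return abundance / interactor_sum


def interactors_per_molecule(loneliness_value: float) -> float:
    """Reciprocal reading of loneliness: interactor copies per molecule."""
    if not loneliness_value > 0:
        raise ValueError("loneliness must be > 0")
    return 1.0 / loneliness_value


def spearman(x, y, n_perm: int | None = None, seed: int = 0):
    """Spearman rank correlation with mean ranks for ties.

    Returns ``(r, p)``. With ``n_perm`` a permutation p-value is computed
    instead of the asymptotic one (useful at small n). Constant input has
    no rank ordering; returns ``(nan, nan)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    r, p = stats.spearmanr(x, y)
    if n_perm:
        rng = np.random.default_rng(seed)
        obs = abs(r)
        hits = sum(
            abs(stats.spearmanr(x, rng.permutation(y)).statistic) >= obs - 1e-12
            for _ in range(n_perm)
        )
        p = (hits + 1) / (n_perm + 1)
    return float(r), float(p)


@dataclass
class PowerLawResults:
    """Least-squares fit of ``y = alpha * x**beta`` on the linear scale."""

    alpha: float
    beta: float
    se_alpha: float
    se_beta: float
    cov: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fitted: np.ndarray
    converged: bool

    @property
    def residuals(self) -> np.ndarray:
        """Observed minus fitted values."""
        return self.y - self.fitted

    @property
    def rss(self) -> float:
        return float((self.residuals**2).sum())

    def predict(self, x) -> np.ndarray:
        return self.alpha * np.asarray(x, dtype=float) ** self.beta

    def summary(self) -> str:
        lines = [
            "Power-law fit  y = alpha * x^beta",
            "=" * 44,
            f"{'n points':<26}{len(self.x):>18}",
            f"{'alpha':<26}{self.alpha:>18.4f}",
            f"{'SE(alpha)':<26}{self.se_alpha:>18.4f}",
            f"{'beta':<26}{self.beta:>18.4f}",
            f"{'SE(beta)':<26}{self.se_beta:>18.4f}",
            f"{'RSS':<26}{self.rss:>18.4f}",
            f"{'converged':<26}{str(self.converged):>18}",
        ]
        return "\n".join(lines)


class PowerLawModel:
    """Nonlinear least squares for ``y = alpha * x**beta``.

    The fit is performed on the linear scale (so absolute deviations are
    minimized, optionally weighted by per-point uncertainties ``sigma``)
    and initialized from the log-log linear regression solution. Standard
    errors come from the diagonal of the fit covariance matrix.
    """

    def __init__(self, x, y, sigma=None):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.x.size != self.y.size or self.x.size < 3:
            raise ValueError("need >= 3 paired points")
        if np.any(self.x <= 0) or np.any(self.y <= 0):
            raise ValueError("power-law fitting requires positive data")
        self.sigma = None if sigma is None else np.asarray(sigma, dtype=float)

    def loglog_start(self) -> tuple[float, float]:
        """(alpha, beta) from ordinary linear regression of log y on log x."""
        beta, log_alpha = np.polyfit(np.log(self.x), np.log(self.y), 1)
        return float(np.exp(log_alpha)), float(beta)

    def fit(self) -> PowerLawResults:
        alpha0, beta0 = self.loglog_start()
        converged = True
        try:
            popt, pcov = optimize.curve_fit(
                lambda x, a, b: a * x**b,
                self.x,
                self.y,
                p0=[alpha0, beta0],
                sigma=self.sigma,
                absolute_sigma=False,
                maxfev=10000,
            )
        except RuntimeError:
            popt, pcov = np.array([alpha0, beta0]), np.full((2, 2), np.nan)
            converged = False
        alpha, beta = popt
        se = np.sqrt(np.diag(pcov))
        return PowerLawResults(
            alpha=float(alpha),
            beta=float(beta),
            se_alpha=float(se[0]),
            se_beta=float(se[1]),
            cov=pcov,
            x=self.x,
            y=self.y,
            fitted=alpha * self.x**beta,
            converged=converged,
        )


def fit_power_law(masses, d_values, sigma=None) -> PowerLawResults:
    """Fit ``D = alpha * M**beta`` by nonlinear least squares.

    ``sigma`` optionally weights each point by its uncertainty (e.g. the
    per-construct SD of the measured diffusion coefficients).
    """
    return PowerLawModel(masses, d_values, sigma=sigma).fit()


@dataclass
class PoleCenterEnsemble:
    """Per-cell pole/center ratios with ensemble summary statistics."""

    ratios: np.ndarray
    skipped: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.ratios)) if self.ratios.size else float("nan")

    @property
    def sd(self) -> float:
        return float(np.std(self.ratios, ddof=1)) if self.ratios.size > 1 else float("nan")

    def kde(self, grid_size: int = 256):
        """Kernel-density summary (grid, density) for plotting."""
        kde = stats.gaussian_kde(self.ratios)
        lo, hi = self.ratios.min(), self.ratios.max()
        pad = 0.15 * (hi - lo + 1e-12)
        grid = np.linspace(lo - pad, hi + pad, grid_size)
        return grid, kde(grid)


def pole_center_ratio(region_fits) -> PoleCenterEnsemble:
    """Ensemble of per-cell ``mean(D_poles) / D_center`` ratios.

    Accepts a list of :class:`~smdmap.mapping.RegionFits`, a list of
    precomputed ratios, or a DataFrame with a ``ratio`` column (as
    produced by :func:`smdmap.confinement.pole_center_ensemble`). Cells
    without a valid center fit are skipped and counted.
    """
    if isinstance(region_fits, pd.DataFrame):
        values = region_fits["ratio"].to_numpy(float)
    else:
        values = np.array(
            [f.pole_center_ratio() if hasattr(f, "pole_center_ratio") else float(f)
             for f in region_fits],
            dtype=float,
        )
    good = np.isfinite(values)
    return PoleCenterEnsemble(ratios=values[good], skipped=int((~good).sum()))


@dataclass(frozen=True)
class ViscosityModel:
    """Stokes-Einstein mapping between diffusivity, mass and viscosity.

    The hydrodynamic radius of a globular complex of mass ``M`` (kDa) is
    derived from its partial specific volume ``v`` (cm³/g, default 0.73 —
    a typical protein value): ``r = (3 M v / (4 pi N_A))**(1/3)``. The
    perceived viscosity is then ``eta = k_B T / (6 pi D r)``. Temperature
    defaults to 294.15 K (21 °C stage temperature).
    """

    temperature: float = 294.15
    specific_volume: float = 0.73

    def hydrodynamic_radius_nm(self, mass_kda) -> np.ndarray | float:
        mass_g = np.asarray(mass_kda, dtype=float) * 1000.0 / AVOGADRO
        r_cm = (3.0 * mass_g * self.specific_volume / (4.0 * math.pi)) ** (1.0 / 3.0)
        return r_cm * 1e7

    def eta_cp(self, d_um2s, mass_kda) -> np.ndarray | float:
        """Perceived viscosity in centipoise for given D (μm²/s) and mass."""
        d = np.asarray(d_um2s, dtype=float)
        if np.any(d <= 0):
            raise ValueError("d must be > 0")
        r_m = np.asarray(self.hydrodynamic_radius_nm(mass_kda)) * 1e-9
        eta_pas = BOLTZMANN_J_PER_K * self.temperature / (6.0 * math.pi * d * 1e-12 * r_m)
        return eta_pas * 1000.0

    def d_um2s(self, eta_cp, mass_kda) -> np.ndarray | float:
        """Invert: diffusion coefficient from viscosity (cP) and mass."""
        r_m = np.asarray(self.hydrodynamic_radius_nm(mass_kda)) * 1e-9
        d_m2s = BOLTZMANN_J_PER_K * self.temperature / (
            6.0 * math.pi * np.asarray(eta_cp, dtype=float) * 1e-3 * r_m
        )
        return d_m2s * 1e12


def perceived_viscosity(
    d_values,
    masses_kda,
    model: ViscosityModel = ViscosityModel(),
    sigma=None,
) -> tuple[np.ndarray, PowerLawResults]:
    """Per-complex perceived viscosity and its mass power law.

    Returns ``(eta_cp, fit)`` where ``fit`` is the nonlinear fit of
    ``eta = a * M**gamma`` over the panel. For data following exactly
    ``D ∝ M**beta`` the viscosity exponent is ``-beta - 1/3`` (the radius
    contributes M^(1/3)).
    """
    eta = np.asarray(model.eta_cp(d_values, masses_kda))
    fit = PowerLawModel(masses_kda, eta, sigma=sigma).fit()
    return eta, fit


def two_sample_rank_test(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U rank test.

    Uses the exact null distribution when both samples are tie-free and
    small enough to enumerate (``n_a * n_b <= 10_000``), otherwise the
    normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (not has_ties and a.size * b.size <= 10_000) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def normality_test(x) -> tuple[float, float]:
    """Shapiro-Wilk normality test; requires 3 <= n <= 5000."""
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.all(x == x[0]):
        raise ValueError("normality undefined for a constant sample")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def f_test_nested(
    rss_restricted: float,
    rss_full: float,
    n: int,
    p_full: int,
    p_restricted: int,
) -> tuple[float, float]:
    """F test comparing nested least-squares fits (restricted vs full)."""
    if p_full <= p_restricted:
        raise ValueError("full model must have more parameters")
    df_num = p_full - p_restricted
    df_den = n - p_full
    if df_den <= 0:
        raise ValueError("no residual degrees of freedom")
    f_stat = ((rss_restricted - rss_full) / df_num) / (rss_full / df_den)
    return float(f_stat), float(stats.f.sf(f_stat, df_num, df_den))
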