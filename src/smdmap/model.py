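"""Maximum-likelihood fitting of planar single-molecule displacements.

The displacement length ``r`` of a particle undergoing free 2-D Brownian
motion over a lag ``t`` follows the Rayleigh density
``p(r) = (2r / 4Dt) exp(-r^2 / 4Dt)``. Two corrections adapt this to
stroboscopic displacement data from crowded fields of view:

* a linear background term ``k * r`` absorbing misassigned pairs (two
  independent detections uniform over an area have a pair-distance density
  proportional to ``r`` at short range);
* truncation to ``0 <= r <= r_max`` (displacements beyond the pairing
  radius are never observed), with the density renormalized so it
  integrates to one on that interval:

``p(r) = [ (2r/4Dt) exp(-r^2/4Dt) + k r ] / [ 1 - exp(-r_max^2/4Dt) + k r_max^2 / 2 ]``

`DisplacementModel` wraps a set of observed displacement lengths and fits
``D`` (and optionally ``k``) by maximum likelihood; `DisplacementFitResults`
carries the estimates, their standard errors from the observed information,
the log-likelihood and a `summary()` table.

Internally lengths are in nm, times in seconds and ``D`` in nm²/s; reported
diffusion coefficients are in μm²/s (1 μm²/s = 1e6 nm²/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "DisplacementModel",
    "DisplacementFitResults",
    "pdf_eval",
    "sample_displacements",
    "fit_mle",
    "d_from_rmsd",
]

UM2_PER_NM2 = 1e-6
DEFAULT_DT = 1.5e-3
DEFAULT_R_MAX = 600.0


def _pdf_terms(r: np.ndarray, d_nm2s: float, k: float, dt: float, r_max: float):
    s = 4.0 * d_nm2s * dt  # nm^2
    norm = 1.0 - np.exp(-(r_max**2) / s) + 0.5 * k * r_max**2
    body = (2.0 * r / s) * np.exp(-(r**2) / s) + k * r
    return body, norm


def pdf_eval(
    r,
    d: float,
    k: float = 0.0,
    dt: float = DEFAULT_DT,
    r_max: float = DEFAULT_R_MAX,
):
    """Evaluate the truncated, background-corrected displacement density.

    Parameters
    ----------
    r : array_like
        Displacement lengths in nm; must lie in ``[0, r_max]``.
    d : float
        Diffusion coefficient in μm²/s (> 0).
    k : float
        Background slope in nm⁻² (>= 0).
    dt, r_max : float
        Lag time (s) and truncation bound (nm).

    Returns
    -------
    ndarray
        Density in nm⁻¹; integrates to 1 over ``[0, r_max]``.
    """
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > r_max)):
        raise ValueError(f"r must lie in [0, {r_max}] nm")
    if d <= 0:
        raise ValueError("d must be > 0")
    if k < 0:
        raise ValueError("k must be >= 0")
    body, norm = _pdf_terms(r, d / UM2_PER_NM2, k, dt, r_max)
    return body / norm


def sample_displacements(
    n: int,
    d: float,
    k: float = 0.0,
    dt: float = DEFAULT_DT,
    r_max: float = DEFAULT_R_MAX,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw displacement lengths (nm) from the parametric model.

    The density is a two-component mixture of a truncated Rayleigh and a
    triangular (linear) background; both components are sampled by inverse
    transform.
    """
    rng = np.random.default_rng(rng)
    s = 4.0 * (d / UM2_PER_NM2) * dt
    w_ray = 1.0 - np.exp(-(r_max**2) / s)
    w_bg = 0.5 * k * r_max**2
    p_bg = w_bg / (w_ray + w_bg)
    from_bg = rng.random(n) < p_bg
    u = rng.random(n)
    out = np.empty(n)
    out[from_bg] = r_max * np.sqrt(u[from_bg])
    out[~from_bg] = np.sqrt(-s * np.log1p(-u[~from_bg] * w_ray))
    return out


def d_from_rmsd(rmsd: float, n_dims: int = 2, t: float = DEFAULT_DT) -> float:
    """Diffusion coefficient (μm²/s) from an RMS displacement (μm).

    Inverts ``RMSD = sqrt(2 n D t)``: ``D = RMSD² / (2 n t)``.
    """
    if t <= 0:
        raise ValueError("t must be > 0")
    if n_dims not in (1, 2, 3):
        raise ValueError("n_dims must be 1, 2 or 3")
    if rmsd < 0:
        raise ValueError("rmsd must be >= 0")
    return rmsd**2 / (2.0 * n_dims * t)


@dataclass
class DisplacementFitResults:
    """MLE estimates for one displacement set.

    Attributes
    ----------
    d : float
        Apparent diffusion coefficient, μm²/s.
    k : float
        Background slope, nm⁻² (0 when the background was fixed).
    se_d, se_k : float
        Standard errors from the observed information matrix (NaN when
        unavailable; ``se_k`` is NaN when ``k`` was fixed).
    loglik : float
        Maximized log-likelihood.
    n : int
        Number of displacements.
    converged : bool
        Optimizer convergence flag; non-converged fits are excluded from
        downstream ensembles.
    """

    d: float
    k: float
    se_d: float
    se_k: float
    loglik: float
    n: int
    converged: bool
    model: "DisplacementModel | None" = field(default=None, repr=False)

    def summary(self) -> str:
        lines = [
            "Displacement MLE fit",
            "=" * 44,
            f"{'n displacements':<26}{self.n:>18}",
            f"{'lag time (ms)':<26}{(self.model.dt * 1e3 if self.model else float('nan')):>18.3f}",
            f"{'D (um^2/s)':<26}{self.d:>18.4f}",
            f"{'SE(D)':<26}{self.se_d:>18.4f}",
            f"{'k (nm^-2)':<26}{self.k:>18.3e}",
            f"{'SE(k)':<26}{self.se_k:>18.3e}",
            f"{'log-likelihood':<26}{self.loglik:>18.3f}",
            f"{'converged':<26}{str(self.converged):>18}",
        ]
        return "\n".join(lines)


class DisplacementModel:
    """MLE model for a set of planar displacement lengths.

    Parameters
    ----------
    r_nm : array_like
        Observed displacement lengths in nm, all within ``[0, r_max]``.
    dt : float
        Lag time between the two frames of a couple, seconds.
    r_max : float
        Truncation bound, nm (displacements beyond it must have been
        filtered out before fitting).
    background : bool
        Fit the linear misassignment slope ``k`` freely (use for
        experimental or synthetic localization streams); when False, ``k``
        is fixed at zero (use for simulation-derived displacements, which
        have no pairing ambiguity).
    """

    def __init__(
        self,
        r_nm,
        dt: float = DEFAULT_DT,
        r_max: float = DEFAULT_R_MAX,
        background: bool = True,
    ):
        r = np.asarray(r_nm, dtype=float).ravel()
        if r.size == 0:
            raise ValueError("cannot fit an empty displacement set")
        if np.any((r < 0) | (r > r_max)):
            raise ValueError("displacements outside [0, r_max]; filter first")
        self.r = r
        self.dt = float(dt)
        self.r_max = float(r_max)
        self.background = bool(background)
        self._r2_mean = float((r**2).mean())

    @classmethod
    def from_dataframe(cls, displacements: pd.DataFrame, **kwargs) -> "DisplacementModel":
        """Build a model from a displacement table with an ``r_nm`` column."""
        if "dt" not in kwargs and "dt" in displacements.attrs:
            kwargs["dt"] = displacements.attrs["dt"]
        return cls(displacements["r_nm"].to_numpy(), **kwargs)

    # -- likelihood ---------------------------------------------------------

    def loglike(self, d: float, k: float = 0.0) -> float:
        """Log-likelihood at ``d`` (μm²/s) and ``k`` (nm⁻²)."""
        body, norm = _pdf_terms(self.r, d / UM2_PER_NM2, k, self.dt, self.r_max)
        if np.any(body <= 0) or norm <= 0:
            return -np.inf
        return float(np.log(body).sum() - self.r.size * np.log(norm))

    def _nll_free(self, params: np.ndarray) -> float:
        """NLL in the mixture parametrization (log D, background weight w).

        ``p = (1-w) * truncated-Rayleigh + w * triangular`` is algebraically
        identical to the ``k``-form with
        ``k = 2 A w / ((1-w) r_max^2)``, ``A = 1 - exp(-r_max^2/4Dt)``,
        but keeps both coordinates O(1) for the optimizer.
        """
        log_d_nm, w = params
        if not 0.0 <= w < 1.0:
            return np.inf
        s = 4.0 * np.exp(log_d_nm) * self.dt
        a = 1.0 - np.exp(-(self.r_max**2) / s)
        dens = (1.0 - w) * (2.0 * self.r / s) * np.exp(-(self.r**2) / s) / a \
            + w * 2.0 * self.r / self.r_max**2
        if np.any(dens <= 0):
            return np.inf
        return -float(np.log(dens).sum())

    def _k_from_weight(self, log_d_nm: float, w: float) -> float:
        s = 4.0 * np.exp(log_d_nm) * self.dt
        a = 1.0 - np.exp(-(self.r_max**2) / s)
        return 2.0 * a * w / ((1.0 - w) * self.r_max**2)

    def _nll_fixed(self, log_d_nm: float) -> float:
        s = 4.0 * np.exp(log_d_nm) * self.dt
        # closed-form sum for the pure truncated-Rayleigh case
        n = self.r.size
        return -(
            n * np.log(2.0 / s)
            + np.log(self.r).sum()
            - n * self._r2_mean / s
            - n * np.log(1.0 - np.exp(-(self.r_max**2) / s))
        )

    # -- fitting ------------------------------------------------------------

    def fit(self, start_d: float | None = None, start_k: float = 0.0) -> DisplacementFitResults:
        """Maximize the likelihood.

        The diffusion coefficient is optimized on a log scale (it is
        positive by construction); the background slope is bounded below
        by zero. Initialization uses the method-of-moments value
        ``D0 = mean(r²) / (4 dt)`` unless ``start_d`` (μm²/s) is given.
        """
        d0_nm = self._r2_mean / (4.0 * self.dt) if start_d is None else start_d / UM2_PER_NM2
        d0_nm = max(d0_nm, 1e-12)
        if self.background:
            s0 = 4.0 * d0_nm * self.dt
            a0 = 1.0 - np.exp(-(self.r_max**2) / s0)
            b0 = 0.5 * start_k * self.r_max**2
            w0 = min(b0 / (a0 + b0), 0.99) if b0 > 0 else 0.05
            res = optimize.minimize(
                self._nll_free,
                x0=np.array([np.log(d0_nm), w0]),
                method="L-BFGS-B",
                bounds=[(None, None), (0.0, 1.0 - 1e-9)],
                options={"ftol": 1e-13, "gtol": 1e-10},
            )
            log_d_nm, w_hat = res.x
            k_hat = self._k_from_weight(log_d_nm, w_hat)
            converged = bool(res.success)
            loglik = -float(res.fun)
            se_log_d, se_k = self._standard_errors(log_d_nm, w_hat, free_k=True)
        else:
            res = optimize.minimize_scalar(
                self._nll_fixed,
                bracket=(np.log(d0_nm) - 0.7, np.log(d0_nm)),
                method="brent",
                options={"xtol": 1e-12},
            )
            log_d_nm, k_hat = float(res.x), 0.0
            converged = bool(res.success) if res.success is not None else True
            loglik = -float(res.fun)
            se_log_d, se_k = self._standard_errors(log_d_nm, 0.0, free_k=False)
        d_hat = float(np.exp(log_d_nm)) * UM2_PER_NM2
        return DisplacementFitResults(
            d=d_hat,
            k=float(k_hat),
            se_d=d_hat * se_log_d,  # delta method from log scale
            se_k=se_k,
            loglik=loglik,
            n=self.r.size,
            converged=converged and np.isfinite(loglik),
            model=self,
        )

    def _standard_errors(self, log_d_nm: float, second: float, free_k: bool):
        """SEs from a finite-difference observed information matrix.

        For the free-background fit the information is computed in the
        well-scaled (log D, w) coordinates and the SE of ``k`` follows by
        the delta method.
        """
        if free_k:
            f = self._nll_free
            w = second
            x = np.array([log_d_nm, w])
            h = np.array([1e-4, min(1e-4, max(w / 2, 1e-6), (1 - w) / 2)])
            hess = np.empty((2, 2))
            for i in range(2):
                for j in range(2):
                    ei = np.eye(2)[i] * h[i]
                    ej = np.eye(2)[j] * h[j]
                    hess[i, j] = (
                        f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                    ) / (4 * h[i] * h[j])
            try:
                cov = np.linalg.inv(hess)
                if cov[0, 0] <= 0 or cov[1, 1] <= 0:
                    raise np.linalg.LinAlgError
                grad_k = np.array([
                    (self._k_from_weight(log_d_nm + h[0], w)
                     - self._k_from_weight(log_d_nm - h[0], w)) / (2 * h[0]),
                    (self._k_from_weight(log_d_nm, w + h[1])
                     - self._k_from_weight(log_d_nm, max(w - h[1], 0.0)))
                    / (h[1] + min(w, h[1])),
                ])
                var_k = float(grad_k @ cov @ grad_k)
                se_k = float(np.sqrt(var_k)) if var_k > 0 else float("nan")
                return float(np.sqrt(cov[0, 0])), se_k
            except np.linalg.LinAlgError:
                return float("nan"), float("nan")
        h = 1e-4
        d2 = (self._nll_fixed(log_d_nm + h) - 2 * self._nll_fixed(log_d_nm)
              + self._nll_fixed(log_d_nm - h)) / h**2
        return (float(1.0 / np.sqrt(d2)) if d2 > 0 else float("nan")), float("nan")

    # -- simulation ---------------------------------------------------------

    def sample(self, n: int, d: float, k: float = 0.0, rng=None) -> np.ndarray:
        """Draw ``n`` displacement lengths (nm) from the fitted family."""
        return sample_displacements(n, d, k, self.dt, self.r_max, rng)


def fit_mle(
    displacements,
    dt: float = DEFAULT_DT,
    r_max: float = DEFAULT_R_MAX,
    fix_k_zero: bool = False,
) -> DisplacementFitResults:
    """Convenience wrapper: fit a displacement set in one call.

    ``displacements`` may be a DataFrame with an ``r_nm`` column or a bare
    array of lengths in nm.
    """
    if isinstance(displacements, pd.DataFrame):
        r = displacements["r_nm"].to_numpy()
    else:
        r = np.asarray(displacements, dtype=float)
    return DisplacementModel(r, dt=dt, r_max=r_max, background=not fix_k_zero).fit()
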