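"""Fitting binding models to measurement tables.

The workhorse is the 2-parameter saturation binding curve

    B(c) = B_max * c / (K_d + c)

fitted per DNA target to (free concentration, bound signal) pairs by
nonlinear least squares, with 5-95 % credible intervals from an MCMC
exploration of (log K_d, log B_max, log sigma) under flat log-priors.

On top of that sit:

* occupancy calibration — the linear increase of B_max with the number of
  identical sites; its slope is the fluorescence step per bound TF and
  converts signal to mean occupancy;
* cross points — the concentration at which a cluster's occupancy curve
  meets a reference (single strong site) curve;
* clash-energy fitting — the permissive model's single floating
  interaction energy eps_clash, fitted against the exclusive alternative
  and compared by AIC/BIC.

Model classes follow the Model -> fit() -> Results convention; every
operation is also exposed as a plain function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .designs import ClusterDesign
from .statmech import StatMechModel, mean_occupancy

__all__ = [
    "FitError",
    "NoCrossingError",
    "DegenerateCurvesError",
    "ConvergenceError",
    "IdentifiabilityError",
    "SaturationBindingModel",
    "SaturationBindingResults",
    "OccupancyCalibration",
    "CrossPoint",
    "ClashEnergyModel",
    "ClashEnergyResults",
    "fit_sbc",
    "mcmc_credible_intervals",
    "calibrate_occupancy",
    "to_occupancy",
    "cross_point",
    "closed_form_cross_point",
    "langmuir_curve",
    "independent_cluster_curve",
    "fit_clash_energy",
    "aic",
    "bic",
    "select_model",
]


class FitError(ValueError):
    """Degenerate or invalid input to a fitting routine."""


class NoCrossingError(ValueError):
    """The two occupancy curves do not cross inside the search bracket."""


class DegenerateCurvesError(ValueError):
    """The two occupancy curves coincide; the cross point is undefined."""


class ConvergenceError(RuntimeError):
    """MCMC convergence diagnostic exceeded its threshold."""


class IdentifiabilityError(ValueError):
    """The requested parameter is not identifiable from the design."""


# ---------------------------------------------------------------------------
# Information criteria (Gaussian-likelihood forms)
# ---------------------------------------------------------------------------

def aic(rss: float, n_obs: int, k: int) -> float:
    """Akaike information criterion, AIC = n ln(RSS/n) + 2k."""
    _check_ic_args(rss, n_obs, k)
    return n_obs * np.log(rss / n_obs) + 2 * k


def bic(rss: float, n_obs: int, k: int) -> float:
    """Bayesian information criterion, BIC = n ln(RSS/n) + k ln(n)."""
    _check_ic_args(rss, n_obs, k)
    return n_obs * np.log(rss / n_obs) + k * np.log(n_obs)


def _check_ic_args(rss: float, n_obs: int, k: int) -> None:
    if not rss > 0:
        raise ValueError("rss must be > 0")
    if k < 1 or n_obs <= k:
        raise ValueError("need n_obs > k >= 1")


def select_model(
    fits: Mapping[str, tuple[float, int]], n_obs: int, criterion: str = "bic"
) -> str:
    """Pick the model with the lowest criterion.

    ``fits`` maps a model label to ``(rss, k)``; ``criterion`` is "aic" or
    "bic".  The parameter count ``k`` should include the noise variance so
    that differences reflect only the structural parameters.
    """
    fn = {"aic": aic, "bic": bic}[criterion]
    return min(fits, key=lambda name: fn(fits[name][0], n_obs, fits[name][1]))


# ---------------------------------------------------------------------------
# Saturation binding curve
# ---------------------------------------------------------------------------

def _sbc(c: np.ndarray, kd: float, bmax: float) -> np.ndarray:
    return bmax * c / (kd + c)


class SaturationBindingModel:
    """2-parameter saturation binding curve model for one DNA target.

    Parameters
    ----------
    conc : array-like
        Free TF concentrations at equilibrium, nM.
    signal : array-like
        Bound-TF signal (RFU, normalized by DNA signal), one per chamber.

    Notes
    -----
    Initialization for the least-squares fit is deterministic: K_d starts
    at the concentration whose mean signal is nearest half-maximal, B_max
    at the maximum observed signal.
    """

    def __init__(self, conc, signal, target_id: str = ""):
        conc = np.asarray(conc, dtype=float)
        signal = np.asarray(signal, dtype=float)
        if conc.shape != signal.shape or conc.ndim != 1:
            raise FitError("conc and signal must be equal-length 1-D arrays")
        if not (np.all(np.isfinite(conc)) and np.all(np.isfinite(signal))):
            raise FitError("non-finite values in measurements")
        if np.any(conc < 0):
            raise FitError("negative concentrations")
        if np.unique(conc).size < 3:
            raise FitError("need measurements at >= 3 distinct concentrations")
        if np.all(signal == 0):
            raise FitError("all-zero signals")
        self.conc = conc
        self.signal = signal
        self.target_id = target_id

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        target_id: str | None = None,
        conc_col: str = "free_conc_nM",
        signal_col: str = "bound_rfu",
        target_col: str = "target_id",
    ) -> "SaturationBindingModel":
        if target_id is not None:
            df = df[df[target_col] == target_id]
        return cls(
            df[conc_col].to_numpy(),
            df[signal_col].to_numpy(),
            target_id=target_id or "",
        )

    def _group_means(self) -> tuple[np.ndarray, np.ndarray]:
        cs = np.unique(self.conc)
        means = np.array([self.signal[self.conc == c].mean() for c in cs])
        return cs, means

    def fit(self) -> "SaturationBindingResults":
        cs, means = self._group_means()
        spread = means.max() - means.min()
        scale = max(abs(means).max(), 1.0)
        if spread <= 1e-12 * scale:
            raise FitError("no concentration dependence in the signal")
        bmax0 = float(self.signal.max())
        half = 0.5 * bmax0
        pos = cs[cs > 0]
        kd0 = float(pos[np.argmin(np.abs(means[cs > 0] - half))]) if pos.size else 1.0
        popt, pcov = optimize.curve_fit(
            _sbc,
            self.conc,
            self.signal,
            p0=[kd0, bmax0],
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            maxfev=20000,
        )
        kd, bmax = map(float, popt)
        resid = self.signal - _sbc(self.conc, kd, bmax)
        rss = float(resid @ resid)
        n = self.conc.size
        k = 3  # kd, bmax, sigma
        if kd < self.conc[self.conc > 0].min() or kd > self.conc.max():
            warnings.warn(
                f"target {self.target_id or '?'}: fitted K_d {kd:.3g} nM lies "
                "outside the measured concentration range",
                stacklevel=2,
            )
        return SaturationBindingResults(
            model=self,
            kd=kd,
            bmax=bmax,
            rss=rss,
            n_obs=n,
            aic=aic(rss, n, k) if rss > 0 else -np.inf,
            bic=bic(rss, n, k) if rss > 0 else -np.inf,
        )


@dataclass
class SaturationBindingResults:
    """Point estimates (K_d, B_max) with diagnostics and, after
    :meth:`sample_posterior`, 5-95 % credible intervals and draws."""

    model: SaturationBindingModel
    kd: float
    bmax: float
    rss: float
    n_obs: int
    aic: float
    bic: float
    kd_ci: tuple[float, float] | None = None
    bmax_ci: tuple[float, float] | None = None
    posterior_samples: pd.DataFrame | None = None
    converged: bool | None = None
    rhat: float | None = None

    @property
    def sigma(self) -> float:
        """Residual noise scale from the least-squares fit."""
        return float(np.sqrt(self.rss / self.n_obs))

    def predict(self, conc) -> np.ndarray:
        return _sbc(np.asarray(conc, dtype=float), self.kd, self.bmax)

    # -- MCMC ---------------------------------------------------------------

    def _log_prob_factory(self):
        c, y = self.model.conc, self.model.signal
        cpos = c[c > 0]
        lo_kd = np.log(cpos.min()) - 7.0
        hi_kd = np.log(c.max()) + 7.0
        lb = np.log(max(self.bmax, 1e-12))
        sigma0 = max(self.sigma, 1e-9 * max(abs(y).max(), 1.0))
        ls = np.log(sigma0)
        bounds = np.array(
            [[lo_kd, hi_kd], [lb - 7.0, lb + 7.0], [ls - 10.0, ls + 5.0]]
        )

        def log_prob(theta: np.ndarray) -> np.ndarray:
            theta = np.atleast_2d(theta)
            ok = np.all(
                (theta >= bounds[:, 0]) & (theta <= bounds[:, 1]), axis=1
            )
            kd = np.exp(theta[:, 0])
            bm = np.exp(theta[:, 1])
            sg = np.exp(theta[:, 2])
            pred = bm[:, None] * c[None, :] / (kd[:, None] + c[None, :])
            r = y[None, :] - pred
            ll = -0.5 * np.sum((r / sg[:, None]) ** 2, axis=1) - y.size * np.log(sg)
            ll = np.where(ok, ll, -np.inf)
            return ll

        return log_prob, bounds

    def sample_posterior(
        self,
        n_walkers: int = 32,
        n_steps: int = 700,
        burn: int = 200,
        seed: int = 0,
        rhat_threshold: float = 1.05,
        quantiles: tuple[float, float] = (5.0, 95.0),
    ) -> "SaturationBindingResults":
        """Sample (log K_d, log B_max, log sigma) and attach 5-95 %
        marginal credible intervals.

        Flat priors on the log-parameters within broad declared bounds.
        Raises :class:`ConvergenceError` (intervals withheld) when the
        split-walker R-hat exceeds ``rhat_threshold``.
        """
        import emcee

        log_prob, _ = self._log_prob_factory()
        rng = np.random.default_rng(seed)
        center = np.array(
            [np.log(self.kd), np.log(self.bmax), np.log(max(self.sigma, 1e-12))]
        )
        p0 = center[None, :] + 1e-3 * rng.standard_normal((n_walkers, 3))
        sampler = emcee.EnsembleSampler(n_walkers, 3, log_prob, vectorize=True)
        sampler.random_state = np.random.RandomState(seed).get_state()
        sampler.run_mcmc(p0, n_steps, progress=False)
        chain = sampler.get_chain(discard=burn)  # (steps, walkers, 3)
        self.rhat = float(_split_walker_rhat(chain))
        self.converged = self.rhat <= rhat_threshold
        if not self.converged:
            self.kd_ci = self.bmax_ci = None
            raise ConvergenceError(
                f"R-hat {self.rhat:.4f} exceeds threshold {rhat_threshold}; "
                "credible intervals withheld"
            )
        flat = chain.reshape(-1, 3)
        samples = pd.DataFrame(
            {
                "kd": np.exp(flat[:, 0]),
                "bmax": np.exp(flat[:, 1]),
                "sigma": np.exp(flat[:, 2]),
            }
        )
        self.posterior_samples = samples
        lo, hi = quantiles
        self.kd_ci = tuple(np.percentile(samples["kd"], [lo, hi]))
        self.bmax_ci = tuple(np.percentile(samples["bmax"], [lo, hi]))
        return self

    def curve_envelope(
        self, conc_grid, quantiles: tuple[float, float] = (5.0, 95.0)
    ) -> pd.DataFrame:
        """Pointwise posterior percentile envelope of B(c) over the draws."""
        if self.posterior_samples is None:
            raise ValueError("run sample_posterior() first")
        c = np.asarray(conc_grid, dtype=float)
        kd = self.posterior_samples["kd"].to_numpy()
        bm = self.posterior_samples["bmax"].to_numpy()
        pred = bm[:, None] * c[None, :] / (kd[:, None] + c[None, :])
        lo, hi = np.percentile(pred, quantiles, axis=0)
        return pd.DataFrame(
            {"c_nM": c, "lower": lo, "upper": hi, "fit": self.predict(c)}
        )

    def summary(self) -> str:
        lines = [
            "Saturation binding curve fit"
            + (f" — target {self.model.target_id}" if self.model.target_id else ""),
            "-" * 46,
            f"  K_d    : {self.kd:12.4g} nM",
            f"  B_max  : {self.bmax:12.4g} RFU",
            f"  RSS    : {self.rss:12.4g} RFU^2   (n = {self.n_obs})",
            f"  AIC    : {self.aic:12.4g}",
            f"  BIC    : {self.bic:12.4g}",
        ]
        if self.kd_ci is not None:
            lines.append(
                f"  K_d  5-95% : [{self.kd_ci[0]:.4g}, {self.kd_ci[1]:.4g}] nM"
            )
            lines.append(
                f"  B_max 5-95%: [{self.bmax_ci[0]:.4g}, {self.bmax_ci[1]:.4g}] RFU"
            )
        return "\n".join(lines)

    def plot(self, ax=None, n_grid: int = 200):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c, y = self.model.conc, self.model.signal
        cpos = c[c > 0]
        grid = np.geomspace(cpos.min() / 3, c.max() * 3, n_grid)
        ax.plot(c, y, "o", ms=4, alpha=0.5, label="chambers")
        ax.plot(grid, self.predict(grid), "-", label="fit")
        if self.posterior_samples is not None:
            env = self.curve_envelope(grid)
            ax.fill_between(env["c_nM"], env["lower"], env["upper"], alpha=0.25)
        ax.set_xscale("log")
        ax.set_xlabel("free TF (nM)")
        ax.set_ylabel("bound signal (RFU)")
        ax.legend()
        return ax


def _split_walker_rhat(chain: np.ndarray, n_groups: int = 4) -> float:
    """Gelman-Rubin R-hat treating groups of walkers as chains.

    ``chain`` has shape (steps, walkers, ndim).  Returns the max over
    parameters.
    """
    steps, walkers, ndim = chain.shape
    groups = np.array_split(np.arange(walkers), n_groups)
    worst = 1.0
    for d in range(ndim):
        seqs = [chain[:, g, d].ravel() for g in groups]
        m = len(seqs)
        n = min(len(s) for s in seqs)
        seqs = np.array([s[:n] for s in seqs])
        means = seqs.mean(axis=1)
        variances = seqs.var(axis=1, ddof=1)
        b = n * means.var(ddof=1)
        w = variances.mean()
        if w <= 0:
            continue
        var_hat = (n - 1) / n * w + b / n
        worst = max(worst, float(np.sqrt(var_hat / w)))
    return worst


def fit_sbc(conc, signal, target_id: str = "") -> SaturationBindingResults:
    """Least-squares 2-parameter saturation-binding fit (functional API)."""
    return SaturationBindingModel(conc, signal, target_id=target_id).fit()


def mcmc_credible_intervals(
    fit: SaturationBindingResults, seed: int = 0, **settings
) -> SaturationBindingResults:
    """Attach MCMC 5-95 % credible intervals to a point fit."""
    return fit.sample_posterior(seed=seed, **settings)


# ---------------------------------------------------------------------------
# Occupancy calibration
# ---------------------------------------------------------------------------

@dataclass
class OccupancyCalibration:
    """Linear B_max(n) = step * n + intercept calibration.

    ``step`` is the fluorescence per bound TF (RFU per molecule); dividing
    bound signal by it converts RFU to mean occupancy.
    """

    step: float
    intercept: float
    r_squared: float
    fit_range: tuple[int, int]
    n_used: int

    def to_occupancy(self, bound_signal, use_intercept: bool = False):
        return to_occupancy(bound_signal, self, use_intercept=use_intercept)


def calibrate_occupancy(
    site_counts,
    bmax_values,
    fit_range: tuple[int, int] | None = None,
    through_origin: bool = False,
) -> OccupancyCalibration:
    """OLS of B_max against the number of identical sites.

    ``fit_range`` restricts to site counts in the closed interval (the
    linear regime); by default the intercept is free, with a
    through-the-origin option.
    """
    n = np.asarray(site_counts, dtype=float)
    b = np.asarray(bmax_values, dtype=float)
    if n.shape != b.shape or n.ndim != 1:
        raise FitError("site_counts and bmax_values must be equal-length 1-D")
    if fit_range is not None:
        keep = (n >= fit_range[0]) & (n <= fit_range[1])
        n, b = n[keep], b[keep]
    if np.unique(n).size < 2:
        raise FitError("need >= 2 distinct site counts in the fit range")
    if through_origin:
        step = float(n @ b / (n @ n))
        intercept = 0.0
        pred = step * n
        ss_res = float(((b - pred) ** 2).sum())
        ss_tot = float(((b - b.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    else:
        res = stats.linregress(n, b)
        step, intercept = float(res.slope), float(res.intercept)
        r2 = float(res.rvalue**2)
    return OccupancyCalibration(
        step=step,
        intercept=intercept,
        r_squared=r2,
        fit_range=(int(n.min()), int(n.max())),
        n_used=n.size,
    )


def to_occupancy(
    bound_signal, calibration: OccupancyCalibration, use_intercept: bool = False
):
    """Convert bound signal (RFU) to mean occupancy via the calibration step.

    Default policy divides the raw signal by the step; ``use_intercept``
    subtracts the calibration intercept first.
    """
    if not calibration.step > 0:
        raise FitError("calibration step must be > 0")
    sig = np.asarray(bound_signal, dtype=float)
    if use_intercept:
        sig = sig - calibration.intercept
    out = sig / calibration.step
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Cross points
# ---------------------------------------------------------------------------

@dataclass
class CrossPoint:
    """Concentration at which two occupancy curves meet."""

    conc: float
    occupancy_at_cross: float
    bracket: tuple[float, float]
    all_roots: tuple[float, ...] = ()


def langmuir_curve(kd: float) -> Callable[[np.ndarray], np.ndarray]:
    """Single-site occupancy curve c -> c / (c + K_d)."""
    return lambda c: np.asarray(c, dtype=float) / (np.asarray(c, dtype=float) + kd)


def independent_cluster_curve(n: int, kd: float) -> Callable[[np.ndarray], np.ndarray]:
    """n identical independent sites: c -> n c / (c + K_d)."""
    return lambda c: n * np.asarray(c, dtype=float) / (np.asarray(c, dtype=float) + kd)


def closed_form_cross_point(n: int, kd_weak: float, kd_strong: float) -> float:
    """Cross point of n identical independent weak sites against one strong
    site: c* = (K_w - n K_s) / (n - 1).  Raises on degenerate/no-crossing."""
    if n == 1:
        if np.isclose(kd_weak, kd_strong):
            raise DegenerateCurvesError("curves coincide")
        raise NoCrossingError("single-site curves never cross for K_w != K_s")
    c = (kd_weak - n * kd_strong) / (n - 1)
    if c <= 0:
        raise NoCrossingError("no crossing at positive concentration")
    return c


def cross_point(
    cluster_curve: Callable,
    reference_curve: Callable,
    bracket: tuple[float, float] = (1e-3, 1e6),
    n_scan: int = 241,
    xtol: float = 1e-12,
) -> CrossPoint:
    """Concentration where the cluster occupancy equals the reference.

    Bisection (Brent) on log-concentration over the bracket; the first
    sign change is used and multiple crossings raise a warning listing all
    roots.  Curves that coincide over the whole bracket raise
    :class:`DegenerateCurvesError`; no sign change raises
    :class:`NoCrossingError`.
    """
    lo, hi = bracket
    grid = np.geomspace(lo, hi, n_scan)
    diff = np.asarray(cluster_curve(grid)) - np.asarray(reference_curve(grid))
    scale = max(
        np.abs(np.asarray(cluster_curve(grid))).max(),
        np.abs(np.asarray(reference_curve(grid))).max(),
        1e-30,
    )
    if np.all(np.abs(diff) <= 1e-12 * scale):
        raise DegenerateCurvesError("degenerate: curves coincide")

    def f(logc: float) -> float:
        c = np.exp(logc)
        return float(cluster_curve(c) - reference_curve(c))

    roots = []
    for i in range(n_scan - 1):
        a, b = diff[i], diff[i + 1]
        if a == 0.0:
            roots.append(grid[i])
        elif a * b < 0:
            r = optimize.brentq(
                f, np.log(grid[i]), np.log(grid[i + 1]), xtol=xtol
            )
            roots.append(float(np.exp(r)))
    if diff[-1] == 0.0:
        roots.append(grid[-1])
    # dedupe near-identical roots from exact-zero endpoints
    uniq: list[float] = []
    for r in roots:
        if not uniq or abs(r - uniq[-1]) > 1e-9 * max(r, uniq[-1]):
            uniq.append(r)
    if not uniq:
        raise NoCrossingError("no crossing inside the bracket")
    if len(uniq) > 1:
        warnings.warn(
            f"multiple crossings found at {uniq}; reporting the first",
            stacklevel=2,
        )
    c_star = uniq[0]
    return CrossPoint(
        conc=c_star,
        occupancy_at_cross=float(np.asarray(reference_curve(c_star))),
        bracket=bracket,
        all_roots=tuple(uniq),
    )


# ---------------------------------------------------------------------------
# Clash-energy fitting and model selection
# ---------------------------------------------------------------------------

class ClashEnergyModel:
    """Fit the permissive model's clash energy on a cluster with overlaps.

    Parameters
    ----------
    design : ClusterDesign
        Must contain at least one pair of sites sharing basepairs.
    site_kds : sequence of float
        Per-specific-site K_d (nM) from an independent single-site
        characterization; held fixed during the fit.
    conc, response : array-like
        Measured free concentrations (nM) and responses.  The response is
        signal proportional to mean occupancy (e.g. bound RFU); an overall
        signal scale is co-fitted, so units are free.

    The permissive fit floats (eps_clash, scale); the exclusive
    alternative floats only the scale.  Both are compared via AIC/BIC with
    the noise variance counted as a parameter in each.
    """

    def __init__(self, design: ClusterDesign, site_kds, conc, response):
        if not design.has_overlaps():
            raise IdentifiabilityError(
                f"target {design.target_id}: no overlapping pair, "
                "no clash parameter identifiable"
            )
        self.design = design
        self.kds = np.asarray(site_kds, dtype=float)
        self.conc = np.asarray(conc, dtype=float)
        self.response = np.asarray(response, dtype=float)
        if self.conc.shape != self.response.shape:
            raise FitError("conc and response must have the same shape")

    def _occ(self, eps: float, mode: str) -> np.ndarray:
        model = StatMechModel(
            kds=self.kds, mode=mode, eps_clash=max(eps, 0.0)
        )
        return np.asarray(mean_occupancy(self.design, self.conc, model))

    def fit(
        self,
        eps_bounds: tuple[float, float] = (0.0, 30.0),
        eps_grid: int = 31,
    ) -> "ClashEnergyResults":
        y = self.response
        n = y.size

        def scale_for(occ: np.ndarray) -> float:
            denom = occ @ occ
            return float(y @ occ / denom) if denom > 0 else 0.0

        def rss_perm(eps: float) -> float:
            occ = self._occ(eps, "permissive")
            s = scale_for(occ)
            r = y - s * occ
            return float(r @ r)

        # profile eps on a grid, refine around the best point
        grid = np.linspace(eps_bounds[0], eps_bounds[1], eps_grid)
        rss_grid = np.array([rss_perm(e) for e in grid])
        i = int(np.argmin(rss_grid))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, eps_grid - 1)]
        res = optimize.minimize_scalar(
            rss_perm, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        eps_hat = float(res.x)
        occ_p = self._occ(eps_hat, "permissive")
        scale_p = scale_for(occ_p)
        rss_p = rss_perm(eps_hat)

        occ_e = self._occ(0.0, "exclusive")
        scale_e = scale_for(occ_e)
        r_e = y - scale_e * occ_e
        rss_e = float(r_e @ r_e)

        # curvature-based standard error for eps (Gaussian approximation)
        sigma2 = rss_p / n
        h = 1e-3 * max(eps_hat, 1.0)
        e_lo = max(eps_hat - h, eps_bounds[0])
        e_hi = min(eps_hat + h, eps_bounds[1])
        d2 = (
            rss_perm(e_hi) - 2.0 * rss_p + rss_perm(e_lo)
        ) / ((0.5 * (e_hi - e_lo)) ** 2 or 1.0)
        if d2 > 0:
            se = float(np.sqrt(2.0 * sigma2 / d2))
            z = stats.norm.ppf(0.95)
            eps_ci = (max(eps_hat - z * se, 0.0), eps_hat + z * se)
        else:
            eps_ci = (eps_bounds[0], eps_bounds[1])

        k_perm, k_excl = 3, 2  # (eps, scale, sigma) vs (scale, sigma)
        return ClashEnergyResults(
            model=self,
            eps_clash=eps_hat,
            eps_ci=eps_ci,
            scale_permissive=scale_p,
            scale_exclusive=scale_e,
            rss_permissive=rss_p,
            rss_exclusive=rss_e,
            n_obs=n,
            aic_permissive=aic(rss_p, n, k_perm),
            bic_permissive=bic(rss_p, n, k_perm),
            aic_exclusive=aic(rss_e, n, k_excl),
            bic_exclusive=bic(rss_e, n, k_excl),
        )


@dataclass
class ClashEnergyResults:
    """Fitted clash energy plus the permissive/exclusive model comparison."""

    model: ClashEnergyModel
    eps_clash: float
    eps_ci: tuple[float, float]
    scale_permissive: float
    scale_exclusive: float
    rss_permissive: float
    rss_exclusive: float
    n_obs: int
    aic_permissive: float
    bic_permissive: float
    aic_exclusive: float
    bic_exclusive: float

    def select(self, criterion: str = "bic") -> str:
        vals = {
            "permissive": (
                self.aic_permissive if criterion == "aic" else self.bic_permissive
            ),
            "exclusive": (
                self.aic_exclusive if criterion == "aic" else self.bic_exclusive
            ),
        }
        return min(vals, key=vals.get)

    def summary(self) -> str:
        return "\n".join(
            [
                f"Clash-energy fit — target {self.model.design.target_id}",
                "-" * 46,
                f"  eps_clash        : {self.eps_clash:8.3f} k_BT "
                f"(5-95% [{self.eps_ci[0]:.3f}, {self.eps_ci[1]:.3f}])",
                f"  permissive  RSS {self.rss_permissive:10.4g}  "
                f"AIC {self.aic_permissive:9.2f}  BIC {self.bic_permissive:9.2f}",
                f"  exclusive   RSS {self.rss_exclusive:10.4g}  "
                f"AIC {self.aic_exclusive:9.2f}  BIC {self.bic_exclusive:9.2f}",
                f"  selected (AIC/BIC): {self.select('aic')}/{self.select('bic')}",
            ]
        )


def fit_clash_energy(
    design: ClusterDesign, site_kds, conc, response, **kwargs
) -> ClashEnergyResults:
    """Functional wrapper around :class:`ClashEnergyModel`."""
    return ClashEnergyModel(design, site_kds, conc, response).fit(**kwargs)
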