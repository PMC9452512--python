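"""Platereader response analysis and the occupancy-expression threshold model.

Yeast strains carrying promoter variants are grown with and without
induction while OD600 and a GFP reporter are read every 10 minutes.  The
processing chain is:

1. blank-subtract both channels and divide GFP by OD at every time point;
2. average the normalized expression inside a fixed window after induction
   (8.5-9.5 h by default);
3. split each strain's output into a TF-specific response
   (induced - uninduced window means) and a non-specific response
   (uninduced strain - uninduced no-site reference strain);
4. predict each promoter's mean TF occupancy from in-vitro parameters
   (site K_ds and a nuclear concentration estimate) and fit a hinge
   ("thresholded") model: expression is at baseline until the predicted
   occupancy exceeds a threshold theta (around one bound TF), then rises
   linearly with occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import optimize

from .designs import ClusterDesign
from .statmech import StatMechModel, mean_occupancy

__all__ = [
    "AVOGADRO",
    "DEFAULT_WINDOW_H",
    "DEFAULT_OD_FLOOR",
    "InVivoError",
    "ThresholdUnidentifiableError",
    "WindowMean",
    "Response",
    "normalize_series",
    "window_average",
    "specific_response",
    "nonspecific_response",
    "copies_to_concentration",
    "predict_occupancy",
    "ThresholdModel",
    "ThresholdResults",
    "fit_threshold_model",
]

AVOGADRO = 6.02214076e23  # molecules per mole

#: Window after induction over which normalized expression is averaged (h).
DEFAULT_WINDOW_H = (8.5, 9.5)

#: Minimum blank-subtracted OD for a usable normalized point.
DEFAULT_OD_FLOOR = 0.01

#: Candidate thresholds below this occupancy are not considered; activation
#: at a small fraction of one bound TF is indistinguishable from baseline.
DEFAULT_THETA_MIN = 0.2


class InVivoError(ValueError):
    """Invalid platereader input."""


class ThresholdUnidentifiableError(InVivoError):
    """Occupancies all fall on one side of every feasible threshold."""


def normalize_series(
    od600,
    gfp,
    blank_od: float = 0.0,
    blank_gfp: float = 0.0,
    od_floor: float = DEFAULT_OD_FLOOR,
) -> np.ndarray:
    """Blank-subtracted GFP divided by blank-subtracted OD, per time point.

    Points whose OD falls below ``od_floor`` after blank subtraction are
    masked (NaN).  Raises when every point is below the floor.
    """
    od = np.asarray(od600, dtype=float) - blank_od
    g = np.asarray(gfp, dtype=float) - blank_gfp
    ok = od >= od_floor
    if not ok.any():
        raise InVivoError("all points below the OD floor after blank subtraction")
    out = np.full_like(g, np.nan, dtype=float)
    out[ok] = g[ok] / od[ok]
    return out


class WindowMean(NamedTuple):
    mean: float
    n_readings: int


def window_average(
    time_h,
    values,
    window: tuple[float, float] = DEFAULT_WINDOW_H,
) -> WindowMean:
    """Arithmetic mean of readings inside the closed time window.

    A 10-minute cadence starting at induction time zero places 7 readings
    in the default [8.5, 9.5] h window.  Masked (NaN) readings are dropped.
    """
    t = np.asarray(time_h, dtype=float)
    v = np.asarray(values, dtype=float)
    sel = (t >= window[0]) & (t <= window[1]) & np.isfinite(v)
    if not sel.any():
        raise InVivoError(f"no readings inside window {window}")
    return WindowMean(mean=float(v[sel].mean()), n_readings=int(sel.sum()))


@dataclass
class Response:
    """A condition-difference response with its replicate spread."""

    value: float
    replicate_values: tuple[float, ...] = ()
    sd: float = float("nan")


def _response(a: Sequence[float], b: Sequence[float]) -> Response:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InVivoError("missing condition: empty replicate set")
    value = float(a.mean() - b.mean())
    if a.size == b.size:
        diffs = a - b
        return Response(
            value=value,
            replicate_values=tuple(diffs),
            sd=float(diffs.std(ddof=1)) if diffs.size > 1 else float("nan"),
        )
    sd = float(np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)) if (
        a.size > 1 and b.size > 1
    ) else float("nan")
    return Response(value=value, replicate_values=(), sd=sd)


def specific_response(induced_means, uninduced_means) -> Response:
    """TF-specific response: induced minus uninduced window means.

    Replicates are paired positionally when the two conditions have equal
    counts; otherwise the unpaired difference of condition means is used.
    """
    return _response(induced_means, uninduced_means)


def nonspecific_response(strain_uninduced_means, reference_uninduced_means) -> Response:
    """Non-specific response: uninduced strain minus uninduced reference
    (no-site or ablated promoter) strain.  May be negative."""
    return _response(strain_uninduced_means, reference_uninduced_means)


def copies_to_concentration(copies: float, nuclear_volume_fl: float = 4.2) -> float:
    """Convert TF copies per cell to a nuclear concentration in nM.

    conc = copies / (N_A * V).  The default nuclear volume of 4.2 fL maps
    538 copies to roughly 213 nM.
    """
    if copies < 0:
        raise InVivoError("copies must be >= 0")
    if not nuclear_volume_fl > 0:
        raise InVivoError("nuclear volume must be > 0")
    molar = copies / (AVOGADRO * nuclear_volume_fl * 1e-15)
    return molar * 1e9


def predict_occupancy(
    design: ClusterDesign,
    nuclear_conc_nm: float,
    consensus_kd: float,
    mode: str | None = None,
    eps_clash: float = 0.0,
) -> float:
    """Predicted mean occupancy of a promoter at a nuclear concentration.

    Delegates to the statistical-mechanical model; by default binding is
    independent, switching to the permissive model (with the supplied
    eps_clash) when the design contains overlapping sites.
    """
    if design.n_sites == 0:
        return 0.0
    if mode is None:
        mode = "permissive" if design.has_overlaps() else "independent"
    model = StatMechModel.from_design(
        design, consensus_kd, mode=mode, eps_clash=eps_clash
    )
    return float(mean_occupancy(design, nuclear_conc_nm, model))


# ---------------------------------------------------------------------------
# Threshold (hinge) model
# ---------------------------------------------------------------------------

def _hinge_lsq(occ: np.ndarray, expr: np.ndarray, theta: float):
    """Least-squares (baseline, slope) for fixed theta; returns rss too."""
    x = np.maximum(0.0, occ - theta)
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, expr, rcond=None)
    resid = expr - design @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


class ThresholdModel:
    """Hinge model of expression against predicted mean occupancy:

        expression = baseline + slope * max(0, <N> - theta)

    theta is profiled over a grid of candidate thresholds and refined by
    bounded scalar minimization of the residual sum of squares;
    uncertainty comes from a bootstrap over promoters.
    """

    def __init__(self, occupancies, expressions):
        occ = np.asarray(occupancies, dtype=float)
        expr = np.asarray(expressions, dtype=float)
        if occ.shape != expr.shape or occ.ndim != 1:
            raise InVivoError("occupancies and expressions must match 1-D")
        if occ.size < 4:
            raise InVivoError("need >= 4 promoters to fit a threshold model")
        self.occ = occ
        self.expr = expr

    def _theta_grid(self, theta_min: float, n_grid: int) -> np.ndarray:
        grid = np.linspace(theta_min, float(self.occ.max()), n_grid)
        feasible = np.array(
            [
                (self.occ <= t).any() and (self.occ > t).sum() >= 2
                for t in grid
            ]
        )
        if not feasible.any():
            raise ThresholdUnidentifiableError(
                "threshold unidentifiable: occupancies lie on one side of "
                "every feasible threshold"
            )
        return grid[feasible]

    def _fit_point(self, occ, expr, theta_min, n_grid):
        grid = np.linspace(theta_min, float(occ.max()), n_grid)
        feasible = [
            t for t in grid if (occ <= t).any() and (occ > t).sum() >= 2
        ]
        if not feasible:
            raise ThresholdUnidentifiableError("threshold unidentifiable")
        feasible = np.asarray(feasible)
        rss = np.array([_hinge_lsq(occ, expr, t)[2] for t in feasible])
        i = int(np.argmin(rss))
        lo = feasible[max(i - 1, 0)]
        hi = feasible[min(i + 1, feasible.size - 1)]
        if hi > lo:
            res = optimize.minimize_scalar(
                lambda t: _hinge_lsq(occ, expr, t)[2],
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-10},
            )
            theta = float(res.x)
            if res.fun > rss[i]:
                theta = float(feasible[i])
        else:
            theta = float(feasible[i])
        baseline, slope, rss_hat = _hinge_lsq(occ, expr, theta)
        return theta, slope, baseline, rss_hat

    def fit(
        self,
        theta_min: float = DEFAULT_THETA_MIN,
        n_grid: int = 101,
        n_bootstrap: int = 200,
        seed: int = 0,
    ) -> "ThresholdResults":
        self._theta_grid(theta_min, n_grid)  # identifiability check
        theta, slope, baseline, rss = self._fit_point(
            self.occ, self.expr, theta_min, n_grid
        )
        rng = np.random.default_rng(seed)
        boot = []
        n = self.occ.size
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, n)
            try:
                boot.append(
                    self._fit_point(self.occ[idx], self.expr[idx], theta_min, n_grid)
                )
            except ThresholdUnidentifiableError:
                continue
        boot_arr = np.asarray(boot) if boot else np.empty((0, 4))
        def ci(col: int) -> tuple[float, float]:
            if boot_arr.shape[0] < 10:
                return (float("nan"), float("nan"))
            lo, hi = np.percentile(boot_arr[:, col], [5, 95])
            return (float(lo), float(hi))

        return ThresholdResults(
            model=self,
            theta=theta,
            slope=slope,
            baseline=baseline,
            rss=rss,
            n_obs=n,
            theta_ci=ci(0),
            slope_ci=ci(1),
            baseline_ci=ci(2),
            n_bootstrap=int(boot_arr.shape[0]),
        )


@dataclass
class ThresholdResults:
    """Fitted hinge parameters with bootstrap 5-95 % intervals."""

    model: ThresholdModel
    theta: float
    slope: float
    baseline: float
    rss: float
    n_obs: int
    theta_ci: tuple[float, float]
    slope_ci: tuple[float, float]
    baseline_ci: tuple[float, float]
    n_bootstrap: int

    def predict(self, occupancies) -> np.ndarray:
        occ = np.asarray(occupancies, dtype=float)
        return self.baseline + self.slope * np.maximum(0.0, occ - self.theta)

    def summary(self) -> str:
        return "\n".join(
            [
                "Thresholded activation fit",
                "-" * 46,
                f"  theta    : {self.theta:8.3f} occupancy "
                f"(5-95% [{self.theta_ci[0]:.3f}, {self.theta_ci[1]:.3f}])",
                f"  slope    : {self.slope:8.3f} expr / occupancy",
                f"  baseline : {self.baseline:8.3f} expr",
                f"  RSS      : {self.rss:8.4g}  (n = {self.n_obs}, "
                f"{self.n_bootstrap} bootstrap refits)",
            ]
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        occ, expr = self.model.occ, self.model.expr
        ax.plot(occ, expr, "o", alpha=0.6, label="promoters")
        grid = np.linspace(0, occ.max() * 1.05, 200)
        ax.plot(grid, self.predict(grid), "-", label="hinge fit")
        ax.axvline(self.theta, ls="--", color="gray", lw=1)
        ax.set_xlabel(r"predicted mean occupancy $\langle N\rangle$")
        ax.set_ylabel("expression (GFP/OD)")
        ax.legend()
        return ax


def fit_threshold_model(occupancies, expressions, **kwargs) -> ThresholdResults:
    """Functional wrapper around :class:`ThresholdModel`."""
    return ThresholdModel(occupancies, expressions).fit(**kwargs)
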