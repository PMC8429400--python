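"""Quantification of ratiometric pH-probe data.

Covers the analysis chain from raw 420/470 nm excitation ratios to
biological summaries: sigmoidal calibration fitting and its analytic
inverse, mono-exponential initial-rate estimation for acidification and
leak time courses, expression-binned regression, Gaussian-mixture
subpopulation detection, and group comparison statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.mixture import GaussianMixture

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "CellMeasurement",
    "RateEstimate",
    "BinRegression",
    "MixtureResult",
    "BoxSummary",
    "CalibrationError",
    "fit_calibration",
    "sigmoid_ratio",
    "ratio_to_ph",
    "estimate_initial_rate",
    "bin_and_regress",
    "detect_populations",
    "group_compare",
    "box_summary",
]


class CalibrationError(RuntimeError):
    """Raised when calibration data cannot support a sigmoid fit."""


@dataclass(frozen=True)
class CalibrationPoint:
    buffer_ph: float
    ratio: float

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")


@dataclass(frozen=True)
class CalibrationCurve:
    """Four-parameter logistic ratio(pH) curve.

    ``ratio(pH) = r_min + (r_max - r_min) / (1 + 10**(hill_slope * (midpoint_ph - pH)))``

    Invertible for ratios strictly inside ``(r_min, r_max)``.
    """

    r_min: float
    r_max: float
    midpoint_ph: float
    hill_slope: float
    residual_sd: float
    n_points: int

    def __post_init__(self) -> None:
        if not self.r_min < self.r_max:
            raise ValueError("requires r_min < r_max")
        if self.hill_slope <= 0:
            raise ValueError("hill_slope must be positive")

    def predict(self, ph):
        return sigmoid_ratio(ph, self.r_min, self.r_max, self.midpoint_ph, self.hill_slope)


def sigmoid_ratio(ph, r_min, r_max, midpoint_ph, hill_slope):
    ph = np.asarray(ph, dtype=float)
    out = r_min + (r_max - r_min) / (1.0 + 10.0 ** (hill_slope * (midpoint_ph - ph)))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class CellMeasurement:
    cell_id: str
    ratio: float
    expression_au: float
    group: str = ""


@dataclass(frozen=True)
class RateEstimate:
    """Mono-exponential relaxation fit of a pH time course.

    ``initial_rate`` is the fitted t=0 derivative in pH/min, negative for
    acidification.  ``flat`` marks series where no relaxation was resolvable
    (rate forced to 0).
    """

    initial_rate: float
    plateau_ph: float
    rate_constant: float
    fit_rmse: float
    flat: bool = False


@dataclass(frozen=True)
class BoxSummary:
    median: float
    p10: float
    p90: float
    n: int

    def __post_init__(self) -> None:
        if not self.p10 <= self.median <= self.p90:
            raise ValueError("requires p10 <= median <= p90")


@dataclass(frozen=True)
class BinRegression:
    bin_edges: np.ndarray
    bin_mean_ph: np.ndarray
    bin_sd_ph: np.ndarray
    bin_n: np.ndarray
    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class MixtureResult:
    n_components: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    selection_score: dict[int, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# calibration


def fit_calibration(points) -> CalibrationCurve:
    """Least-squares 4-parameter logistic fit of ratio vs buffer pH.

    ``points`` is an iterable of :class:`CalibrationPoint` or ``(ph, ratio)``
    pairs; at least four distinct pH values spanning the sigmoid are
    required.  Degenerate (flat or non-monotone) data raise
    :class:`CalibrationError` with diagnostics.
    """
    ph = np.array([p.buffer_ph if isinstance(p, CalibrationPoint) else p[0] for p in points])
    ratio = np.array([p.ratio if isinstance(p, CalibrationPoint) else p[1] for p in points])
    if np.unique(ph).size < 4:
        raise CalibrationError(f"need >= 4 distinct pH points, got {np.unique(ph).size}")
    if np.ptp(ratio) < 1e-12 * max(1.0, abs(ratio.mean())):
        raise CalibrationError("ratios are constant; r_min = r_max is degenerate")
    order = np.argsort(ph)
    rho = stats.spearmanr(ph[order], ratio[order]).statistic
    if not rho > 0:
        raise CalibrationError(
            f"ratio is not increasing with pH (spearman rho = {rho:.2f}); "
            "check probe orientation or data integrity"
        )

    span = np.ptp(ratio)
    p0 = (ratio.min() - 0.05 * span, ratio.max() + 0.05 * span, float(np.median(ph)), 1.0)
    lower = (-np.inf, -np.inf, ph.min() - 5.0, 1e-3)
    upper = (np.inf, np.inf, ph.max() + 5.0, 50.0)
    try:
        popt, _ = optimize.curve_fit(
            sigmoid_ratio, ph, ratio, p0=p0, bounds=(lower, upper), maxfev=20000
        )
    except RuntimeError as exc:
        raise CalibrationError(f"sigmoid fit did not converge: {exc}") from exc
    r_min, r_max, mid, slope = popt
    resid = ratio - sigmoid_ratio(ph, *popt)
    dof = max(len(ph) - 4, 1)
    return CalibrationCurve(
        r_min=float(r_min),
        r_max=float(r_max),
        midpoint_ph=float(mid),
        hill_slope=float(slope),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
        n_points=len(ph),
    )


def ratio_to_ph(curve: CalibrationCurve, ratio):
    """Analytic inverse of the calibration sigmoid.

    Ratios outside the open interval ``(r_min, r_max)`` are flagged as NaN
    with a warning — never clamped.  Accepts scalars or arrays.
    """
    r = np.atleast_1d(np.asarray(ratio, dtype=float))
    out = np.full(r.shape, np.nan)
    ok = (r > curve.r_min) & (r < curve.r_max)
    if not np.all(ok):
        warnings.warn(
            f"{int((~ok).sum())} ratio(s) outside the invertible range "
            f"({curve.r_min:.4g}, {curve.r_max:.4g}); returned as NaN",
            stacklevel=2,
        )
    span = curve.r_max - curve.r_min
    out[ok] = curve.midpoint_ph - np.log10(span / (r[ok] - curve.r_min) - 1.0) / curve.hill_slope
    return out if np.ndim(ratio) else float(out[0])


# ---------------------------------------------------------------------------
# rates


def _exp_model(t, p_inf, p0, k):
    return p_inf + (p0 - p_inf) * np.exp(-k * t)


def estimate_initial_rate(timecourse, linear_fallback: bool = False) -> RateEstimate:
    """Fit ``pH(t) = p_inf + (p0 - p_inf) * exp(-k t)`` and report the t=0 rate.

    ``timecourse`` is an (n, 2) array-like of (minutes, pH) with n >= 6.
    The initial rate is the fitted derivative at t=0, ``k * (p_inf - p0)``,
    negative for acidification.  Flat or unresolvable series yield rate 0
    with ``flat=True``.  ``linear_fallback=True`` instead returns the OLS
    slope of the first five points.
    """
    tc = np.asarray(timecourse, dtype=float)
    if tc.ndim != 2 or tc.shape[1] != 2 or tc.shape[0] < 6:
        raise ValueError("timecourse must be an (n >= 6, 2) array of (min, pH)")
    t = tc[:, 0] - tc[0, 0]
    ph = tc[:, 1]

    if linear_fallback:
        res = stats.linregress(t[:5], ph[:5])
        return RateEstimate(
            initial_rate=float(res.slope),
            plateau_ph=float(ph[-1]),
            rate_constant=float("nan"),
            fit_rmse=float(np.std(ph[:5] - (res.intercept + res.slope * t[:5]))),
        )

    span = np.ptp(ph)
    noise = float(np.std(np.diff(ph))) / math.sqrt(2.0)
    if span < 1e-6 or span < 2.0 * noise:
        return RateEstimate(
            initial_rate=0.0, plateau_ph=float(np.median(ph)),
            rate_constant=0.0, fit_rmse=noise, flat=True,
        )

    t_half = max(t[-1] / 5.0, t[1] - t[0])
    p0_guess = (ph[-1], ph[0], math.log(2.0) / t_half)
    try:
        popt, _ = optimize.curve_fit(
            _exp_model, t, ph, p0=p0_guess,
            bounds=((2.0, 2.0, 1e-6), (10.0, 10.0, 1e4)), maxfev=20000,
        )
    except RuntimeError:
        return RateEstimate(
            initial_rate=0.0, plateau_ph=float(ph[-1]),
            rate_constant=0.0, fit_rmse=float("nan"), flat=True,
        )
    p_inf, p0, k = popt
    resid = ph - _exp_model(t, *popt)
    return RateEstimate(
        initial_rate=float(k * (p_inf - p0)),
        plateau_ph=float(p_inf),
        rate_constant=float(k),
        fit_rmse=float(np.sqrt(np.mean(resid**2))),
    )


# ---------------------------------------------------------------------------
# binned regression


def bin_and_regress(
    expression_au, ph_values, lo: float = 200.0, hi: float = 5000.0, width: float = 600.0
) -> BinRegression:
    """Bin cells by expression intensity and regress bin-mean pH on midpoints.

    Bins are left-closed right-open ``[lo + i*width, lo + (i+1)*width)``;
    cells outside ``[lo, hi)`` are excluded (a cell at exactly ``hi`` is
    out).  Ordinary least squares on the non-empty bin means; at least two
    non-empty bins are required.
    """
    au = np.asarray(expression_au, dtype=float)
    ph = np.asarray(ph_values, dtype=float)
    if au.shape != ph.shape:
        raise ValueError("expression_au and ph_values must have the same length")
    edges = np.arange(lo, hi + width / 2, width)
    if edges[-1] < hi - 1e-9:
        edges = np.append(edges, hi)
    included = (au >= lo) & (au < hi)
    idx = np.digitize(au[included], edges) - 1  # 0-based bin index
    ph_in = ph[included]

    nbins = len(edges) - 1
    means = np.full(nbins, np.nan)
    sds = np.full(nbins, np.nan)
    counts = np.zeros(nbins, dtype=int)
    for b in range(nbins):
        sel = idx == b
        counts[b] = sel.sum()
        if counts[b]:
            means[b] = ph_in[sel].mean()
            sds[b] = ph_in[sel].std(ddof=1) if counts[b] > 1 else 0.0
    nonempty = counts > 0
    if nonempty.sum() < 2:
        raise ValueError(f"need >= 2 non-empty bins, got {int(nonempty.sum())}")

    mids = (edges[:-1] + edges[1:]) / 2.0
    res = stats.linregress(mids[nonempty], means[nonempty])
    return BinRegression(
        bin_edges=edges,
        bin_mean_ph=means,
        bin_sd_ph=sds,
        bin_n=counts,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


# ---------------------------------------------------------------------------
# mixtures


def detect_populations(
    ph_values, max_components: int = 2, seed: int = 0, n_init: int = 5
) -> MixtureResult:
    """Select between 1- and 2-component Gaussian mixtures by BIC.

    EM with k-means initialization; n >= 50 observations required.  Means
    are reported in ascending order.
    """
    x = np.asarray(ph_values, dtype=float).reshape(-1, 1)
    if x.shape[0] < 50:
        raise ValueError(f"need n >= 50 observations, got {x.shape[0]}")
    scores: dict[int, float] = {}
    fits: dict[int, GaussianMixture] = {}
    for k in range(1, max_components + 1):
        gm = GaussianMixture(
            n_components=k, init_params="kmeans", n_init=n_init,
            random_state=seed, covariance_type="full",
        ).fit(x)
        if not gm.converged_:
            raise RuntimeError(f"EM failed to converge for {k} component(s)")
        scores[k] = float(gm.bic(x))
        fits[k] = gm
    best = min(scores, key=scores.get)
    gm = fits[best]
    order = np.argsort(gm.means_.ravel())
    return MixtureResult(
        n_components=best,
        means=gm.means_.ravel()[order],
        sds=np.sqrt(gm.covariances_.reshape(best, -1)[:, 0])[order],
        weights=gm.weights_[order],
        selection_score=scores,
    )


# ---------------------------------------------------------------------------
# group statistics


def box_summary(values) -> BoxSummary:
    """Median with 10th/90th percentile whiskers."""
    v = np.asarray(values, dtype=float)
    return BoxSummary(
        median=float(np.median(v)),
        p10=float(np.percentile(v, 10)),
        p90=float(np.percentile(v, 90)),
        n=int(v.size),
    )


def group_compare(groups: dict, welch: bool = False) -> dict:
    """Two-group Student t-test or multi-group one-way ANOVA.

    ``groups`` maps label -> array of pH values (each n >= 2).  Returns the
    test name, statistic, p-value and a :class:`BoxSummary` per group.
    ``welch=True`` switches the two-group test to unequal variances.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")
    if all(np.ptp(v) == 0 for v in arrays.values()):
        raise ValueError("all groups have zero variance; tests are undefined")

    values = list(arrays.values())
    if len(values) == 2:
        stat, p = stats.ttest_ind(values[0], values[1], equal_var=not welch)
        test = "welch_t" if welch else "student_t"
    else:
        stat, p = stats.f_oneway(*values)
        test = "anova"
    return {
        "test": test,
        "statistic": float(stat),
        "p_value": float(p),
        "groups": {k: box_summary(v) for k, v in arrays.items()},
    }
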