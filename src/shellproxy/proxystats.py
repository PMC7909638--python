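"""Distributional statistics and temperature-proxy calibration.

The proxy rests on an asymmetry of the size distributions: the bulk of
biomineral units and pores is temperature-invariant, while the upper tail
scales with culturing temperature.  Analysis therefore compares whole
distributions (ECDFs, two-sample Kolmogorov–Smirnov tests) but calibrates on
the pooled N largest entities per temperature group (N = 15 by default, the
balance between explanatory power and sample size).  Calibration models are
linear ``S = alpha + beta*T`` (ordinary least squares) or exponential
``S = a*exp(b*T)`` (nonlinear least squares initialized from the log-linear
fit); the exponential form is preferred for pores, where linear fits predict
negative sizes and leave non-randomly distributed residuals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .io import ParticleRecord

__all__ = [
    "TemperatureGroup",
    "ECDF",
    "CalibrationModel",
    "TemperaturePrediction",
    "ecdf",
    "ks_two_sample",
    "top_n",
    "threshold_sensitivity",
    "spearman",
    "fit_linear",
    "fit_exponential",
    "predict_temperature",
]


@dataclass
class TemperatureGroup:
    """All particle records pooled across the specimens of one temperature level."""

    temperature: float  # °C (nominal level or measured tank mean)
    records: list[ParticleRecord]

    def areas(self, kind: str | None = None) -> np.ndarray:
        recs = self.records if kind is None else [r for r in self.records if r.kind == kind]
        return np.array([r.area for r in recs], dtype=float)


class ECDF:
    """Right-continuous empirical cumulative distribution function.

    ``F(x)`` is the fraction of sample values ``<= x``; ``quantile(p)`` is the
    order statistic ``x_(ceil(p*n))``, the smallest value with ``F(x) >= p``.
    """

    def __init__(self, values) -> None:
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise ValueError("ECDF requires at least one value")
        if not np.isfinite(values).all():
            raise ValueError("ECDF values must be finite")
        self.values = np.sort(values)
        self.n = int(values.size)

    def __call__(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        out = np.searchsorted(self.values, x, side="right") / self.n
        return out if out.ndim else float(out)

    def quantile(self, p: float) -> float:
        if not 0.0 < p <= 1.0:
            raise ValueError("p must lie in (0, 1]")
        return float(self.values[math.ceil(p * self.n) - 1])


def ecdf(values) -> ECDF:
    """Build the ECDF of a sample (errors on empty input)."""
    return ECDF(values)


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test.

    Returns ``(D, p)`` where ``D = sup_x |F_a(x) - F_b(x)|`` and ``p`` is the
    two-sided asymptotic p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def top_n(group: TemperatureGroup, n: int = 15, kind: str | None = None) -> list[ParticleRecord]:
    """The ``n`` largest entities of a temperature group, pooled over its specimens.

    Ties at the selection boundary are broken deterministically by
    ``(specimen_id, entity_id)``.  If the group holds fewer than ``n`` records
    the whole group is returned with a warning.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    recs = group.records if kind is None else [r for r in group.records if r.kind == kind]
    if not recs:
        raise ValueError("temperature group holds no records")
    ordered = sorted(recs, key=lambda r: (-r.area, r.specimen_id, r.entity_id))
    if len(ordered) < n:
        warnings.warn(
            f"group at {group.temperature}°C has only {len(ordered)} records (< n={n})",
            stacklevel=2,
        )
        return ordered
    return ordered[:n]


def top_n_pairs(
    groups: list[TemperatureGroup],
    n: int = 15,
    kind: str | None = None,
    aggregate: str = "pooled",
) -> tuple[list[float], list[float]]:
    """(area, temperature) pairs from the top-``n`` of each group.

    ``aggregate="pooled"`` (default) pairs every selected entity with its
    group temperature; ``"group_means"`` collapses each group's top-``n`` to
    its mean, one pair per group.
    """
    if aggregate not in ("pooled", "group_means"):
        raise ValueError("aggregate must be 'pooled' or 'group_means'")
    areas: list[float] = []
    temps: list[float] = []
    for g in groups:
        selected = [r.area for r in top_n(g, n=n, kind=kind)]
        if aggregate == "pooled":
            areas.extend(selected)
            temps.extend([g.temperature] * len(selected))
        else:
            areas.append(float(np.mean(selected)))
            temps.append(g.temperature)
    return areas, temps


def spearman(areas, temperatures) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and two-sided p."""
    areas = np.asarray(areas, dtype=float)
    temperatures = np.asarray(temperatures, dtype=float)
    if areas.size != temperatures.size or areas.size < 3:
        raise ValueError("need paired samples of length >= 3")
    if np.ptp(areas) == 0 or np.ptp(temperatures) == 0:
        warnings.warn("zero variance: Spearman correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    res = stats.spearmanr(areas, temperatures)
    return float(res.statistic), float(res.pvalue)


def threshold_sensitivity(
    groups: list[TemperatureGroup],
    n_values,
    kind: str | None = None,
) -> list[tuple[int, float, float]]:
    """Spearman r between pooled top-``n`` areas and group temperature, per ``n``.

    Because only the upper tail carries the temperature signal, the
    correlation decays as the subset size grows into the invariant bulk.
    Returns ``[(n, r, p), ...]``.
    """
    if len(groups) < 2:
        raise ValueError("need at least two temperature groups")
    curve = []
    for n in n_values:
        areas, temps = [], []
        for g in groups:
            for r in top_n(g, n=int(n), kind=kind):
                areas.append(r.area)
                temps.append(g.temperature)
        r_val, p_val = spearman(areas, temps)
        curve.append((int(n), r_val, p_val))
    return curve


# ---------------------------------------------------------------------------
# calibration models
# ---------------------------------------------------------------------------


@dataclass
class CalibrationModel:
    """Size-vs-temperature calibration with correlation statistics and SE bands.

    ``params``/``ses`` hold ``alpha``/``beta`` (linear) or ``a``/``b``
    (exponential) with their standard errors from the fit covariance.  Both
    the regression goodness-of-fit ``r_squared`` and the rank statistics
    (``spearman_r`` and its square) are reported separately: squaring the rank
    correlation and the regression R² answer different questions and need not
    agree.
    """

    kind: str  # "linear" | "exponential"
    params: dict
    ses: dict
    spearman_r: float
    spearman_p: float
    r_squared: float  # regression goodness-of-fit
    n: int
    residuals: np.ndarray
    temperatures: np.ndarray
    areas: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    @property
    def spearman_r_squared(self) -> float:
        return self.spearman_r**2

    def predict(self, temperature) -> np.ndarray | float:
        t = np.asarray(temperature, dtype=float)
        if self.kind == "linear":
            out = self.params["alpha"] + self.params["beta"] * t
        else:
            out = self.params["a"] * np.exp(self.params["b"] * t)
        return out if out.ndim else float(out)

    def band(self, temperature) -> tuple[np.ndarray, np.ndarray]:
        """Prediction band: the fit with every parameter shifted by ±2 SE."""
        t = np.asarray(temperature, dtype=float)
        if self.kind == "linear":
            curves = [
                (self.params["alpha"] + sa * 2 * self.ses["alpha"])
                + (self.params["beta"] + sb * 2 * self.ses["beta"]) * t
                for sa in (-1, 1)
                for sb in (-1, 1)
            ]
        else:
            curves = [
                max(self.params["a"] + sa * 2 * self.ses["a"], 1e-12)
                * np.exp((self.params["b"] + sb * 2 * self.ses["b"]) * t)
                for sa in (-1, 1)
                for sb in (-1, 1)
            ]
        arr = np.stack([np.atleast_1d(c) for c in curves])
        return arr.min(axis=0), arr.max(axis=0)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "params": {k: float(v) for k, v in self.params.items()},
            "ses": {k: float(v) for k, v in self.ses.items()},
            "spearman_r": float(self.spearman_r),
            "spearman_r_squared": float(self.spearman_r_squared),
            "spearman_p": float(self.spearman_p),
            "r_squared": float(self.r_squared),
            "n": int(self.n),
            "diagnostics": self.diagnostics,
        }


@dataclass
class TemperaturePrediction:
    """Inverse-model temperature estimate with a ±2 SE interval."""

    temperature: float
    interval: tuple[float, float]
    extrapolated: bool


def _sign_runs(residuals: np.ndarray) -> dict:
    """Wald–Wolfowitz runs test on residual signs (zeros dropped)."""
    signs = np.sign(residuals)
    signs = signs[signs != 0]
    n_pos = int((signs > 0).sum())
    n_neg = int((signs < 0).sum())
    n_runs = int(1 + (np.diff(signs) != 0).sum()) if signs.size else 0
    if n_pos == 0 or n_neg == 0:
        return {"n_runs": n_runs, "z": float("nan"), "p": float("nan")}
    n = n_pos + n_neg
    mu = 2.0 * n_pos * n_neg / n + 1.0
    var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n**2 * (n - 1.0))
    z = (n_runs - mu) / math.sqrt(var) if var > 0 else float("nan")
    p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else float("nan")
    return {"n_runs": n_runs, "z": float(z), "p": float(p)}


def _check_fit_inputs(temperatures, areas) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(temperatures, dtype=float)
    s = np.asarray(areas, dtype=float)
    if t.size != s.size or t.size < 3:
        raise ValueError("need paired samples of length >= 3")
    if np.unique(t).size < 3:
        raise ValueError("need at least 3 distinct temperatures")
    return t, s


def _diagnostics(model_kind: str, params: dict, residuals: np.ndarray) -> dict:
    grid = np.linspace(0.0, 16.0, 161)
    if model_kind == "linear":
        pred = params["alpha"] + params["beta"] * grid
    else:
        pred = params["a"] * np.exp(params["b"] * grid)
    return {
        "runs_test": _sign_runs(residuals),
        "predicts_negative_on_0_16C": bool((pred < 0).any()),
    }


def fit_linear(temperatures, areas) -> CalibrationModel:
    """Ordinary-least-squares linear calibration ``S = alpha + beta*T``."""
    import statsmodels.api as sm

    t, s = _check_fit_inputs(temperatures, areas)
    X = sm.add_constant(t)
    try:
        res = sm.OLS(s, X).fit()
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ValueError(f"singular design: {exc}") from exc
    params = {"alpha": float(res.params[0]), "beta": float(res.params[1])}
    ses = {"alpha": float(res.bse[0]), "beta": float(res.bse[1])}
    resid = np.asarray(res.resid)
    r, p = spearman(s, t)
    return CalibrationModel(
        kind="linear",
        params=params,
        ses=ses,
        spearman_r=r,
        spearman_p=p,
        r_squared=float(res.rsquared),
        n=int(t.size),
        residuals=resid,
        temperatures=t,
        areas=s,
        diagnostics=_diagnostics("linear", params, resid),
    )


def fit_exponential(temperatures, areas) -> CalibrationModel:
    """Nonlinear-least-squares exponential calibration ``S = a*exp(b*T)``.

    Initialized from the log-linear regression of ``ln S`` on ``T``; when
    non-positive areas preclude the log step, a two-point estimate through the
    group means at the extreme temperatures is used instead.
    """
    t, s = _check_fit_inputs(temperatures, areas)
    if np.all(s > 0):
        slope, intercept = np.polyfit(t, np.log(s), 1)
        p0 = (math.exp(intercept), slope)
    else:
        t_lo, t_hi = t.min(), t.max()
        m_lo = max(float(s[t == t_lo].mean()), 1e-9)
        m_hi = max(float(s[t == t_hi].mean()), 1e-9)
        b0 = math.log(m_hi / m_lo) / (t_hi - t_lo)
        p0 = (m_lo / math.exp(b0 * t_lo), b0)
    try:
        popt, pcov = optimize.curve_fit(
            lambda x, a, b: a * np.exp(b * x), t, s, p0=p0, maxfev=20000
        )
    except RuntimeError as exc:
        raise ValueError(f"exponential fit failed to converge: {exc}") from exc
    params = {"a": float(popt[0]), "b": float(popt[1])}
    perr = np.sqrt(np.diag(pcov))
    ses = {"a": float(perr[0]), "b": float(perr[1])}
    resid = s - params["a"] * np.exp(params["b"] * t)
    ss_res = float(resid @ resid)
    ss_tot = float(((s - s.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    r, p = spearman(s, t)
    return CalibrationModel(
        kind="exponential",
        params=params,
        ses=ses,
        spearman_r=r,
        spearman_p=p,
        r_squared=r2,
        n=int(t.size),
        residuals=resid,
        temperatures=t,
        areas=s,
        diagnostics=_diagnostics("exponential", params, resid),
    )


CALIBRATED_RANGE = (1.0, 15.0)  # °C spanned by the culturing design


def predict_temperature(model: CalibrationModel, area: float) -> TemperaturePrediction:
    """Invert a calibration model: temperature (±2 SE interval) for a size.

    Values inverting outside the calibrated 1–15 °C range are returned with
    the extrapolation flag set.
    """
    if model.kind == "linear":
        if model.params["beta"] == 0:
            raise ValueError("flat linear model cannot be inverted")
        centre = (area - model.params["alpha"]) / model.params["beta"]
    else:
        if area <= 0:
            raise ValueError("exponential model inversion requires area > 0")
        if model.params["b"] == 0:
            raise ValueError("flat exponential model cannot be inverted")
        centre = math.log(area / model.params["a"]) / model.params["b"]

    # invert the ±2 SE band numerically on a dense temperature grid
    grid = np.linspace(-20.0, 50.0, 7001)
    lo_curve, hi_curve = model.band(grid)
    inside = (area >= lo_curve) & (area <= hi_curve)
    if inside.any():
        t_lo = float(grid[inside].min())
        t_hi = float(grid[inside].max())
    else:
        t_lo = t_hi = float(centre)
    extrapolated = not (CALIBRATED_RANGE[0] <= centre <= CALIBRATED_RANGE[1])
    return TemperaturePrediction(
        temperature=float(centre), interval=(t_lo, t_hi), extrapolated=extrapolated
    )
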