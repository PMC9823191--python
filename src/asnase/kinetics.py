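"""Fermentation kinetics for batch, fed-batch and continuous culture.

Biomass growth follows the logistic model in (X0, Xmax, mu_max); product
formation and cumulative substrate consumption follow the Zwietering
re-parameterized Gompertz model in (Amax, r_max, t_L), whose parameters
are the asymptote, the maximum (inflection) rate and the lag time.
Derived quantities cover yield coefficients, specific and volumetric
rates, doubling time, and the exponential feed-rate schedule used to hold
the specific growth rate of a fed-batch culture at a set point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .response_surface import FitStatistics

__all__ = [
    "TimeCourse",
    "LogisticParams",
    "GompertzParams",
    "DerivedYields",
    "FeedPlan",
    "KineticRun",
    "FitFailureError",
    "logistic_curve",
    "gompertz_curve",
    "fit_logistic",
    "fit_gompertz",
    "doubling_time",
    "specific_growth_rate",
    "yields_and_rates",
    "feed_rate",
    "compare_modes",
    "read_timecourse_csv",
    "write_timecourse_csv",
]

_E = np.e
_MIN_X0 = 1e-6  # floor on initial biomass so the logistic stays non-degenerate


class FitFailureError(RuntimeError):
    """Nonlinear fit did not converge after all restarts."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TimeCourse:
    """Sampled fermentation time course.

    t in hours (strictly increasing), X biomass in g DCW/L, P product
    activity in U, S substrate in g/L. P and S are optional channels.
    """

    t: np.ndarray
    X: np.ndarray | None = None
    P: np.ndarray | None = None
    S: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time points must be strictly increasing")
        for name in ("X", "P", "S"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.t.shape:
                    raise ValueError(f"channel {name} length mismatch")
                setattr(self, name, v)

    def channel(self, name: str) -> np.ndarray:
        v = getattr(self, name)
        if v is None:
            raise ValueError(f"time course has no {name} channel")
        return v


@dataclass
class LogisticParams:
    """Logistic growth parameters: X(t) = Xmax / (1 + ((Xmax-X0)/X0) e^{-mu t})."""

    X0: float
    Xmax: float
    mu_max: float

    @property
    def Td(self) -> float:
        """Population doubling time ln2 / mu_max (h)."""
        return doubling_time(self.mu_max)


@dataclass
class GompertzParams:
    """Zwietering Gompertz parameters: asymptote, maximum rate, lag time."""

    Amax: float
    r_max: float
    t_L: float


@dataclass
class DerivedYields:
    """Yield coefficients and rates derived from fitted kinetic parameters."""

    Yxs: float   # g biomass per g substrate
    Yps: float   # U product per g substrate
    Ypx: float   # U product per g biomass
    qp: float    # specific product formation rate, Ypx * mu_max
    qs: float    # specific substrate consumption rate, mu_max / Yxs
    Qp: float    # volumetric product productivity, U/(L h)
    Qx: float    # volumetric biomass productivity, g DCW/(L h)


@dataclass
class FeedPlan:
    """Exponential fed-batch feeding schedule F(t) = F(0) e^{mu t}."""

    mu: float
    X0: float
    V0: float
    Yxs: float
    S0: float
    t: np.ndarray
    F: np.ndarray


@dataclass
class KineticRun:
    """Fitted kinetics of one fermentation mode, for cross-mode reports."""

    name: str
    logistic: LogisticParams | None = None
    product: GompertzParams | None = None
    substrate: GompertzParams | None = None
    yields: DerivedYields | None = None
    timecourse: TimeCourse | None = None


# ---------------------------------------------------------------------------
# model curves
# ---------------------------------------------------------------------------

def logistic_curve(params: LogisticParams, t) -> np.ndarray:
    """Logistic biomass curve; returns zeros (with a warning) when X0 == 0."""
    t = np.asarray(t, dtype=float)
    if params.X0 == 0:
        warnings.warn("X0 = 0: logistic curve is identically zero",
                      RuntimeWarning, stacklevel=2)
        return np.zeros_like(t)
    ratio = (params.Xmax - params.X0) / params.X0
    return params.Xmax / (1.0 + ratio * np.exp(-params.mu_max * t))


def gompertz_curve(params: GompertzParams, t) -> np.ndarray:
    """Zwietering Gompertz curve A(t) = Amax exp(-exp(r e/Amax (tL - t) + 1))."""
    t = np.asarray(t, dtype=float)
    z = params.r_max * _E / params.Amax * (params.t_L - t) + 1.0
    return params.Amax * np.exp(-np.exp(z))


def doubling_time(mu_max: float) -> float:
    """Doubling time ln 2 / mu_max in hours."""
    if mu_max <= 0:
        raise ValueError(f"mu_max must be > 0, got {mu_max}")
    return float(np.log(2.0) / mu_max)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _fit_stats(y, yhat, n_params, residual_jac=None):
    resid = y - yhat
    n = len(y)
    sse = float(np.sum(resid ** 2))
    sst = float(np.sum((y - np.mean(y)) ** 2))
    dfe = max(n - n_params, 1)
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / dfe
    msr = (sst - sse) / max(n_params - 1, 1)
    f = msr / (sse / dfe) if sse > 0 else np.inf
    p = float(stats.f.sf(f, n_params - 1, dfe)) if np.isfinite(f) else 0.0
    return FitStatistics(
        adj_r2=float(adj),
        rmse=float(np.sqrt(sse / n)),
        mae=float(np.mean(np.abs(resid))),
        f_statistic=float(f) if np.isfinite(f) else 0.0,
        p_value=p,
    )


def _multistart_curve_fit(model, t, y, p0, bounds, seed=0, restarts=20,
                          patience=3):
    """curve_fit with seeded +/-20% jitter restarts on the initial values.

    Restarting stops early once ``patience`` consecutive starts fail to
    improve the best residual sum of squares by more than 0.1%.
    """
    rng = np.random.default_rng(seed)
    p0 = np.asarray(p0, dtype=float)
    lo, hi = np.asarray(bounds[0]), np.asarray(bounds[1])
    best = None
    last_err = None
    stale = 0
    for attempt in range(restarts + 1):
        start = p0 if attempt == 0 else p0 * rng.uniform(0.8, 1.2, size=p0.size)
        start = np.clip(start, lo, hi)
        try:
            popt, pcov = optimize.curve_fit(
                model, t, y, p0=start, bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError) as err:  # no convergence this start
            last_err = err
            continue
        sse = float(np.sum((y - model(t, *popt)) ** 2))
        if best is None or sse < best[0] * (1 - 1e-3):
            best = (sse, popt, pcov)
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
    if best is None:
        raise FitFailureError(
            f"nonlinear fit failed after {restarts + 1} starts: {last_err}")
    return best[1], best[2]


def fit_logistic(tc: TimeCourse, seed: int = 0
                 ) -> tuple[LogisticParams, FitStatistics]:
    """Fit the logistic growth model to the biomass channel.

    Self-starting: X0 from the first observation (clipped positive), Xmax
    from the maximum, mu_max from the steepest log-difference. Trust-region
    least squares with up to 20 seeded restarts.
    """
    t, y = tc.t, tc.channel("X")
    _check_fittable(y)

    def model(t, x0, xmax, mu):
        return logistic_curve(LogisticParams(x0, xmax, mu), t)

    x0_init = max(float(y[0]), _MIN_X0)
    xmax_init = float(np.max(y))
    mu_init = _max_log_slope(t, y)
    p0 = [x0_init, xmax_init, mu_init]
    bounds = ([_MIN_X0, x0_init, 1e-4],
              [xmax_init, 10 * xmax_init, 20.0])
    popt, pcov = _multistart_curve_fit(model, t, y, p0, bounds, seed=seed)
    params = LogisticParams(*map(float, popt))
    fs = _fit_stats(y, model(t, *popt), 3)
    fs.param_se = np.sqrt(np.diag(pcov))
    return params, fs


def fit_gompertz(tc: TimeCourse, channel: str = "product", seed: int = 0
                 ) -> tuple[GompertzParams, FitStatistics]:
    """Fit the Zwietering Gompertz model to the product or substrate channel.

    The substrate channel is interpreted as *cumulative consumption* (a
    rising sigmoid), matching how a consumption asymptote is reported.
    """
    names = {"product": "P", "substrate": "S", "P": "P", "S": "S"}
    try:
        y = tc.channel(names[channel])
    except KeyError:
        raise ValueError(f"unknown channel {channel!r}") from None
    t = tc.t
    _check_fittable(y)

    def model(t, amax, rmax, tl):
        return gompertz_curve(GompertzParams(amax, rmax, tl), t)

    amax_init = float(np.max(y))
    grad = np.gradient(y, t)
    m = int(np.argmax(grad))
    rmax_init = max(float(grad[m]), amax_init / (t[-1] - t[0]))
    # lag: where the steepest tangent crosses zero
    tl_init = float(np.clip(t[m] - y[m] / max(grad[m], 1e-12), 0.0, t[-1]))
    p0 = [amax_init, rmax_init, tl_init]
    bounds = ([amax_init * 0.2, 1e-6, 0.0],
              [amax_init * 10, rmax_init * 50 + 1e-6, float(t[-1])])
    popt, pcov = _multistart_curve_fit(model, t, y, p0, bounds, seed=seed)
    params = GompertzParams(*map(float, popt))
    fs = _fit_stats(y, model(t, *popt), 3)
    fs.param_se = np.sqrt(np.diag(pcov))
    return params, fs


def _check_fittable(y: np.ndarray) -> None:
    if len(y) < 5:
        raise ValueError("need at least 5 points for a kinetic fit")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in response")
    if np.ptp(y) == 0:
        raise FitFailureError("constant response: sigmoid parameters undefined")


def _max_log_slope(t, y) -> float:
    pos = y > 0
    if pos.sum() < 2:
        return 0.1
    slopes = np.diff(np.log(y[pos])) / np.diff(t[pos])
    s = float(np.max(slopes))
    return s if s > 0 else 0.1


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def specific_growth_rate(tc: TimeCourse) -> np.ndarray:
    """Instantaneous specific growth rate mu = (1/X) dX/dt.

    Central finite differences at interior points, one-sided at the ends.
    Non-positive biomass yields a masked (NaN) value with a warning.
    """
    X = tc.channel("X")
    dxdt = np.gradient(X, tc.t)
    mu = np.full_like(X, np.nan)
    ok = X > 0
    if not ok.all():
        warnings.warn("non-positive biomass: mu masked at those points",
                      RuntimeWarning, stacklevel=2)
    mu[ok] = dxdt[ok] / X[ok]
    return mu


def yields_and_rates(
    X0: float, Xm: float, S0: float, Sm: float,
    Pmax: float, mu_max: float, duration: float,
) -> DerivedYields:
    """Yield coefficients and volumetric/specific rates from endpoint values.

    X0/Xm initial and maximum biomass (g/L), S0/Sm initial and final
    substrate (g/L), Pmax maximum product (U), duration in hours.
    """
    consumed = S0 - Sm
    if consumed <= 0:
        raise ZeroDivisionError("no substrate consumed (S0 <= Sm)")
    if Xm <= X0:
        raise ValueError("Xm must exceed X0")
    yxs = (Xm - X0) / consumed
    yps = Pmax / consumed
    ypx = Pmax / (Xm - X0)
    return DerivedYields(
        Yxs=yxs,
        Yps=yps,
        Ypx=ypx,
        qp=ypx * mu_max,
        qs=mu_max / yxs,
        Qp=Pmax / duration,
        Qx=(Xm - X0) / duration,
    )


def feed_rate(mu: float, X0: float, V0: float, Yxs: float, S0: float,
              t) -> FeedPlan:
    """Exponential feed schedule F(t) = mu X0 V0 e^{mu t} / (Yxs S0).

    Holds the specific growth rate of a substrate-limited fed-batch
    culture at ``mu``, given the biomass X0 (g/L) and volume V0 (L) at the
    end of the batch phase, the biomass yield Yxs (g/g) and the feed
    substrate concentration S0 (g/L).
    """
    for name, v in (("mu", mu), ("X0", X0), ("V0", V0)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    if Yxs <= 0 or S0 <= 0:
        raise ZeroDivisionError("Yxs and S0 must be > 0")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    F = mu * X0 * V0 * np.exp(mu * t) / (Yxs * S0)
    return FeedPlan(mu=mu, X0=X0, V0=V0, Yxs=Yxs, S0=S0, t=t, F=F)


# ---------------------------------------------------------------------------
# cross-mode comparison
# ---------------------------------------------------------------------------

_RATIO_FIELDS = {
    "Pmax": lambda r: r.product.Amax if r.product else None,
    "mu_max": lambda r: r.logistic.mu_max if r.logistic else None,
    "Smax": lambda r: r.substrate.Amax if r.substrate else None,
    "rs_max": lambda r: r.substrate.r_max if r.substrate else None,
    "Yps": lambda r: r.yields.Yps if r.yields else None,
    "Yxs": lambda r: r.yields.Yxs if r.yields else None,
    "Ypx": lambda r: r.yields.Ypx if r.yields else None,
}


def compare_modes(runs: list[KineticRun], ndigits: int = 2) -> dict:
    """Pairwise fold-ratio report across fermentation modes.

    Returns ``{"ratios": DataFrame, "pearson_r": {name: r}}``. Ratios are
    numerator/denominator for every ordered pair of runs and every
    parameter both runs carry; missing parameters drop the pair with a
    notice. Pearson r between product and biomass is reported per run
    whose time course has both channels.
    """
    if len(runs) < 2:
        raise ValueError("need at least 2 runs to compare")
    rows = []
    for a in runs:
        for b in runs:
            if a.name == b.name:
                continue
            for param, get in _RATIO_FIELDS.items():
                va, vb = get(a), get(b)
                if va is None or vb is None or vb == 0:
                    continue
                rows.append({
                    "numerator": a.name, "denominator": b.name,
                    "parameter": param,
                    "fold": round(va / vb, ndigits),
                })
    pearson = {}
    for r in runs:
        tc = r.timecourse
        if tc is not None and tc.X is not None and tc.P is not None:
            pearson[r.name] = float(stats.pearsonr(tc.X, tc.P)[0])
    return {"ratios": pd.DataFrame(rows), "pearson_r": pearson}


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

_CSV_COLS = {"t": "t_h", "X": "biomass_gdcw_L", "P": "product_U",
             "S": "substrate_g_L"}


def write_timecourse_csv(path, tc: TimeCourse) -> None:
    data = {"t_h": tc.t}
    for attr in ("X", "P", "S"):
        v = getattr(tc, attr)
        if v is not None:
            data[_CSV_COLS[attr]] = v
    pd.DataFrame(data).to_csv(path, index=False)


def read_timecourse_csv(path) -> TimeCourse:
    frame = pd.read_csv(path)
    kwargs = {"t": frame["t_h"].to_numpy()}
    for attr, col in _CSV_COLS.items():
        if attr != "t" and col in frame and not frame[col].isna().all():
            kwargs[attr] = frame[col].to_numpy()
    return TimeCourse(**kwargs)
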