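"""Coded-variable response-surface methodology.

Design-of-experiments matrices (Plackett-Burman, Box-Behnken, central
composite), second-order polynomial surfaces in coded factors, ordinary
least-squares fitting with lack-of-fit diagnostics, constrained
optimization on the coded cube, and Derringer-Suich desirability for
multi-objective optimization.

A *coded factor* maps an actual setting ``a`` to ``(a - center) / half_range``
so the design region becomes the cube [-1, +1]^k.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

logger = logging.getLogger(__name__)

DEFAULT_SEED = 1729  #: default seed for multi-start optimization

__all__ = [
    "CodedFactor",
    "QuadraticSurface",
    "FitStatistics",
    "DesirabilitySpec",
    "DimensionError",
    "SingularDesignError",
    "DegenerateSpecError",
    "code_point",
    "decode_point",
    "fit_quadratic",
    "make_design",
    "optimize_on_cube",
    "desirability",
    "composite_desirability",
    "maximize_composite",
    "read_design_csv",
    "write_design_csv",
]


class DimensionError(ValueError):
    """Vector/matrix length does not match the number of factors."""


class SingularDesignError(ValueError):
    """Design matrix is rank-deficient; some model terms are aliased."""


class DegenerateSpecError(ValueError):
    """Desirability specification with L == T has no defined scale."""


# ---------------------------------------------------------------------------
# coded factors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodedFactor:
    """One design variable with its actual-units center and half-range.

    Coding is the bijection ``coded = (actual - center) / half_range``.
    """

    name: str
    center: float
    half_range: float

    def __post_init__(self) -> None:
        if not self.half_range > 0:
            raise ValueError(f"half_range must be > 0, got {self.half_range}")

    def code(self, actual: float) -> float:
        return (actual - self.center) / self.half_range

    def decode(self, coded: float) -> float:
        return self.center + coded * self.half_range


def code_point(factors: list[CodedFactor], actual) -> np.ndarray:
    """Map a point in actual units onto the coded scale, factor by factor."""
    actual = np.asarray(actual, dtype=float)
    if actual.shape != (len(factors),):
        raise DimensionError(
            f"expected {len(factors)} coordinates, got shape {actual.shape}")
    return np.array([f.code(a) for f, a in zip(factors, actual)])


def decode_point(factors: list[CodedFactor], coded) -> np.ndarray:
    """Inverse of :func:`code_point`."""
    coded = np.asarray(coded, dtype=float)
    if coded.shape != (len(factors),):
        raise DimensionError(
            f"expected {len(factors)} coordinates, got shape {coded.shape}")
    return np.array([f.decode(c) for f, c in zip(factors, coded)])


# ---------------------------------------------------------------------------
# quadratic surfaces
# ---------------------------------------------------------------------------

def _pairs(k: int) -> list[tuple[int, int]]:
    return list(itertools.combinations(range(k), 2))


@dataclass
class QuadraticSurface:
    """Second-order polynomial in coded factors.

    y(x) = b0 + sum_i b_lin[i] x_i + sum_{i<j} b_int[ij] x_i x_j
              + sum_i b_sq[i] x_i^2

    Interaction coefficients are ordered as ``itertools.combinations(range(k), 2)``.
    """

    factors: tuple[CodedFactor, ...]
    b0: float
    linear: np.ndarray
    interactions: np.ndarray
    squares: np.ndarray
    response_name: str = "response"
    units: str = ""

    def __post_init__(self) -> None:
        self.factors = tuple(self.factors)
        k = len(self.factors)
        self.linear = np.asarray(self.linear, dtype=float)
        self.interactions = np.asarray(self.interactions, dtype=float)
        self.squares = np.asarray(self.squares, dtype=float)
        if self.linear.shape != (k,):
            raise DimensionError(f"linear coefficients: expected {k} entries")
        if self.interactions.shape != (k * (k - 1) // 2,):
            raise DimensionError(
                f"interaction coefficients: expected {k * (k - 1) // 2} entries")
        if self.squares.shape != (k,):
            raise DimensionError(f"squared coefficients: expected {k} entries")

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    def __call__(self, x) -> float | np.ndarray:
        return self.evaluate(x)

    def evaluate(self, x) -> float | np.ndarray:
        """Evaluate at one coded point (shape (k,)) or many (shape (n, k))."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        pts = np.atleast_2d(x)
        if pts.shape[1] != self.k:
            raise DimensionError(
                f"expected {self.k} coordinates, got {pts.shape[1]}")
        y = np.full(pts.shape[0], self.b0)
        y += pts @ self.linear
        for b, (i, j) in zip(self.interactions, _pairs(self.k)):
            y += b * pts[:, i] * pts[:, j]
        y += (pts ** 2) @ self.squares
        return float(y[0]) if single else y

    def evaluate_actual(self, actual) -> float:
        """Evaluate at a point given in actual (uncoded) units."""
        return self.evaluate(code_point(list(self.factors), actual))

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "factors": [
                {"name": f.name, "center": f.center, "half_range": f.half_range}
                for f in self.factors
            ],
            "b0": self.b0,
            "linear": self.linear.tolist(),
            "interactions": [
                [i, j, float(b)]
                for b, (i, j) in zip(self.interactions, _pairs(self.k))
            ],
            "squares": self.squares.tolist(),
            "response_name": self.response_name,
            "units": self.units,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "QuadraticSurface":
        d = json.loads(text)
        factors = tuple(
            CodedFactor(f["name"], f["center"], f["half_range"])
            for f in d["factors"]
        )
        k = len(factors)
        ints = np.zeros(k * (k - 1) // 2)
        index = {p: n for n, p in enumerate(_pairs(k))}
        for i, j, b in d["interactions"]:
            ints[index[(i, j)]] = b
        return cls(
            factors=factors,
            b0=d["b0"],
            linear=np.asarray(d["linear"], dtype=float),
            interactions=ints,
            squares=np.asarray(d["squares"], dtype=float),
            response_name=d.get("response_name", "response"),
            units=d.get("units", ""),
        )


@dataclass
class FitStatistics:
    """Goodness-of-fit summary for a regression model."""

    adj_r2: float
    rmse: float
    mae: float
    f_statistic: float
    p_value: float
    lof_f: float | None = None
    lof_p: float | None = None
    param_se: np.ndarray | None = None


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _model_matrix(design: np.ndarray) -> tuple[np.ndarray, list[str]]:
    n, k = design.shape
    cols = [np.ones(n)]
    names = ["b0"]
    for i in range(k):
        cols.append(design[:, i])
        names.append(f"x{i + 1}")
    for i, j in _pairs(k):
        cols.append(design[:, i] * design[:, j])
        names.append(f"x{i + 1}:x{j + 1}")
    for i in range(k):
        cols.append(design[:, i] ** 2)
        names.append(f"x{i + 1}^2")
    return np.column_stack(cols), names


def _aliased_terms(X: np.ndarray, names: list[str]) -> list[str]:
    """Greedy scan for columns that do not increase the matrix rank."""
    aliased = []
    kept = np.empty((X.shape[0], 0))
    rank = 0
    for col, name in zip(X.T, names):
        cand = np.column_stack([kept, col])
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            kept, rank = cand, r
        else:
            aliased.append(name)
    return aliased


def fit_quadratic(
    design,
    responses,
    factors: list[CodedFactor] | None = None,
    response_name: str = "response",
) -> tuple[QuadraticSurface, FitStatistics]:
    """Fit a full second-order model to a coded design by OLS.

    Parameters
    ----------
    design : (n, k) array of coded factor settings.
    responses : (n,) response vector.
    factors : optional actual-unit factor definitions; defaults to unit
        factors named x1..xk (center 0, half-range 1, i.e. the design IS
        the actual space).

    Returns the fitted surface and fit statistics. Lack-of-fit F/p are
    reported only when replicate runs give pure-error degrees of freedom.
    """
    design = np.asarray(design, dtype=float)
    responses = np.asarray(responses, dtype=float)
    n, k = design.shape
    if responses.shape != (n,):
        raise DimensionError("responses length must match design rows")
    n_terms = 1 + 2 * k + k * (k - 1) // 2
    if n < n_terms:
        raise ValueError(
            f"need at least {n_terms} runs to fit a quadratic in {k} factors, got {n}")

    X, names = _model_matrix(design)
    if np.linalg.matrix_rank(X) < n_terms:
        raise SingularDesignError(
            "design cannot estimate all quadratic terms; aliased: "
            + ", ".join(_aliased_terms(X, names)))

    with warnings.catch_warnings():
        # statsmodels warns on saturated / zero-variance fits; the summary
        # statistics below remain well defined
        warnings.simplefilter("ignore")
        res = sm.OLS(responses, X).fit()
        adj_r2 = float(res.rsquared_adj)
        fval = float(res.fvalue) if np.isfinite(res.fvalue) else 0.0
        fp = float(res.f_pvalue) if np.isfinite(res.f_pvalue) else 1.0
        bse = np.asarray(res.bse)

    beta = res.params
    resid = responses - X @ beta
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    mae = float(np.mean(np.abs(resid)))

    lof_f = lof_p = None
    lof = _lack_of_fit(design, responses, resid, n_terms)
    if lof is not None:
        lof_f, lof_p = lof
    else:
        logger.info("no replicate runs: lack-of-fit not computed")

    if factors is None:
        factors = [CodedFactor(f"x{i + 1}", 0.0, 1.0) for i in range(k)]

    surface = QuadraticSurface(
        factors=tuple(factors),
        b0=float(beta[0]),
        linear=beta[1:1 + k],
        interactions=beta[1 + k:1 + k + k * (k - 1) // 2],
        squares=beta[1 + k + k * (k - 1) // 2:],
        response_name=response_name,
    )
    stats_out = FitStatistics(
        adj_r2=adj_r2 if np.isfinite(adj_r2) else 1.0,
        rmse=rmse,
        mae=mae,
        f_statistic=fval,
        p_value=fp,
        lof_f=lof_f,
        lof_p=lof_p,
        param_se=bse,
    )
    return surface, stats_out


def _lack_of_fit(design, responses, resid, n_terms):
    """Classical lack-of-fit F test; None when pure-error df == 0."""
    from scipy import stats as sps

    keys = [tuple(np.round(row, 9)) for row in design]
    groups: dict[tuple, list[int]] = {}
    for idx, key in enumerate(keys):
        groups.setdefault(key, []).append(idx)
    n = len(responses)
    m = len(groups)
    df_pe = n - m
    df_lof = m - n_terms
    if df_pe <= 0 or df_lof <= 0:
        return None
    ss_pe = sum(
        float(np.sum((responses[ix] - np.mean(responses[ix])) ** 2))
        for ix in groups.values()
    )
    sse = float(np.sum(resid ** 2))
    ss_lof = max(sse - ss_pe, 0.0)
    if ss_pe == 0:
        return None
    f = (ss_lof / df_lof) / (ss_pe / df_pe)
    p = float(sps.f.sf(f, df_lof, df_pe))
    return float(f), p


# ---------------------------------------------------------------------------
# design generation
# ---------------------------------------------------------------------------

# Cyclic Plackett-Burman generator rows (first row; subsequent rows are
# right cyclic shifts, plus a final all -1 row).
_PB_GENERATORS = {
    8: "+++-+--",
    12: "++-+++---+-",
    20: "++--++++-+-+----++-",
    24: "+++++-+-++--++--+-+----",
}


def make_design(
    kind: str,
    k: int,
    center_points: int = 5,
    alpha: float | str = 1.0,
) -> np.ndarray:
    """Generate a standard coded design matrix.

    kind : 'plackett_burman', 'box_behnken' or 'central_composite'.
    k : number of factors (Box-Behnken needs k >= 3).
    center_points : number of all-zero runs appended (ignored for
        Plackett-Burman, which has no center).
    alpha : axial distance for the central composite design; 1.0 gives the
        face-centred design, 'rotatable' gives (2**k) ** 0.25.
    """
    if k < 2:
        raise ValueError("designs require k >= 2 factors")
    if center_points < 0:
        raise ValueError("center_points must be >= 0")

    if kind == "plackett_burman":
        return _plackett_burman(k)
    if kind == "box_behnken":
        return _box_behnken(k, center_points)
    if kind == "central_composite":
        if alpha == "rotatable":
            alpha = (2 ** k) ** 0.25
        return _central_composite(k, center_points, float(alpha))
    raise ValueError(f"unknown design kind: {kind!r}")


def _plackett_burman(k: int) -> np.ndarray:
    n = 4 * int(np.ceil((k + 1) / 4))
    if n in _PB_GENERATORS:
        gen = np.array([1 if c == "+" else -1 for c in _PB_GENERATORS[n]])
        rows = [np.roll(gen, r) for r in range(n - 1)]
        rows.append(-np.ones(n - 1, dtype=int))
        mat = np.array(rows, dtype=float)
    elif (n & (n - 1)) == 0:  # power of two: Sylvester Hadamard
        h = np.array([[1.0]])
        while h.shape[0] < n:
            h = np.block([[h, h], [h, -h]])
        mat = h[:, 1:]  # drop the all-ones column
    else:
        raise ValueError(f"no Plackett-Burman construction for {n} runs")
    return mat[:, :k]


def _box_behnken(k: int, center_points: int) -> np.ndarray:
    if k < 3:
        raise ValueError("Box-Behnken design requires k >= 3")
    rows = []
    for i, j in _pairs(k):
        for si, sj in itertools.product((-1.0, 1.0), repeat=2):
            row = np.zeros(k)
            row[i], row[j] = si, sj
            rows.append(row)
    rows.extend(np.zeros(k) for _ in range(center_points))
    return np.array(rows)


def _central_composite(k: int, center_points: int, alpha: float) -> np.ndarray:
    rows = [np.array(c, dtype=float)
            for c in itertools.product((-1.0, 1.0), repeat=k)]
    for i in range(k):
        for s in (-alpha, alpha):
            row = np.zeros(k)
            row[i] = s
            rows.append(row)
    rows.extend(np.zeros(k) for _ in range(center_points))
    return np.array(rows)


# ---------------------------------------------------------------------------
# optimization on the coded cube
# ---------------------------------------------------------------------------

def _grid_argopt(fun, k: int, step: float, maximize: bool):
    axes = [np.arange(-1.0, 1.0 + step / 2, step)] * k
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([m.ravel() for m in mesh])
    vals = fun(pts)
    idx = int(np.argmax(vals) if maximize else np.argmin(vals))
    return pts[idx], float(vals[idx])


def _multistart_argopt(fun, k: int, maximize: bool, seed: int, n_starts: int = 64):
    rng = np.random.default_rng(seed)
    sign = -1.0 if maximize else 1.0

    def obj(x):
        return sign * fun(np.atleast_2d(x))[0]

    starts = rng.uniform(-1, 1, size=(n_starts, k))
    starts[0] = 0.0
    best: list[tuple[float, np.ndarray]] = []
    for x0 in starts:
        res = optimize.minimize(
            obj, x0, method="L-BFGS-B", bounds=[(-1, 1)] * k)
        best.append((res.fun, res.x))
    fopt = min(f for f, _ in best)
    # deterministic tie-break: lexicographically smallest near-optimal point
    candidates = sorted(
        tuple(np.round(x, 10)) for f, x in best if f <= fopt + 1e-9)
    x = np.array(candidates[0])
    return x, float(fun(np.atleast_2d(x))[0])


def optimize_on_cube(
    surface: QuadraticSurface,
    goal: str = "maximize",
    seed: int = DEFAULT_SEED,
) -> tuple[np.ndarray, float]:
    """Globally optimize a quadratic surface over the coded cube [-1, 1]^k.

    Dense 0.01-step grid search for k <= 3; seeded 64-start projected
    quasi-Newton otherwise. Ties are broken toward the lexicographically
    smallest coded point, so the result is reproducible for a given seed.
    """
    if goal not in ("maximize", "minimize"):
        raise ValueError("goal must be 'maximize' or 'minimize'")
    if surface.k > 10:
        raise ValueError("optimization supported for k <= 10")
    maximize = goal == "maximize"
    if surface.k <= 3:
        x, v = _grid_argopt(surface.evaluate, surface.k, 0.01, maximize)
        # polish on the continuous cube from the grid winner
        sign = -1.0 if maximize else 1.0
        res = optimize.minimize(
            lambda p: sign * surface.evaluate(p),
            x, method="L-BFGS-B", bounds=[(-1, 1)] * surface.k)
        polished = float(sign * res.fun)
        if (polished > v) if maximize else (polished < v):
            x, v = res.x, polished
        return np.asarray(x), v
    return _multistart_argopt(surface.evaluate, surface.k, maximize, seed)


# ---------------------------------------------------------------------------
# desirability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesirabilitySpec:
    """One-sided Derringer-Suich desirability specification.

    For ``goal='maximize'`` the response is worthless at or below ``low``
    and fully desirable at or above ``target`` (target > low). For
    ``goal='minimize'`` the roles mirror (target < low).
    """

    response: str
    goal: str
    low: float
    target: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.goal not in ("maximize", "minimize"):
            raise ValueError("goal must be 'maximize' or 'minimize'")
        if self.low == self.target:
            raise DegenerateSpecError(
                f"{self.response}: low == target == {self.low}")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")
        if self.goal == "maximize" and not self.target > self.low:
            raise ValueError("maximize goal requires target > low")
        if self.goal == "minimize" and not self.target < self.low:
            raise ValueError("minimize goal requires target < low")


def desirability(y: float, spec: DesirabilitySpec) -> float:
    """Map a response value onto [0, 1] per the one-sided Derringer-Suich rule."""
    u = (y - spec.low) / (spec.target - spec.low)
    return float(np.clip(u, 0.0, 1.0) ** spec.weight)


def composite_desirability(
    surfaces: list[QuadraticSurface],
    specs: list[DesirabilitySpec],
    x,
) -> float:
    """Geometric mean of per-response desirabilities at one coded point."""
    if len(surfaces) != len(specs):
        raise DimensionError("one desirability spec per surface required")
    ds = [desirability(s.evaluate(np.asarray(x, dtype=float)), spec)
          for s, spec in zip(surfaces, specs)]
    return float(np.prod(ds) ** (1.0 / len(ds)))


def default_desirability_specs(
    surfaces: list[QuadraticSurface],
    design,
    goals: list[str],
) -> list[DesirabilitySpec]:
    """Bounds from each surface's min/max predictions over the design points.

    This mirrors the common DoE-software default when explicit limits are
    not given: L and T span the predicted range, weight 1.
    """
    design = np.asarray(design, dtype=float)
    specs = []
    for s, goal in zip(surfaces, goals):
        preds = s.evaluate(design)
        lo, hi = float(np.min(preds)), float(np.max(preds))
        if goal == "maximize":
            specs.append(DesirabilitySpec(s.response_name, goal, lo, hi))
        else:
            specs.append(DesirabilitySpec(s.response_name, goal, hi, lo))
    return specs


def maximize_composite(
    surfaces: list[QuadraticSurface],
    specs: list[DesirabilitySpec],
    seed: int = DEFAULT_SEED,
) -> tuple[np.ndarray, float]:
    """Maximize the composite desirability D over the shared coded cube."""
    if len(surfaces) != len(specs):
        raise DimensionError("one desirability spec per surface required")
    k = surfaces[0].k
    if any(s.k != k for s in surfaces):
        raise DimensionError("all surfaces must share one factor space")

    def dvals(pts):
        pts = np.atleast_2d(pts)
        d = np.ones(pts.shape[0])
        for s, spec in zip(surfaces, specs):
            u = (s.evaluate(pts) - spec.low) / (spec.target - spec.low)
            d *= np.clip(u, 0.0, 1.0) ** spec.weight
        return d ** (1.0 / len(surfaces))

    if k <= 3:
        x, v = _grid_argopt(dvals, k, 0.01, maximize=True)
    else:
        x, v = _multistart_argopt(dvals, k, maximize=True, seed=seed)
    # refine with a local polish (D is piecewise smooth)
    res = optimize.minimize(
        lambda p: -dvals(p)[0], x, method="Nelder-Mead",
        bounds=[(-1, 1)] * k)
    if -res.fun > v:
        x, v = np.clip(res.x, -1, 1), float(-res.fun)
    return np.asarray(x), float(v)


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def write_design_csv(path, design, responses=None,
                     factor_names=None, response_name="response") -> None:
    """Write a coded design (and optional responses) as one run per row."""
    design = np.asarray(design, dtype=float)
    if factor_names is None:
        factor_names = [f"x{i + 1}" for i in range(design.shape[1])]
    frame = pd.DataFrame(design, columns=list(factor_names))
    if responses is not None:
        frame[response_name] = np.asarray(responses, dtype=float)
    frame.to_csv(path, index=False)


def read_design_csv(path, has_response: bool = True):
    """Read a design table written by :func:`write_design_csv`.

    Returns ``(design, responses, factor_names)``; responses is None when
    ``has_response`` is False.
    """
    frame = pd.read_csv(path)
    if has_response:
        design = frame.iloc[:, :-1].to_numpy(dtype=float)
        responses = frame.iloc[:, -1].to_numpy(dtype=float)
        return design, responses, list(frame.columns[:-1])
    return frame.to_numpy(dtype=float), None, list(frame.columns)
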