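"""Variance-based global sensitivity analysis of response-surface models.

Two routes to the same decomposition:

* a closed form for quadratic surfaces with independent Uniform(-1, 1)
  inputs on the coded cube, and
* a Monte-Carlo Saltelli A/B/AB estimator driven by a scrambled Sobol'
  quasi-random sequence, usable on any black-box function and serving as
  the general path.

For ``U ~ Uniform(-1, 1)``: Var(U) = 1/3 and Var(U^2) = 4/45, so a
quadratic ``y = b0 + sum b_i x_i + sum b_ij x_i x_j + sum c_i x_i^2``
decomposes exactly into

    V_i  = b_i^2 / 3 + c_i^2 * 4/45
    V_ij = b_ij^2 / 9
    V(Y) = sum V_i + sum V_ij

with no effects above second order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import qmc

from .response_surface import QuadraticSurface, _pairs

__all__ = [
    "VarianceDecomposition",
    "FactorRanking",
    "ZeroVarianceError",
    "analytic_sobol_quadratic",
    "saltelli_sobol",
    "rank_factors",
]

SENSITIVITY_THRESHOLD = 0.1  #: conventional "sensitive factor" cutoff on S_Ti


class ZeroVarianceError(ValueError):
    """The model output has zero variance; indices are undefined."""


@dataclass
class VarianceDecomposition:
    """Sobol variance decomposition of a model over the coded cube.

    ``second_order`` entries follow ``itertools.combinations(range(k), 2)``
    ordering; they are None for the Monte-Carlo route, which estimates
    first-order and total indices only.
    """

    total_variance: float
    first_order: np.ndarray           # V_i
    second_order: np.ndarray | None   # V_ij
    s_first: np.ndarray               # S_i
    s_second: np.ndarray | None       # S_ij
    s_total: np.ndarray               # S_Ti
    method: str
    n_samples: int | None = None
    seed: int | None = None

    @property
    def k(self) -> int:
        return len(self.first_order)

    def to_report(self, names: list[str] | None = None,
                  threshold: float = SENSITIVITY_THRESHOLD) -> dict:
        """JSON-ready summary of the decomposition."""
        names = names or [f"x{i + 1}" for i in range(self.k)]
        report = {
            "method": self.method,
            "n": self.n_samples,
            "seed": self.seed,
            "V": self.total_variance,
            "factors": [
                {
                    "name": names[i],
                    "Vi": float(self.first_order[i]),
                    "Si": float(self.s_first[i]),
                    "STi": float(self.s_total[i]),
                    "sensitive": bool(self.s_total[i] > threshold),
                }
                for i in range(self.k)
            ],
        }
        if self.second_order is not None:
            report["pairs"] = [
                {"i": i, "j": j, "Vij": float(v), "Sij": float(s)}
                for (i, j), v, s in zip(
                    _pairs(self.k), self.second_order, self.s_second)
            ]
        ranking = rank_factors(self, names, threshold)
        report["ranking"] = ranking.ordered_names
        return report


@dataclass
class FactorRanking:
    """Factors ordered by descending total sensitivity index."""

    ordered_names: list[str]
    ordered_s_total: np.ndarray
    sensitive: list[bool]
    threshold: float


# ---------------------------------------------------------------------------
# analytic route (quadratic surfaces)
# ---------------------------------------------------------------------------

def analytic_sobol_quadratic(surface: QuadraticSurface) -> VarianceDecomposition:
    """Exact Sobol decomposition of a quadratic surface, inputs iid U(-1, 1)."""
    k = surface.k
    vi = surface.linear ** 2 / 3.0 + surface.squares ** 2 * (4.0 / 45.0)
    vij = surface.interactions ** 2 / 9.0
    total = float(vi.sum() + vij.sum())
    if total == 0.0:
        raise ZeroVarianceError("constant surface: output variance is zero")
    s_total = vi.copy()
    for b2, (i, j) in zip(vij, _pairs(k)):
        s_total[i] += b2
        s_total[j] += b2
    return VarianceDecomposition(
        total_variance=total,
        first_order=vi,
        second_order=vij,
        s_first=vi / total,
        s_second=vij / total,
        s_total=s_total / total,
        method="analytic",
    )


# ---------------------------------------------------------------------------
# Monte-Carlo route (Saltelli estimator)
# ---------------------------------------------------------------------------

def saltelli_sobol(
    f,
    k: int,
    n: int,
    seed: int,
) -> VarianceDecomposition:
    """Estimate first-order and total Sobol indices of ``f`` on [-1, 1]^k.

    Uses the radial A/B/AB sampling scheme on a scrambled Sobol' sequence
    (n base points, (k + 2) * n model evaluations), the Saltelli (2010)
    first-order estimator and the Jansen total-effect estimator.

    ``f`` must accept an (m, k) array and return m values (a
    :class:`QuadraticSurface` works directly). ``n`` must be a power of
    two >= 64 so the quasi-random sample stays balanced.
    """
    if n < 64 or (n & (n - 1)) != 0:
        raise ValueError("n must be a power of two >= 64")

    sampler = qmc.Sobol(d=2 * k, scramble=True, seed=seed)
    base = sampler.random(n) * 2.0 - 1.0  # scale to the coded cube
    a, b = base[:, :k], base[:, k:]

    fa = _evaluate(f, a)
    fb = _evaluate(f, b)
    all_f = [fa, fb]
    si = np.empty(k)
    sti = np.empty(k)
    fab = []
    for i in range(k):
        ab = a.copy()
        ab[:, i] = b[:, i]
        fab_i = _evaluate(f, ab)
        fab.append(fab_i)
        all_f.append(fab_i)

    var = float(np.var(np.concatenate([fa, fb]), ddof=0))
    if var == 0.0:
        raise ZeroVarianceError("constant function: output variance is zero")
    for i in range(k):
        si[i] = np.mean(fb * (fab[i] - fa)) / var
        sti[i] = 0.5 * np.mean((fa - fab[i]) ** 2) / var

    if np.any(si < -0.05) or np.any(sti < -0.05):
        warnings.warn(
            "negative index estimates suggest the sample has not converged; "
            "increase n", RuntimeWarning, stacklevel=2)

    return VarianceDecomposition(
        total_variance=var,
        first_order=si * var,
        second_order=None,
        s_first=si,
        s_second=None,
        s_total=sti,
        method="monte_carlo",
        n_samples=n,
        seed=seed,
    )


def _evaluate(f, pts: np.ndarray) -> np.ndarray:
    vals = np.asarray(f(pts), dtype=float)
    if vals.shape != (pts.shape[0],):
        raise ValueError("f must map an (m, k) array to m values")
    if not np.all(np.isfinite(vals)):
        bad = pts[~np.isfinite(vals)][0]
        raise ValueError(f"non-finite model output at point {bad}")
    return vals


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def rank_factors(
    decomp: VarianceDecomposition,
    names: list[str],
    threshold: float = SENSITIVITY_THRESHOLD,
) -> FactorRanking:
    """Order factors by descending S_Ti; ties keep input order."""
    if len(names) != decomp.k:
        raise ValueError(f"expected {decomp.k} names, got {len(names)}")
    order = np.argsort(-decomp.s_total, kind="stable")
    st = decomp.s_total[order]
    return FactorRanking(
        ordered_names=[names[i] for i in order],
        ordered_s_total=st,
        sensitive=[bool(v > threshold) for v in st],
        threshold=threshold,
    )
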