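"""Downstream enzyme characterization arithmetic.

Purification-table accounting (specific activity, yield, fold), activity
units from ammonia release, size-exclusion molecular-weight calibration,
Michaelis-Menten kinetics via the Lineweaver-Burk double reciprocal (plus
a direct nonlinear fit, statistically the better estimator), relative
activity panels with significance classification, four-parameter-logistic
dose-response IC50 and selectivity index, free-radical scavenging and
acrylamide-reduction percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .response_surface import FitStatistics
from .kinetics import FitFailureError, _fit_stats, _multistart_curve_fit

__all__ = [
    "PurificationStep",
    "MMKinetics",
    "DoseResponse",
    "ActivityPanel",
    "MWCalibration",
    "InvalidKineticsError",
    "NoIC50Error",
    "purification_table",
    "activity_from_ammonia",
    "mw_calibrate",
    "mw_predict",
    "lineweaver_burk",
    "mm_fit_nonlinear",
    "mm_derive",
    "michaelis_menten",
    "relative_activity",
    "four_param_logistic",
    "ic50_4pl",
    "selectivity_index",
    "scavenging_effect",
    "acrylamide_reduction",
    "read_purification_csv",
]


class InvalidKineticsError(ValueError):
    """Double-reciprocal regression produced a non-positive intercept."""


class NoIC50Error(ValueError):
    """Dose-response shows no transition in the tested range."""


# ---------------------------------------------------------------------------
# purification accounting
# ---------------------------------------------------------------------------

@dataclass
class PurificationStep:
    """One row of a purification table, relative to the crude extract."""

    label: str
    total_protein_mg: float
    total_activity_U: float
    specific_activity: float  # U/mg
    yield_pct: float          # % of crude activity
    fold: float               # specific activity / crude specific activity


def purification_table(steps: list[tuple[str, float, float]]
                       ) -> list[PurificationStep]:
    """Compute specific activity, yield % and fold purification per step.

    ``steps`` are (label, total protein mg, total activity U) tuples with
    the crude extract first; yield and fold are relative to that row.
    """
    if not steps:
        raise ValueError("empty purification table")
    label0, prot0, act0 = steps[0]
    if prot0 <= 0:
        raise ValueError("crude protein must be > 0")
    if act0 == 0:
        raise ZeroDivisionError("crude activity is zero")
    sa0 = act0 / prot0
    out = []
    for label, prot, act in steps:
        if prot <= 0:
            raise ValueError(f"{label}: protein must be > 0")
        sa = act / prot
        out.append(PurificationStep(
            label=label,
            total_protein_mg=prot,
            total_activity_U=act,
            specific_activity=sa,
            yield_pct=100.0 * act / act0,
            fold=sa / sa0,
        ))
    return out


def purification_frame(steps: list[PurificationStep]) -> pd.DataFrame:
    """Display table rounded to 2 dp, mirroring the usual published layout."""
    return pd.DataFrame([
        {
            "step": s.label,
            "total_protein_mg": round(s.total_protein_mg, 3),
            "total_activity_U": round(s.total_activity_U, 2),
            "specific_activity_U_mg": round(s.specific_activity, 2),
            "yield_pct": round(s.yield_pct, 2),
            "fold": round(s.fold, 2),
        }
        for s in steps
    ])


def activity_from_ammonia(nh3_umol: float, minutes: float) -> float:
    """Enzyme units: 1 U liberates 1 umol ammonia per minute."""
    if nh3_umol < 0 or minutes <= 0:
        raise ValueError("require nh3_umol >= 0 and minutes > 0")
    return nh3_umol / minutes


# ---------------------------------------------------------------------------
# molecular-weight calibration (size exclusion)
# ---------------------------------------------------------------------------

@dataclass
class MWCalibration:
    """log10(kDa) vs elution-ratio regression line for size exclusion."""

    slope: float
    intercept: float
    adj_r2: float | None = None
    ratio_range: tuple[float, float] | None = None

    def predict(self, elution_ratio: float) -> float:
        return mw_predict(self, elution_ratio)


def mw_calibrate(standards: list[tuple[str, float, float]]) -> MWCalibration:
    """Least-squares line through (elution ratio, log10 kDa) standards.

    ``standards`` are (name, kDa, elution_ratio) tuples; at least three
    are required. Larger proteins elute earlier, so the slope should be
    negative.
    """
    if len(standards) < 3:
        raise ValueError("need at least 3 standards")
    ratios = np.array([s[2] for s in standards], dtype=float)
    logmw = np.log10([s[1] for s in standards])
    res = stats.linregress(ratios, logmw)
    n = len(standards)
    adj = 1.0 - (1.0 - res.rvalue ** 2) * (n - 1) / (n - 2)
    if res.slope >= 0:
        warnings.warn("calibration slope is non-negative; check standards",
                      RuntimeWarning, stacklevel=2)
    return MWCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        adj_r2=float(adj),
        ratio_range=(float(ratios.min()), float(ratios.max())),
    )


def mw_predict(cal: MWCalibration, elution_ratio: float) -> float:
    """Molecular weight (kDa) = 10 ** (slope * ratio + intercept)."""
    if cal.ratio_range is not None and not (
            cal.ratio_range[0] <= elution_ratio <= cal.ratio_range[1]):
        warnings.warn(
            f"elution ratio {elution_ratio} outside calibrated range "
            f"{cal.ratio_range}: extrapolating", RuntimeWarning, stacklevel=2)
    return float(10.0 ** (cal.slope * elution_ratio + cal.intercept))


# ---------------------------------------------------------------------------
# Michaelis-Menten kinetics
# ---------------------------------------------------------------------------

@dataclass
class MMKinetics:
    """Michaelis-Menten constants with catalytic rate and efficiency.

    Km in mol/L, Vmax in umol/min, E0 in uM (= umol/L); kcat = Vmax/E0 in
    1/min on a concentration basis, efficiency kcat/Km in 1/(M min).
    """

    Km: float
    Vmax: float
    E0: float
    kcat: float
    efficiency: float


def michaelis_menten(S, Km: float, Vmax: float) -> np.ndarray:
    """Forward model V = Vmax [S] / (Km + [S])."""
    S = np.asarray(S, dtype=float)
    return Vmax * S / (Km + S)


def lineweaver_burk(S, V) -> tuple[float, float]:
    """Estimate (Km, Vmax) from the double-reciprocal regression.

    Regresses 1/V on 1/[S]; Vmax = 1/intercept, Km = slope * Vmax. This is
    the classical graphical method; for noisy data prefer
    :func:`mm_fit_nonlinear`, which weights observations correctly.
    """
    S = np.asarray(S, dtype=float)
    V = np.asarray(V, dtype=float)
    if len(S) < 4:
        raise ValueError("need at least 4 points")
    if np.any(S <= 0) or np.any(V <= 0):
        raise ValueError("all S and V must be > 0")
    res = stats.linregress(1.0 / S, 1.0 / V)
    if res.intercept <= 0:
        raise InvalidKineticsError(
            f"non-positive 1/Vmax intercept ({res.intercept:.3g})")
    vmax = 1.0 / res.intercept
    km = res.slope * vmax
    return float(km), float(vmax)


def mm_fit_nonlinear(S, V, seed: int = 0) -> tuple[float, float]:
    """Direct nonlinear least-squares Michaelis-Menten fit -> (Km, Vmax)."""
    S = np.asarray(S, dtype=float)
    V = np.asarray(V, dtype=float)
    vmax0 = float(np.max(V)) * 1.2
    km0 = float(S[np.argmin(np.abs(V - vmax0 / 2))])
    popt, _ = _multistart_curve_fit(
        lambda s, km, vm: michaelis_menten(s, km, vm),
        S, V, [km0, vmax0],
        ([1e-12, 1e-12], [np.inf, np.inf]), seed=seed)
    return float(popt[0]), float(popt[1])


def mm_derive(Km: float, Vmax: float, E0_uM: float) -> MMKinetics:
    """Catalytic rate and efficiency from (Km, Vmax) and enzyme concentration.

    kcat = Vmax / E0 with Vmax in umol/min and E0 in uM (umol/L), giving
    kcat in 1/min on a per-litre concentration basis; efficiency is
    kcat/Km in 1/(M min).
    """
    if Km <= 0 or Vmax <= 0 or E0_uM <= 0:
        raise ValueError("Km, Vmax and E0 must all be > 0")
    kcat = Vmax / E0_uM
    return MMKinetics(Km=Km, Vmax=Vmax, E0=E0_uM, kcat=kcat,
                      efficiency=kcat / Km)


# ---------------------------------------------------------------------------
# relative-activity panels
# ---------------------------------------------------------------------------

@dataclass
class ActivityPanel:
    """Relative activities (% of control) with per-condition classification."""

    table: pd.DataFrame  # condition, mean_pct, p_value, classification


def relative_activity(
    panel: dict[str, np.ndarray],
    control: np.ndarray,
    alpha: float = 0.05,
) -> ActivityPanel:
    """Express replicate activities as % of control and classify each condition.

    A Welch two-sided t-test against the control replicates drives the
    call: ``enhance`` (mean above control, p < alpha), ``inhibit`` (below,
    p < alpha), else ``neutral``. A zero-variance comparison falls back to
    an exact equality test.
    """
    control = np.asarray(control, dtype=float)
    if len(control) < 2:
        raise ValueError("need at least 2 control replicates")
    cmean = control.mean()
    rows = [{"condition": "control", "mean_pct": 100.0,
             "p_value": 1.0, "classification": "neutral"}]
    for cond, reps in panel.items():
        reps = np.asarray(reps, dtype=float)
        if len(reps) < 2:
            raise ValueError(f"{cond}: need at least 2 replicates")
        pct = 100.0 * reps.mean() / cmean
        if np.var(reps) == 0 and np.var(control) == 0:
            p = 1.0 if reps.mean() == cmean else 0.0
        else:
            p = float(stats.ttest_ind(reps, control, equal_var=False).pvalue)
        if p < alpha:
            cls = "enhance" if reps.mean() > cmean else "inhibit"
        else:
            cls = "neutral"
        rows.append({"condition": cond, "mean_pct": pct,
                     "p_value": p, "classification": cls})
    return ActivityPanel(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# dose-response / IC50
# ---------------------------------------------------------------------------

@dataclass
class DoseResponse:
    """Four-parameter logistic dose-response fit of % viability."""

    doses: np.ndarray
    viability: np.ndarray
    top: float
    bottom: float
    ic50: float
    hill: float
    fit: FitStatistics | None = None


def four_param_logistic(dose, top, bottom, ic50, hill) -> np.ndarray:
    """Descending 4PL: V(d) = bottom + (top-bottom)/(1+(d/ic50)^hill)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)


def ic50_4pl(doses, viability, seed: int = 0,
             top_max: float = 110.0) -> DoseResponse:
    """Fit a 4PL to viability data and report IC50.

    Requires at least 5 dose levels spanning the transition; the top is
    bounded by ``top_max`` % and the bottom by 0 (physical limits of a
    percent-viability readout). A flat curve raises :class:`NoIC50Error`.
    """
    doses = np.asarray(doses, dtype=float)
    viability = np.asarray(viability, dtype=float)
    if len(doses) < 5:
        raise ValueError("need at least 5 dose levels")
    if np.any(doses <= 0):
        raise ValueError("doses must be > 0")
    span = np.ptp(viability)
    if span < 10.0:  # less than 10 points of viability change: no transition
        raise NoIC50Error("viability shows no transition over the dose range")

    top0 = min(float(np.max(viability)), top_max)
    bot0 = max(float(np.min(viability)), 0.0)
    mid = (top0 + bot0) / 2
    ic50_0 = float(doses[np.argmin(np.abs(viability - mid))])
    p0 = [top0, bot0 + 1e-3, ic50_0, 1.0]
    bounds = ([0.0, 0.0, float(doses.min()) / 10, 0.05],
              [top_max, top_max, float(doses.max()) * 10, 20.0])
    popt, pcov = _multistart_curve_fit(
        lambda d, t, b, i, h: four_param_logistic(d, t, b, i, h),
        doses, viability, p0, bounds, seed=seed)
    top, bottom, ic50, hill = map(float, popt)
    if top <= bottom:
        raise NoIC50Error("fitted top does not exceed bottom")
    fs = _fit_stats(viability, four_param_logistic(doses, *popt), 4)
    fs.param_se = np.sqrt(np.diag(pcov))
    return DoseResponse(doses=doses, viability=viability, top=top,
                        bottom=bottom, ic50=ic50, hill=hill, fit=fs)


def selectivity_index(ic50_nontumor: float, ic50_tumor: float) -> float:
    """SI = IC50(non-tumor line) / IC50(tumor line); > 1 means selective."""
    if ic50_tumor <= 0 or ic50_nontumor <= 0:
        raise ValueError("IC50 values must be > 0")
    return ic50_nontumor / ic50_tumor


# ---------------------------------------------------------------------------
# simple percentage reductions
# ---------------------------------------------------------------------------

def scavenging_effect(A0: float, A1: float, conventional: bool = False) -> float:
    """Free-radical scavenging percentage from control (A0) and test (A1)
    absorbances.

    The default reproduces the reporting convention used for this assay in
    the source study: SE% = 100 - ((A0 - A1)/A0 * 100), which equals 100
    when A1 == A0. ``conventional=True`` gives the standard DPPH formula
    (A0 - A1)/A0 * 100 instead — the two are complements.
    """
    if A0 == 0:
        raise ZeroDivisionError("control absorbance A0 must be nonzero")
    drop = (A0 - A1) / A0 * 100.0
    return drop if conventional else 100.0 - drop


def acrylamide_reduction(control_amount: float, treated_amount: float) -> float:
    """Percent acrylamide reduction = 100 (control - treated) / control."""
    if control_amount == 0:
        raise ZeroDivisionError("control amount must be nonzero")
    return 100.0 * (control_amount - treated_amount) / control_amount


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def read_purification_csv(path) -> list[PurificationStep]:
    """Read `label,total_protein_mg,total_activity_U` rows and compute the table."""
    frame = pd.read_csv(path)
    steps = [(r["label"], float(r["total_protein_mg"]),
              float(r["total_activity_U"])) for _, r in frame.iterrows()]
    return purification_table(steps)
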