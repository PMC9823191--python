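"""Bundled reference data for the *Aspergillus* protoplast-fusant
L-asparaginase process.

These are the published summary quantities of the fusant bioprocess this
package models — fitted response-surface coefficient sets, kinetic
parameters per fermentation mode, the cost ledger, the purification
table, the size-exclusion calibration line, Michaelis-Menten constants
and cytotoxicity IC50s. The raw experimental data behind them were never
deposited, so these coefficient sets are the authoritative inputs for
every downstream reduction; they double as worked-example fixtures.
"""

from __future__ import annotations

import numpy as np

from .economics import CostLedger
from .enzymology import MWCalibration
from .kinetics import (DerivedYields, GompertzParams, KineticRun,
                       LogisticParams)
from .response_surface import CodedFactor, QuadraticSurface

# ---------------------------------------------------------------------------
# response surfaces
# ---------------------------------------------------------------------------

#: Protoplast-release model: log10 protoplast concentration as a function of
#: coded mycelial age (36-108 h), pH (4-8) and lytic incubation time (2-6 h).
PROTOPLAST_SURFACE = QuadraticSurface(
    factors=(
        CodedFactor("mycelial_age_h", 72.0, 36.0),
        CodedFactor("pH", 6.0, 2.0),
        CodedFactor("incubation_h", 4.0, 2.0),
    ),
    b0=5.53,
    linear=np.array([-0.3861, -0.1621, -0.1078]),
    # pair order: (1,2), (1,3), (2,3)
    interactions=np.array([-0.1016, -0.0768, -0.0342]),
    squares=np.array([-0.2758, -0.0288, -0.2555]),
    response_name="log10_protoplasts",
    units="log10(sfu/mL)",
)

#: Shared coded factor space of the aqueous two-phase extraction models:
#: PEG molecular weight, PEG %, sodium citrate %, NaCl % and pH.
ATPS_FACTORS = (
    CodedFactor("peg_molecular_weight", 4500.0, 1500.0),
    CodedFactor("peg_pct", 15.8, 5.0),
    CodedFactor("citrate_pct", 20.8, 5.0),
    CodedFactor("nacl_pct", 12.5, 3.0),
    CodedFactor("pH", 7.8, 1.0),
)

# interaction order for k=5: (1,2) (1,3) (1,4) (1,5) (2,3) (2,4) (2,5)
#                            (3,4) (3,5) (4,5)

#: ATPS enzyme recovery (% yield) response surface.
ATPS_YIELD_SURFACE = QuadraticSurface(
    factors=ATPS_FACTORS,
    b0=66.29,
    linear=np.array([9.3, 4.61, -5.34, 1.55, -3.79]),
    interactions=np.array(
        [2.18, -3.02, -4.36, 3.06, -1.8, 0.72, 1.76, -0.01, 8.05, -2.98]),
    squares=np.array([-1.52, -1.81, -3.18, -4.93, -0.04]),
    response_name="yield",
    units="%",
)

#: ATPS purification-factor response surface.
ATPS_PURIFICATION_SURFACE = QuadraticSurface(
    factors=ATPS_FACTORS,
    b0=29.58,
    linear=np.array([-1.97, 3.81, 4.37, -3.2, -1.51]),
    interactions=np.array(
        [4.92, -11.74, 2.23, -6.24, -5.05, -1.28, 0.53, -1.42, 7.73, -0.73]),
    squares=np.array([3.08, -1.76, 2.88, 1.72, 0.554]),
    response_name="purification_factor",
    units="fold",
)

#: Coded settings selected for the preparative ATPS purification, and the
#: extraction outcomes measured there (the measured yield/fold, not model
#: predictions).
ATPS_SELECTED_POINT = np.array([1.0, -1.0, 1.0, 1.0, -1.0])
ATPS_COMPOSITE_DESIRABILITY = 0.989
ATPS_MEASURED_YIELD_PCT = 89.34
ATPS_MEASURED_FOLD = 69.96

# ---------------------------------------------------------------------------
# fermentation kinetics (fusant, three modes)
# ---------------------------------------------------------------------------

def _run(name, x0, xmax, mu, pmax, rp, tlp, smax, rs, tls,
         yps, yxs, ypx, qp, qs):
    return KineticRun(
        name=name,
        logistic=LogisticParams(X0=x0, Xmax=xmax, mu_max=mu),
        product=GompertzParams(Amax=pmax, r_max=rp, t_L=tlp),
        substrate=GompertzParams(Amax=smax, r_max=rs, t_L=tls),
        yields=DerivedYields(Yxs=yxs, Yps=yps, Ypx=ypx, qp=qp, qs=qs,
                             Qp=float("nan"), Qx=float("nan")),
    )


#: Fitted kinetic parameter sets per fermentation mode (fusant strain).
KINETIC_RUNS = {
    "batch": _run("batch", 0.034, 76.14, 0.26,
                  94048.10, 3653.83, 18.45,
                  543.46, 20.33, 23.07,
                  173.05, 1.612, 107.34, 1.118, 0.007),
    "fed_batch": _run("fed_batch", 0.000, 2061.84, 0.85,
                      134364.1, 4454.93, 20.07,
                      2742.08, 77.56, 20.62,
                      48.14, 0.752, 65.17, 0.679, 0.018),
    "continuous": _run("continuous", 0.01, 1688.72, 0.647,
                       112251.13, 3657.56, 19.09,
                       2286.62, 135.94, 20.02,
                       49.09, 0.756, 64.94, 0.676, 0.014),
}

#: Fed-batch feeding-schedule inputs: target mu (h^-1), end-of-batch
#: biomass (g/L) and volume (L), batch-phase biomass yield (g/g), feed
#: substrate concentration (g/L).
FEED_PLAN_INPUTS = dict(mu=0.85, X0=5.0, V0=3.5, Yxs=0.752, S0=30.0)

#: Pearson correlation between product activity and biomass reported for
#: the production runs (basis for costing on dry cell weight).
ACTIVITY_BIOMASS_PEARSON_R = 0.960

# ---------------------------------------------------------------------------
# cost ledgers (USD, per 3.5 L working-volume vessel, 100 h campaign)
# ---------------------------------------------------------------------------

#: Nine strain x mode ledgers. The fusant batch labour is the recorded
#: $4900 rather than the 1 worker x $50/h x 100 h = $5000 the staffing
#: formula gives; recorded component values win over the formula.
COST_LEDGERS = {
    ("fusant", "batch"): CostLedger("batch", 14.8, 750.0, 3066.49,
                                    labour_usd=4900.0),
    ("fusant", "fed_batch"): CostLedger("fed_batch", 24.5, 1150.0, 8122.59,
                                        labour_usd=10000.0),
    ("fusant", "continuous"): CostLedger("continuous", 16.8, 1025.0, 6050.065,
                                         labour_usd=15000.0),
    ("candidus", "batch"): CostLedger("batch", 14.8, 750.0, 2475.0,
                                      labour_usd=5000.0),
    ("candidus", "fed_batch"): CostLedger("fed_batch", 24.5, 1150.0, 5294.34,
                                          labour_usd=10000.0),
    ("candidus", "continuous"): CostLedger("continuous", 16.8, 1025.0,
                                           4228.25, labour_usd=15000.0),
    ("sydowii", "batch"): CostLedger("batch", 14.8, 750.0, 2599.24,
                                     labour_usd=5000.0),
    ("sydowii", "fed_batch"): CostLedger("fed_batch", 24.5, 1150.0, 4677.42,
                                         labour_usd=10000.0),
    ("sydowii", "continuous"): CostLedger("continuous", 16.8, 1025.0,
                                          3938.45, labour_usd=15000.0),
}

#: Published ledger sums and unit costs for the nine columns above.
COST_EXPECTED = {
    ("fusant", "batch"): (5664.8, 1.85),
    ("fusant", "fed_batch"): (11174.5, 1.38),
    ("fusant", "continuous"): (16041.8, 2.65),
    ("candidus", "batch"): (5764.8, 2.33),
    ("candidus", "fed_batch"): (11174.5, 2.11),
    ("candidus", "continuous"): (16041.8, 3.79),
    ("sydowii", "batch"): (5764.8, 2.22),
    ("sydowii", "fed_batch"): (11174.5, 2.39),
    ("sydowii", "continuous"): (16041.8, 4.07),
}

# ---------------------------------------------------------------------------
# downstream characterization
# ---------------------------------------------------------------------------

#: Purification ledger rows: (step, total protein mg, total activity U).
PURIFICATION_STEPS = [
    ("crude extract", 1926.400, 132007.00),
    ("ATPS (PEG-6000/citrate)", 24.601, 117935.05),
    ("Sephadex G-100", 8.036, 80511.07),
]

#: Size-exclusion calibration: log10(kDa) = slope * elution_ratio + intercept,
#: fitted on standards from 12.4 to 115 kDa. Standard-by-standard elution
#: ratios were not published, so the fitted line itself is bundled.
MW_CALIBRATION = MWCalibration(slope=-1.7519, intercept=3.0946, adj_r2=0.9203)

#: Elution ratio measured for the fusant enzyme.
FUSANT_ELUTION_RATIO = 0.587

#: Michaelis-Menten constants of the fusant enzyme: Km in mol/L, Vmax in
#: umol/min, assay enzyme concentration in uM.
MM_KM_M = 6.67e-5
MM_VMAX_UMOL_MIN = 1666.67
MM_E0_UM = 0.043

#: Cytotoxicity IC50s (ug/mL) per strain and cell line. HEK-238T is the
#: non-tumor reference for selectivity indices.
IC50_UG_ML = {
    ("fusant", "HL-60"): 1.055,
    ("fusant", "HepG-2"): 6.359,
    ("fusant", "MCF-7"): 9.446,
    ("fusant", "HEK-238T"): 81.370,
    ("asp_c", "HL-60"): 3.178,
    ("asp_c", "HepG-2"): 9.392,
    ("asp_c", "MCF-7"): 11.831,
    ("asp_c", "HEK-238T"): 87.890,
    ("asp_s", "HL-60"): 19.738,
    ("asp_s", "HepG-2"): 22.683,
    ("asp_s", "MCF-7"): 25.458,
    ("asp_s", "HEK-238T"): 98.361,
}

#: Relative metal-ion activities (% of metal-free control) for the two
#: extreme responses: Mn2+ strongly activates, Fe3+ most inhibits.
METAL_RELATIVE_ACTIVITY = {"Mn2+": 184.60, "Fe3+": 31.62}

#: Acrylamide reduction achieved in fried sweet-potato chips (%).
ACRYLAMIDE_REDUCTION_PCT = 76.46
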