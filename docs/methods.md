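# Methods

This note records the models implemented in `asnase`, the choices made
where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate.

## Coded factors and quadratic surfaces

All design-of-experiments work happens in coded units,
`x = (actual − center)/half-range`, so every factor spans [−1, 1] over
its design region and coefficients are directly comparable. Coding is
exact and bijective; round-trip error is at machine precision.

A response surface is the full second-order polynomial (intercept, k
linear, k(k−1)/2 two-way interaction, k squared terms). Fitting is
ordinary least squares on the expanded model matrix (statsmodels OLS
underneath). A rank-deficient matrix raises an error that names the
aliased terms, found by a greedy rank scan of the columns in model
order. Reported statistics: adjusted r², RMSE, MAE, the overall
regression F and p, and a classical lack-of-fit F test computed only
when replicate runs leave pure-error degrees of freedom — without
replicates the lack-of-fit fields are None and a notice is logged.

Design constructors: Box–Behnken (all factor pairs at (±1, ±1) with the
rest at 0; 12 edge runs + 5 center runs by default for k = 3, giving the
classical 17-run plan), face-centred central composite (2^k factorial +
2k axial at ±α + centers; α defaults to 1.0 because the process optimum
of interest sits on the ±1 faces, with α = (2^k)^{1/4} available for
rotatability), and Plackett–Burman (cyclic generators for 8/12/20/24
runs, Sylvester–Hadamard construction for power-of-two run counts).
These are standard constructions, implemented here directly and verified
in tests by combinatorial enumeration and brute-force orthogonality
checks.

Optimization over the cube: for k ≤ 3 a dense 0.01-step grid scan
followed by a bound-constrained quasi-Newton polish; for larger k, 64
seeded random starts of L-BFGS-B with box projection (default seed
1729). Near-ties are resolved toward the lexicographically smallest
coded point so results are reproducible.

Desirability follows the one-sided Derringer–Suich form
d = clip(((y − L)/(T − L))^s, 0, 1) with the mirrored ordering for
minimization, and composite D is the geometric mean. Published reports
of such optimizations rarely print L/T bounds; the default here takes
each response's min/max prediction over the design points with weight
s = 1, matching common DoE-software behaviour and keeping D
well-defined. The k = 5 composite-desirability cross-check in the tests
uses a 0.25-step lattice (59 049 nodes) as a lower-bound oracle; the
optimizer must dominate every node. A 0.01-grid in five dimensions would
be ~10^10 nodes and adds nothing to the property being checked.

## Sobol variance decomposition

Inputs are modelled as independent Uniform(−1, 1) on the coded cube —
the only support the design itself defines. For U ~ U(−1, 1), Var(U) =
1/3 and Var(U²) = 4/45, so a quadratic surface decomposes exactly:

    V_i  = b_i²/3 + b_ii²·4/45        (linear + pure-quadratic main effect)
    V_ij = b_ij²/9                    (two-way interaction)
    V(Y) = Σ V_i + Σ V_ij             (no higher-order terms exist)

with S_i = V_i/V, S_ij = V_ij/V and S_Ti = (V_i + Σ_j V_ij)/V. The
identity V = ΣV_i + ΣV_ij holds exactly and S_Ti − S_i ≥ 0 by
construction; both are asserted as properties. Indices are invariant to
shifting or uniformly scaling the response.

The Monte-Carlo route uses the Saltelli radial A/B/AB scheme on a
scrambled Sobol' sequence (scipy's generator), the Saltelli (2010)
first-order estimator and the Jansen total-effect estimator — the
lowest-variance standard pairing. n must be a power of two (quasi-random
balance); negative estimates are reported as-is with a convergence
warning rather than clipped, and the analytic path is authoritative for
quadratics. At n = 2^16 the two routes agree within |ΔS| ≤ 0.01 on the
five-factor extraction models, which is the equivalence the acceptance
suite asserts. A factor is flagged "sensitive" when S_Ti exceeds 0.1,
the conventional benchmark.

For the bundled extraction models the analytic ranking puts PEG
molecular weight first and NaCl last for the yield model, and citrate
concentration first for the purification-factor model. The absolute
index values reported for the original campaign are not recoverable
from the printed coefficient sets under any independent-input
assumption (they came from a metamodel-based implementation), so this
package treats rankings, not those absolute values, as the reproducible
quantity.

## Fermentation kinetics

Biomass follows the logistic model, parameterized by initial biomass
X0 (g DCW/L), carrying capacity Xmax and maximum specific growth rate
μ_max (1/h); it is evaluated in the numerically stable form
Xmax/(1 + ((Xmax − X0)/X0)e^{−μt}). Doubling time is ln2/μ_max. Product
formation and cumulative substrate consumption follow the Zwietering
re-parameterization of the Gompertz curve,
A(t) = Amax·exp(−exp(r_max·e/Amax·(t_L − t) + 1)), whose parameters are
exactly the asymptote Amax, maximum (inflection) rate r_max and lag time
t_L — the parameter set in which such campaigns report their fits.
Substrate is modelled as a rising cumulative-consumption sigmoid,
consistent with an asymptote labelled "maximum substrate consumption".

Fitting is trust-region nonlinear least squares (scipy curve_fit) with
self-starting values — X0 from the first observation clipped to ≥ 1e−6
(a fed-batch inoculum can print as 0.000), Xmax from the maximum, μ from
the steepest log-difference, t_L from the zero-crossing of the steepest
tangent — and up to 20 seeded ±20% jitter restarts. Restarting stops
early once three consecutive starts fail to improve the residual sum of
squares by 0.1%; for these well-conditioned sigmoids the first start
almost always finds the global optimum and the cap only matters for
adversarial noise. A constant response raises a fit-failure error.

Derived quantities use the endpoint identities: Y_X/S = (Xm − X0)/(S0 −
Sm), Y_P/S = Pmax/(S0 − Sm), Y_P/X = Pmax/(Xm − X0) (so Y_P/X·Y_X/S =
Y_P/S by construction), q_p = Y_P/X·μ_max, q_s = μ_max/Y_X/S, and
volumetric productivities Pmax/duration and (Xm − X0)/duration. The
specific-rate unit conventions printed in the original campaign's
kinetics table are not reconstructible from these identities (its q_p
values do not equal Y_P/X·μ_max in any obvious unit system); this
package implements the identity-based definitions and does not attempt
to reverse-engineer that table's convention. The maximum-rate arguments
(r_pmax, r_smax) belong to the Gompertz fits and are therefore not
inputs to the yield calculation here.

The exponential fed-batch feed rate is F(t) = μX₀V₀e^{μt}/(Y_X/S·S₀),
which holds the specific growth rate of a substrate-limited culture at μ
given end-of-batch biomass and volume, the batch-phase biomass yield and
the feed concentration. F is homogeneous of degree 1 in X₀V₀ and −1 in
Y_X/S·S₀, and doubles every ln2/μ hours; both are asserted as
properties.

## Enzymology

Purification accounting is relative to the first (crude) row: specific
activity U/mg, yield % of crude activity, fold = SA/SA_crude; yield and
fold are invariant to a global rescaling of activity units. One enzyme
unit is 1 µmol ammonia released per minute.

Molecular weight comes from the size-exclusion calibration
log₁₀(kDa) = slope·(elution ratio) + intercept; the slope is negative
(larger proteins elute earlier) and predictions outside the calibrated
ratio range warn about extrapolation. The bundled calibration carries
the fitted line itself (−1.7519, 3.0946, adjusted r² 0.9203) because
per-standard elution ratios were never published.

Michaelis–Menten constants are estimated by the Lineweaver–Burk double
reciprocal (regress 1/V on 1/[S]; Vmax = 1/intercept, Km = slope·Vmax) —
the method the source data were analysed with — alongside a direct
nonlinear fit, which is the statistically preferred estimator for noisy
data since reciprocation inflates low-velocity errors. kcat = Vmax/E0 on
a concentration basis (µmol·min⁻¹ over µM), efficiency kcat/Km. The
source's Results and Discussion print mutually inconsistent Km and
kcat/Km values; the Results figures (Km = 6.67 × 10⁻⁵ M) are taken as
canonical.

Relative-activity panels express each condition as % of the control
mean and classify enhance/inhibit/neutral by a Welch two-sided t-test at
α = 0.05 (the full ANOVA + Tukey structure of the original triplicates
is not reconstructible from published summaries; the test is
configurable via the α argument and a zero-variance comparison falls
back to exact equality). Dose–response viability uses a descending
four-parameter logistic with the top bounded at 110% and the bottom at
0% (physical limits of a percent-viability readout); a curve spanning
less than 10 percentage points is treated as transition-free and raises
a no-IC50 error rather than returning an unstable estimate. Selectivity
index = IC50(non-tumor)/IC50(tumor).

The free-radical scavenging percentage is implemented exactly as the
source campaign reported it, SE% = 100 − ((A0 − A1)/A0 × 100), which
returns 100 when the test absorbance equals the control — the
complement of the conventional DPPH formula. A `conventional=True`
switch gives the standard form; the two always sum to 100.

## Economics

A cost ledger holds chemicals, consumables and labour (directly, or as
rate × workers × hours); total = sum of the three, unit cost =
total/DCW. Energy, equipment and rent are deliberately outside the
model — they vary too much across laboratory set-ups to transfer. A
directly recorded labour figure wins over the staffing formula, so
ledgers can reproduce historical tables whose components do not match
the footnoted formula (the bundled fusant batch column records $4900
where 1 × $50/h × 100 h would give $5000; its printed sum is consistent
with $4900, and the discrepancy is preserved, not corrected).

## Synthetic data and what the tests show

Generators produce logistic/Gompertz time courses (6-h cadence over
96 h, the bench-scale sampling plan), DoE response vectors, velocity
series and 4PL viability curves from known ground truth plus additive
iid Gaussian noise, clipped at physical zero. Noise defaults emulate
triplicate-assay scatter at 2% of each channel's range; DoE noise uses
sd 0.05 on the log-scale protoplast model. Each artifact consumes one
integer seed with independent per-channel sub-streams, so adding a
channel never perturbs another and identical specs are byte-identical.

Because the noise is additive, homoscedastic and Gaussian, the recovery
tests demonstrate estimator correctness and numerical robustness — not
performance under real fermentation data, whose errors are
heteroscedastic, autocorrelated and occasionally non-sigmoidal.
Parameter-recovery acceptance uses noiseless refits (< 0.5% relative
error) and 100-seed noisy suites (median worst-parameter error < 5% at
2% noise); the problem sizes (17-run designs, 17-point time courses,
12-point dose grids, n = 2^16 sensitivity samples) are the package's
standard desk-scale defaults and run in seconds.

## Known limitations

- The analytic Sobol path applies only to quadratic surfaces with
  independent uniform inputs; correlated-input variants and metamodel
  reconstructions are out of scope.
- The Monte-Carlo route does not estimate second-order indices (that
  would need the doubled Saltelli scheme); the analytic path provides
  them for quadratics.
- No mechanistic bioreactor simulation (oxygen transfer, pH control),
  no mixture/split-plot designs, no discounted-cash-flow economics.
- The published coded optimum of the extraction campaign is internally
  inconsistent with its printed actual values and model predictions;
  this package reports the measured outcomes as data and does not force
  the model to reproduce them.
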