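# Methods

## Model and assumptions

Thymocyte development through β-selection is modeled as a linear chain of
four well-mixed compartments — DN3, DN4, ISP (immature CD8 single-positive)
and DP — with population sizes C₁–C₄. Progenitor arrival and maturation
through DN1–DN3 is collapsed into a single constant influx K (cells/day)
into DN3. Each compartment drains into the next at a per-cell
differentiation rate Kᵢ and is additionally depleted at a net turnover rate
K_dᵢ that lumps death and proliferation into one signed loss term; the model
therefore cannot represent a compartment whose proliferation outpaces its
loss (net turnover is constrained ≥ 0). SP maturation out of DP is neglected
— DP is terminal, emptied only by K_d4. All rates are first-order and
constant in time: no feedback, no niche saturation, no age structure within
a compartment.

Time is in days everywhere; the conventional 3-hour reporting grid is
Δt = 0.125 days. The DN4 and ISP turnover rates K_d2, K_d3 are retained as
explicit parameters but default to 0, since these highly proliferative
stages show negligible net loss relative to their differentiation rates;
the genotype presets ship with K_d2 = K_d3 = 0 and users may override them.

Genotype presets: wild type (K = 15.4×10⁴ cells/day, K₁ = 0.1, K_d1 = 0.1,
K₂ = 0.162, K₃ = 0.07, K_d4 = 0.00058), Itpkb-deficient (K₁ = 0.2,
K₂ = 0.486, K₃ = 0.21, influx and turnover unchanged), and the two
Rag2-deficient counterparts with K = 0. How K and K_d4 were originally
calibrated to thymic cellularity is not re-derived here; the presets are
taken as given.

## Solution routes

**Exact steady state.** The fixed point is the product of influx and
branching ratios, C₁ = K/(K₁+K_d1) through
C₄ = K·K₁K₂K₃/(K_d4·(K₁+K_d1)(K₂+K_d2)(K₃+K_d3)). It is reported with
`t = inf` as an explicit marker (serialized as the string `"inf"`) so a
steady state can never be confused with a late time point. A **simplified
steady state** valid for K_d2 ≪ K₂, K_d3 ≪ K₃ is also exposed; when the
smallness assumption is violated (e.g. K_d2 = K₂) it overestimates DN4 by
the corresponding factor, and a test pins this behavior.

**Explicit transient.** With K = 0, K_d2 = K_d3 = 0 and a pure DN3 initial
pool, the cascade solves in closed form as sums of exponentials in the four
decay rates {K₁+K_d1, K₂, K₃, K_d4}. The terms are evaluated in double
precision grouped exactly as hand-derived, so each line of code can be
checked against the pencil-and-paper solution. The DN4 curve
∝ e^−(K₁+K_d1)t − e^−K₂t peaks at t* = ln(K₂/(K₁+K_d1))/(K₂−(K₁+K_d1))
(limit 1/K₂ at equal rates); faster differentiation moves the peak earlier
(≈5.55 d wild type vs ≈2.59 d knockout presets).

**Spectral (matrix-exponential) solution.** The explicit formula divides by
pairwise rate differences and is numerically catastrophic near repeated
eigenvalues. Two rates are treated as degenerate when
|a−b| ≤ 10⁻⁹·max(a, b, 1/day); at or below that tolerance — and for any
case the explicit form does not cover (K > 0, K_d2/K_d3 > 0, occupied
downstream compartments) — the solver dispatches to an exact affine
solution via the augmented matrix exponential
(C(t),1) = exp([[A,b],[0,0]]·t)(C₀,1), which handles repeated eigenvalues
and singular A without special-casing.

**Numerical and stochastic oracles.** An adaptive LSODA integration
(default rtol 10⁻⁸, atol 10⁻⁶ cells; the output grid is not the internal
step) and an exact Gillespie direct-method simulation of the cell-level
jump process (8 reactions: influx, three differentiation steps, four
turnover sinks) provide two independent verification routes. The agreement
bar between closed forms and the integrator is 10⁻⁶ relative — a package
choice, as no printed tolerance exists for this model. SSA verification
runs use initial pools scaled down to ~3×10⁴ cells: rates are per-cell, so
the scaled process is statistically faithful while 200 replicates complete
in seconds; means are compared to the ODE solution within 3 standard
errors. Each SSA call takes one explicit integer seed and reproduces
bit-identically.

**Floating-point policy.** Closed-form outputs that come out negative by
less than 10⁻⁹ of the problem scale are zeroed as cancellation roundoff;
anything more negative raises instead of being clipped, so genuine defects
cannot hide. The long-time-limit check of the spectral route against the
fixed point uses t = 5×10⁴ days, chosen so the slowest mode
(K_d4 ≈ 5.8×10⁻⁴/day) has decayed below double-precision resolution.

## Synthetic data generator

Two observation designs are emulated. A *steady-state cross-section* gives
each virtual mouse the four fixed-point subset counts of its genotype. An
*α-CD3 time course* samples the transient solution at fixed days (default
0, 0.5, …, 3 — the span over which the synchronized wave traverses the
cascade) from C(0) = (3×10⁸, 0, 0, 0); designs in this scenario must have
K = 0. Default group size is 20 virtual mice per design point.

Noise is multiplicative log-normal per mouse and subset with unit median
and configurable CV — chosen over additive Gaussian so counts stay positive
and log-scale residuals are homoscedastic; the published figures show
mouse-to-mouse scatter only graphically, so no empirical CV exists to
calibrate against and the default CV = 0.05 is a package choice
representative of inbred-mouse cellularity variation. Optionally a
multinomial layer draws a fixed number of flow events (default 10⁵) from
the subset proportions and rescales to total cellularity, emulating
finite-event counting (which can produce exact zeros for rare subsets);
"both" composes log-normal then multinomial. Counts are continuous by
default, with opt-in banker's rounding. The generator does not emulate
gating, compensation, spillover, fluorescence intensities or FCS files —
passing tests therefore demonstrate recoverability under the model's own
noise assumptions, not robustness to real cytometry artifacts such as
gating bias or misclassification between adjacent gates.

Generation is deterministic under (design, noise model, seed); datasets
serialize as tidy CSV plus a JSON sidecar holding the design, noise, seed
and true parameters.

## Estimation

The declared estimator is least squares on log counts: residuals
log(observed + c) − log(predicted + c) with pseudo-count c = 0.5 so
multinomial zeros stay finite while a noiseless dataset still has exactly
zero loss at the truth. No formal likelihood is claimed. Free parameters
are optimized as logarithms (positivity by construction) with
box-constrained trust-region least squares, and reported on the natural
scale. Default bounds: rates in [10⁻⁶, 10] /day, K in [1, 10⁷] cells/day.

Eight multi-start restarts drawn log-uniformly within bounds guard against
the shallow valley between K₁ and K_d1 (their sum is strongly determined by
the DN3 decay, their split only by downstream amplitudes). A fit is
declared converged when the optimizer succeeded and the restart optima
agree to within 10⁻³ maximum pairwise relative difference.

Identifiability is enforced, not discovered: the steady state exposes only
four observable combinations, so with the differentiation rates fixed only
{K, K_d4} may be freed; in the transient design, freeing both K₁ and K_d1
requires a subset beyond DN3 to be observed, and each free parameter must
influence at least one observed subset. K_d4 is fixed by default in
transient fits — over a 3-day window with K_d4 ~ 6×10⁻⁴/day its signal is
far below the noise floor — and freeing it is allowed but flagged.

Uncertainty comes from a case-resampling bootstrap: mice are resampled with
replacement within each (genotype, time) stratum, each replicate refit from
the point estimate, and 95% percentile intervals reported; a replicate
failure rate above 5% flags the result as unstable. Fold changes between a
wild-type and a knockout fit are ratios of shared estimates, with ratio
percentile intervals when bootstrap draws exist for both.

## Problem sizes

Test and acceptance runs use the study-scale designs directly — 20 mice per
design point, 7 transient time points, 200 stochastic replicates at the
3×10⁴-cell scale, 20-seed recovery sweeps, B = 200 bootstrap replicates
with 20 outer coverage replications — all completing in well under a minute
apiece on one core.

## Known limitations

* Linearity: no density dependence, competition for niches, or signaling
  feedback; rate constants are time-invariant even during the α-CD3 wave.
* Net turnover conflates death and proliferation; a compartment with net
  expansion (K_dᵢ < 0) is outside the supported parameter space.
* The transitional CD25-intermediate population between DN3 and DN4 is not
  a separate compartment; the chain has exactly four stages and no SP
  compartment.
* The estimator assumes the generator's noise law; real cytometry data with
  gating drift or heavy-tailed counts would need a robust loss.
* Steady-state fits cannot separate more than the four observable
  combinations of rates no matter how many mice are measured — more free
  parameters require time-resolved designs.
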