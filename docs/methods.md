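# Methods

## Model

`ncakin` models amine-initiated NCA ring-opening polymerization in which
chain growth switches mechanism at a critical degree of polymerization
(DP) *s*, the length at which the chain folds into an α-helix:

* **Coil stage (i < s).** Chain end + monomer react in a single
  second-order step with rate constant `k1` (M⁻¹s⁻¹). The free initiator is
  treated as the DP-0 chain `P_0` and initiates with the same `k1`; chains
  are indexed by incorporated monomer count. This convention is a modelling
  choice — if amine initiation were slower or faster than coil propagation a
  distinct constant could be introduced, but conversion data of the kind the
  package targets cannot resolve the difference.
* **Helix stage (i ≥ s).** The monomer first adsorbs to the helical
  N terminus (`kon`, M⁻¹s⁻¹; desorption `koff`, s⁻¹), forming a complex
  `C_i` whose ring is still intact; ring opening inside the complex
  (`kr`, s⁻¹) then extends the chain. This is a Michaelis–Menten mechanism
  with the helix terminus as the "enzyme": binding equilibrium constant
  K = kon/koff (M⁻¹), standard binding free energy ΔG° = −RT ln(K·c°).

No termination or monomer-degradation channels are included (end-group
analysis of the experimental system shows ≈1% loss of active amines over a
polymerization), and complexes exist only for helical chains.

Reference parameter set used throughout tests and examples:
`k1 = 0.02 M⁻¹s⁻¹, kon = 10 M⁻¹s⁻¹, koff = 2 s⁻¹, kr = 0.2 s⁻¹, s = 10`,
with [M]0 = 0.05–0.4 mol/L and [M]0/[I]0 = 50–150.

## Deterministic integration

The population balance lives on a finite DP ladder `P_0..P_Nmax`,
`C_s..C_{Nmax−1}`. Complexes stop one rung below the cap so every
ring-opening flux stays on the ladder: chain count Σ(P+C) and monomer units
M + Σ i·P_i + Σ (i+1)·C_i are then conserved *identically* by the
right-hand side, and the suite checks both to ≤1e−6 relative along every
trajectory (in practice they hold to ~1e−12). `Nmax` defaults to
4·[M]0/[I]0; after each run a guard requires the top 5% of the ladder to
hold < 1e−10·[I]0 of chains. The default is adequate for the reference
conditions at 0.2–0.4 M but **not** for the broadest distributions (at
[M]0 = 0.05 M the MWD tail reaches DP ≈ 900); the guard raises a
`TruncationError` and the caller picks a taller ladder
(`predict_from_fit` grows it automatically).

The stiff system is integrated with BDF (`scipy.solve_ivp`) using an
analytic sparse Jacobian (~6 non-zeros per row; the monomer row/column are
dense, which is also why finite-difference sparsity grouping would not
work). Defaults `rtol = 1e−8`, `atol = 1e−12·[M]0` keep the conservation
residuals far below the test threshold.

**Exact lumping for conversion.** Because `kon`, `koff`, `kr` are
chain-length independent, the dynamics of (M, P_0..P_{s−1}, H = Σ_{i≥s}P_i,
C = ΣC_i) close exactly — the lumped system is an algebraic projection of
the infinite ladder, with no truncation. All conversion-only work (fitting,
synthetic data) uses this s+3-dimensional system via LSODA/`odeint` with
numba-compiled callbacks (~2 ms per curve); equivalence with the full
ladder is asserted to <1e−6 in the suite. When s exceeds the reachable DP
range (s > 4·ratio + 10) the model is pure chain growth and the closed form
x = 1 − exp(−k1·[I]0·t) is returned directly.

**Conversion conventions.** NMR integration cannot distinguish a bound but
unreacted monomer from a free one, so the default observable
(`ring-intact`) counts complexed monomer as unconverted:
x = 1 − (M + ΣC)/[M]0. The alternative `free-monomer` convention
(x = 1 − M/[M]0) is exposed; the two differ by ΣC/[M]0 ≤ [I]0/[M]0
pointwise and converge at full conversion.

**Apparent rate constants.** Stage-wise pseudo-first-order analysis: slope
of ln(1/(1−x)) vs t divided by [I]0, in conversion windows [0.02, 0.15] and
[0.45, 0.85] by default. The windows are a reporting convention; the
underlying "~20×" experimental acceleration depends on the windows chosen,
and the reference parameter set gives kapp2/kapp1 ≈ 13.

**QSSA reduction.** Eliminating the complex at quasi-steady state gives a
per-chain helix-stage rate kr·θ with occupancy
θ = kon·M/(kon·M + koff + kr) — Michaelis–Menten saturation, reducing to
the pseudo-second-order k2eff·M, k2eff = kr·kon/(koff+kr), away from
saturation. The saturated form matters: at the reference constants
kon·M0/(koff+kr) ≈ 1.8, and the unsaturated reduction errs by >0.2 in
conversion where the full one stays within 0.01.

## Behaviour on the τ axis

On dimensionless time τ = t·k1·[M]0 the coil stage is scale-free, so curves
at different [M]0 (fixed ratio) collapse until helical chains appear
(spread < 0.005 below 5% conversion for the reference set) and separate in
the second stage. The direction of the separation follows from saturation:
the per-chain helix-stage rate is capped at kr, which in τ units scales
like 1/[M]0 — so **higher [M]0 lags on the τ axis** while being faster in
real time (the per-chain rate kr·θ and [I]0 both grow with [M]0). Both
orderings are asserted in the suite. The same mechanism makes the terminal
MWD broaden as [M]0 decreases: dispersity 1.33 / 1.50 / 1.64 / 1.74 at
0.4 / 0.2 / 0.1 / 0.05 M for the reference set, with short-chain (DP < s)
mass fractions 1.1–2.2%. The MWD is asymmetric relative to the Poisson
distribution of ideal living growth (third central moments differ by far
more than 20%), because chains cross the coil→helix threshold at randomly
staggered times and then grow ~13× faster.

Note the terminal dispersity of the reference simulation (1.33 at 0.4 M)
sits *above* the ≤1.25 range measured by GPC for the real polymers; the
reference constants are illustrative test cases, not the constants fitted
to experiment, and the acceptance suite records this discrepancy rather
than hiding it.

## Stochastic oracle

The Gillespie direct method runs on the identical network with integer
molecule counts; volume is set by the initiator copy number,
V = n_init/(N_A·[I]0), so bimolecular propensities scale by [I]0/n_init.
Within each category (coil, free helix, complex) all per-chain rates are
equal, so an event picks a chain uniformly from the category pool
(swap-remove index lists, O(1) per event) — exact, with no per-DP
propensity walk. The event loop is numba-jitted (~10⁷ events/s) with a
pure-Python fallback. Conservation is exact by construction; the ensemble
mean conversion (10⁴ initiators, 64 replicates) agrees with the ODE within
3 standard errors at every checkpoint, and the terminal DP histogram of the
single-stage limit passes a χ² test against Poisson at α = 0.01.

## Global fitting

Nine (or any number of) conversion datasets are fit jointly: `kr` and the
integer `s` shared, `k1` and `K = kon/koff` per dataset, `koff` fixed
(2 s⁻¹ by default). Fixing `koff` is an identifiability decision, not a
physical claim: in the fast-equilibrium regime scaling kon and koff
together at fixed K moves conversion by <0.5% absolute (asserted in the
suite), so conversion data determine only their ratio. Fitted kon values
are therefore meaningful only as K·koff_nominal.

For each s in the grid (2..30 by default) one bounded nonlinear least
squares runs over [log10 kr, per-dataset log10 k1, log10 K] (bounds
k1 ∈ [1e−4, 10], K ∈ [1e−2, 1e4], kr ∈ [1e−4, 1e2]). The residual Jacobian
is block-diagonal plus one shared-kr column, so grouped finite differencing
(`jac_sparsity`) costs ~4 residual evaluations per iteration regardless of
the dataset count. Two numerical choices proved essential and are worth
recording:

* `diff_step = 1e−4` (log10 units): the default FD step (~1e−8) is smaller
  than the ODE solver's O(rtol = 1e−6) evaluation noise, which yields
  meaningless gradients and premature convergence.
* Multistart along kr: the SSE landscape is multimodal chiefly in the
  shared kr direction (stage-two onset trades off against ring-opening
  speed), while k1 is well initialized from the early-time slope
  (x ≈ k1·[I]0·t below 10% conversion) and K from the mid-bound. Each s is
  therefore started from the heuristic swept over five log-spaced kr values
  plus the previous s's optimum; random joint starts are available
  (`FitSpec.random_starts`) and used by the bootstrap.

The SSE-minimizing s wins (ties to the smallest s) and is re-polished at
tight tolerance. On the nine-condition synthetic panel with σ = 0.01 noise
this recovers s = 10 exactly and k1 within 10% per dataset (asserted in the
acceptance suite at seed 1; the acceptance script repeats three seeds and
takes the majority).

**Bootstrap.** Residual-resampling within each dataset, refitting with s
held at the point estimate (re-running the integer grid per replicate is
disproportionate to its uncertainty). Each refit adds one random start so
that flat likelihood directions show up as interval width; a parameter is
flagged non-identifiable when its percentile interval reaches both bounds
or spans over two decades — the signature produced by first-stage-only data,
which cannot constrain K.

## Synthetic data

The generator emulates in-situ NMR kinetic monitoring: the model conversion
(ring-intact convention) sampled every 120 s out to 150 min, plus additive
Gaussian noise with σ = 0.01 on the conversion scale (an NMR-integration
magnitude), clipped to [0, 1]. Replicates and panel cells draw independent
streams spawned from one master seed, so every dataset is reproducible from
a single integer. The default nine-condition panel crosses
[M]0 = 0.2/0.3/0.4 M with [M]0/[I]0 = 50/100/150. A single-stage generator
(closed-form exponential conversion) provides the DMF-like control whose
rate is independent of [M]0 at fixed [I]0.

What the generator does *not* emulate: NMR baseline drift or integration
bias (noise is i.i.d. Gaussian, not correlated), monomer aggregation,
moisture side reactions, or solvent-dependent changes in mechanism. Passing
recovery tests therefore demonstrate that the estimation machinery works
when the model is correct and the noise is benign — they do not validate
the model against real chemistry.

## Known limitations

* Fitted kr/K pairs are only moderately identifiable from conversion data
  alone (the SSE profile is shallow along the trade-off direction); the
  recovery experiment bounds them at 25% under the panel's conditions, and
  the bootstrap is the honest reporting tool.
* The dispersity and MWD asymmetry predictions are properties of the ideal
  two-stage scheme; band broadening, column cutoffs and calibration of real
  GPC measurements are out of scope (`gpc_trace` offers only a Gaussian
  log-mass blur).
* Rate constants are assumed strictly chain-length independent above and
  below s; a gradual coil→helix transition would smooth the kinetic switch
  and narrow the predicted MWD.
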