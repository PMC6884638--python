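# ncakin

Kinetic modelling of **helix-catalyzed ring-opening polymerization of
N-carboxyanhydrides (NCAs)** with an explicit monomer-adsorption step.

In low-dielectric solvents such as dichloromethane, a growing polypeptide
chain that has folded into an α-helix binds the NCA monomer reversibly at
its N terminus before ring opening — an enzyme-like (Michaelis–Menten)
mechanism that makes the polymerization strongly accelerate once chains pass
a critical length *s*, and makes both the kinetics and the molecular-weight
distribution (MWD) depend on the initial monomer concentration. `ncakin`
implements this two-stage scheme end to end for people who model or fit NCA
polymerization kinetics:

```
P_i + M  --k1-->  P_{i+1}                                   i < s   (coil)
P_i + M  <--kon/koff-->  C_i  --kr-->  P_{i+1}              i >= s  (helix)
```

with `P_i` a chain carrying `i` monomer units and an active amine end
(`P_0` = free initiator), and `C_i` the helix–monomer complex. The package
provides:

* **model_core / simulate** — the population-balance ODEs on a finite DP
  ladder with exact chain-count and monomer-unit conservation, a stiff BDF
  integrator with an analytic sparse Jacobian, and an *exactly lumped*
  conversion system (all helical chains and complexes pooled) that makes a
  single conversion curve a ~2 ms computation. Conversion observables
  (`ring-intact` counts bound monomer as unreacted, NMR-like;
  `free-monomer` does not), dimensionless time τ = t·k1·[M]0, two-stage
  apparent rate constants, and a Michaelis–Menten quasi-steady-state
  reduction.
* **mwd** — chain-length distributions, DPn/DPw, Mn/Mw, dispersity
  Đ = Mw/Mn, short-chain (DP < s) mass fractions, the Poisson reference of
  ideal living chain growth, design molar mass from [M]0/[I]0, GPC-like
  traces on a log10(M) axis.
* **stochastic** — an exact Gillespie simulation of the same network
  (numba-accelerated, O(1) per event) used as a brute-force oracle for the
  deterministic solver and the MWD shapes.
* **fitting** — global estimation from multiple conversion datasets with
  shared (kr, s) and per-dataset (k1, K = kon/koff) parameters, integer
  grid search over s, sparse-Jacobian joint least squares with kr-ladder
  multistarts, binding free energy ΔG° = −RT ln(K·c°), forward MWD
  predictions, and residual-bootstrap intervals with non-identifiability
  flags.
* **synthetic** — seeded NMR-like conversion datasets (additive noise,
  regular sampling schedules), including the nine-condition panel
  ([M]0 = 0.2/0.3/0.4 M × [M]0/[I]0 = 50/100/150) and single-stage
  (DMF-like) controls.
* **cli** — `ncakin simulate | mwd | generate | fit | recover`.

## Worked example

Simulate the reference parameter set (s = 10, k1 = 0.02 M⁻¹s⁻¹,
kon = 10 M⁻¹s⁻¹, koff = 2 s⁻¹, kr = 0.2 s⁻¹) at [M]0 = 0.4 M,
[M]0/[I]0 = 100 and inspect the terminal polymer:

```bash
$ ncakin simulate --t-end 6000 --out conv.csv
kapp2/kapp1 = 12.8
final conversion 1.0000 -> conv.csv

$ ncakin mwd --ratio 100 --t-end 6000 --out mwd.csv
DPn = 100.00  Mn = 22025 g/mol  D = 1.3269
design MW = 22.0 kDa
short-chain (DP<s) mass fraction = 0.0114
```

Reading the numbers: the second stage is ~13× faster than the coil stage
(`kapp2/kapp1`, from log-linear fits in the 2–15% and 45–85% conversion
windows); the number-average DP equals the feed ratio at full conversion
(Mn ≈ design MW of 22.0 kDa for ratio 100); the dispersity 1.33 is well
above the shifted-Poisson value (~1.01) because chains cross the coil→helix
threshold at different times and then race ahead; ~1% of the polymer mass
remains in chains shorter than the critical length.

A full parameter-recovery round trip (generate the nine-condition synthetic
panel with σ = 0.01 noise, refit it globally, compare with the generating
constants):

```bash
$ ncakin recover --seed 1 --out recover.csv
quantity,value,target,comparison,pass
s_recovered,10,10,exact,True
k1_max_rel_err,0.02809583615719629,0.1,<=,True
K_max_rel_err,0.23000214233900432,0.25,<=,True
kr_rel_err,0.18579650668144002,0.25,<=,True
```

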