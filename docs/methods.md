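# Methods

This note records the mathematical conventions, numerical choices and known
limitations of the package. Everything here is stated in the package's own
terms; the embedded benchmark values live in `cspkinetics/reference.py` with
their per-class comparison tolerances.

## Model

The FcRn–IgG recycling model is a mass-action network in
`y = [C_p^IgG, C_e^IgG, C_e^FcRn, C_e^IgG.FcRn]` (nM, time in hours):

```
dy/dt = S1*R1 + S2*R2 + S3f*R3f + S3b*R3b + S4*R4 = g(y)

S1 = [-a, 1, 0, 0]     R1  = k1 * C_p^IgG
S2 = [ 0,-1, 0, 0]     R2  = kdeg * C_e^IgG
S3f= [ 0,-1,-1, 1]     R3f = kon * C_e^IgG * C_e^FcRn
S3b= [ 0, 1, 1,-1]     R3b = koff * C_e^IgG.FcRn
S4 = [ a, 0, 1,-1]     R4  = k1 * C_e^IgG.FcRn
```

`a = Ve/Vp` rescales fluxes crossing the plasma/endosome boundary;
`k1 = CLup/Ve`. The left null vector `[0, 0, 1, 1]` of the stoichiometric
matrix gives the conservation law `C_e^FcRn + C_e^IgG.FcRn = FcRn0`.
The initial condition is `y(0) = [Dose/Vp, 0, FcRn0, 0]`.

Default parameters (human, wild-type IgG):

| parameter | value | units |
|---|---|---|
| Vp | 3.10 | L |
| Ve | 0.34 | L |
| CLup | 0.167 | L/h |
| kon | 0.559 | 1/(nM·h) |
| koff | 23.9 | 1/h |
| kdeg | 25.0 | 1/h |
| FcRn0 | 4.98e4 | nM |
| Dose | 24.0e4 | nmol |

Derived: `a ≈ 0.1097`, `k1 ≈ 0.4912 1/h`.

## Integration

`scipy.integrate.solve_ivp` with the BDF method, the analytic Jacobian,
`rtol = 1e-10`, `atol = 1e-8 nM`, and dense output. The run is split into two
legs at `t = 1e-3 h`; the first leg is step-bounded at `1e-5 h` so the
binding transient (fastest timescale ~4e-5 h) is resolved rather than stepped
over. The default output grid is logarithmic from `1e-6` to `2e3` h.
Solver undershoots below zero are clamped to zero within a `1e-6 nM` band;
larger negative components are an error. Conservation drift over the default
run is at roundoff (≲1e-14 relative).

## CSP decomposition

The leading-order CSP basis at a state is the Jacobian eigenbasis: right
eigenvectors `a_n` (columns), dual rows `b^n` (rows of the inverse
eigenvector matrix), `b^i · a_j = δ^i_j`. Modes are sorted by descending
`|λ_n|`; eigenvalues with `|λ| < 1e-9 · max|λ|` are treated as zero
(conserved moieties) and placed last with `τ = ∞` and `f = 0`. No iterative
CSP refinement is applied; the large timescale gaps of this model make the
eigenbasis adequate at the reported precision. Mode identity over time is by
sorted-timescale position (no eigenvector-continuity tracking); this model
exhibits no timescale crossings.

Quantities per mode: amplitude `f^n = b^n · g`, coefficients
`c^n_k = b^n · S_k`, timescale `τ_n = 1/|λ_n|`.

**Scaling and sign gauge.** Each `(a_n, b^n)` pair carries a free scalar.
The package rescales `a_n` so its largest-magnitude component equals `+1`
(with `b^n` scaled reciprocally), then flips each mode's sign so that
`c^n_1 = b^n · S_1 > 0`. All normalized indices are invariant under positive
rescaling regardless; the gauge only stabilizes the reported signs and
magnitudes of `c^n_k` along the trajectory (e.g. `c^1_3f ≈ -1` throughout).
An alternative convention — pivoting on the largest entry of `b^n` instead of
`a_n` — was evaluated and rejected: it forces one `c` entry to exactly ±1 and
does not reproduce the embedded benchmark coefficient values.

**Indices** (row-normalized to unit absolute sum):

* `P^r_k = c^r_k R^k / Σ_j |c^r_j R^j|` (amplitude participation),
* `J^n_k = λ^n_k / Σ_j |λ^n_j|`, with `λ^n_k = (b^n·S_k)(∂R^k/∂y·a_n)` and
  `Σ_k λ^n_k = λ_n` (timescale participation),
* `D^n_i = a_n(i) b^n(i)`, with `Σ_n D^n_i = 1` (pointer),
* `I^n_k = w^n_k / Σ_j |w^n_j|`, `w^n_k = [Σ_{m>M} a_m(n) c^m_k] R^k`,
  conserved mode included in the slow sum (importance).

Conserved-mode rows of `P` and `J` are structurally zero (they survive only
as cancellation noise) and are reported as exact zeros. A vanishing
normalization denominator for a genuine mode (an all-zero-rates state) raises
`UndefinedIndexError` rather than producing NaN.

**Exhausted-mode count.** `M` is the largest number of leading modes such
that for every mode `m ≤ M` and variable `i`,
`|a_m(i) f^m| · τ_{M+1} < eps_rel·|y_i| + eps_abs`. Defaults
`eps_rel = 5e-2`, `eps_abs = 1e-3 nM` are calibrated on the default
parameter set so the boundaries fall where the fast amplitudes collapse
(M: 0→1 near 4e-4 h, 1→2 near 4–5 h); both are exposed in the API and CLI.

## Reduced models

Two QSSA reductions and their higher-order corrections:

* one-constraint (`qssa1`): net binding flux balances its sources,
  `R3f - R3b ≈ R1 - R2`; slow variables `(C_p^IgG, C_e^IgG.FcRn)`;
* two-constraint (`qssa2`): additionally `R4 ≈ R1 - R2`; slow variable
  `C_p^IgG` only.

The corrections follow from differentiating each constraint in time and
re-substituting the slow dynamics, giving the state-dependent factors
`r1 = k1·a/(kon·C_F + kdeg)`, `r2 = (kon·C_e + koff)/(kon·C_F + kdeg)`,
`m = kdeg/k1` and `Λ = (1 + m·r2)/(1 + a + r1(1-m) + r2(a+m))`:

```
corrected1:  R3f - R3b ≈ [(1 + r1)R1 - R2 + (r2 - r1)R4] / (1 + r2)
corrected2:  R4 ≈ R1 - Λ·R2
```

Both collapse to the plain QSSA as `r1, r2 → 0`. Integration of a reduced
model advances only the slow variables with BDF; at every evaluation the
algebraic constraint is solved for the fast variable(s) — in closed form for
the plain QSSA variants (linear, and a quadratic with a unique nonnegative
root, respectively), by damped Newton started from the closed form for the
corrected variants — and the conservation law eliminates `C_e^FcRn`, so
conservation is exact by construction.

The CSP constraint `f^n ≈ 0`, solved for a pivot rate (`R3f - R3b` for mode
1, `R4` for mode 2), gives a third, algorithmic approximation of the same
fluxes. The six relative errors `er1_{1,2,3}`, `er2_{1,2,3}` (plain,
corrected, CSP, for each constrained flux) are evaluated on the full-model
trajectory.

## Perturbation experiments

A perturbation multiplies one reaction's rate constant by `γ` from a switch
time onward; the state is continuous across the switch. Responses are
classified on two horizons: the **jump** is each variable's relative change
over `[t_switch, t_switch + 5·τ_1]` (re-adjustment of established fast
equilibria), the **drift** is the deviation sign one slow timescale
(`τ_{M+1}`) after the switch. The max-jump variable is compared with the
top-2 pointed variables of the exhausted modes ("pointer consistency"): the
variable enslaved by a perturbed equilibrium is the one that adjusts the
most. A 1% relative deviation threshold separates "no effect" calls.

## Randomized fixtures

`generate_fixture(seed)` draws each parameter log-uniformly within a factor
of 10 of its default (ranges overridable per parameter). Positivity, the
mass-action structure and the conservation law hold by construction. The
property suite exercises the decomposition identities on such fixtures at
random conservation-respecting states; extreme draws can push a genuine slow
eigenvalue below the relative zero threshold, in which case the structurally
conserved mode is identified by its dual row being parallel to `[0,0,1,1]`.

## Known discrepancies and limitations

* The embedded benchmark's `er1_2` column (corrected one-constraint error)
  is not reproducible from the stated correction formula: recomputed values
  disagree with the benchmark column at all twelve times (while `er1_1`,
  `er2_1` and `er2_2` reproduce within 10%). The corresponding regression
  tests fail by design and are not skipped.
* `er2_3` at t = 5, 10, 20 h differs from the benchmark by almost exactly a
  factor of 10 (consistent with an exponent typo in the benchmark; the same
  metric reproduces at t = 50 and 100 h), and `er1_3` at t = 100, 1000 h and
  `er2_3` at t = 1000 h lie below the round-off floor of the constraint
  residual, where the leading-order basis cannot resolve them.
* Benchmark amplitude cells carry only 2–3 significant figures; comparisons
  add the half-unit-in-last-digit quantum to the 0.5% relative tolerance.
* `f^1` deep in each period is a near-complete cancellation and is checked
  by order of magnitude only.
* The rate row of the late-time benchmark table has a corrupted first entry;
  those cells are regenerated from the benchmark concentrations through the
  rate laws.
* Raising `kdeg` during the one-constraint period produces no immediate
  (fast-window) adjustment — degradation does not enter the established
  equilibrium — but it is not inert over the whole period: direct simulation
  shows the deviation growing through the slow mode as `R2` becomes
  comparable to `R1` late in the period. The qualitative suite asserts the
  jump-based statement.
* Only first- and second-order mass action rate laws are implemented; no
  CSP refinement iterations; no slow-manifold re-integration from CSP
  vectors (the CSP reduced model is evaluated diagnostically).
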