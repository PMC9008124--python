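# cspkinetics

Computational Singular Perturbation (CSP) diagnostics and quasi-steady-state
(QSSA) model reduction for stiff kinetic systems, built around a
pharmacokinetic model of IgG disposition with FcRn-mediated endosomal
salvage.

## The scientific problem

Monoclonal IgG antibodies owe their long plasma half-life to the neonatal Fc
receptor (FcRn): IgG taken into endothelial cells by pinocytosis either binds
FcRn — which recycles it back to plasma — or is degraded in the lysosome. A
minimal mechanistic model of this process is a two-compartment mass-action
network in the state vector

```
y = [C_p^IgG, C_e^IgG, C_e^FcRn, C_e^IgG.FcRn]   (nM)
```

with five unidirectional reactions (uptake, degradation, association,
dissociation, recycling):

```
R1  = k1 * C_p^IgG            plasma IgG -> endosomal IgG
R2  = kdeg * C_e^IgG          endosomal IgG -> (lysosome)
R3f = kon * C_e^IgG * C_e^FcRn    IgG + FcRn -> IgG.FcRn
R3b = koff * C_e^IgG.FcRn         IgG.FcRn -> IgG + FcRn
R4  = k1 * C_e^IgG.FcRn       IgG.FcRn -> FcRn + plasma IgG
```

where `a = Ve/Vp` and `k1 = CLup/Ve`; total FcRn is conserved
(`C_e^FcRn + C_e^IgG.FcRn = FcRn0`). The dynamics span timescales from tens
of microseconds (receptor binding) to hundreds of hours (terminal
elimination), which makes the system stiff and the *origin* of each timescale
non-obvious from the equations alone.

CSP answers that question algorithmically. At each state, the Jacobian
eigendecomposition splits the dynamics into modes with timescales
`tau_n = 1/|lambda_n|`; as fast modes exhaust, the system gets confined to a
slow manifold of decreasing dimension. Four normalized indices then attribute
the dynamics to individual reactions:

* **Amplitude Participation Index** `P^r_k` — which reactions cancel in each
  exhausted-mode equilibrium;
* **Timescale Participation Index** `J^n_k` — which reactions generate each
  timescale (negative = dissipative);
* **Pointer** `D^n_i` — which variables a mode's equilibrium enslaves;
* **Importance Index** `I^n_k` — which reactions drive each variable in the
  slow dynamics.

The package computes all of these along the trajectory, counts the exhausted
modes `M(t)` (the model passes through `M = 0 -> 1 -> 2` periods), constructs
the matching one- and two-constraint QSSA reduced models with their
higher-order corrections, measures the accuracy of each reduction, and runs
rate-constant perturbation experiments that test the CSP predictions about
which variable responds to which parameter.

## Worked example

```python
>>> import numpy as np
>>> from cspkinetics import build_fcrn_model, solve, diagnose_state
>>> model = build_fcrn_model()          # default human IgG parameter set
>>> traj = solve(model)                 # stiff BDF integration, dense output
>>> rec = diagnose_state(model, 1e-2, traj(1e-2))
>>> np.round(rec.y, 2)                  # state at t = 0.01 h (nM)
array([7.737776e+04, 1.700000e+00, 4.942284e+04, 3.771600e+02])
>>> np.round(rec.basis.timescales, 5)   # mode timescales (h)
array([4.0000000e-05, 1.7703200e+00, 4.5809175e+02,           inf])
>>> rec.M                               # one fast mode already exhausted
1
>>> np.round(rec.J[0], 3)               # tau_1 is generated by reaction 3f
array([ 0.   , -0.001, -0.998, -0.001, -0.   ])
>>> np.round(rec.D[0], 3)               # ...and enslaves endosomal free IgG
array([-0.   ,  0.999,  0.   ,  0.001])
```

The same diagnostics are available from the command line:

```bash
cspkinetics --out results diagnose --times 1e-2,1e2
cspkinetics --out results errors                      # reduction accuracy
cspkinetics --out results perturb --reaction 3b --gamma 2 --t-switch 0.5
cspkinetics --out results tables                      # benchmark tables
```

## Layout

* `src/cspkinetics/model.py` — mass-action network, parameters, Jacobian
* `src/cspkinetics/integrate.py` — stiff integration with dense output
* `src/cspkinetics/csp.py` — CSP basis, amplitudes, indices, exhausted modes
* `src/cspkinetics/reduced.py` — QSSA reductions, corrections, error metrics
* `src/cspkinetics/perturb.py` — rate-constant perturbation experiments
* `src/cspkinetics/reference.py` — embedded benchmark values and tolerances
* `src/cspkinetics/report.py`, `cli.py` — table regeneration and CLI
* `docs/methods.md` — numerical methods, conventions and limitations
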