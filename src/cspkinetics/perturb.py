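"""Rate-constant perturbation experiments.

A perturbation multiplies one reaction's rate constant by a factor gamma from
a switch time onward and compares the perturbed trajectory with the reference.
Because the switch changes derivatives, not states, variables respond on two
distinct horizons:

* variables slaved to an established fast equilibrium readjust within a few
  fast timescales of the switch (a visible "jump"), and
* all variables drift apart on the timescale of the slowest active mode.

Classifying each variable's response by jump size and drift direction, and
comparing the max-jump variable with the mode Pointer, operationalizes the
prediction that the pointed variable of a perturbed equilibrium is the one
that adjusts the most.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .csp import diagnose_state
from .integrate import Trajectory, solve
from .model import KineticModel, build_fcrn_model

__all__ = ["PerturbationSpec", "ResponseSummary", "run_perturbed", "classify_response"]

JUMP_WINDOW_FAST_SCALES = 5.0  # "immediate" window, in units of tau_1
NO_EFFECT_THRESHOLD = 0.01  # relative deviation below this counts as no effect


@dataclass(frozen=True)
class PerturbationSpec:
    """Multiply one reaction's rate constant by gamma from t_switch onward."""

    reaction: str  # one of "1", "2", "3f", "3b", "4"
    gamma: float
    t_switch: float  # h

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.t_switch < 0:
            raise ValueError("t_switch must be nonnegative")


@dataclass
class ResponseSummary:
    """Per-variable fast-jump and slow-drift classification of a perturbation."""

    spec: PerturbationSpec
    jump: dict  # species -> |relative change| over the fast window
    drift: dict  # species -> sign of (perturbed - reference) at the slow horizon
    max_jump_variable: str
    pointer_variable: str  # variable pointed by the slowest exhausted mode
    pointer_consistent: bool
    significant: dict = field(default_factory=dict)  # species -> any |dev| > threshold


def _perturbed_model(model: KineticModel, spec: PerturbationSpec) -> KineticModel:
    labels = model.reaction_labels
    if spec.reaction not in labels:
        raise ValueError(f"unknown reaction {spec.reaction!r}; choose from {labels}")
    k = labels.index(spec.reaction)
    reactions = list(model.reactions)
    r = reactions[k]
    reactions[k] = type(r)(r.label, r.stoich, r.k * spec.gamma, r.reactants)
    return KineticModel(model.species, tuple(reactions), model.params,
                        model.y0.copy(), list(model.conserved))


def run_perturbed(model: KineticModel, spec: PerturbationSpec, t_grid,
                  rtol: float = 1e-10, atol: float = 1e-8) -> tuple:
    """Reference and perturbed trajectories on a common grid.

    The perturbed run follows the reference parameters up to t_switch, then
    continues from that state with the modified rate constant; the state is
    continuous across the switch.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if not (t_grid[0] <= spec.t_switch < t_grid[-1]):
        raise ValueError("t_switch must lie within the grid span")
    reference = solve(model, t_grid, rtol=rtol, atol=atol)
    if spec.gamma == 1.0:
        return reference, reference

    y_switch = reference(spec.t_switch)
    pert_model = _perturbed_model(model, spec)
    tail_grid = np.unique(np.concatenate([[spec.t_switch],
                                          t_grid[t_grid > spec.t_switch]]))
    tail = _solve_from(pert_model, y_switch, tail_grid, rtol, atol)

    states = reference.states.copy()
    mask = t_grid > spec.t_switch
    states[mask] = np.array([tail(t) for t in t_grid[mask]])
    perturbed = Trajectory(t_grid, states, pert_model, dict(reference.solver_meta),
                           [_ShiftedTail(reference, tail, spec.t_switch)])
    return reference, perturbed


class _ShiftedTail:
    """Dense output that follows the reference before t_switch, the tail after."""

    def __init__(self, reference: Trajectory, tail: Trajectory, t_switch: float):
        self._ref = reference
        self._tail = tail
        self._switch = t_switch
        self.t_min = reference.span[0]
        self.t_max = tail.span[1]

    def __call__(self, t):
        return self._ref(t) if t <= self._switch else self._tail(t)


def _solve_from(model, y0, t_grid, rtol, atol):
    """Integrate from an arbitrary state over an absolute-time grid."""
    from scipy.integrate import solve_ivp

    res = solve_ivp(lambda t, y: model.rhs(y), (t_grid[0], t_grid[-1]), y0,
                    method="BDF", jac=lambda t, y: model.jacobian(y),
                    rtol=rtol, atol=atol, dense_output=True,
                    max_step=min(1.0, (t_grid[-1] - t_grid[0]) / 10))
    if not res.success:
        raise RuntimeError(f"perturbed integration failed: {res.message}")
    states = np.array([res.sol(min(t, res.sol.t_max)) for t in t_grid])
    return Trajectory(t_grid, np.maximum(states, 0.0), model,
                      {"rtol": rtol, "atol": atol}, [res.sol])


def classify_response(reference: Trajectory, perturbed: Trajectory,
                      spec: PerturbationSpec,
                      jump_window_scales: float = JUMP_WINDOW_FAST_SCALES) -> ResponseSummary:
    """Classify fast-jump vs slow-drift responses of each variable.

    The jump is the relative change of the perturbed trajectory between
    t_switch and t_switch + 5*tau_1; the drift is the sign of
    (perturbed - reference) one slow timescale after the switch.
    """
    model = reference.model
    t0 = spec.t_switch
    y0 = reference(t0)
    rec = diagnose_state(model, t0, y0)
    tau1 = rec.basis.timescales[0]
    M = rec.M
    tau_slow = rec.basis.timescales[min(M, rec.basis.n_finite - 1)]

    t_jump = t0 + jump_window_scales * tau1
    t_drift = t0 + tau_slow
    if t_drift > reference.span[1]:
        raise ValueError("t_switch too close to the end of the trajectory span "
                         "to observe the slow response")

    y_jump = perturbed(t_jump)
    jump = {}
    for i, name in enumerate(model.species):
        scale = abs(y0[i]) if y0[i] != 0 else 1.0
        jump[name] = abs(y_jump[i] - y0[i]) / scale

    y_ref_d, y_pert_d = reference(t_drift), perturbed(t_drift)
    drift = {name: int(np.sign(y_pert_d[i] - y_ref_d[i]))
             for i, name in enumerate(model.species)}

    # largest deviation over the slow horizon, for "no effect" calls
    t_probe = np.linspace(t0, min(t_drift, reference.span[1]), 50)
    devs = {name: 0.0 for name in model.species}
    for t in t_probe:
        yr, yp = reference(t), perturbed(t)
        for i, name in enumerate(model.species):
            scale = abs(yr[i]) if yr[i] != 0 else 1.0
            devs[name] = max(devs[name], abs(yp[i] - yr[i]) / scale)
    significant = {name: bool(devs[name] > NO_EFFECT_THRESHOLD)
                   for name in model.species}

    max_jump_variable = max(jump, key=jump.get)
    # pointer of the slowest exhausted mode (mode M); if none exhausted, mode 1
    mode = max(M - 1, 0)
    pointer_variable = model.species[int(np.argmax(np.abs(rec.D[mode])))]
    # the fast-scale jump may express any of the established equilibria, so
    # consistency is judged against the union of their top-2 pointed variables
    pointed = set()
    for m_idx in range(mode + 1):
        for i in np.argsort(np.abs(rec.D[m_idx]))[::-1][:2]:
            pointed.add(model.species[int(i)])
    return ResponseSummary(spec, jump, drift, max_jump_variable,
                           pointer_variable, max_jump_variable in pointed,
                           significant)


def doubling_experiments(params=None) -> list:
    """The bundled perturbation set: koff x2, kdeg x2.5, reaction 1 and 3f x2."""
    model = build_fcrn_model(params)
    return [
        (model, PerturbationSpec("3b", 2.0, 0.5)),   # koff doubled in the one-constraint period
        (model, PerturbationSpec("2", 2.5, 0.5)),    # kdeg raised in the one-constraint period
        (model, PerturbationSpec("2", 2.5, 10.0)),   # kdeg raised in the two-constraint period
        (model, PerturbationSpec("1", 2.0, 0.1)),    # uptake doubled early
        (model, PerturbationSpec("3f", 2.0, 5.0)),   # binding doubled late
    ]
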