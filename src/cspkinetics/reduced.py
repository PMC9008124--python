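"""QSSA reduced models, higher-order corrections, and CSP constraint errors.

Two quasi-steady-state reductions of the FcRn-IgG model are implemented:

* one-constraint ("qssa1"): endosomal free IgG is fast, so the net binding
  flux balances its sources, R3f - R3b ~ R1 - R2;
* two-constraint ("qssa2"): the IgG.FcRn complex is fast as well, so the
  recycling flux balances too, R4 ~ R1 - R2.

Each has a higher-order correction obtained by differentiating the constraint
in time and re-substituting the slow dynamics, which introduces the
dimensionless factors

    r1 = k1*a / (kon*C_FcRn + kdeg)
    r2 = (kon*C_IgG_e + koff) / (kon*C_FcRn + kdeg)
    m  = kdeg / k1
    Lambda = (1 + m*r2) / (1 + a + r1*(1 - m) + r2*(a + m))

giving the corrected constraints

    R3f - R3b ~ [(1 + r1)R1 - R2 + (r2 - r1)R4] / (1 + r2)       ("corrected1")
    R4        ~ R1 - Lambda*R2                                    ("corrected2")

Both corrections collapse to the plain QSSA forms as r1, r2 -> 0.  The CSP
constraint f^n ~ 0, solved for the pivot rate, provides a third, algorithmic
approximation of the same quantities.  Relative errors of all three are the
standard accuracy diagnostics for the reductions.

The reduced systems can also be integrated: the algebraic constraint is solved
for the fast variable(s) at every evaluation (damped Newton), the FcRn
conservation law eliminates one variable, and the remaining slow variables are
advanced by the stated reduced right-hand sides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .csp import diagnose_state
from .integrate import Trajectory
from .model import KineticModel

__all__ = [
    "CorrectionFactors",
    "ReductionErrors",
    "correction_factors",
    "qssa1_approx",
    "corrected1_approx",
    "qssa2_approx",
    "corrected2_approx",
    "csp_constraint_approx",
    "reduction_errors_at",
    "reduction_error_table",
    "simulate_reduced",
]

REDUCED_VARIANTS = ("qssa1", "corrected1", "qssa2", "corrected2")

# First times at which the one- and two-constraint reductions are taken to be
# active for the default parameter set (after the respective fast transients).
QSSA1_START = 1e-3  # h
QSSA2_START = 4.0  # h

NEWTON_RTOL = 1e-10
NEWTON_MAXITER = 50


@dataclass(frozen=True)
class CorrectionFactors:
    """State-dependent dimensionless factors of the corrected constraints."""

    r1: float
    r2: float
    m: float
    Lambda: float


@dataclass(frozen=True)
class ReductionErrors:
    """Relative errors of the three approximations of each constrained flux.

    ``er1_*`` approximate the net binding flux R3f - R3b, ``er2_*`` the
    recycling flux R4; suffix 1 = plain QSSA, 2 = higher-order correction,
    3 = CSP constraint.  ``period`` is the exhausted-mode count at t.
    """

    t: float
    er1_1: float
    er1_2: float
    er1_3: float
    er2_1: float
    er2_2: float
    er2_3: float
    period: int


def correction_factors(model: KineticModel, y) -> CorrectionFactors:
    p = model.params
    y = np.asarray(y, dtype=float)
    denom = p.kon * y[2] + p.kdeg
    r1 = p.k1 * p.a / denom
    r2 = (p.kon * y[1] + p.koff) / denom
    m = p.kdeg / p.k1
    Lam = (1.0 + m * r2) / (1.0 + p.a + r1 * (1.0 - m) + r2 * (p.a + m))
    return CorrectionFactors(r1, r2, m, Lam)


def qssa1_approx(model: KineticModel, y) -> float:
    """QSSA estimate of the net binding flux: R1 - R2."""
    R = model.reaction_rates(y)
    return float(R[0] - R[1])


def corrected1_approx(model: KineticModel, y) -> float:
    """Higher-order estimate of the net binding flux."""
    R = model.reaction_rates(y)
    cf = correction_factors(model, y)
    return float(((1.0 + cf.r1) * R[0] - R[1] + (cf.r2 - cf.r1) * R[4]) / (1.0 + cf.r2))


def qssa2_approx(model: KineticModel, y) -> float:
    """QSSA estimate of the recycling flux: R1 - R2."""
    R = model.reaction_rates(y)
    return float(R[0] - R[1])


def corrected2_approx(model: KineticModel, y) -> float:
    """Higher-order estimate of the recycling flux: R1 - Lambda*R2."""
    R = model.reaction_rates(y)
    cf = correction_factors(model, y)
    return float(R[0] - cf.Lambda * R[1])


def csp_constraint_approx(c: np.ndarray, rates: np.ndarray, mode: int) -> float:
    """Solve the CSP constraint f^mode ~ 0 for its pivot rate.

    mode 1 pivots on the net binding flux (coefficient c^1_3f, with
    c^1_3b = -c^1_3f), mode 2 on the recycling flux (coefficient c^2_4).
    Being a ratio of c-coefficients, the result is invariant to the basis
    scaling.
    """
    c = np.asarray(c, dtype=float)
    R = np.asarray(rates, dtype=float)
    if mode == 1:
        row = c[0]
        pivot = row[2]  # c^1_3f; c^1_3b = -c^1_3f for mass-action pairs
        if pivot == 0.0:
            raise ZeroDivisionError("zero pivot coefficient c^1_3f")
        return float(-(row[0] * R[0] + row[1] * R[1] + row[4] * R[4]) / pivot)
    if mode == 2:
        row = c[1]
        pivot = row[4]  # c^2_4
        if pivot == 0.0:
            raise ZeroDivisionError("zero pivot coefficient c^2_4")
        return float(-(row[0] * R[0] + row[1] * R[1] + row[2] * R[2] + row[3] * R[3]) / pivot)
    raise ValueError("mode must be 1 or 2")


def reduction_errors_at(model: KineticModel, t: float, y) -> ReductionErrors:
    """All six relative approximation errors at one state."""
    rec = diagnose_state(model, t, y)
    R = rec.rates
    net3 = R[2] - R[3]
    r4 = R[4]

    def rel(target, approx):
        return (target - approx) / target if target != 0 else np.nan

    return ReductionErrors(
        t=float(t),
        er1_1=rel(net3, qssa1_approx(model, y)),
        er1_2=rel(net3, corrected1_approx(model, y)),
        er1_3=rel(net3, csp_constraint_approx(rec.amp.c, R, 1)),
        er2_1=rel(r4, qssa2_approx(model, y)),
        er2_2=rel(r4, corrected2_approx(model, y)),
        er2_3=rel(r4, csp_constraint_approx(rec.amp.c, R, 2)),
        period=rec.M,
    )


def reduction_error_table(model: KineticModel, traj: Trajectory, times) -> pd.DataFrame:
    """Errors of all approximations at the requested times, as a DataFrame."""
    rows = [reduction_errors_at(model, t, traj(t)) for t in np.atleast_1d(times)]
    return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# Reduced-model integration
# ---------------------------------------------------------------------------


def _newton(func, x0, args=(), rtol=NEWTON_RTOL):
    """Damped Newton with numerical derivative on a scalar or vector residual."""
    x = np.atleast_1d(np.asarray(x0, dtype=float))
    for _ in range(NEWTON_MAXITER):
        f = np.atleast_1d(func(x, *args))
        n = x.size
        Jm = np.empty((n, n))
        for j in range(n):
            h = 1e-7 * max(abs(x[j]), 1.0)
            xp = x.copy()
            xp[j] += h
            Jm[:, j] = (np.atleast_1d(func(xp, *args)) - f) / h
        try:
            step = np.linalg.solve(Jm, -f)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("constraint root-finding failure: singular Jacobian") from exc
        lam = 1.0
        norm0 = np.linalg.norm(f)
        for _damp in range(30):
            xn = x + lam * step
            if np.linalg.norm(np.atleast_1d(func(xn, *args))) <= norm0 or norm0 == 0.0:
                break
            lam *= 0.5
        x = xn
        if np.linalg.norm(lam * step) <= rtol * (np.linalg.norm(x) + 1e-300):
            return x
    raise RuntimeError("constraint root-finding failure: Newton did not converge")


def _rates_unchecked(model: KineticModel, y) -> np.ndarray:
    """Mass-action rates without the nonnegativity guard (Newton iterates only)."""
    return np.array([r.rate(np.asarray(y, dtype=float)) for r in model.reactions])


def _solve_fast_one(model: KineticModel, Cp: float, CC: float, variant: str) -> float:
    """Fast endosomal free IgG from the one-constraint relation."""
    p = model.params
    CF = p.FcRn0 - CC
    Ce0 = (p.k1 * Cp + p.koff * CC) / (p.kon * CF + p.kdeg)  # plain-QSSA solution
    if variant == "qssa1":
        return Ce0

    def resid(x):
        y = np.array([Cp, x[0], CF, CC])
        R = _rates_unchecked(model, y)
        cf = correction_factors(model, y)
        return np.array([R[2] - R[3]
                         - ((1.0 + cf.r1) * R[0] - R[1] + (cf.r2 - cf.r1) * R[4])
                         / (1.0 + cf.r2)])

    return float(_newton(resid, [Ce0])[0])


def _qssa2_closed_form(model: KineticModel, Cp: float) -> tuple:
    """Exact (C_IgG_e, C_IgG.FcRn_e) for the plain two-constraint reduction.

    Eliminating the complex through the recycling balance, CC = Cp - m*Ce,
    turns the binding balance into a quadratic in Ce with a unique
    nonnegative root.
    """
    p = model.params
    m = p.kdeg / p.k1
    A = p.kon * m
    B = p.kon * (p.FcRn0 - Cp) + p.koff * m + p.kdeg
    C = -(p.koff + p.k1) * Cp
    Ce = (-B + np.sqrt(B * B - 4.0 * A * C)) / (2.0 * A)
    return float(Ce), float(Cp - m * Ce)


def _solve_fast_two(model: KineticModel, Cp: float, variant: str) -> tuple:
    """Fast (C_IgG_e, C_IgG.FcRn_e) from the two constraints plus conservation."""
    p = model.params
    guess = _qssa2_closed_form(model, Cp)
    if variant == "qssa2":
        return guess

    def resid(x):
        Ce, CC = x
        y = np.array([Cp, Ce, p.FcRn0 - CC, CC])
        R = _rates_unchecked(model, y)
        cf = correction_factors(model, y)
        g1 = (R[2] - R[3]
              - ((1.0 + cf.r1) * R[0] - R[1] + (cf.r2 - cf.r1) * R[4]) / (1.0 + cf.r2))
        g2 = R[4] - (R[0] - cf.Lambda * R[1])
        return np.array([g1, g2])

    out = _newton(resid, guess)
    return float(out[0]), float(out[1])


def simulate_reduced(model: KineticModel, which: str, t_grid,
                     full_traj: Trajectory | None = None,
                     rtol: float = 1e-10, atol: float = 1e-8) -> Trajectory:
    """Integrate a reduced model over t_grid.

    The reduction is initialized on its constraint at the first grid time
    (states from ``full_traj`` if given, else a fresh full-model solve),
    because the QSSA is invalid during the initial transient; t_grid must
    therefore start inside the validity period of the chosen variant.
    """
    if which not in REDUCED_VARIANTS:
        raise ValueError(f"unknown reduced variant {which!r}; pick from {REDUCED_VARIANTS}")
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")

    if full_traj is None:
        from .integrate import solve as solve_full
        full_traj = solve_full(model, np.array([0.0, t_grid[0] * 1.0001, t_grid[-1]]))
    y_init = full_traj(t_grid[0])
    p = model.params
    one_constraint = which in ("qssa1", "corrected1")

    if one_constraint:
        # slow states: (Cp, CC); CF by conservation, Ce by constraint
        def unpack(z):
            Cp, CC = z
            Ce = _solve_fast_one(model, Cp, CC, which)
            return np.array([Cp, Ce, p.FcRn0 - CC, CC])

        def rhs(t, z):
            y = unpack(z)
            R = model.reaction_rates(y)
            if which == "qssa1":
                dCp = -p.a * (R[0] - R[4])
                dCC = R[0] - R[1] - R[4]
            else:
                cf = correction_factors(model, y)
                dCp = -p.a * (R[0] - R[4])
                dCC = ((1.0 + cf.r1) * (R[0] - R[4]) - R[1]) / (1.0 + cf.r2)
            return [dCp, dCC]

        z0 = [float(y_init[0]), float(y_init[3])]
    else:
        # slow state: Cp only; Ce, CC by the two constraints, CF by conservation
        def unpack(z):
            Cp = z[0]
            Ce, CC = _solve_fast_two(model, Cp, which)
            return np.array([Cp, Ce, p.FcRn0 - CC, CC])

        def rhs(t, z):
            y = unpack(z)
            R = model.reaction_rates(y)
            if which == "qssa2":
                return [-p.a * R[1]]
            cf = correction_factors(model, y)
            return [-p.a * cf.Lambda * R[1]]

        z0 = [float(y_init[0])]

    res = solve_ivp(rhs, (t_grid[0], t_grid[-1]), z0, method="BDF",
                    rtol=rtol, atol=atol, dense_output=True)
    if not res.success:
        raise RuntimeError(f"reduced-model integration failed: {res.message}")

    states = np.empty((t_grid.size, model.n_species))
    for i, t in enumerate(t_grid):
        states[i] = unpack(res.sol(min(t, res.sol.t_max)))
    meta = {"variant": which, "rtol": rtol, "atol": atol, "nfev": res.nfev}

    class _FullStateSol:
        """Dense output lifted from the slow state to the full state."""
        t_min = res.sol.t_min
        t_max = res.sol.t_max

        def __call__(self, t):
            return unpack(res.sol(t))

    return Trajectory(t_grid, states, model, meta, [_FullStateSol()])
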