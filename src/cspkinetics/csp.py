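"""Computational Singular Perturbation (CSP) decomposition and diagnostics.

At a state y of a kinetic model dy/dt = g(y) = sum_k S_k R^k, the leading-order
CSP basis is the eigenbasis of the Jacobian J = dg/dy: right eigenvectors a_n
(column vectors), dual left vectors b^n (rows of the inverse eigenvector
matrix), with b^i . a_j = delta^i_j.  Each mode a_n f^n has amplitude
f^n = b^n . g and timescale tau_n = 1/|lambda_n|.  Modes are ordered fastest
first; a conserved moiety produces a zero eigenvalue, whose mode is placed
last with tau = infinity and f = 0.

Diagnostics (all normalized to unit absolute row/column sums):

* Amplitude Participation Index  P^r_k = c^r_k R^k / sum_j |c^r_j R^j|,
  with c^n_k = b^n . S_k: which reactions cancel in the constraint f^r ~ 0.
* Timescale Participation Index  J^n_k = lambda^n_k / sum_j |lambda^n_j|,
  with lambda^n_k = b^n . S_k (dR^k/dy . a_n): which reactions generate
  tau_n (negative = dissipative).
* Pointer  D^n_i = a_n(i) b^n(i): which variables a mode's equilibrium slaves.
* Importance Index  I^n_k = w^n_k / sum_j |w^n_j|, with
  w^n_k = [sum_{m>M} a_m(n) c^m_k] R^k: which reactions drive variable n in
  the slow subspace once M modes are exhausted.

The exhausted-mode count M is the largest number of leading modes whose
contribution to every variable over the next-active timescale is below a
mixed relative/absolute threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import KineticModel

__all__ = [
    "CSPBasis",
    "ModeAmplitudes",
    "DiagnosticsRecord",
    "csp_basis",
    "amplitudes",
    "amplitude_participation",
    "timescale_participation",
    "pointers",
    "exhausted_modes",
    "importance_index",
    "diagnose_state",
    "diagnose_trajectory",
]

ZERO_EIG_RTOL = 1e-9  # |lambda| below this times max|lambda| counts as conserved
# Exhaustion thresholds.  eps_rel is calibrated on the default parameter set so
# that the exhausted-mode count steps 0 -> 1 near 3e-4 h and 1 -> 2 near 3 h,
# the times at which the fast amplitudes collapse; eps_abs guards variables
# near zero.
EPS_REL_DEFAULT = 5e-2
EPS_ABS_DEFAULT = 1e-3  # nM
DUALITY_TOL = 1e-10


class UndefinedIndexError(ZeroDivisionError):
    """A normalized index is undefined (all contributions vanish)."""


@dataclass
class CSPBasis:
    """Eigen-based CSP basis at one state.

    ``a`` has modes as columns, ``b`` as rows, both ordered fastest first with
    any conserved (zero-eigenvalue) modes last.  ``timescales`` holds
    tau_n = 1/|lambda_n| (np.inf for conserved modes).
    """

    a: np.ndarray
    b: np.ndarray
    eigvals: np.ndarray
    timescales: np.ndarray
    conserved_mode_index: int | None

    @property
    def n_modes(self) -> int:
        return self.a.shape[1]

    @property
    def n_finite(self) -> int:
        """Number of modes with finite timescale."""
        return int(np.sum(np.isfinite(self.timescales)))


@dataclass
class ModeAmplitudes:
    """Mode amplitudes f^n = b^n.g and coefficients c^n_k = b^n.S_k."""

    f: np.ndarray  # (N,) nM/h
    c: np.ndarray  # (N, K)


@dataclass
class DiagnosticsRecord:
    """Full CSP diagnostics at one time point."""

    t: float
    y: np.ndarray
    g: np.ndarray
    rates: np.ndarray
    basis: CSPBasis
    amp: ModeAmplitudes
    P: np.ndarray  # (N, K) amplitude participation
    J: np.ndarray  # (N, K) timescale participation
    D: np.ndarray  # (N, N) pointers, D[n, i]
    I: np.ndarray  # (N, K) importance (slow subspace, given M)
    M: int


def csp_basis(J: np.ndarray, zero_tol: float = ZERO_EIG_RTOL,
              orient: np.ndarray | None = None) -> CSPBasis:
    """Leading-order CSP basis from the Jacobian eigen-decomposition.

    Modes are sorted by descending |lambda| among dissipative (finite) modes;
    eigenvalues with |lambda| < zero_tol * max|lambda| are treated as exactly
    zero (conserved moieties) and placed last.  Each column a_n is rescaled so
    its largest-magnitude component equals unity, with b^n scaled reciprocally,
    which fixes the scale of the reported c^n_k without affecting any
    normalized index.

    The remaining sign freedom of each (a_n, b^n) pair is a gauge.  If
    ``orient`` (an N-vector s) is given, each mode with b^n.s != 0 is flipped
    so that b^n.s > 0; passing the stoichiometric vector of a reference
    reaction keeps the reported c/P/J signs stable along a trajectory.
    """
    J = np.asarray(J, dtype=float)
    lam, V = np.linalg.eig(J)
    if np.any(np.abs(lam.imag) > 1e-9 * (np.max(np.abs(lam)) + 1e-300)):
        pairs = lam[np.abs(lam.imag) > 0]
        raise ValueError(f"complex eigenvalue pair encountered: {pairs}")
    lam = lam.real
    V = V.real

    cond = np.linalg.cond(V)
    if not np.isfinite(cond) or cond > 1e14:
        raise ValueError("defective (non-diagonalizable) Jacobian")

    scale = np.max(np.abs(lam))
    is_zero = np.abs(lam) < zero_tol * scale if scale > 0 else np.ones_like(lam, bool)
    # fastest first among finite modes, conserved modes last
    order = sorted(range(len(lam)),
                   key=lambda i: (1 if is_zero[i] else 0,
                                  -abs(lam[i])))
    lam = lam[order]
    V = V[:, order]
    is_zero = is_zero[order]

    # scaling convention: max-|entry| of each a_n set to +1
    for n in range(V.shape[1]):
        pivot = V[np.argmax(np.abs(V[:, n])), n]
        V[:, n] /= pivot
    B = np.linalg.inv(V)

    if orient is not None:
        s = np.asarray(orient, dtype=float)
        proj = B @ s
        for n in range(V.shape[1]):
            if proj[n] < 0:
                V[:, n] *= -1.0
                B[n, :] *= -1.0

    timescales = np.where(is_zero, np.inf, 1.0 / np.maximum(np.abs(lam), 1e-300))
    lam = np.where(is_zero, 0.0, lam)
    conserved_idx = int(np.argmax(is_zero)) if np.any(is_zero) else None
    return CSPBasis(V, B, lam, timescales, conserved_idx)


def amplitudes(basis: CSPBasis, model: KineticModel, y) -> ModeAmplitudes:
    """Amplitudes f^n = b^n.g and stoichiometric coefficients c^n_k."""
    g = model.rhs(y)
    S = model.stoichiometric_matrix()
    c = basis.b @ S
    f = basis.b @ g
    return ModeAmplitudes(f, c)


def _normalize_rows(raw: np.ndarray, zero_ok: np.ndarray | None = None) -> np.ndarray:
    """Normalize each row to unit absolute sum.

    Rows flagged in ``zero_ok`` (conserved modes, whose contributions vanish
    structurally and survive only as cancellation noise) come back as exact
    zero rows; a vanishing denominator anywhere else means the index is
    undefined at this state (e.g. an equilibrium point with all rates zero)
    and raises, rather than returning NaN.
    """
    raw = raw.copy()
    if zero_ok is not None:
        raw[zero_ok] = 0.0
    denom = np.sum(np.abs(raw), axis=1, keepdims=True)
    bad = denom[:, 0] == 0.0
    if zero_ok is not None:
        bad &= ~zero_ok
    if np.any(bad):
        raise UndefinedIndexError("all contributions vanish for at least one row")
    safe = np.where(denom == 0.0, 1.0, denom)
    return raw / safe


def _conserved_rows(basis: CSPBasis) -> np.ndarray:
    return ~np.isfinite(basis.timescales)


def amplitude_participation(amp: ModeAmplitudes, rates: np.ndarray,
                            basis: CSPBasis | None = None) -> np.ndarray:
    """P^r_k: normalized reaction contributions to each amplitude f^r."""
    zero_ok = _conserved_rows(basis) if basis is not None else None
    return _normalize_rows(amp.c * rates[np.newaxis, :], zero_ok)


def timescale_participation(basis: CSPBasis, model: KineticModel, y) -> np.ndarray:
    """J^n_k: normalized reaction contributions to each eigenvalue lambda_n."""
    S = model.stoichiometric_matrix()           # (N, K)
    G = model.rate_gradients(y)                 # (K, N)
    # lambda^n_k = (b^n . S_k) * (dR^k/dy . a_n)
    raw = (basis.b @ S) * (G @ basis.a).T
    return _normalize_rows(raw, _conserved_rows(basis))


def eigenvalue_contributions(basis: CSPBasis, model: KineticModel, y) -> np.ndarray:
    """Unnormalized lambda^n_k; rows sum to the eigenvalues."""
    S = model.stoichiometric_matrix()
    G = model.rate_gradients(y)
    return (basis.b @ S) * (G @ basis.a).T


def pointers(basis: CSPBasis) -> np.ndarray:
    """D[n, i] = a_n(i) b^n(i), the diagonal of each mode projector."""
    return basis.a.T * basis.b


def exhausted_modes(basis: CSPBasis, amp: ModeAmplitudes, y,
                    eps_rel: float = EPS_REL_DEFAULT,
                    eps_abs: float = EPS_ABS_DEFAULT) -> int:
    """Count the exhausted fast modes M.

    M is the largest count such that for every mode m <= M and every variable
    i, the contribution |a_m(i) f^m| accumulated over the next active
    timescale tau_{M+1} stays below eps_rel*|y_i| + eps_abs.  Conserved modes
    are never counted.
    """
    y = np.asarray(y, dtype=float)
    n_finite = basis.n_finite
    M = 0
    for candidate in range(1, n_finite):  # at least one mode must stay active
        tau_next = basis.timescales[candidate]
        ok = True
        for m in range(candidate):
            contrib = np.abs(basis.a[:, m] * amp.f[m]) * tau_next
            if np.any(contrib >= eps_rel * np.abs(y) + eps_abs):
                ok = False
                break
        if ok:
            M = candidate
        else:
            break
    return M


def importance_index(basis: CSPBasis, amp: ModeAmplitudes, rates: np.ndarray,
                     M: int) -> np.ndarray:
    """I^n_k: normalized slow-subspace contribution of reaction k to variable n."""
    # slow projector coefficients: sum over modes m > M (conserved included)
    slow = basis.a[:, M:] @ amp.c[M:, :]        # (N, K)
    return _normalize_rows(slow * rates[np.newaxis, :])


def diagnose_state(model: KineticModel, t: float, y,
                   eps_rel: float = EPS_REL_DEFAULT,
                   eps_abs: float = EPS_ABS_DEFAULT) -> DiagnosticsRecord:
    """Compute the full diagnostics record at one state."""
    y = np.asarray(y, dtype=float)
    S = model.stoichiometric_matrix()
    basis = csp_basis(model.jacobian(y), orient=S[:, 0])
    amp = amplitudes(basis, model, y)
    rates = model.reaction_rates(y)
    P = amplitude_participation(amp, rates, basis)
    Jmat = timescale_participation(basis, model, y)
    D = pointers(basis)
    M = exhausted_modes(basis, amp, y, eps_rel=eps_rel, eps_abs=eps_abs)
    I = importance_index(basis, amp, rates, M)
    return DiagnosticsRecord(float(t), y, model.rhs(y), rates, basis, amp,
                             P, Jmat, D, I, M)


def diagnose_trajectory(model: KineticModel, traj, times,
                        eps_rel: float = EPS_REL_DEFAULT,
                        eps_abs: float = EPS_ABS_DEFAULT) -> list:
    """Diagnostics records along a trajectory at the requested times.

    Mode identity across times follows the sorted-timescale position (no
    eigenvector continuity tracking; the model exhibits no reported
    timescale crossings).
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    records = []
    for t in times:
        y = traj(t)
        records.append(diagnose_state(model, t, y, eps_rel=eps_rel, eps_abs=eps_abs))
    return records
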