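import numpy as np
import pytest

from cspkinetics import (
    amplitude_participation,
    amplitudes,
    csp_basis,
    diagnose_state,
    diagnose_trajectory,
    exhausted_modes,
    importance_index,
    pointers,
    timescale_participation,
)
from cspkinetics.csp import UndefinedIndexError

TIMES = (1e-3, 1e-2, 1.0, 1e2, 1e3)


@pytest.fixture(scope="module")
def records(model, traj):
    return diagnose_trajectory(model, traj, TIMES)


def test_duality(records):
    for rec in records:
        np.testing.assert_allclose(rec.basis.b @ rec.basis.a, np.eye(4),
                                   atol=1e-10)


def test_reconstruction(records):
    for rec in records:
        g_rec = rec.basis.a @ rec.amp.f
        np.testing.assert_allclose(g_rec, rec.g,
                                   rtol=1e-8, atol=1e-8 * np.abs(rec.g).max())


def test_normalization_identities(records):
    for rec in records:
        nf = rec.basis.n_finite
        np.testing.assert_allclose(np.sum(np.abs(rec.P[:nf]), axis=1), 1.0,
                                   atol=1e-12)
        np.testing.assert_allclose(np.sum(np.abs(rec.J[:nf]), axis=1), 1.0,
                                   atol=1e-12)
        np.testing.assert_allclose(np.sum(np.abs(rec.I), axis=1), 1.0,
                                   atol=1e-12)
        np.testing.assert_allclose(np.sum(rec.D, axis=0), 1.0, atol=1e-9)


def test_eigen_rows_sum_to_eigenvalues(model, records):
    from cspkinetics.csp import eigenvalue_contributions

    for rec in records:
        contrib = eigenvalue_contributions(rec.basis, model, rec.y)
        np.testing.assert_allclose(np.sum(contrib, axis=1), rec.basis.eigvals,
                                   rtol=1e-8, atol=1e-6)


def test_conserved_mode(records):
    for rec in records:
        assert rec.basis.conserved_mode_index == 3
        assert rec.basis.timescales[3] == np.inf
        assert abs(rec.amp.f[3]) < 1e-6 * np.abs(rec.amp.f[:3]).max()


def test_timescales_sorted_and_gapped(records):
    for rec in records:
        tau = rec.basis.timescales[:3]
        assert np.all(np.diff(tau) > 0)
        # fast binding mode stays well separated from the second mode
        assert tau[0] / tau[1] < 1e-2


def test_index_invariance_under_rescaling(model, records):
    rng = np.random.default_rng(42)
    for rec in records:
        basis = rec.basis
        mag = rng.uniform(0.1, 10.0, size=4)
        sign = rng.choice([-1.0, 1.0], size=4)
        scale = mag * sign
        rescaled = type(basis)(basis.a * scale[np.newaxis, :],
                               basis.b / scale[:, np.newaxis],
                               basis.eigvals, basis.timescales,
                               basis.conserved_mode_index)
        amp = amplitudes(rescaled, model, rec.y)
        # P rows are linear in b^n: invariant in magnitude under any
        # rescaling, and covariant with the sign of the scale
        np.testing.assert_allclose(
            amplitude_participation(amp, rec.rates, rescaled),
            rec.P * sign[:, np.newaxis], atol=1e-10)
        # J, D and I involve matched a.b products: fully invariant
        np.testing.assert_allclose(
            timescale_participation(rescaled, model, rec.y), rec.J, atol=1e-10)
        np.testing.assert_allclose(pointers(rescaled), rec.D, atol=1e-10)
        np.testing.assert_allclose(
            importance_index(rescaled, amp, rec.rates, rec.M), rec.I, atol=1e-10)


def test_exhausted_modes_monotone_in_eps(model, traj):
    y = traj(1e-2)
    from cspkinetics import csp_basis as _b  # noqa: F401

    rec = diagnose_state(model, 1e-2, y)
    strict = exhausted_modes(rec.basis, rec.amp, y, eps_rel=1e-12, eps_abs=1e-12)
    loose = exhausted_modes(rec.basis, rec.amp, y, eps_rel=1e3, eps_abs=1e3)
    assert strict <= rec.M <= loose
    assert loose <= rec.basis.n_finite - 1  # one mode always stays active


def test_undefined_index_at_zero_rate_state(model):
    rec_like_y = np.zeros(4)
    basis = csp_basis(model.jacobian(np.array([1.0, 1.0, 1.0, 1.0])))
    amp = amplitudes(basis, model, np.array([1.0, 1.0, 1.0, 1.0]))
    zero_rates = np.zeros(5)
    with pytest.raises(UndefinedIndexError):
        amplitude_participation(amp, zero_rates, basis)
    del rec_like_y


def test_orientation_gauge_fixes_signs(model, traj):
    """With the reference-reaction orientation, c^n_1 > 0 for every mode."""
    for t in TIMES:
        rec = diagnose_state(model, t, traj(t))
        assert np.all(rec.amp.c[: rec.basis.n_finite, 0] > 0)
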