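import numpy as np
import pytest

from cspkinetics import default_grid, solve


def test_grid_validation(model):
    with pytest.raises(ValueError):
        solve(model, np.array([1.0, 0.5]))
    with pytest.raises(ValueError):
        solve(model, np.array([-1.0, 1.0]))
    with pytest.raises(ValueError):
        solve(model, np.array([1.0]))


def test_conservation_drift(traj):
    assert traj.conservation_drift() < 1e-9


def test_plasma_igg_monotone_decreasing(traj):
    cp = traj.states[:, 0]
    assert np.all(np.diff(cp) <= 1e-8 * cp[:-1])


def test_states_nonnegative(traj):
    assert np.all(traj.states >= 0.0)


def test_dense_output_consistent_with_grid(traj):
    for i in (0, 1000, -1):
        np.testing.assert_allclose(traj(traj.times[i]), traj.states[i],
                                   rtol=1e-12, atol=1e-12)
    with pytest.raises(ValueError):
        traj(5e3)


def test_to_frame(traj):
    df = traj.to_frame()
    assert list(df.columns) == ["t", "C_IgG_p", "C_IgG_e", "C_FcRn_e",
                                "C_IgG_FcRn_e"]
    assert len(df) == traj.times.size


def test_tolerance_convergence(model, traj):
    """Halving rtol leaves the solution unchanged to ~5 significant figures."""
    grid = np.array([0.0, 1e-2, 1.0, 1e2, 1e3])
    loose = solve(model, grid, rtol=1e-10)
    tight = solve(model, grid, rtol=5e-11)
    np.testing.assert_allclose(loose.states[1:], tight.states[1:],
                               rtol=1e-6, atol=1e-8)


def test_default_grid_shape():
    g = default_grid()
    assert g[0] == pytest.approx(1e-6) and g[-1] == pytest.approx(2e3)
    assert np.all(np.diff(g) > 0)
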