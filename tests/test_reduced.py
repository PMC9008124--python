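import numpy as np
import pytest

from cspkinetics import (
    correction_factors,
    csp_constraint_approx,
    reduction_error_table,
    reduction_errors_at,
    simulate_reduced,
)
from cspkinetics.reduced import (
    QSSA1_START,
    QSSA2_START,
    corrected1_approx,
    corrected2_approx,
    qssa1_approx,
    qssa2_approx,
)


def test_correction_factors_positive_and_small(model, traj):
    for t in (1e-2, 1.0, 1e2):
        cf = correction_factors(model, traj(t))
        assert 0 < cf.r1 < 1e-3
        assert 0 < cf.r2 < 1e-1
        assert cf.Lambda > 0
        assert cf.m == pytest.approx(model.params.kdeg / model.params.k1)


def test_corrections_collapse_to_qssa(model, traj):
    """As r1, r2 -> 0 the corrected fluxes approach the plain QSSA fluxes."""
    y = traj(1e2)
    cf = correction_factors(model, y)
    assert abs(corrected1_approx(model, y) - qssa1_approx(model, y)) \
        <= 2 * (cf.r1 + cf.r2) * abs(qssa1_approx(model, y)) + 1e-9
    assert abs(corrected2_approx(model, y) - qssa2_approx(model, y)) \
        <= 2 * (abs(1 - cf.Lambda)) * abs(qssa2_approx(model, y)) + 1e-9


def test_error_ordering(model, traj):
    """Corrections and CSP constraints beat plain QSSA inside each period."""
    for t in (1e-1, 1.0, 2.0):
        e = reduction_errors_at(model, t, traj(t))
        assert abs(e.er1_2) < abs(e.er1_1)
        assert abs(e.er1_3) < abs(e.er1_1)
    for t in (10.0, 50.0, 100.0):
        e = reduction_errors_at(model, t, traj(t))
        assert abs(e.er2_2) < abs(e.er2_1)
        assert abs(e.er2_3) < abs(e.er2_1)


def test_error_table_layout(model, traj):
    df = reduction_error_table(model, traj, [1e-2, 1e2])
    assert list(df.columns) == ["t", "er1_1", "er1_2", "er1_3",
                                "er2_1", "er2_2", "er2_3", "period"]
    assert df["period"].tolist() == [1, 2]


def test_csp_constraint_mode_validation():
    c = np.ones((3, 5))
    with pytest.raises(ValueError):
        csp_constraint_approx(c, np.ones(5), 3)
    c[0, 2] = 0.0
    with pytest.raises(ZeroDivisionError):
        csp_constraint_approx(c, np.ones(5), 1)


def test_unknown_variant_rejected(model):
    with pytest.raises(ValueError):
        simulate_reduced(model, "qssa3", np.array([1.0, 2.0]))


@pytest.mark.parametrize("variant,t_lo,t_hi,tol", [
    ("qssa1", QSSA1_START * 10, 3.0, 5e-3),
    ("corrected1", QSSA1_START * 10, 3.0, 1e-3),
    ("qssa2", QSSA2_START + 1.0, 1e3, 0.25),
    ("corrected2", QSSA2_START + 1.0, 1e3, 1e-2),
])
def test_reduced_tracks_full_solution(model, traj, variant, t_lo, t_hi, tol):
    grid = np.logspace(np.log10(t_lo), np.log10(t_hi), 30)
    red = simulate_reduced(model, variant, grid, full_traj=traj)
    full = np.array([traj(t) for t in grid])
    rel = np.abs(red.states[:, 0] - full[:, 0]) / full[:, 0]
    assert np.max(rel) < tol
    # conservation is exact by construction
    assert red.conservation_drift() < 1e-12


def test_reduced_dense_output(model, traj):
    grid = np.logspace(-1, 0, 10)
    red = simulate_reduced(model, "corrected1", grid, full_traj=traj)
    mid = 0.3
    y = red(mid)
    assert y.shape == (4,)
    assert y[2] + y[3] == pytest.approx(model.params.FcRn0)
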