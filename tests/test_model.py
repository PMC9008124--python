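import numpy as np
import pytest

from cspkinetics import (
    DEFAULT_PARAMETERS,
    REACTION_LABELS,
    SPECIES,
    ParameterSet,
    build_fcrn_model,
    load_config,
)


def test_default_parameters_and_derived():
    p = ParameterSet()
    assert p.as_dict() == DEFAULT_PARAMETERS
    assert p.a == pytest.approx(0.34 / 3.10)
    assert p.k1 == pytest.approx(0.167 / 0.34)


@pytest.mark.parametrize("name", list(DEFAULT_PARAMETERS))
def test_nonpositive_parameter_rejected(name):
    with pytest.raises(ValueError):
        ParameterSet(**{name: 0.0})
    with pytest.raises(ValueError):
        ParameterSet(**{name: -1.0})


def test_replace_returns_new_validated_set():
    p = ParameterSet().replace(kon=1.0)
    assert p.kon == 1.0
    assert p.koff == DEFAULT_PARAMETERS["koff"]
    with pytest.raises(ValueError):
        ParameterSet().replace(kon=-1.0)


def test_structure(model):
    assert model.species == SPECIES
    assert model.reaction_labels == REACTION_LABELS
    S = model.stoichiometric_matrix()
    assert S.shape == (4, 5)
    a = model.params.a
    np.testing.assert_allclose(S[:, 0], [-a, 1, 0, 0])
    np.testing.assert_allclose(S[:, 4], [a, 0, 1, -1])
    # conserved moiety lies in the left null space
    coeffs, total = model.conserved[0]
    np.testing.assert_allclose(coeffs @ S, 0.0, atol=1e-14)
    assert total == model.params.FcRn0


def test_initial_condition(model):
    p = model.params
    np.testing.assert_allclose(model.y0, [p.Dose / p.Vp, 0.0, p.FcRn0, 0.0])


def test_rate_laws(model):
    p = model.params
    y = np.array([100.0, 2.0, 300.0, 40.0])
    R = model.reaction_rates(y)
    expected = [p.k1 * 100.0, p.kdeg * 2.0, p.kon * 2.0 * 300.0,
                p.koff * 40.0, p.k1 * 40.0]
    np.testing.assert_allclose(R, expected, rtol=1e-14)
    np.testing.assert_allclose(model.rhs(y),
                               model.stoichiometric_matrix() @ R, rtol=1e-14)


def test_jacobian_matches_finite_differences(model):
    y = np.array([7.7e4, 1.7, 4.9e4, 3.8e2])
    J = model.jacobian(y)
    h = 1e-4
    for j in range(4):
        yp, ym = y.copy(), y.copy()
        yp[j] += h * max(abs(y[j]), 1.0)
        ym[j] -= h * max(abs(y[j]), 1.0)
        col = (model.rhs(yp) - model.rhs(ym)) / (yp[j] - ym[j])
        np.testing.assert_allclose(J[:, j], col, rtol=1e-6, atol=1e-10)


def test_negative_state_clamp_and_rejection(model):
    R = model.reaction_rates(np.array([1.0, -1e-8, 1.0, 1.0]))
    assert R[1] == 0.0 and R[2] == 0.0
    with pytest.raises(ValueError):
        model.reaction_rates(np.array([1.0, -1e-3, 1.0, 1.0]))
    with pytest.raises(ValueError):
        model.reaction_rates(np.array([1.0, 1.0]))


def test_load_config(tmp_path):
    path = tmp_path / "params.yaml"
    path.write_text("kon: 1.5\nDose: 1.0e4\n")
    p = load_config(path)
    assert p.kon == 1.5 and p.Dose == 1.0e4
    assert p.Vp == DEFAULT_PARAMETERS["Vp"]
    path.write_text("bogus: 1.0\n")
    with pytest.raises(ValueError):
        load_config(path)
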