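import numpy as np
import pytest

from cspkinetics import PerturbationSpec, classify_response, run_perturbed
from cspkinetics.perturb import _perturbed_model


def test_spec_validation():
    with pytest.raises(ValueError):
        PerturbationSpec("3b", 0.0, 1.0)
    with pytest.raises(ValueError):
        PerturbationSpec("3b", 2.0, -1.0)


def test_perturbed_model_scales_one_rate(model):
    pert = _perturbed_model(model, PerturbationSpec("3b", 2.0, 1.0))
    for r_ref, r_pert in zip(model.reactions, pert.reactions):
        factor = 2.0 if r_ref.label == "3b" else 1.0
        assert r_pert.k == pytest.approx(factor * r_ref.k)
    with pytest.raises(ValueError):
        _perturbed_model(model, PerturbationSpec("5", 2.0, 1.0))


def test_gamma_one_is_identity(model):
    grid = np.logspace(-2, 1, 40)
    ref, pert = run_perturbed(model, PerturbationSpec("3b", 1.0, 0.5), grid)
    assert pert is ref


def test_state_continuous_at_switch(model):
    grid = np.logspace(-2, 1, 60)
    spec = PerturbationSpec("3b", 2.0, 0.5)
    ref, pert = run_perturbed(model, spec, grid)
    np.testing.assert_allclose(pert(spec.t_switch), ref(spec.t_switch),
                               rtol=1e-8)
    # after the switch the trajectories deviate
    assert np.abs(pert(1.0) - ref(1.0)).max() > 0


def test_switch_outside_grid_rejected(model):
    grid = np.logspace(-2, 0, 10)
    with pytest.raises(ValueError):
        run_perturbed(model, PerturbationSpec("3b", 2.0, 5.0), grid)


def test_classify_response_structure(model):
    grid = np.logspace(-3, 2, 120)
    spec = PerturbationSpec("3b", 2.0, 0.5)
    ref, pert = run_perturbed(model, spec, grid)
    summary = classify_response(ref, pert, spec)
    assert set(summary.jump) == set(model.species)
    assert set(summary.drift) == set(model.species)
    assert summary.max_jump_variable in model.species
    assert all(v in (-1, 0, 1) for v in summary.drift.values())
    assert all(isinstance(v, bool) for v in summary.significant.values())
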