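import numpy as np
import pytest

from picorefine.fixtures import ToySpec, make_toy_structure, simulate_fobs


@pytest.fixture(scope="session")
def std_spec():
    """The standard toy: P1, ~20 atoms, 1.6 A data, 5% noise, bulk solvent."""
    return ToySpec(seed=3)


@pytest.fixture(scope="session")
def std_crystal(std_spec):
    model = make_toy_structure(std_spec)
    data = simulate_fobs(model, std_spec)
    return model, data


@pytest.fixture(scope="session")
def noiseless_spec():
    return ToySpec(seed=3, noise=0.0, d_min=1.5)


@pytest.fixture(scope="session")
def noiseless_crystal(noiseless_spec):
    model = make_toy_structure(noiseless_spec)
    data = simulate_fobs(model, noiseless_spec)
    return model, data


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def strategy_comparison(noiseless_crystal):
    """Final R_work of three strategies on one heavily distorted model:
    minimization-only, minimization+annealing, dual-space with solvent
    update.  Computed once; several tests assert different aspects."""
    from picorefine.engines import RefinementState, run_macro_cycles
    from picorefine.fixtures import perturb_model
    model, data = noiseless_crystal

    def distorted():
        m = perturb_model(model, "shake", 1.0, seed=9)
        m = perturb_model(m, "reset_adp")
        return perturb_model(m, "strip_waters")

    results = {}
    st = RefinementState.create(distorted(), data.copy())
    run_macro_cycles(st, 5, strategy=("scales", "xyz_reciprocal", "adp"))
    results["minimization"] = st.fmodel.r_work()
    st = RefinementState.create(distorted(), data.copy())
    run_macro_cycles(st, 5, strategy=("scales", "xyz_reciprocal", "adp"),
                     anneal_cycles=3)
    results["minimization_sa"] = st.fmodel.r_work()
    st = RefinementState.create(distorted(), data.copy())
    run_macro_cycles(st, 5, strategy=("scales", "waters", "xyz_real",
                                      "xyz_reciprocal", "adp"))
    results["dual_space"] = st.fmodel.r_work()
    return results
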