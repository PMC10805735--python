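import numpy as np
import pytest

import nucleoshell as ns


@pytest.fixture(scope="session")
def control_field():
    """One default control-condition field with its ground truth."""
    spec = ns.make_condition_spec("control", seed=3)
    return ns.generate_field(spec)


@pytest.fixture(scope="session")
def segmented_control(control_field):
    field, truth = control_field
    nuclei = ns.segment_nuclei(field)
    nucleoli = ns.segment_nucleoli(field, nuclei)
    return field, truth, nuclei, nucleoli


@pytest.fixture(scope="session")
def noiseless_single_nucleolus():
    """Noiseless, blur-free field containing exactly one nucleolus."""
    from nucleoshell.simulate import SyntheticSpec, condition_preset

    spec = condition_preset("control")(
        SyntheticSpec(
            seed=11,
            nucleoli_per_nucleus=(1, 1),
            blur_sigma=0.0,
            poisson_scale=None,
            gaussian_noise_sd=0.0,
        )
    )
    return ns.generate_field(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
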