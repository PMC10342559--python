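import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def mean_faces():
    """Noiseless (means-only) synthetic face + built targets per group."""
    from facemorph.synthetic import GeneratorParams, generate_face_detailed

    out = {}
    for group in ("female", "male"):
        params = GeneratorParams(group=group).noiseless()
        ls, built = generate_face_detailed(params, np.random.default_rng(0), group)
        out[group] = (ls, built)
    return out


@pytest.fixture(scope="session")
def mean_records(mean_faces):
    """Measured battery on the noiseless mean faces."""
    from facemorph.measurements import measure_face

    return {g: measure_face(ls) for g, (ls, _) in mean_faces.items()}


@pytest.fixture(scope="session")
def default_cohorts():
    """Small default-noise cohorts (n=8 per group, fixed seed) for unit tests."""
    from facemorph.synthetic import GeneratorParams, generate_cohort

    return {
        g: generate_cohort(GeneratorParams(group=g), 8, seed=11 + i)
        for i, g in enumerate(("female", "male"))
    }
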