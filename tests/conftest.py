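import warnings

import numpy as np
import pytest
from hypothesis import settings

import posespace as ps

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


def small_spec(seed: int = 7, jitter: float = 0.3) -> ps.SyntheticSpec:
    """3 compounds × 20 poses from 3 planted modes separated by >= 10σ."""
    modes = [
        ps.ModeSpec(1, (0.0, 0.0, 0.0), (0.0, 0.0, 0.0), jitter, 5.0),
        ps.ModeSpec(2, (0.0, 0.0, np.pi / 2), (5.0, 0.0, 0.0), jitter, 2.0),
        ps.ModeSpec(3, (np.pi / 2, 0.0, 0.0), (0.0, 5.0, 0.0), jitter, 0.0),
    ]
    compounds = [
        ps.CompoundSpec("C1", (0.8, 0.1, 0.1), "g1"),
        ps.CompoundSpec("C2", (0.1, 0.8, 0.1), "g2"),
        ps.CompoundSpec("C3", (0.34, 0.33, 0.33), "g3"),
    ]
    return ps.SyntheticSpec(modes=modes, compounds=compounds,
                            poses_per_compound=20, score_base=20.0,
                            score_noise_sigma=0.5, seed=seed)


@pytest.fixture(scope="session")
def small_run():
    ensemble, truth = ps.generate_ensemble(small_spec())
    return ensemble, truth


@pytest.fixture(scope="session")
def paper_run():
    """Canonical 30×200 fixture, generated and analyzed once per session."""
    spec = ps.paper_scale_fixture()
    ensemble, truth = ps.generate_ensemble(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        result = ps.analyze_ensemble(ensemble, n_clusters=len(spec.modes))
    return spec, ensemble, truth, result
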