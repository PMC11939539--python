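import numpy as np
import pytest

from ridgewidth import phantom


@pytest.fixture(scope="session")
def default_spec() -> phantom.PhantomSpec:
    return phantom.PhantomSpec()


@pytest.fixture(scope="session")
def default_phantom(default_spec):
    """Noiseless default phantom pair + ground truth (rendered once)."""
    return phantom.generate_phantom(default_spec)


@pytest.fixture(scope="session")
def default_grid(default_spec):
    return phantom.default_grid(default_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def fixture_spec() -> phantom.PhantomSpec:
    return phantom.PhantomSpec(seed=3)


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory, fixture_spec):
    """On-disk DICOM fixture (both timepoints + truth + manifest)."""
    out = tmp_path_factory.mktemp("phantom_fixture")
    return phantom.write_fixture(fixture_spec, out)


def truth_lookup(truth, timepoint):
    """true width indexed by (depth_mm, offset_mm) for one timepoint."""
    sub = truth[truth.timepoint == timepoint]
    return sub.set_index(["depth_mm", "offset_mm"]).true_width_mm
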