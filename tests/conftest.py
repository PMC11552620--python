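import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from polykmer import KmerHistogram

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def delta_histogram() -> KmerHistogram:
    """Two spikes: heterozygous class at coverage 25, homozygous at 50."""
    return KmerHistogram(
        coverages=np.array([25, 50]), frequencies=np.array([4e5, 8e5])
    )


@pytest.fixture
def delta_file(tmp_path, delta_histogram):
    from polykmer import write_histogram

    path = tmp_path / "delta.histo"
    write_histogram(delta_histogram, path)
    return path
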