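import pytest

from memovec import (
    BatchEffect,
    FragmentationSpectrum,
    StudyDesign,
    generate_study,
)


@pytest.fixture
def spectrum():
    """A well-behaved 12-peak spectrum with losses inside and outside the window."""
    peaks = [(100.0 + 10.0 * k, 100.0 + k) for k in range(12)]  # 100..210
    return FragmentationSpectrum(
        feature_id="f1",
        precursor_mz=250.1,
        peaks=tuple(peaks),
        retention_time=65.0,
        source_sample="S1",
    )


@pytest.fixture(scope="session")
def small_design():
    """Desk-scale two-batch design: RT shift plus sensitivity drop."""
    return StudyDesign(
        n_parents=2,
        compounds_per_parent=8,
        replicates=2,
        n_contaminants=2,
        batches=(
            BatchEffect("B1", rt_shift=0.0, sensitivity=1.0),
            BatchEffect("B2", rt_shift=120.0, sensitivity=0.8),
        ),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_design):
    return generate_study(small_design)
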