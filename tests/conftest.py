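import pytest

from mpracal import (
    AmpliconLayout,
    GroundTruth,
    TraceSpec,
    make_library,
)


@pytest.fixture
def small_library():
    """5-entry library (2 CM / 2 endothelial / 1 ESC), 8 bp barcodes."""
    return make_library(2, 2, 1, barcode_length=8, seed=7)


@pytest.fixture
def study_library():
    """The 55-entry study design: 25 CM, 25 endothelial, 5 ESC."""
    return make_library(25, 25, 5, barcode_length=16, seed=1)


@pytest.fixture
def layout8():
    return AmpliconLayout(barcode_length=8)


@pytest.fixture
def clean_spec():
    """Noiseless, driftless 2 Hz / 5-cycle trace spec with grid-aligned apexes."""
    return TraceSpec(noise_sd=0.0, drift_magnitude=0.0, drift_kind="none")


def uniform_truth(library, activities=None, seed=0):
    """Ground truth with uniform DNA frequencies and given (or unit) activities."""
    ids = list(library.entry_ids)
    if activities is None:
        activities = {i: 1.0 for i in ids}
    return GroundTruth(
        activity=dict(activities),
        dna_frequency={i: 1.0 / len(ids) for i in ids},
        seed=seed,
    )
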