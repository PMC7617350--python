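import pytest

from widcfoc.simulate import ReadSimParams, make_reference_panel


@pytest.fixture(scope="session")
def panel3():
    """Default three-region panel: 220 bp amplicons, 6 CpGs each."""
    return make_reference_panel(3, 220, 6, seed=1)


@pytest.fixture(scope="session")
def panel_short():
    """Single-amplicon panel fully covered by one 150 bp read."""
    return make_reference_panel(1, 150, 6, seed=3)


@pytest.fixture()
def clean_params():
    """Error-free chemistry: conversion perfect, no sequencing error."""
    return ReadSimParams(
        depth_per_region=200,
        tumor_fraction=0.05,
        conversion_rate=1.0,
        overconversion_rate=0.0,
        seq_error_rate=0.0,
        seed=42,
    )
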