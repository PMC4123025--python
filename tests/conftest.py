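import dataclasses

import pytest

import coarselur as cl


@pytest.fixture(scope="session")
def campaign():
    """One default-condition city campaign with injected QC defects."""
    layout = cl.default_layouts()[0]
    truth = cl.default_truth(seed=7)
    return cl.generate_campaign(layout, cl.compact_schema(), truth)


@pytest.fixture(scope="session")
def clean_campaign():
    """Defect-free campaign (no QC injection) for modelling tests."""
    layout = cl.default_layouts()[0]
    truth = dataclasses.replace(
        cl.default_truth(seed=11), outlier_rate=0.0, defect_rates={}
    )
    return cl.generate_campaign(layout, cl.compact_schema(), truth)


@pytest.fixture(scope="session")
def valid_samples(campaign):
    valid, _ = cl.apply_qc(campaign.samples)
    return valid
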