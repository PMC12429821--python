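"""Shared fixtures: the packaged study table and reconstructed count sets."""

from __future__ import annotations

import pytest

import dtameta as dm


@pytest.fixture(scope="session")
def records():
    return dm.load_fixture()


@pytest.fixture(scope="session")
def tables_by_modality(records):
    out = {}
    for modality in ("EST", "SE", "SPECT", "CMR"):
        recs = dm.filter_records(records, modality=modality)
        out[modality] = [dm.reconstruct_record(r).table for r in recs]
    return out


@pytest.fixture(scope="session")
def fast_mcmc():
    """Reduced iteration budget for tests that only need a rough posterior."""
    return dict(chains=4, iters_per_chain=2000)
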