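import logging

import pytest

import waitcea as w


@pytest.fixture(autouse=True)
def _quiet_item_warnings(caplog):
    # item-level all-missing warnings are expected noise in simulated data
    logging.getLogger("waitcea.costing").setLevel(logging.ERROR)
    yield


@pytest.fixture(scope="session")
def tables():
    return w.default_costing_tables()


@pytest.fixture(scope="session")
def config():
    return w.AnalysisConfig(seed=1)


@pytest.fixture(scope="session")
def sim_default():
    """One default-condition simulated trial (N=179, no treatment effects)."""
    return w.simulate_frames(w.SimulationSpec(seed=1))


@pytest.fixture(scope="session")
def pipeline_default(sim_default, tables, config):
    """Full main-analysis pipeline output on the default simulated trial."""
    trial, drugs = sim_default
    return w.analyze(trial, drugs, tables, config)


def make_records(rows):
    """Hand-build records from (pid, arm, wave, responded, hrqol, counts, drugs)."""
    return [
        w.TrialRecord(
            participant_id=pid,
            arm=arm,
            wave=wave,
            responded=resp,
            hrqol=hrqol,
            use_counts=dict(counts or {}),
            drug_entries=list(drugs or []),
        )
        for pid, arm, wave, resp, hrqol, counts, drugs in rows
    ]
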