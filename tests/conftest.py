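import time

import pytest

from cypind.library import default_enzyme_settings, load_compound, load_design

#: victims with packaged rifampicin DDI designs and published outcome rows
TABLE_VICTIMS = [
    "midazolam",
    "alfentanil",
    "atorvastatin",
    "omeprazole",
    "pioglitazone",
    "tolbutamide",
    "glyburide",
    "bupropion",
    "repaglinide",
]


@pytest.fixture(scope="session")
def rifampicin():
    return load_compound("rifampicin")


@pytest.fixture(scope="session")
def settings():
    return default_enzyme_settings()


@pytest.fixture(scope="session")
def ddi_outcomes(rifampicin, settings):
    """Full dynamic-model sweep over the packaged rifampicin designs, shared
    across tests. Returns ({victim: DDIOutcome}, wall_seconds)."""
    from cypind.pbpk import run_ddi

    t0 = time.perf_counter()
    outcomes = {
        v: run_ddi(rifampicin, load_compound(v), load_design(v), settings=settings)
        for v in TABLE_VICTIMS
    }
    return outcomes, time.perf_counter() - t0
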