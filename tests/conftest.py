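import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tndecay as td

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=20,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def catalog():
    return td.default_catalog()


@pytest.fixture(scope="session")
def cargo():
    return td.default_cargo()


@pytest.fixture(scope="session")
def isapl1(catalog):
    return catalog["ISApl1-like"]


@pytest.fixture(scope="session")
def small_element():
    """A short synthetic IS for fast property tests."""
    rng = np.random.default_rng(99)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=80)])
    return td.ISElementSpec(name="mini-IS", seq=seq, irl_len=15, irr_len=15,
                            tsd_len=2)


@pytest.fixture(scope="session")
def composite_demo(catalog, cargo, isapl1):
    """One intact composite with its backbone, used across modules."""
    rng = np.random.default_rng(42)
    backbone = td.make_backbone(5000, 0.5, rng)
    site = td.choose_clean_site(backbone, rng, isapl1.tsd_len, 1100, 3900)
    parent, truth = td.form_composite(backbone, cargo, isapl1, site,
                                      record_id="demo")
    return {"backbone": backbone, "site": site, "parent": parent,
            "truth": truth}
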