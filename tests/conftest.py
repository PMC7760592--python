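"""Shared fixtures: the reference kinetic constants and small simulators.

The reference constants are those of the trifluoroketone/acetylcholinesterase
system the package was validated on: competitive fast binding with
Ki = 5.15 nM followed by slow isomerization (k+4 = 0.456 min^-1,
k-4 = 0.054 min^-1), association rate assumed 3e9 M^-1 min^-1.
"""

import numpy as np
import pytest
from hypothesis import settings

from slowbind import AssayConditions, MechanismSpec

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

REF = {
    "Ki": 5.15e-9,
    "k_plus3": 3.0e9,
    "k_plus4": 0.456,
    "k_minus4": 0.054,
}


@pytest.fixture(scope="session")
def ref_constants():
    return dict(REF)


@pytest.fixture(scope="session")
def ref_spec():
    return MechanismSpec(
        k_plus3=REF["k_plus3"],
        k_minus3=REF["Ki"] * REF["k_plus3"],
        k_plus4=REF["k_plus4"],
        k_minus4=REF["k_minus4"],
        kcat=2.0e2,
    )


@pytest.fixture
def make_condition():
    def _make(S=1e-4, I=0.0, Km=1e-4, E0=1e-10, kcat=2.0e2):
        return AssayConditions(S=S, Km=Km, I=I, E0=E0, Vmax=kcat * E0)

    return _make


@pytest.fixture(scope="session")
def times_60min():
    return np.linspace(0.0, 60.0, 241)
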