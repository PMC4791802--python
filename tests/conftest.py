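import numpy as np
import pytest

from flux13c import network as nw
from flux13c import synthetic as sy
from flux13c.emu import PositionalLabeling
from flux13c.labeling import make_tracer


def toy_path(name: str) -> str:
    from importlib.resources import files

    return str(files("flux13c").joinpath(f"data/toys/{name}.txt"))


#: toy labeling scenarios: (fluxes, exchange, input labeling) per network
TOY_CASES = {
    "linear": (
        {"R1": 1.0, "R2": 1.0, "R3": 1.0},
        {},
        {"A": PositionalLabeling([(0.5, (0.9, 0.01)), (0.5, (0.05, 0.6))])},
    ),
    "branch": (
        {"RIN": 0.3, "RSPL": 0.7, "RCND": 0.7, "REXP": 1.0},
        {},
        {"X": PositionalLabeling([(0.4, (0.95, 0.02, 0.3)), (0.6, (0.01,) * 3)])},
    ),
    "scramble": (
        {"R1": 1.0, "R2": 1.0, "R3": 1.0, "R4": 1.0},
        {},
        {"A": PositionalLabeling([(1.0, (0.99, 0.01, 0.2, 0.5))])},
    ),
    "revloop": (
        {"R1": 1.0, "R2": 0.6, "R3": 1.0, "R4": 0.4},
        {"R2": 0.8, "R4": 0.3},
        {"A": PositionalLabeling([(1.0, (0.7, 0.05, 0.3))])},
    ),
    "cycle": (
        {"RCS": 1.0, "RDC": 1.0, "RKD": 0.6, "RAN": 0.4, "RKX": 0.4},
        {},
        {
            "AC": PositionalLabeling([(0.2, (0.99, 0.99)), (0.8, (0.011, 0.011))]),
            "AN": PositionalLabeling([(1.0, (0.5, 0.011, 0.011))]),
            "co2": PositionalLabeling.uniform(1),
        },
    ),
}


@pytest.fixture(scope="session")
def yeast_net():
    return nw.load_yeast_network()


@pytest.fixture(scope="session")
def yeast_net_3hp():
    return nw.load_yeast_network(with_3hp=True)


@pytest.fixture(scope="session")
def reference_fluxes(yeast_net):
    return sy.build_strain_fluxes(yeast_net, sy.REFERENCE_STRAIN)


@pytest.fixture(scope="session")
def producer_fluxes(yeast_net_3hp):
    return sy.build_strain_fluxes(yeast_net_3hp, sy.PRODUCER_STRAIN)


@pytest.fixture(scope="session")
def reference_measurements(yeast_net, reference_fluxes):
    """One noisy measurement set per tracer design, fixed seeds."""
    return [
        sy.generate_measurements(yeast_net, reference_fluxes, make_tracer("1-13C"), seed=11),
        sy.generate_measurements(
            yeast_net, reference_fluxes, make_tracer("20pct-U13C"), seed=12
        ),
    ]
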