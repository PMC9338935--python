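import numpy as np
import pytest

import helixread as hx

HMPA1 = "AACACGAATATCATCTACCAATT"


@pytest.fixture(scope="session")
def hmpa1_duplex():
    return hx.build_fiber_bdna(HMPA1)


@pytest.fixture(scope="session")
def hmpa1_numbering(hmpa1_duplex):
    return hx.assign_operator_numbering(hmpa1_duplex, ("C", 12))


@pytest.fixture(scope="session")
def hmpa1_pairs(hmpa1_duplex):
    pairs = hx.detect_base_pairs(hmpa1_duplex)
    pairs, steps = hx.bp_and_step_parameters(pairs)
    return pairs, steps


@pytest.fixture(scope="session")
def probe_complex(hmpa1_duplex):
    return hx.make_probe_complex(hmpa1_duplex, [
        ("point-atom", 0, "phosphate", 3.2),
        ("HIS-like", 2, "phosphate", 3.1),
        ("ARG-like", -3, "minor", 2.5),
    ])


def random_rigid(rng):
    """A random proper rotation + translation."""
    from helixread.geom import rotation_about_axis
    axis = rng.normal(size=3)
    R = rotation_about_axis(axis, rng.uniform(0, 360.0))
    t = rng.normal(size=3) * 20.0
    return R, t
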