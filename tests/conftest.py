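import numpy as np
import pytest

from edenp import ENPSystem, ExecutionPolicy, GrayImage, Membrane, Program


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def random_image(rng):
    """An 8x8 unit-scale image with irregular texture."""
    return GrayImage(rng.random((8, 8)), "unit")


def one_membrane_system(variables, programs, enzymes=()):
    """A single-membrane (skin-only) system, handy for engine tests."""
    return ENPSystem(
        [
            Membrane(
                "s",
                parent=None,
                variables=dict(variables),
                enzymes=tuple(enzymes),
                programs=list(programs),
            )
        ]
    )


def all_parallel(**kwargs):
    defaults = dict(mode="all-parallel", consumption="non-consuming", max_steps=50)
    defaults.update(kwargs)
    return ExecutionPolicy(**defaults)


@pytest.fixture
def doubling_system():
    """One rule (2*a)| -> 1|b with a=3: the minimal firing example."""
    prog = Program(name="double", production="2*a", repartition=((1.0, "b"),))
    return one_membrane_system({"a": 3.0, "b": 0.0}, [prog])
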