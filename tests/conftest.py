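import pytest

from bncana import LookupTable


@pytest.fixture
def and2():
    return LookupTable("and", ("a", "b"), (0, 0, 0, 1))


@pytest.fixture
def xor2():
    return LookupTable("xor", ("a", "b"), (0, 1, 1, 0))


@pytest.fixture
def tfl1():
    """The floral-repressor automaton: on iff LFY=0, EMF1=1, AP1=0.

    AP2 is wired in but fully redundant.
    """
    return LookupTable.from_function(
        "TFL1",
        ("AP2", "LFY", "EMF1", "AP1"),
        lambda ap2, lfy, emf1, ap1: (not lfy) and emf1 and (not ap1),
    )


@pytest.fixture
def majority3():
    return LookupTable.from_function(
        "maj", ("a", "b", "c"), lambda a, b, c: a + b + c >= 2
    )


def random_lut(rng, k, name="f"):
    import random

    inputs = tuple(f"i{j}" for j in range(k))
    outputs = tuple(rng.randint(0, 1) for _ in range(2 ** k))
    return LookupTable(name, inputs, outputs)
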