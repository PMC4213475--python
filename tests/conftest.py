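import numpy as np
import pytest

from sigcircuits.simulate import (
    complex_alternatives_pathway,
    cycle_pathway,
    fig6_pathway,
    inhibitor_pathway,
)


@pytest.fixture
def fig6():
    return fig6_pathway()


@pytest.fixture
def inhib():
    return inhibitor_pathway()


@pytest.fixture
def cxalt():
    return complex_alternatives_pathway()


@pytest.fixture
def cyc():
    return cycle_pathway()


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


MINIMAL_KGML = """<?xml version="1.0"?>
<pathway name="path:toy01" org="hsa" number="01">
  <entry id="1" name="hsa:10" type="gene"/>
  <entry id="2" name="hsa:20" type="gene"/>
  <relation entry1="1" entry2="2" type="PPrel">
    <subtype name="activation" value="--&gt;"/>
  </relation>
</pathway>
"""


@pytest.fixture
def minimal_kgml():
    return MINIMAL_KGML
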