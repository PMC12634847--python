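import numpy as np
import pytest

from openhist.chemistry import default_registry
from openhist.proteolysis import DigestionRule, Protocol, bundled_histones, digest


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def histones():
    return bundled_histones()


@pytest.fixture(scope="session")
def pro_pic(registry):
    return Protocol.preset("PRO-PIC", registry)


@pytest.fixture(scope="session")
def argc_rule():
    return DigestionRule(frozenset("R"), max_missed_cleavages=1, min_length=6, max_length=30)


@pytest.fixture(scope="session")
def h3_tail_peptide(histones, argc_rule):
    """H3 residues 9-17, KSTGGKAPR."""
    h3 = next(h for h in histones if h.accession == "P68431")
    return next(
        p for p in digest(h3, argc_rule) if p.sequence == "KSTGGKAPR" and p.start == 9
    )


@pytest.fixture(scope="session")
def h4_68_78_peptide(histones, argc_rule):
    """H4 residues 68-78, DAVTYTEHAKR (K77 is peptide position 10)."""
    h4 = next(h for h in histones if h.accession == "P62805")
    return next(p for p in digest(h4, argc_rule) if p.sequence == "DAVTYTEHAKR")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
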