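"""Shared fixtures: designed barcode sets, synthetic amplicons and libraries.

Everything is generated programmatically and seeded; session scope keeps the
more expensive designs to a single computation.
"""

import pytest

from sasiseq.barcodes import BarcodeSet, DesignConstraints, design_barcode_set
from sasiseq.simulate import random_genome
from sasiseq.spikein import (
    PHIX_PRIMERS,
    build_amplicon,
    make_sasi_set,
    synthetic_primer_site_reference,
)


@pytest.fixture(scope="session")
def set384() -> BarcodeSet:
    """The 384-plex, length-11, distance-5 production profile (seed 1,
    composition constraints off for pure code-theoretic properties)."""
    return design_barcode_set(
        11, 5, 384, DesignConstraints.none(), seed=1, profile_name="384x11_d5"
    )


@pytest.fixture(scope="session")
def small_set() -> BarcodeSet:
    """A small 11-mer d>=5 set for simulation fixtures."""
    return design_barcode_set(11, 5, 8, DesignConstraints.none(), seed=2)


@pytest.fixture(scope="session")
def lib_set() -> BarcodeSet:
    """Library (index) barcodes: 8-mers at distance >= 4."""
    return design_barcode_set(8, 4, 8, DesignConstraints.none(), seed=3)


@pytest.fixture(scope="session")
def reference() -> str:
    return synthetic_primer_site_reference()


@pytest.fixture(scope="session")
def amplicons(reference):
    return {name: build_amplicon(reference, p) for name, p in PHIX_PRIMERS.items()}


@pytest.fixture(scope="session")
def genome() -> str:
    return random_genome(200_000, seed=7)


@pytest.fixture(scope="session")
def sasi_sets(amplicons, small_set):
    return {bc.id: make_sasi_set(amplicons, bc) for bc in small_set}
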