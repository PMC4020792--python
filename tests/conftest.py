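import io

import pytest

from orphan_enzymes.ec_catalog import parse_enzyme_catalog

CATALOG_TEXT = """\
ID   1.1.1.3
DE   homoserine dehydrogenase.
AN   HSD.
CA   L-homoserine + NAD(P)+ = L-aspartate 4-semialdehyde + NAD(P)H.
CC   -!- Systematic name: L-homoserine:NAD(P)+ oxidoreductase.
//
ID   1.1.1.173
DE   L-rhamnose 1-dehydrogenase.
AN   L-rhamnose-1-dehydrogenase.
AN   rhamnose dehydrogenase.
//
ID   2.8.2.34
DE   glycochenodeoxycholate sulfotransferase.
//
ID   1.1.1.33
DE   mevaldate reductase (NADPH).
//
ID   4.2.1.99
DE   Deleted entry.
//
ID   5.3.1.88
DE   Transferred entry: 5.3.1.12.
//
"""


@pytest.fixture
def small_catalog():
    return parse_enzyme_catalog(io.StringIO(CATALOG_TEXT))


@pytest.fixture
def catalog_text():
    return CATALOG_TEXT
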