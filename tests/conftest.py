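import pytest

from teheat.annotation import TECatalogue, TEFeature


@pytest.fixture
def small_catalogue():
    """Two ONSEN copies and one COPIA37 copy on one chromosome."""
    return TECatalogue(
        [
            TEFeature("chr1", 101, 500, "+", "ONSEN_1", "ONSEN", "COPIA"),
            TEFeature("chr1", 1001, 1400, "+", "ONSEN_2", "ONSEN", "COPIA"),
            TEFeature("chr1", 2001, 2400, "-", "COPIA37_1", "COPIA37", "COPIA"),
        ]
    )


@pytest.fixture
def gff_text():
    return (
        "##gff-version 3\n"
        "chr1\tsrc\ttransposable_element\t101\t500\t.\t+\t.\t"
        "ID=ONSEN_1;Family=ONSEN;Superfamily=COPIA\n"
        "chr1\tsrc\ttransposable_element\t1001\t1400\t.\t+\t.\t"
        "ID=ONSEN_2;Family=ONSEN;Superfamily=COPIA\n"
        "chr1\tsrc\ttransposable_element\t2001\t2400\t.\t-\t.\t"
        "ID=COPIA37_1;Family=COPIA37;Superfamily=COPIA\n"
    )
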