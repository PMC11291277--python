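import numpy as np
import pytest

from paleozooms.markerdb import Taxonomy, TaxonNode


@pytest.fixture
def hominin_taxonomy() -> Taxonomy:
    """Primates > Hominoidea > Homininae > Homo > Homo sp., plus Pongo."""
    tax = Taxonomy(TaxonNode("Primates", "order"))
    tax.add("Hominoidea", "superfamily", "Primates")
    tax.add("Homininae", "subfamily", "Hominoidea")
    tax.add("Homo", "genus", "Homininae")
    tax.add("Homo sp.", "species", "Homo")
    tax.add("Ponginae", "subfamily", "Hominoidea")
    tax.add("Pongo", "genus", "Ponginae")
    return tax


@pytest.fixture
def ungulate_taxonomy() -> Taxonomy:
    tax = Taxonomy(TaxonNode("Artiodactyla", "order"))
    tax.add("Bovidae", "family", "Artiodactyla")
    tax.add("Caprinae", "subfamily", "Bovidae")
    tax.add("Capra", "genus", "Caprinae")
    tax.add("Bovinae", "subfamily", "Bovidae")
    tax.add("Bos", "genus", "Bovinae")
    tax.add("Bos cf. mutus", "species", "Bos")
    tax.add("Cervidae", "family", "Artiodactyla")
    tax.add("Cervus", "genus", "Cervidae")
    tax.add("Cervus elaphus", "species", "Cervus")
    return tax


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
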