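import pytest

from funlink.model import GoldStandard, ProteinRef, TaxonomyTree, canonical_pair


@pytest.fixture
def toy_tree() -> TaxonomyTree:
    """((A,B)X,(C)Y)R — two genera under one root."""
    return TaxonomyTree({"A": "X", "B": "X", "C": "Y", "X": "R", "Y": "R"}, "R")


@pytest.fixture
def toy_gold() -> GoldStandard:
    return GoldStandard(
        {
            "K1": {"P1", "P2", "P4"},
            "K2": {"P2", "P5", "P6"},
            "K3": {"P7", "P8"},
            "ABC": {"P1", "P9"},  # homology-dominated, excluded
        },
        excluded_sets={"ABC"},
    )


def ref(pid: str, taxon: str = "TAX1") -> ProteinRef:
    return ProteinRef(taxon, pid)


def pair(a: str, b: str, taxon: str = "TAX1"):
    return canonical_pair(ref(a, taxon), ref(b, taxon))
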