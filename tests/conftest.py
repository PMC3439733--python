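import pytest

from gsatk.genesets import GeneSet, GeneSetCollection


def make_set(set_id, genes, name=None, source="user", organism=""):
    return GeneSet.from_symbols(set_id, name or set_id, genes,
                                source=source, organism=organism)


@pytest.fixture
def small_collection():
    """Four sets with a known overlap structure over a 8-gene universe."""
    sets = [
        make_set("S1", ["A", "B", "C"], name="Alpha pathway", source="KEGG"),
        make_set("S2", ["B", "C", "D"], name="Beta signature", source="MSigDB"),
        make_set("S3", ["E", "F"], name="Gamma module", source="KEGG"),
        make_set("S4", ["A", "B", "C", "D", "G", "H"], name="Delta disease",
                 source="OMIM"),
    ]
    return GeneSetCollection(collection_id="small", sets=sets)


@pytest.fixture
def nested_sets():
    """A strict-subset chain: set k holds the first 2(k+1) symbols."""
    symbols = [f"G{i:03d}" for i in range(40)]
    return [
        make_set(f"N{k:02d}", symbols[: 2 * (k + 1)]) for k in range(20)
    ]
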