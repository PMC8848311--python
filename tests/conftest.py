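import pytest

from extaxsi import fixtures as fx


@pytest.fixture(scope="session")
def demo_table():
    """Curated demo taxonomy (cod lineage + sparse virus branch)."""
    return fx.demo_table()


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory, demo_table):
    """37-record GenBank corpus over the demo taxonomy, with manifest."""
    d = tmp_path_factory.mktemp("corpus")
    out = d / "records.gb"
    manifest = fx.make_records(
        seed=11, table=demo_table, n_records=37,
        gene_pool=[("COI", 12), ("CYTB", 7), ("nd2", 3)],
        geo_profile=(0.4, 0.3, 0.3), out=out,
    )
    return out, manifest


def corpus_as_transport_dict(path):
    """Split a flat GenBank file into an accession -> record-text mapping."""
    corpus = {}
    for chunk in path.read_text(encoding="utf-8").split("//\n"):
        if not chunk.strip():
            continue
        acc = None
        for line in chunk.splitlines():
            if line.startswith("VERSION"):
                parts = line.split()
                if len(parts) > 1:
                    acc = parts[1]
        corpus[acc] = chunk + "//\n"
    return corpus


@pytest.fixture(scope="session")
def demo_store(tmp_path_factory):
    """Demo taxonomy written as a taxdump store directory."""
    d = tmp_path_factory.mktemp("store")
    fx.write_taxdump(fx.demo_taxonomy(), d)
    return d
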