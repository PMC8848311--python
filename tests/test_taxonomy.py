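"""Taxonomy store: taxdump loading, lineage resolution, conversion."""

import pytest

from extaxsi import (
    ConvertDirection,
    TaxdumpParseError,
    TaxonomyIntegrityError,
    UnknownTxidError,
    convert_batch,
    convert_values,
    load_taxdump,
    name_to_txids,
    resolve_lineage,
)
from extaxsi import fixtures as fx
from extaxsi.taxonomy import MAIN_RANKS, TaxonNode, TaxonomyTable


def brute_force_lineage(table, txid):
    """Independent oracle: materialize the full ancestor chain, then scan it
    per rank; fall back to the queried node's own name."""
    chain = []
    node = table.nodes[txid]
    while True:
        chain.append(node)
        if node.parent_txid == node.txid:
            break
        node = table.nodes[node.parent_txid]
    out = []
    for rank in MAIN_RANKS:
        hit = [n.scientific_name for n in chain if n.rank.lower() == rank]
        out.append(hit[0] if hit else table.nodes[txid].scientific_name)
    return tuple(out)


class TestLoadTaxdump:
    def test_minimal_tree_roundtrip(self, tmp_path):
        nodes = {
            1: TaxonNode(1, 1, "no rank", "root"),
            10: TaxonNode(10, 1, "phylum", "Phylum A"),
            100: TaxonNode(100, 10, "species", "Species a"),
        }
        fx.write_taxdump(nodes, tmp_path)
        table = load_taxdump(tmp_path / "nodes.dmp", tmp_path / "names.dmp")
        assert len(table) == 3
        assert table.root_txid == 1
        assert table.nodes == nodes

    def test_synthetic_tree_roundtrip_exhaustive(self, tmp_path):
        fixture = fx.make_taxonomy(seed=3, n_nodes=500, rank_missing_prob=0.2,
                                   out_dir=tmp_path)
        table = load_taxdump(tmp_path / "nodes.dmp", tmp_path / "names.dmp")
        assert table.nodes == fixture.nodes

    def test_malformed_line_names_file_and_line(self, tmp_path):
        nodes = tmp_path / "nodes.dmp"
        nodes.write_text("1\t|\t1\t|\tno rank\t|\n2\t|\t1\t|\n")
        names = tmp_path / "names.dmp"
        names.write_text("1\t|\troot\t|\t\t|\tscientific name\t|\n")
        with pytest.raises(TaxdumpParseError) as err:
            load_taxdump(nodes, names)
        assert err.value.lineno == 2
        assert "nodes.dmp" in err.value.path

    def test_orphan_parent_is_integrity_error(self, tmp_path):
        nodes = {
            1: TaxonNode(1, 1, "no rank", "root"),
            2: TaxonNode(2, 99, "phylum", "Orphaned"),
        }
        fx.write_taxdump(nodes, tmp_path)
        with pytest.raises(TaxonomyIntegrityError) as err:
            load_taxdump(tmp_path / "nodes.dmp", tmp_path / "names.dmp")
        assert err.value.txids == [2]

    def test_name_index_covers_exactly_the_node_names(self, demo_table):
        from_nodes = {n.scientific_name.lower() for n in demo_table.nodes.values()}
        assert set(demo_table.name_index) == from_nodes
        for name, txids in demo_table.name_index.items():
            for t in txids:
                assert demo_table.nodes[t].scientific_name.lower() == name


class TestResolveLineage:
    def test_cod_lineage_placements(self, demo_table):
        path = resolve_lineage(demo_table, 8049)
        assert path.order == "Gadiformes"
        assert path.family == "Gadidae"
        assert path.species == "Gadus morhua"
        assert path.phylum == "Chordata"
        assert path.class_ == "Actinopterygii"
        serialized = path.serialize()
        assert serialized == ("Chordata;Actinopterygii;Gadiformes;"
                              "Gadidae;Gadus;Gadus morhua")
        assert serialized.count(";") == 5
        assert serialized == serialized.strip()

    def test_root_resolves_to_its_own_name_six_times(self, demo_table):
        path = resolve_lineage(demo_table, demo_table.root_txid)
        assert path.ranks() == ("root",) * 6

    def test_sparse_virus_branch_fallback_fills_missing_ranks(self, demo_table):
        path = resolve_lineage(demo_table, 2697049)
        name = "Severe acute respiratory syndrome coronavirus 2"
        assert path.family == "Coronaviridae"  # the one labelled ancestor
        assert path.species == name
        assert path.phylum == path.class_ == path.order == path.genus == name
        assert all(path.ranks())  # no empty field, ever

    def test_unknown_txid_raises_lookup_error(self, demo_table):
        with pytest.raises(UnknownTxidError) as err:
            resolve_lineage(demo_table, 424242)
        assert err.value.txid == 424242

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle_on_every_node(self, seed):
        fixture = fx.make_taxonomy(seed=seed, n_nodes=150,
                                   rank_missing_prob=0.35)
        table = fixture.table()
        for txid in table.nodes:
            assert resolve_lineage(table, txid).ranks() == \
                brute_force_lineage(table, txid), f"txid {txid}, seed {seed}"

    def test_deterministic_repeated_calls(self, demo_table):
        first = [resolve_lineage(demo_table, t).serialize()
                 for t in sorted(demo_table.nodes)]
        second = [resolve_lineage(demo_table, t).serialize()
                  for t in sorted(demo_table.nodes)]
        assert first == second


class TestNameLookup:
    def test_case_insensitive_exact_match(self, demo_table):
        assert name_to_txids(demo_table, "Gadus morhua") == [8049]
        assert name_to_txids(demo_table, "GADUS MORHUA") == [8049]

    def test_unmatched_name_is_empty_not_error(self, demo_table):
        assert name_to_txids(demo_table, "no such organism") == []

    def test_homonyms_return_all_txids_ascending(self):
        nodes = {
            1: TaxonNode(1, 1, "no rank", "root"),
            5: TaxonNode(5, 1, "genus", "Morus"),   # the mulberry...
            3: TaxonNode(3, 1, "genus", "Morus"),   # ...and the gannet
        }
        table = TaxonomyTable(nodes)
        assert name_to_txids(table, "morus") == [3, 5]

    def test_main_rank_names_roundtrip_through_lineage(self, demo_table):
        # every node at one of the six ranks is findable by name, and its
        # own lineage places that name at that rank
        for node in demo_table.nodes.values():
            rank = node.rank.lower()
            if rank not in MAIN_RANKS:
                continue
            assert node.txid in name_to_txids(demo_table, node.scientific_name)
            path = resolve_lineage(demo_table, node.txid)
            assert path.ranks()[MAIN_RANKS.index(rank)] == node.scientific_name


class TestConvertBatch:
    def test_tsv_happy_path_preserves_order(self, demo_table, tmp_path):
        f = tmp_path / "in.tsv"
        f.write_text("8049\n8043\n7711\n")
        frame = convert_batch(demo_table, f, ConvertDirection.TXID_TO_RANKS)
        assert list(frame["input_value"]) == ["8049", "8043", "7711"]
        assert list(frame["status"]) == ["ok"] * 3
        assert frame.loc[0, "lineage"].endswith("Gadus morhua")

    def test_unknown_txid_flags_row_without_aborting(self, demo_table, tmp_path):
        f = tmp_path / "in.csv"
        f.write_text("8049\n999999\n8043\n7742\n7711\n")
        frame = convert_batch(demo_table, f, "txid_to_ranks")
        assert len(frame) == 5
        assert list(frame["status"]).count("unresolved") == 1
        assert frame.loc[1, "status"] == "unresolved"

    def test_batch_equals_concatenated_single_calls(self, demo_table, tmp_path):
        txids = [str(t) for t in sorted(demo_table.nodes)] * 10  # 200 rows
        f = tmp_path / "batch.tsv"
        f.write_text("\n".join(txids) + "\n")
        batch = convert_batch(demo_table, f, "txid_to_ranks")
        import pandas as pd
        singles = pd.concat(
            [convert_values(demo_table, [t], "txid_to_ranks") for t in txids],
            ignore_index=True)
        assert batch.equals(singles)

    def test_name_direction_and_ambiguity_flag(self, demo_table):
        frame = convert_values(demo_table, ["Gadus morhua", "nobody"],
                               ConvertDirection.NAME_TO_TXID)
        assert frame.loc[0, "txid"] == 8049
        assert frame.loc[1, "status"] == "unresolved"

    def test_empty_file_yields_empty_output(self, demo_table, tmp_path, caplog):
        f = tmp_path / "empty.tsv"
        f.write_text("")
        frame = convert_batch(demo_table, f, "txid_to_ranks")
        assert frame.empty
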