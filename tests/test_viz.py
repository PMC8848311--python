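"""Plot-data builders: filtering, scatter, sunburst, world map, HTML export."""

import random

import pytest

from extaxsi import (
    GeoKind,
    GeoRef,
    TaxonomyFileError,
    apply_filter,
    build_scatter,
    build_sunburst,
    build_worldmap,
    export_html,
    extract_embedded_data,
    extract_geo,
    load_taxonomy_file,
    parse_records,
    write_taxonomy_tsv,
)
from extaxsi import fixtures as fx
from extaxsi.taxonomy import MAIN_RANKS


def random_paths(seed, n):
    """Random six-rank paths over a small name pool (collisions intended)."""
    rng = random.Random(seed)
    pool = [[f"{rank[:3].title()}{i}" for i in range(1 + level * 2)]
            for level, rank in enumerate(MAIN_RANKS)]
    return [tuple(rng.choice(names) for names in pool) for _ in range(n)]


COD_PATH = "Chordata;Actinopterygii;Gadiformes;Gadidae;Gadus;Gadus morhua"


class TestLoadTaxonomyFile:
    def test_two_column_row(self, tmp_path):
        f = tmp_path / "t.tsv"
        f.write_text(f"X1\t{COD_PATH}\n")
        (path,) = load_taxonomy_file(f)
        assert path.species == "Gadus morhua"
        assert path.serialize() == COD_PATH

    def test_headerless_single_column_accepted(self, tmp_path):
        f = tmp_path / "t.tsv"
        f.write_text(f"{COD_PATH}\n{COD_PATH}\n")
        assert len(load_taxonomy_file(f)) == 2

    def test_short_path_right_padded_with_last_name(self, tmp_path):
        f = tmp_path / "t.tsv"
        f.write_text("X1\tChordata;Actinopterygii;Gadiformes\n")
        (path,) = load_taxonomy_file(f)
        assert path.ranks() == ("Chordata", "Actinopterygii", "Gadiformes",
                                "Gadiformes", "Gadiformes", "Gadiformes")

    def test_more_than_six_fields_is_parse_error_with_line(self, tmp_path):
        f = tmp_path / "t.tsv"
        f.write_text(f"X1\t{COD_PATH}\nX2\t{COD_PATH};extra\n")
        with pytest.raises(TaxonomyFileError) as err:
            load_taxonomy_file(f)
        assert err.value.lineno == 2

    def test_database_output_reloads_identically(self, demo_table, small_corpus,
                                                 tmp_path):
        path, manifest = small_corpus
        records = parse_records(path)
        out = tmp_path / "tax.tsv"
        write_taxonomy_tsv(records, demo_table, out)
        reloaded = load_taxonomy_file(out)
        assert len(reloaded) == len(manifest.records)
        from extaxsi import resolve_lineage
        for lineage, spec in zip(reloaded, manifest.records):
            assert lineage.ranks() == resolve_lineage(demo_table, spec.txid).ranks()


class TestApplyFilter:
    def test_threshold_zero_is_identity_without_overflow(self, tmp_path):
        paths = random_paths(1, 100)
        result = apply_filter(paths, 0, tmp_path)
        assert result.kept == paths
        assert result.discarded == []
        assert result.overflow_file is None
        assert not list(tmp_path.glob("filtered_out_*"))

    def test_hand_countable_partition(self, tmp_path):
        a = ("P", "C", "O", "F", "G", "Species A")
        b = ("P", "C", "O", "F", "G", "Species B")
        result = apply_filter([a] * 10 + [b] * 2, 3, tmp_path)
        assert len(result.kept) == 10
        assert result.discarded == [("Species B", 2)]
        assert result.overflow_file.name == "filtered_out_min3.tsv"
        assert result.overflow_file.read_text() == "Species B\t2\n"

    def test_threshold_above_every_count_discards_all(self, tmp_path):
        paths = random_paths(2, 50)
        result = apply_filter(paths, 10_000, tmp_path)
        assert result.kept == []
        assert sum(c for _, c in result.discarded) == 50

    @pytest.mark.parametrize("threshold", [0, 1, 3, 10])
    def test_conservation_for_every_threshold(self, threshold, tmp_path):
        paths = random_paths(3, 1000)
        result = apply_filter(paths, threshold, tmp_path)
        assert len(result.kept) + sum(c for _, c in result.discarded) == 1000
        for _, count in result.discarded:
            assert count < threshold


class TestBuildScatter:
    def test_published_gadiformes_family_counts(self):
        data = build_scatter(fx.gadiformes_scatter_paths())
        family = [(p.taxon, p.count) for p in data.series["family"]]
        assert family == [("Gadidae", 381460), ("Merlucciidae", 3252),
                          ("Macrouridae", 1673)]
        assert all(p.parent == "Gadiformes" for p in data.series["family"])

    def test_single_path_gives_count_one_everywhere(self):
        data = build_scatter([("P", "C", "O", "F", "G", "S")])
        for rank in MAIN_RANKS:
            (pt,) = data.series[rank]
            assert pt.count == 1

    def test_per_rank_sums_equal_corpus_size(self):
        paths = random_paths(4, 500)
        data = build_scatter(paths)
        for rank in MAIN_RANKS:
            assert sum(p.count for p in data.series[rank]) == 500


class TestBuildSunburst:
    def test_additivity_on_shared_phylum(self):
        tree = build_sunburst([
            ("P", "C1", "O", "F", "G", "S"),
            ("P", "C2", "O", "F", "G", "S"),
        ])
        (root,) = tree.roots()
        assert root.count == 2
        assert sorted(n.count for n in tree.children(root.id)) == [1, 1]

    def test_homonym_genus_under_two_families_not_merged(self):
        tree = build_sunburst([
            ("P", "C", "O", "F1", "G", "S"),
            ("P", "C", "O", "F2", "G", "S"),
        ])
        genus_nodes = [n for n in tree.nodes.values()
                       if n.level == 5 and n.label == "G"]
        assert len(genus_nodes) == 2

    def test_every_internal_node_sums_its_children(self):
        tree = build_sunburst(random_paths(5, 400))
        assert sum(n.count for n in tree.roots()) == tree.total == 400
        for node in tree.nodes.values():
            kids = tree.children(node.id)
            if kids:
                assert node.count == sum(k.count for k in kids), node.id


class TestBuildWorldmap:
    def test_aggregation_by_site_and_country(self):
        refs = ([GeoRef(GeoKind.COORDINATES, lat=60.0, lon=5.0)] * 3
                + [GeoRef(GeoKind.COUNTRY, country_name="Norway")] * 2)
        arrays = build_worldmap(refs, ["cod"] * 5)
        (coord,) = arrays.coordinate_points
        (country,) = arrays.country_points
        assert coord.count == 3 and (coord.lat, coord.lon) == (60.0, 5.0)
        assert country.count == 2 and country.country_name == "Norway"
        assert "cod" in coord.label and "3 records" in coord.label

    def test_nearby_encodings_of_one_site_merge_at_4dp(self):
        refs = [GeoRef(GeoKind.COORDINATES, lat=60.00001, lon=5.0),
                GeoRef(GeoKind.COORDINATES, lat=60.00002, lon=5.0)]
        arrays = build_worldmap(refs)
        assert len(arrays.coordinate_points) == 1

    def test_all_none_yields_empty_arrays_still_exportable(self, tmp_path):
        arrays = build_worldmap([GeoRef(GeoKind.NONE)] * 4)
        assert arrays.coordinate_points == [] and arrays.country_points == []
        assert arrays.n_unlocated == 4
        out = tmp_path / "map.html"
        export_html(arrays, out)
        assert extract_embedded_data(out)["n_unlocated"] == 4

    def test_totals_match_generator_manifest(self, small_corpus):
        path, manifest = small_corpus
        records = parse_records(path)
        arrays = build_worldmap([extract_geo(r) for r in records])
        assert sum(p.count for p in arrays.coordinate_points) == \
            manifest.geo_totals["coordinates"]
        assert sum(p.count for p in arrays.country_points) == \
            manifest.geo_totals["country"]
        assert arrays.n_unlocated == manifest.geo_totals["none"]


class TestExportHtml:
    def test_scatter_html_contains_all_taxon_names(self, tmp_path):
        paths = random_paths(6, 30)
        data = build_scatter(paths)
        out = tmp_path / "s.html"
        export_html(data, out)
        text = out.read_text()
        for p in paths:
            for name in p:
                assert name in text

    def test_empty_sunburst_is_valid_html_with_warning(self, tmp_path, caplog):
        with caplog.at_level("WARNING"):
            out = export_html(build_sunburst([]), tmp_path / "e.html")
        text = out.read_text()
        assert text.startswith("<!DOCTYPE html>")
        assert extract_embedded_data(out)["nodes"] == []

    @pytest.mark.parametrize("builder", [build_scatter, build_sunburst])
    def test_embedded_data_roundtrips(self, builder, tmp_path):
        data = builder(random_paths(7, 120))
        out = tmp_path / "p.html"
        export_html(data, out)
        assert extract_embedded_data(out) == data.to_payload()
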