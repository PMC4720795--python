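"""Gene-set parsing, homology maps and harmonization."""

import logging

import pytest

from genelattice import (
    GeneSet,
    GeneSetCollection,
    GmtParseError,
    HomologyMap,
    HomologyMapError,
    harmonize,
    identity_map,
    read_gmt,
    read_homology_map,
    write_gmt,
    write_homology_map,
)


def gmt(tmp_path, text, name="sets.gmt"):
    path = tmp_path / name
    path.write_text(text, encoding="utf-8")
    return path


class TestReadGmt:
    def test_duplicate_members_collapse_with_warning(self, tmp_path, caplog):
        path = gmt(tmp_path, "A\tspecies=Mm;tier=III\tg1\tg2\tg2\n")
        with caplog.at_level(logging.WARNING):
            coll = read_gmt(path)
        assert coll["A"].members == {"g1", "g2"}
        assert coll["A"].species == "Mm"
        assert coll["A"].tier == "III"
        assert any("duplicate" in rec.message for rec in caplog.records)

    def test_empty_file_gives_empty_collection(self, tmp_path):
        assert len(read_gmt(gmt(tmp_path, ""))) == 0

    def test_duplicate_set_id_is_error(self, tmp_path):
        path = gmt(tmp_path, "A\td\tg1\nA\td\tg2\n")
        with pytest.raises(GmtParseError, match="duplicate set id"):
            read_gmt(path)

    def test_short_line_names_line_number(self, tmp_path):
        path = gmt(tmp_path, "A\tdesc\tg1\nB\tonlydesc\n")
        with pytest.raises(GmtParseError, match=":2"):
            read_gmt(path)

    def test_comments_and_blank_lines_skipped(self, tmp_path):
        coll = read_gmt(gmt(tmp_path, "# comment\n\nA\td\tg1\n"))
        assert coll.set_ids == ["A"]

    def test_defaults_when_description_has_no_tokens(self, tmp_path):
        coll = read_gmt(gmt(tmp_path, "A\tfree text description\tg1\tg2\n"))
        assert coll["A"].species == "unknown"
        assert coll["A"].tier == "IV"
        assert coll["A"].label == "free text description"

    def test_unknown_description_keys_ignored(self, tmp_path):
        coll = read_gmt(gmt(tmp_path, "A\tspecies=Hs;foo=bar;tier=I\tg1\n"))
        assert (coll["A"].species, coll["A"].tier) == ("Hs", "I")


class TestGeneSet:
    def test_members_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            GeneSet(set_id="A", members=frozenset({"g1"}), universe=frozenset({"g2"}))

    def test_unknown_tier_rejected(self):
        with pytest.raises(ValueError, match="tier"):
            GeneSet(set_id="A", tier="VI", members=frozenset({"g1"}))


class TestHomologyMap:
    def test_cross_species_cluster(self):
        hmap = HomologyMap([("H1", "Mm", "Pafah1b1"), ("H1", "Hs", "PAFAH1B1")])
        assert hmap.get("Mm", "Pafah1b1") == "H1"
        assert hmap.get("Hs", "PAFAH1B1") == "H1"

    def test_conflicting_cluster_is_error(self):
        with pytest.raises(HomologyMapError, match="conflict"):
            HomologyMap([("H1", "Mm", "g"), ("H2", "Mm", "g")])

    def test_empty_body(self, tmp_path):
        path = tmp_path / "h.tsv"
        path.write_text("cluster_id\tspecies\tgene_id\n")
        assert len(read_homology_map(path)) == 0

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "h.tsv"
        path.write_text("a\tb\tc\nH1\tMm\tg1\n")
        with pytest.raises(HomologyMapError, match="header"):
            read_homology_map(path)

    def test_roundtrip(self, tmp_path):
        hmap = HomologyMap([("H1", "Mm", "g1"), ("H1", "Hs", "G1"), ("H2", "Mm", "g2")])
        path = write_homology_map(hmap, tmp_path / "h.tsv")
        assert read_homology_map(path) == hmap


class TestHarmonize:
    def test_cross_species_intersection_premise(self):
        coll = GeneSetCollection([
            GeneSet(set_id="A", species="Mm", members=frozenset({"Pafah1b1"})),
            GeneSet(set_id="B", species="Hs", members=frozenset({"PAFAH1B1"})),
        ])
        hmap = HomologyMap([("H1", "Mm", "Pafah1b1"), ("H1", "Hs", "PAFAH1B1")])
        hc = harmonize(coll, hmap)
        assert hc.sets["A"].members == hc.sets["B"].members == {"H1"}
        assert hc.sets["A"].members & hc.sets["B"].members == {"H1"}
        assert hc.unmapped_count == 0

    def test_unmapped_gene_becomes_singleton_cluster(self):
        coll = GeneSetCollection(
            [GeneSet(set_id="A", species="Mm", members=frozenset({"gX"}))]
        )
        hc = harmonize(coll, HomologyMap())
        assert hc.sets["A"].members == {"solo:Mm:gX"}
        assert hc.unmapped_count == 1

    def test_paralog_collapse_within_set(self):
        coll = GeneSetCollection(
            [GeneSet(set_id="A", species="Mm", members=frozenset({"g1", "g2"}))]
        )
        hmap = HomologyMap([("H1", "Mm", "g1"), ("H1", "Mm", "g2")])
        hc = harmonize(coll, hmap)
        assert hc.sets["A"].members == {"H1"}
        assert hc.n_raw_genes == 2
        assert hc.n_clusters == 1

    def test_idempotent_under_identity_map(self):
        coll = GeneSetCollection([
            GeneSet(set_id="A", species="Mm", members=frozenset({"g1", "g2"})),
            GeneSet(set_id="B", species="Hs", members=frozenset({"G2", "G3"})),
        ])
        hmap = HomologyMap([("H1", "Mm", "g1"), ("H2", "Mm", "g2"), ("H2", "Hs", "G2")])
        once = harmonize(coll, hmap)
        twice = harmonize(once.sets, identity_map(once.sets))
        assert {gs.set_id: gs.members for gs in twice.sets} == {
            gs.set_id: gs.members for gs in once.sets
        }

    def test_edge_count_equals_sum_of_set_sizes(self):
        coll = GeneSetCollection([
            GeneSet(set_id="A", species="Mm", members=frozenset({"g1", "g2", "g3"})),
            GeneSet(set_id="B", species="Mm", members=frozenset({"g2"})),
        ])
        hc = harmonize(coll, HomologyMap())
        assert hc.n_edges == sum(gs.size for gs in hc.sets) == 4

    def test_cluster_count_bounded_by_raw_pairs(self):
        coll = GeneSetCollection([
            GeneSet(set_id="A", species="Mm", members=frozenset({"g1", "g2"})),
            GeneSet(set_id="B", species="Hs", members=frozenset({"G1"})),
        ])
        hmap = HomologyMap([("H1", "Mm", "g1"), ("H1", "Hs", "G1")])
        hc = harmonize(coll, hmap)
        assert hc.n_clusters <= hc.n_raw_genes


def test_gmt_roundtrip_preserves_collection(tmp_path):
    coll = GeneSetCollection([
        GeneSet(set_id="A", label="first", species="Mm", tier="III",
                members=frozenset({"g1", "g2"})),
        GeneSet(set_id="B", species="Hs", tier="I", members=frozenset({"G3"})),
    ])
    path = write_gmt(coll, tmp_path / "out.gmt")
    back = read_gmt(path)
    assert {gs.set_id: (gs.species, gs.tier, gs.members) for gs in back} == {
        gs.set_id: (gs.species, gs.tier, gs.members) for gs in coll
    }
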