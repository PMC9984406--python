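"""Splicegraph construction, gene assignment, de novo updates, simplifier,
and LSV definition."""

import pytest

from lsvkit.splicegraph import (
    AnnotationError,
    BuildGroup,
    BuildThresholds,
    Candidate,
    Exon,
    Junction,
    RetainedIntron,
    SpliceGraph,
    assign_junction_to_gene,
    define_lsvs,
    graph_from_transcripts,
    parse_annotation,
    simplify,
    update_splicegraph,
)


def cassette_graph() -> SpliceGraph:
    return graph_from_transcripts(
        "g", "chr1", "+",
        [[(0, 100), (400, 500), (800, 900)], [(0, 100), (800, 900)]],
    )


class TestGraphFromTranscripts:
    def test_union_of_two_transcripts(self):
        sg = cassette_graph()
        assert len(sg.exons) == 3
        assert {(j.start, j.end) for j in sg.junctions} == {
            (100, 400), (500, 800), (100, 800)
        }
        assert sg.introns == []

    def test_spanning_exon_split_into_retained_intron(self):
        # one transcript's single exon covers another's junction entirely
        sg = graph_from_transcripts(
            "g", "chr1", "+", [[(0, 100), (400, 500)], [(0, 500)]]
        )
        assert [(e.start, e.end) for e in sg.exons] == [(0, 100), (400, 500)]
        assert len(sg.introns) == 1
        ri = sg.introns[0]
        assert (ri.start, ri.end) == (100, 400) and ri.annotated

    def test_overlapping_transcript_exons_rejected(self):
        with pytest.raises(AnnotationError):
            graph_from_transcripts("g", "chr1", "+", [[(0, 100), (50, 200)]])

    def test_every_junction_connects_two_exons(self, panel_graphs):
        for sg in panel_graphs.values():
            sg.check_invariants()


class TestParseAnnotation:
    def test_roundtrip_matches_generator_inventory(self, panel_gff3, panel_specs):
        graphs = parse_annotation(panel_gff3)
        for spec in panel_specs:
            if spec.denovo_junctions:
                continue  # annotation holds only the annotated part
            sg = graphs[spec.gene_id]
            assert len(sg.exons) == spec.expected_exons, spec.gene_id
            assert len(sg.junctions) == spec.expected_junctions, spec.gene_id
            assert len(sg.introns) == spec.expected_introns, spec.gene_id

    def test_malformed_hierarchy_names_record(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text(
            "chr1\tx\tgene\t1\t100\t.\t+\t.\tID=g1\n"
            "chr1\tx\texon\t1\t50\t.\t+\t.\tParent=missing_tx\n"
        )
        with pytest.raises(AnnotationError, match="missing_tx"):
            parse_annotation(str(p))

    def test_gene_without_exons_skipped(self, tmp_path):
        p = tmp_path / "empty.gff3"
        p.write_text("chr1\tx\tgene\t1\t100\t.\t+\t.\tID=g1\n")
        assert parse_annotation(str(p)) == {}


class TestAssignJunction:
    def make_gene(self, gid, exons, strand="+"):
        return SpliceGraph(gid, "chr1", strand,
                           exons=[Exon(s, e) for s, e in exons],
                           junctions=[])

    def test_containing_gene_beats_overlapping(self):
        a = self.make_gene("A", [(0, 100), (400, 500)])
        a.junctions.append(Junction(100, 400))
        b = self.make_gene("B", [(0, 600)])
        assert assign_junction_to_gene((100, 400), [b, a]) == "A"

    def test_nearby_exons_beat_boundary_containment(self):
        b = self.make_gene("B", [(0, 100), (600, 700)])   # ends 100 bp away
        c = self.make_gene("C", [(0, 1000)])
        # junction (200, 500): 100 bp from B's exons on both sides
        c2 = SpliceGraph("C", "chr1", "+", exons=[Exon(0, 10), Exon(990, 1000)])
        assert assign_junction_to_gene((200, 500), [c2, b]) == "B"

    def test_one_far_end_falls_back_to_boundary_tier(self):
        g = self.make_gene("G", [(0, 100), (1000, 1100)])
        # end 600 is 400+ bp from both exons -> tier 3 via boundaries
        assert assign_junction_to_gene((150, 600), [g]) == "G"

    def test_no_match_returns_none(self):
        g = self.make_gene("G", [(0, 100)])
        assert assign_junction_to_gene((5000, 6000), [g]) is None


class TestUpdateSplicegraph:
    groups = [BuildGroup("g", ["e1", "e2"], 2)]

    def test_candidate_passing_both_filters_added(self):
        sg = cassette_graph()
        cand = Candidate("junction", 500, 700,
                         {"e1": (6.0, 4), "e2": (6.0, 4)})
        out = update_splicegraph(sg, [cand], self.groups)
        j = out.find_junction(500, 700)
        assert j is not None and not j.annotated
        # exon [800,900) extended leftwards to host the acceptor at 700
        assert out.exon_index(700) is not None

    def test_position_filter_rejects_high_read_single_position(self):
        sg = cassette_graph()
        cand = Candidate("junction", 500, 700, {"e1": (100.0, 1), "e2": (100.0, 1)})
        out = update_splicegraph(sg, [cand], self.groups)
        assert out.find_junction(500, 700) is None

    def test_exon_extension_keeps_invariants(self):
        sg = cassette_graph()
        # donor endpoint 50 bp past the middle exon's end
        cand = Candidate("junction", 550, 800, {"e1": (6.0, 4), "e2": (6.0, 4)})
        out = update_splicegraph(sg, [cand], self.groups)
        out.check_invariants()
        mid = [e for e in out.exons if e.start == 400][0]
        assert mid.end == 550 and mid.denovo_extended

    def test_idempotent_on_incorporated_evidence(self):
        sg = cassette_graph()
        cand = Candidate("junction", 500, 700, {"e1": (6.0, 4), "e2": (6.0, 4)})
        once = update_splicegraph(sg, [cand], self.groups)
        twice = update_splicegraph(once, [cand], self.groups)
        assert [(j.start, j.end, j.annotated) for j in once.junctions] == \
               [(j.start, j.end, j.annotated) for j in twice.junctions]
        assert [(e.start, e.end) for e in once.exons] == \
               [(e.start, e.end) for e in twice.exons]

    def test_intron_split_by_new_exon_inherits_source(self):
        sg = graph_from_transcripts(
            "g", "chr1", "+", [[(0, 100), (1000, 1100)], [(0, 1100)]]
        )
        assert len(sg.introns) == 1
        cands = [
            Candidate("junction", 100, 500, {"e1": (6.0, 4), "e2": (6.0, 4)}),
            Candidate("junction", 600, 1000, {"e1": (6.0, 4), "e2": (6.0, 4)}),
        ]
        out = update_splicegraph(sg, cands, self.groups)
        out.check_invariants()
        # de novo exon [500, 600) splits the retained intron in two fragments
        assert any(not e.annotated for e in out.exons)
        assert len(out.introns) == 2
        assert all(i.source == (100, 1000) for i in out.introns)


class TestSimplify:
    def graph(self):
        return cassette_graph()

    def rates(self, minor):
        return {
            ("J", 100, 400): {"g1": 98.0},
            ("J", 500, 800): {"g1": 50.0},
            ("J", 100, 800): {"g1": minor},
        }

    def test_consistently_low_edge_simplified(self):
        out = simplify(self.graph(), self.rates(2.0), 0.05)
        assert out.find_junction(100, 800).simplified
        assert not out.find_junction(100, 400).simplified

    def test_not_simplified_when_high_in_one_group(self):
        rates = self.rates(2.0)
        for k in rates:
            rates[k]["g2"] = {("J", 100, 400): 10.0, ("J", 500, 800): 10.0,
                              ("J", 100, 800): 30.0}[k]
        out = simplify(self.graph(), rates, 0.05)
        assert not out.find_junction(100, 800).simplified

    def test_threshold_zero_is_identity(self):
        out = simplify(self.graph(), self.rates(0.0), 0.0)
        assert not any(e.simplified for e in out.edges())

    @pytest.mark.parametrize("thr", [0.01, 0.03, 0.05, 0.2])
    def test_monotone_in_threshold(self, thr):
        low = simplify(self.graph(), self.rates(2.0), thr)
        high = simplify(self.graph(), self.rates(2.0), thr + 0.1)
        for e_lo, e_hi in zip(low.edges(), high.edges()):
            if e_lo.simplified:
                assert e_hi.simplified


class TestDefineLsvs:
    def test_cassette_has_source_and_target(self):
        lsvs = define_lsvs(cassette_graph())
        ids = {l.lsv_id for l in lsvs}
        assert ids == {"g:s:0-100", "g:t:800-900"}
        by_id = {l.lsv_id: l for l in lsvs}
        assert [e.key for e in by_id["g:s:0-100"].edges] == [
            ("J", 100, 400), ("J", 100, 800)
        ]

    def test_simplified_edge_collapses_lsvs(self):
        sg = cassette_graph()
        sg.find_junction(100, 800).simplified = True
        assert define_lsvs(sg) == []

    def test_intron_retention_forms_lsvs(self):
        sg = graph_from_transcripts(
            "g", "chr1", "+", [[(0, 100), (400, 500)], [(0, 500)]]
        )
        lsvs = define_lsvs(sg)
        assert {l.lsv_id for l in lsvs} == {"g:s:0-100", "g:t:400-500"}
        for l in lsvs:
            assert {k.key[0] for k in l.edges} == {"J", "I"}

    def test_minus_strand_swaps_direction(self):
        sg = graph_from_transcripts(
            "g", "chr1", "-",
            [[(0, 100), (400, 500), (800, 900)], [(0, 100), (800, 900)]],
        )
        ids = {l.lsv_id for l in define_lsvs(sg)}
        # donor-side split at the left exon is a *target* LSV on minus strand
        assert ids == {"g:t:0-100", "g:s:800-900"}

    def test_each_edge_in_at_most_two_lsvs(self, panel_graphs):
        for sg in panel_graphs.values():
            seen = {}
            for l in define_lsvs(sg):
                for e in l.edges:
                    seen.setdefault(e.key, []).append(l.direction)
            for key, dirs in seen.items():
                assert len(dirs) <= 2
                assert len(set(dirs)) == len(dirs)
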