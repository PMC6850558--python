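"""Event-catalog construction from annotation: coordinate conventions,
hand-enumerated event counts, deduplication, strand symmetry, round trips."""

import pytest

from splicerank.events import (
    AnnotationError,
    CatalogFormatError,
    GenomicInterval,
    build_all_events,
    build_ass_events,
    build_mxe_events,
    build_ri_events,
    build_se_events,
    read_event_catalog,
    write_event_catalog,
)
from splicerank.gtf import GTFParseError, parse_gtf, write_gtf

from conftest import make_transcript


class TestParseGtf:
    def test_coordinates_converted_to_zero_based_half_open(self, toy_gtf):
        models = parse_gtf(toy_gtf)
        assert len(models) == 1
        assert [(e.start, e.end) for e in models[0].exons] == [
            (0, 100),
            (200, 300),
            (400, 500),
        ]

    def test_empty_file_gives_empty_collection(self, tmp_path):
        path = tmp_path / "empty.gtf"
        path.write_text("")
        assert parse_gtf(path) == []

    def test_two_transcripts_share_gene_id(self, tmp_path):
        lines = [
            f'chr1\tx\texon\t{s}\t{e}\t.\t+\t.\tgene_id "g1"; transcript_id "{t}";\n'
            for t, (s, e) in [("t1", (1, 100)), ("t1", (201, 300)), ("t2", (1, 300))]
        ]
        path = tmp_path / "two.gtf"
        path.write_text("".join(lines))
        models = parse_gtf(path)
        assert [m.transcript_id for m in models] == ["t1", "t2"]
        assert {m.gene_id for m in models} == {"g1"}

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.gtf"
        path.write_text(
            'chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            "only three\tfields\there\n"
        )
        with pytest.raises(GTFParseError, match=":2"):
            parse_gtf(path)

    def test_overlapping_exons_name_transcript(self, tmp_path):
        lines = [
            f'chr1\tx\texon\t{s}\t{e}\t.\t+\t.\tgene_id "g1"; transcript_id "tbad";\n'
            for s, e in [(1, 100), (50, 200)]
        ]
        path = tmp_path / "overlap.gtf"
        path.write_text("".join(lines))
        with pytest.raises(AnnotationError, match="tbad"):
            parse_gtf(path)

    def test_round_trip_through_writer(self, toy_gtf, tmp_path):
        models = parse_gtf(toy_gtf)
        out = tmp_path / "rt.gtf"
        write_gtf(models, out)
        again = parse_gtf(out)
        assert [m.exons for m in again] == [m.exons for m in models]


class TestEventConstruction:
    def test_three_exon_transcript_events(self, three_exon_transcript):
        models = [three_exon_transcript]
        ri = build_ri_events(models)
        se = build_se_events(models)
        assert len(ri) == 2  # two introns, both retention candidates
        assert len(se) == 1  # one internal exon
        assert ri[0].core == GenomicInterval("chr1", 100, 200, "+")
        assert ri[0].boundaries == (100, 200)
        assert se[0].core == GenomicInterval("chr1", 200, 300, "+")
        assert se[0].exclusion_junctions == frozenset(
            {GenomicInterval("chr1", 100, 400, "+")}
        )

    def test_minus_strand_ri_boundaries_are_strand_oriented(self):
        m = make_transcript("t1", "g1", [(0, 100), (200, 300)], strand="-")
        (ri,) = build_ri_events([m])
        assert ri.boundaries == (200, 100)  # 5' boundary is the intron end

    @pytest.mark.parametrize(
        "n_exons,expected_ri,expected_se",
        [(1, 0, 0), (2, 1, 0), (3, 2, 1), (4, 3, 2), (5, 4, 3)],
    )
    def test_event_counts_match_hand_enumeration(self, n_exons, expected_ri, expected_se):
        exons = [(i * 200, i * 200 + 100) for i in range(n_exons)]
        models = [make_transcript("t1", "g1", exons)]
        assert len(build_ri_events(models)) == expected_ri
        assert len(build_se_events(models)) == expected_se

    def test_shared_introns_deduplicated(self, three_exon_transcript):
        other = make_transcript("t2", "g1", [(0, 100), (200, 300), (400, 500)])
        assert len(build_ri_events([three_exon_transcript, other])) == 2

    def test_mxe_from_exclusive_middle_exons(self):
        t1 = make_transcript("t1", "g1", [(0, 100), (200, 250), (400, 500)])
        t2 = make_transcript("t2", "g1", [(0, 100), (300, 350), (400, 500)])
        (mxe,) = build_mxe_events([t1, t2])
        assert mxe.core == GenomicInterval("chr1", 200, 250, "+")
        assert len(mxe.inclusion_junctions) == 2
        assert len(mxe.exclusion_junctions) == 2

    def test_mxe_suppressed_when_exons_cooccur(self):
        t1 = make_transcript("t1", "g1", [(0, 100), (200, 250), (400, 500)])
        t2 = make_transcript("t2", "g1", [(0, 100), (300, 350), (400, 500)])
        t3 = make_transcript(
            "t3", "g1", [(0, 100), (200, 250), (300, 350), (400, 500)]
        )
        assert build_mxe_events([t1, t2, t3]) == []

    def test_mxe_needs_multiple_transcripts(self, three_exon_transcript):
        assert build_mxe_events([three_exon_transcript]) == []

    def test_a5ss_on_plus_strand(self):
        t1 = make_transcript("t1", "g1", [(0, 200), (400, 500)])
        t2 = make_transcript("t2", "g1", [(0, 230), (400, 500)])
        (ev,) = build_ass_events([t1, t2])
        assert ev.kind == "A5SS"  # shared acceptor, differing donor on '+'
        assert ev.core == GenomicInterval("chr1", 230, 400, "+")  # shorter intron

    def test_same_coordinates_on_minus_strand_flip_to_a3ss(self):
        t1 = make_transcript("t1", "g1", [(0, 200), (400, 500)], strand="-")
        t2 = make_transcript("t2", "g1", [(0, 230), (400, 500)], strand="-")
        (ev,) = build_ass_events([t1, t2])
        assert ev.kind == "A3SS"

    def test_identical_intron_sets_give_no_ass(self, three_exon_transcript):
        other = make_transcript("t2", "g1", [(0, 100), (200, 300), (400, 500)])
        assert build_ass_events([three_exon_transcript, other]) == []


class TestCatalogProperties:
    def _mixed_models(self, strand="+"):
        return [
            make_transcript("t1", "g1", [(0, 100), (200, 250), (400, 500)], strand=strand),
            make_transcript("t2", "g1", [(0, 100), (300, 350), (400, 500)], strand=strand),
            make_transcript("t3", "g2", [(1000, 1100), (1200, 1300)], strand=strand),
            make_transcript("t4", "g2", [(1000, 1150), (1200, 1300)], strand=strand),
        ]

    def test_duplicated_input_yields_identical_catalog(self):
        models = self._mixed_models()
        assert build_all_events(models) == build_all_events(models + models)

    def test_event_coordinates_lie_within_gene_span(self):
        models = self._mixed_models()
        spans = {}
        for m in models:
            lo, hi = m.exons[0].start, m.exons[-1].end
            if m.gene_id in spans:
                lo = min(lo, spans[m.gene_id][0])
                hi = max(hi, spans[m.gene_id][1])
            spans[m.gene_id] = (lo, hi)
        for ev in build_all_events(models):
            lo, hi = spans[ev.gene_id]
            assert lo <= ev.core.start < ev.core.end <= hi
            for iv in ev.inclusion_junctions | ev.exclusion_junctions:
                assert lo <= iv.start < iv.end <= hi

    def test_strand_reversal_swaps_ass_kinds_only(self):
        def counts(models):
            evs = build_all_events(models)
            return {
                k: sum(1 for e in evs if e.kind == k)
                for k in ("RI", "SE", "MXE", "A5SS", "A3SS")
            }
        fwd = counts(self._mixed_models("+"))
        rev = counts(self._mixed_models("-"))
        assert fwd["RI"] == rev["RI"] and fwd["SE"] == rev["SE"]
        assert fwd["MXE"] == rev["MXE"]
        assert fwd["A5SS"] == rev["A3SS"] and fwd["A3SS"] == rev["A5SS"]

    def test_catalog_round_trip_lossless(self, tmp_path):
        events = build_all_events(self._mixed_models())
        assert len(events) >= 5
        path = tmp_path / "catalog.tsv"
        write_event_catalog(events, path)
        assert read_event_catalog(path) == events

    def test_empty_catalog_is_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_event_catalog([], path)
        assert path.read_text().count("\n") == 1
        assert read_event_catalog(path) == []

    def test_duplicate_event_id_rejected_on_read(self, tmp_path):
        events = build_ri_events([make_transcript("t", "g", [(0, 100), (200, 300)])])
        path = tmp_path / "dup.tsv"
        write_event_catalog(events, path)
        lines = path.read_text().splitlines(keepends=True)
        path.write_text("".join(lines) + lines[-1])
        with pytest.raises(CatalogFormatError, match="duplicate"):
            read_event_catalog(path)

    def test_unknown_kind_rejected_on_read(self, tmp_path):
        events = build_ri_events([make_transcript("t", "g", [(0, 100), (200, 300)])])
        path = tmp_path / "bad.tsv"
        write_event_catalog(events, path)
        path.write_text(path.read_text().replace("\tRI\t", "\tXX\t"))
        with pytest.raises(CatalogFormatError, match="kind"):
            read_event_catalog(path)
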