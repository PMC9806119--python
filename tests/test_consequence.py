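import pytest

from splicefidelity.annotation import GenomeSequence, TranscriptModel
from splicefidelity.consequence import (
    FRAME_IN,
    FRAME_NONCODING,
    FRAME_SHIFT,
    DomainTable,
    SkippedIsoform,
    classify_frame_effect,
    classify_skip,
    construct_skipped_isoform,
    domain_restoration,
    exon_protein_span,
    is_nmd_targeting,
    scan_for_ptc,
)

from .oracles import splice_translate_nmd_oracle


class TestFrameEffect:
    @pytest.mark.parametrize(
        "length,in_cds,expected",
        [(48, True, FRAME_IN), (50, True, FRAME_SHIFT), (50, False, FRAME_NONCODING)],
    )
    def test_mod3_routing(self, length, in_cds, expected):
        assert classify_frame_effect(length, in_cds) == expected

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            classify_frame_effect(0, True)


@pytest.fixture()
def utr_skip_fixture():
    """3 exons; exon 2 (4 nt) lies entirely in the 5'UTR.

    tx = e1(5) + e2(4) + e3(14); CDS = tx[10..21] = ATG AAA TGC TAA.
    """
    e1, i1, e2, i2, e3 = "GGGAA", "GTTTAG", "TTTT", "GTCCAG", "ATGAAATGCTAACC"
    genome = GenomeSequence({"c": e1 + i1 + e2 + i2 + e3})
    exons = [(1, 5), (12, 15), (22, 35)]
    t = TranscriptModel("t", "g", "c", "+", exons, cds_start=10, cds_end=21)
    return t, genome


class TestConstructSkippedIsoform:
    def test_three_exon_skip_concatenates_flanks(self, utr_skip_fixture):
        t, genome = utr_skip_fixture
        iso = construct_skipped_isoform(t, 1, genome)
        assert iso.sequence == "GGGAA" + "ATGAAATGCTAACC"
        assert iso.junction_positions == [5]

    def test_utr_skip_shifts_cds_offsets(self, utr_skip_fixture):
        t, genome = utr_skip_fixture
        iso = construct_skipped_isoform(t, 1, genome)
        assert iso.cds_start == 6  # shifted left by the 4 removed UTR bases
        assert iso.annotated_stop_start == 15
        assert iso.sequence[iso.cds_start - 1 : iso.cds_start + 2] == "ATG"

    def test_four_exon_junction_bookkeeping(self):
        parts = ["A" * 10, "GTAG", "C" * 7, "GTAG", "G" * 5, "GTAG", "T" * 8]
        genome = GenomeSequence({"c": "".join(parts)})
        exons = [(1, 10), (15, 21), (26, 30), (35, 42)]
        t = TranscriptModel("t", "g", "c", "+", exons)
        iso = construct_skipped_isoform(t, 2, genome)
        assert iso.junction_positions == [10, 17]  # len(e1), len(e1)+len(e2)

    def test_terminal_exons_unsupported(self, utr_skip_fixture):
        t, genome = utr_skip_fixture
        for bad in (0, 2):
            with pytest.raises(ValueError):
                construct_skipped_isoform(t, bad, genome)

    def test_start_codon_removal_flagged(self):
        # CDS starts inside exon 2
        e1, i1, e2, i2, e3 = "GGGAA", "GTTTAG", "ATGTT", "GTCCAG", "TAAACCGGGTTT"
        genome = GenomeSequence({"c": e1 + i1 + e2 + i2 + e3})
        t = TranscriptModel(
            "t", "g", "c", "+", [(1, 5), (12, 16), (23, 34)], cds_start=6, cds_end=13
        )
        iso = construct_skipped_isoform(t, 1, genome)
        assert iso.start_lost and iso.cds_start is None
        with pytest.raises(ValueError):
            scan_for_ptc(iso)


def _iso(sequence, cds_start, stop_start, junctions):
    return SkippedIsoform(
        transcript_id="t",
        gene_id="g",
        skipped_exon=(0, 0),
        skipped_index=1,
        sequence=sequence,
        junction_positions=junctions,
        cds_start=cds_start,
        annotated_stop_start=stop_start,
    )


class TestPtcScan:
    def test_first_in_frame_stop_found(self):
        seq = "ATG" + "AAA" * 5 + "TGA" + "CCC" * 3 + "TAA"
        iso = _iso(seq, 1, len(seq) - 2, junctions=[10])
        assert scan_for_ptc(iso) == 19

    def test_no_internal_stop_returns_none(self):
        seq = "ATG" + "AAA" * 5 + "TAA"
        iso = _iso(seq, 1, len(seq) - 2, junctions=[10])
        assert scan_for_ptc(iso) is None

    def test_out_of_frame_stop_ignored(self):
        # TAA present but offset by one from the reading frame
        seq = "ATG" + "ATAACC" + "TAA"
        iso = _iso(seq, 1, len(seq) - 2, junctions=[5])
        assert scan_for_ptc(iso) is None


class TestNmdRule:
    @pytest.mark.parametrize("distance,expected", [(51, True), (50, False), (-3, False)])
    def test_distance_boundary(self, distance, expected):
        # place a PTC so that junction - ptc_end == distance
        junction = 200
        ptc = junction - distance - 2
        iso = _iso("N" * 300, 1, 280, junctions=[100, junction])
        assert is_nmd_targeting(ptc, iso, rule_distance=50) is expected

    def test_no_junction_never_targets(self):
        iso = _iso("N" * 300, 1, 280, junctions=[])
        assert is_nmd_targeting(10, iso) is False

    def test_any_junction_variant(self):
        # PTC is far upstream of the first junction but close to the last
        iso = _iso("N" * 400, 1, 380, junctions=[200, 230])
        ptc = 100
        assert is_nmd_targeting(ptc, iso, junction_rule="last") is True
        assert is_nmd_targeting(ptc, iso, junction_rule="any") is True
        near = 195  # 3 nt upstream of first junction, 33 of last
        assert is_nmd_targeting(near, iso, junction_rule="any") is False


class TestDomainRestoration:
    @pytest.fixture()
    def coding_transcript(self):
        # 3 exons of 100/48/200 nt; CDS spans tx 10..318 (103 codons incl stop)
        genome = GenomeSequence({"c": "A" * 400})
        t = TranscriptModel(
            "t1", "g", "c", "+", [(1, 100), (111, 158), (169, 368)], cds_start=10, cds_end=318
        )
        return t

    def test_overlap_detected(self, coding_transcript):
        domains = DomainTable({"t1": [("D1", 20, 60), ("D2", 60, 90)]})
        assert domain_restoration(coding_transcript, 1, domains) == ["D1"]

    def test_no_overlap(self, coding_transcript):
        domains = DomainTable({"t1": [("D2", 60, 90)]})
        assert domain_restoration(coding_transcript, 1, domains) == []

    def test_missing_protein_warns_empty(self, coding_transcript):
        domains = DomainTable({"other": [("D1", 1, 10)]})
        assert domain_restoration(coding_transcript, 1, domains) == []

    def test_mid_codon_exon_rounds_outward(self, coding_transcript):
        # exon 2 spans tx 101..148; codons (101-10)//3+1=31 .. (148-10)//3+1=47
        assert exon_protein_span(coding_transcript, 1) == (31, 47)
        edge = DomainTable({"t1": [("E", 31, 31)]})
        assert domain_restoration(coding_transcript, 1, edge) == ["E"]


class TestOracleEquivalence:
    def test_all_internal_skips_match_brute_force(self, bundle, bundle_genome):
        """Exhaustive splice-translate-measure agreement over the fixture
        transcriptome, including the engineered 50/51-nt boundary genes."""
        n_checked = n_nmd = 0
        distances_seen = set()
        for sg in bundle.sim.genes:
            t = sg.full
            for i in range(1, len(t.exons) - 1):
                call = classify_skip(t, i, bundle_genome)
                frame, nmd = splice_translate_nmd_oracle(t, i, bundle_genome)
                assert call.frame_effect == frame, (t.transcript_id, i)
                assert call.nmd_targeting == nmd, (t.transcript_id, i)
                if call.distance_to_reference_junction is not None:
                    distances_seen.add(call.distance_to_reference_junction)
                n_checked += 1
                n_nmd += call.nmd_targeting
        assert n_checked >= 100
        assert 0 < n_nmd < n_checked
        # engineered boundary fixtures must exercise both sides of the rule
        assert {50, 51} <= distances_seen

    def test_in_frame_events_never_nmd(self, bundle, bundle_genome, bundle_index):
        for sg in bundle.sim.genes:
            if sg.frameshift:
                continue
            call = classify_skip(sg.full, sg.skip_index, bundle_genome, bundle.sim.domain_table)
            assert call.frame_effect == FRAME_IN and not call.nmd_targeting

    def test_domain_fixture_events_hit_their_domains(self, bundle, bundle_genome):
        hits = 0
        for sg in bundle.sim.genes:
            if sg.frameshift or sg.full.transcript_id not in bundle.sim.domain_table.domains:
                continue
            call = classify_skip(sg.full, sg.skip_index, bundle_genome, bundle.sim.domain_table)
            assert call.affected_domains, sg.gene_id
            hits += 1
        assert hits > 0
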