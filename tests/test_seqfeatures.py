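from collections import Counter

import numpy as np
import pytest

from splicefidelity.annotation import GenomeSequence, enumerate_introns, junction_key
from splicefidelity.seqfeatures import (
    ACCEPTOR_LEN,
    DONOR_LEN,
    SpliceSiteModel,
    acceptor_window,
    donor_window,
    exon_event_feature_summary,
    gc_content,
    intron_feature_summary,
    splice_site_score,
    train_pwm_from_annotation,
)


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [("GGCC", 1.0), ("ATAT", 0.0), ("GATC", 0.5)])
    def test_basic(self, seq, expected):
        assert gc_content(seq) == expected

    def test_n_bases_excluded_both_sides(self):
        assert gc_content("GNCN") == 1.0
        assert gc_content("ANTN") == 0.0

    def test_all_n_undefined(self):
        with pytest.raises(ValueError):
            gc_content("NNN")


class TestWindows:
    def test_plus_strand_donor_layout(self):
        # exon ...CCC | GTxxxx... intron
        genome = GenomeSequence({"c": "AAAACCCGTTTTTTAGAAAA"})
        # intron at 8..16 (GT...AG)
        w = donor_window(genome, ("c", 8, 16, "+"))
        assert w == "CCCGTTTTT" and len(w) == DONOR_LEN

    def test_minus_strand_window_is_reverse_complement_extraction(self):
        from Bio.Seq import Seq

        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=120))
        genome = GenomeSequence({"c": seq})
        rc_genome = GenomeSequence({"c": str(Seq(seq).reverse_complement())})
        L = len(seq)
        s, e = 40, 80
        plus = donor_window(genome, ("c", s, e, "+"))
        minus = donor_window(rc_genome, ("c", L - e + 1, L - s + 1, "-"))
        assert plus == minus
        plus_a = acceptor_window(genome, ("c", s, e, "+"))
        minus_a = acceptor_window(rc_genome, ("c", L - e + 1, L - s + 1, "-"))
        assert plus_a == minus_a


def _uniform_model():
    return SpliceSiteModel(
        donor_pwm=np.full((4, DONOR_LEN), 0.25),
        acceptor_pwm=np.full((4, ACCEPTOR_LEN), 0.25),
        background=np.full(4, 0.25),
    )


class TestScoring:
    def test_uniform_model_scores_zero(self):
        assert splice_site_score(_uniform_model(), "ACGTACGTA", "donor") == 0.0

    def test_hand_computed_two_position_deviation(self):
        model = _uniform_model()
        model.donor_pwm = model.donor_pwm.copy()
        model.donor_pwm[:, 0] = [0.5, 0.5 / 3, 0.5 / 3, 0.5 / 3]  # A enriched
        model.donor_pwm[:, 1] = [0.125, 0.125, 0.625, 0.125]  # G enriched
        # window "AG..." scores log2(0.5/0.25) + log2(0.625/0.25) = 1 + 1.3219
        score = splice_site_score(model, "AGAAAAAAA", "donor")
        assert score == pytest.approx(1.0 + np.log2(0.625 / 0.25))

    def test_n_contributes_zero(self):
        model = _uniform_model()
        model.donor_pwm = model.donor_pwm.copy()
        model.donor_pwm[:, 0] = [0.97, 0.01, 0.01, 0.01]
        assert splice_site_score(model, "NAAAAAAAA", "donor") == 0.0

    def test_wrong_window_length_rejected(self):
        with pytest.raises(ValueError):
            splice_site_score(_uniform_model(), "ACGT", "donor")
        with pytest.raises(ValueError):
            splice_site_score(_uniform_model(), "A" * 9, "acceptor")


class TestTraining:
    def test_trained_consensus_has_gt_ag(self, bundle_index, bundle_genome):
        model = train_pwm_from_annotation(bundle_index, bundle_genome)
        g, t = 2, 3  # base indices in ACGT
        assert model.donor_pwm[g, 3] > 0.9 and model.donor_pwm[t, 4] > 0.9  # GT
        a = 0
        assert model.acceptor_pwm[a, 18] > 0.9 and model.acceptor_pwm[g, 19] > 0.9  # AG

    def test_columns_are_stochastic(self, bundle_index, bundle_genome):
        model = train_pwm_from_annotation(bundle_index, bundle_genome)
        assert np.allclose(model.donor_pwm.sum(axis=0), 1.0)
        assert np.allclose(model.acceptor_pwm.sum(axis=0), 1.0)

    def test_frequencies_match_brute_force_count(self, bundle_index, bundle_genome):
        model = train_pwm_from_annotation(bundle_index, bundle_genome, pseudocount=1.0)
        counts = Counter()
        n = 0
        for key in bundle_index.junctions:
            w = donor_window(bundle_genome, key)
            counts[w[0]] += 1
            n += 1
        for bi, base in enumerate("ACGT"):
            expected = (counts[base] + 1.0) / (n + 4.0)
            assert model.donor_pwm[bi, 0] == pytest.approx(expected)

    def test_own_site_scores_highest_with_zero_pseudocount(self):
        genome = GenomeSequence({"c": "AAACCCGTTTGCATAGGGTTT"})
        # single annotated junction 7..16 drives the model
        from splicefidelity.annotation import AnnotationIndex, GeneModel, TranscriptModel

        t = TranscriptModel("t", "g", "c", "+", [(1, 6), (17, 21)])
        idx = AnnotationIndex({"g": GeneModel("g", "c", "+", [t])})
        model = train_pwm_from_annotation(idx, genome, pseudocount=1e-9)
        own = donor_window(genome, ("c", 7, 16, "+"))
        best = splice_site_score(model, own, "donor")
        rng = np.random.default_rng(1)
        for _ in range(50):
            variant = list(own)
            pos = int(rng.integers(0, DONOR_LEN))
            variant[pos] = rng.choice([b for b in "ACGT" if b != own[pos]])
            assert splice_site_score(model, "".join(variant), "donor") < best


class TestFeatureSummary:
    def test_self_comparison_has_zero_differences(self, bundle, bundle_index, bundle_genome):
        from splicefidelity.inclusion import ExonEvent

        events = []
        for gid in sorted(bundle_index.multi_exon_genes(10.0)):
            for t in bundle_index.genes[gid].transcripts:
                for i in range(1, len(t.exons) - 1):
                    events.append(
                        ExonEvent(
                            event_id=f"{t.transcript_id}:{i}",
                            gene_id=gid,
                            contig=t.contig,
                            strand=t.strand,
                            exon=t.exons[i],
                            upstream_exon=t.exons[i - 1],
                            downstream_exon=t.exons[i + 1],
                            inclusion_reads=10,
                            skip_reads=0,
                        )
                    )
        summary = exon_event_feature_summary(events, bundle_index, bundle_genome)
        for row in summary.table.itertuples():
            assert row.set_mean == pytest.approx(row.baseline_mean)
            assert row.set_median == pytest.approx(row.baseline_median)

    def test_short_intron_set_departs_from_baseline(self, bundle, bundle_index, bundle_genome):
        from splicefidelity.retention import IntronRecord

        introns = []
        for gid in bundle_index.multi_exon_genes(10.0):
            for t in bundle_index.genes[gid].transcripts:
                for iv in enumerate_introns(t):
                    introns.append((t.contig, iv, t.strand, gid))
        introns.sort(key=lambda x: x[1][1] - x[1][0])
        short = [
            IntronRecord(gid, c, iv[0], iv[1], s, 10.0, 10)
            for c, iv, s, gid in introns[:20]
        ]
        summary = intron_feature_summary(short, bundle_index, bundle_genome)
        row = summary.table.set_index("feature").loc["intron_length"]
        assert row.set_mean < row.baseline_mean

    def test_empty_set_rejected(self, bundle_index, bundle_genome):
        with pytest.raises(ValueError):
            exon_event_feature_summary([], bundle_index, bundle_genome)
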