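"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's bookkeeping code paths: they work on
plain spliced strings, exhaustive enumeration, and exact rational
arithmetic, so agreement with the implementation is a meaningful check.
"""

from fractions import Fraction
from math import comb

from Bio.Seq import Seq


def splice_translate_nmd_oracle(t, exon_index, genome, rule_distance=50):
    """Literal splice -> translate -> measure call for one exon skip.

    Returns (frame_effect, nmd_targeting). Only out-of-frame CDS-overlapping
    skips are scanned for a PTC; the PTC must end more than ``rule_distance``
    nt upstream of the last exon-exon junction of the spliced-out isoform.
    """
    exon_seqs = [genome.fetch(t.contig, s, e, t.strand) for s, e in t.exons]
    lens = [len(s) for s in exon_seqs]
    starts = [sum(lens[:i]) + 1 for i in range(len(lens))]  # tx coord of each exon start
    a = starts[exon_index]
    b = a + lens[exon_index] - 1

    if t.cds_start is None:
        return "noncoding", False
    overlap = max(0, min(b, t.cds_end) - max(a, t.cds_start) + 1)
    if overlap == 0:
        return "noncoding", False
    if overlap % 3 == 0:
        return "in_frame", False

    if a <= t.cds_start <= b:  # start codon removed: nothing to translate
        return "frameshift", False

    new_seq = "".join(s for i, s in enumerate(exon_seqs) if i != exon_index)
    new_lens = [l for i, l in enumerate(lens) if i != exon_index]
    junctions = [sum(new_lens[: i + 1]) for i in range(len(new_lens) - 1)]

    cds_start = t.cds_start - (lens[exon_index] if b < t.cds_start else 0)
    stop_first = t.cds_end - 2
    if b < stop_first:
        stop_first -= lens[exon_index]
    elif a <= t.cds_end and b >= stop_first:
        stop_first = None  # annotated stop removed

    tail = new_seq[cds_start - 1 :]
    prot = str(Seq(tail[: len(tail) - len(tail) % 3]).translate())
    idx = prot.find("*")
    if idx == -1:
        return "frameshift", False
    ptc_start = cds_start + 3 * idx
    if stop_first is not None and ptc_start >= stop_first:
        return "frameshift", False  # translation reached the annotated stop
    if not junctions:
        return "frameshift", False
    return "frameshift", junctions[-1] - (ptc_start + 2) > rule_distance


def hypergeom_upper_tail_exact(k, N, K, n):
    """P(X >= k) by exact rational enumeration."""
    total = comb(N, n)
    s = sum(comb(K, i) * comb(N - K, n - i) for i in range(max(k, 0), min(K, n) + 1))
    return Fraction(s, total)


def fisher_two_sided_exact(a, b, c, d):
    """Two-sided Fisher p by enumeration: sum of table probabilities no
    larger than the observed table's (scipy's definition), exact rationals."""
    row1, row2 = a + b, c + d
    col1 = a + c
    N = row1 + row2
    denom = comb(N, col1)
    probs = {}
    for i in range(max(0, col1 - row2), min(row1, col1) + 1):
        probs[i] = Fraction(comb(row1, i) * comb(row2, col1 - i), denom)
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs)
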