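"""Gene annotation and genome models.

Parses a GTF (Ensembl attribute dialect) and a genome FASTA into queryable
gene/transcript/exon structures, and enumerates the annotated splice-junction
universe that every downstream classification is tested against.

Coordinate conventions (used package-wide):

* All genomic coordinates are 1-based and fully inclusive, matching both GTF
  and the STAR ``SJ.out.tab`` dialect.
* A splice junction is identified by the tuple
  ``(contig, first intronic base, last intronic base, strand)``.
* The *donor* is the intron boundary at the 5' end in transcript orientation:
  on the plus strand the donor position is the intron start, on the minus
  strand it is the intron end. Donor/acceptor sets are strand-aware.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from intervaltree import IntervalTree

#: (contig, intron_start, intron_end, strand)
JunctionKey = tuple[str, int, int, str]
#: (contig, position, strand)
SiteKey = tuple[str, int, str]


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation inputs."""


class GenomeSequence:
    """Uppercase nucleotide sequences keyed by contig name.

    ``fetch`` returns the reverse complement for minus-strand queries, so all
    strand handling funnels through one place.
    """

    def __init__(self, contigs: dict[str, str]):
        self.contigs = {name: seq.upper() for name, seq in contigs.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """Return the sequence of ``[start, end]`` (1-based inclusive).

        Minus-strand queries return the reverse complement.
        """
        if contig not in self.contigs:
            raise AnnotationError(f"unknown contig {contig!r}")
        seq = self.contigs[contig]
        if start < 1 or end > len(seq) or start > end:
            raise AnnotationError(
                f"coordinates {contig}:{start}-{end} outside contig bounds (1-{len(seq)})"
            )
        sub = seq[start - 1 : end]
        if strand == "-":
            return str(Seq(sub).reverse_complement())
        return sub


@dataclass
class TranscriptModel:
    """An ordered exon chain with an optional coding region.

    ``exons`` are genomic ``(start, end)`` intervals sorted 5'->3' in
    transcript orientation (descending genomic coordinates on the minus
    strand). ``cds_start``/``cds_end`` are 1-based *transcript* coordinates of
    the first and last coding base (stop codon included), or ``None`` for
    non-coding transcripts.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 <= e1 + 1:
                raise AnnotationError(
                    f"{self.transcript_id}: exons {s1}-{e1} and {s2}-{e2} overlap "
                    "or lack an intronic gap"
                )
        self.exons = genomic if self.strand == "+" else genomic[::-1]

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        starts, ends = zip(*self.exons)
        return min(starts), max(ends)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    def exon_tx_offsets(self) -> list[tuple[int, int]]:
        """Transcript-coordinate span of each exon, in transcript order."""
        out, pos = [], 0
        for s, e in self.exons:
            out.append((pos + 1, pos + (e - s + 1)))
            pos += e - s + 1
        return out

    def genomic_to_tx(self, pos: int) -> int:
        """Map a genomic position (must be exonic) to transcript coordinates."""
        off = 0
        for s, e in self.exons:
            if s <= pos <= e:
                return off + (pos - s + 1 if self.strand == "+" else e - pos + 1)
            off += e - s + 1
        raise AnnotationError(f"{self.transcript_id}: position {pos} is not exonic")


@dataclass
class GeneModel:
    gene_id: str
    contig: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)
    tpm: float = 0.0

    @property
    def span(self) -> tuple[int, int]:
        spans = [t.span for t in self.transcripts]
        return min(s for s, _ in spans), max(e for _, e in spans)


def enumerate_introns(t: TranscriptModel) -> list[tuple[int, int]]:
    """Genomic intron intervals between consecutive exons, in transcript order.

    Each interval is 1-based inclusive of the first and last intronic base.
    A single-exon transcript yields an empty list.
    """
    introns = []
    for (s1, e1), (s2, e2) in zip(t.exons, t.exons[1:]):
        if t.strand == "+":
            introns.append((e1 + 1, s2 - 1))
        else:
            introns.append((e2 + 1, s1 - 1))
    return introns


def transcript_sequence(t: TranscriptModel, genome: GenomeSequence) -> str:
    """Concatenated exonic sequence in 5'->3' transcript orientation."""
    return "".join(genome.fetch(t.contig, s, e, t.strand) for s, e in t.exons)


def junction_key(contig: str, intron: tuple[int, int], strand: str) -> JunctionKey:
    return (contig, intron[0], intron[1], strand)


def donor_site(key: JunctionKey) -> SiteKey:
    """Donor = first intronic base in transcript orientation."""
    contig, start, end, strand = key
    return (contig, start if strand == "+" else end, strand)


def acceptor_site(key: JunctionKey) -> SiteKey:
    """Acceptor = last intronic base in transcript orientation."""
    contig, start, end, strand = key
    return (contig, end if strand == "+" else start, strand)


class AnnotationIndex:
    """Cross-linked annotation: genes, junction universe, splice-site sets."""

    def __init__(self, genes: dict[str, GeneModel]):
        self.genes = genes
        self.junctions: set[JunctionKey] = set()
        self.donors: set[SiteKey] = set()
        self.acceptors: set[SiteKey] = set()
        self.gene_junctions: dict[str, set[JunctionKey]] = {}
        self._trees: dict[str, IntervalTree] = {}
        for gene in genes.values():
            keys = set()
            for t in gene.transcripts:
                for intron in enumerate_introns(t):
                    keys.add(junction_key(t.contig, intron, t.strand))
            self.gene_junctions[gene.gene_id] = keys
            self.junctions |= keys
            for key in keys:
                self.donors.add(donor_site(key))
                self.acceptors.add(acceptor_site(key))
            s, e = gene.span
            self._trees.setdefault(gene.contig, IntervalTree()).addi(
                s, e + 1, gene.gene_id
            )

    def genes_overlapping(self, contig: str, start: int, end: int, strand: str | None = None) -> list[GeneModel]:
        tree = self._trees.get(contig)
        if tree is None:
            return []
        hits = [self.genes[iv.data] for iv in tree.overlap(start, end + 1)]
        if strand is not None:
            hits = [g for g in hits if g.strand == strand]
        return hits

    def assign_gene(self, contig: str, start: int, end: int, strand: str) -> str | None:
        """Assign a junction to the highest-TPM same-strand overlapping gene.

        Ties break to the lexicographically smallest gene_id.
        """
        hits = self.genes_overlapping(contig, start, end, strand)
        if not hits:
            return None
        return min(hits, key=lambda g: (-g.tpm, g.gene_id)).gene_id

    def multi_exon_genes(self, tpm_gate: float | None = None) -> set[str]:
        """Genes with >= 1 annotated junction, optionally gated at tpm > gate."""
        out = {g for g, keys in self.gene_junctions.items() if keys}
        if tpm_gate is not None:
            out = {g for g in out if self.genes[g].tpm > tpm_gate}
        return out


def _parse_gtf(gtf_path: str | Path) -> dict[str, GeneModel]:
    try:
        db = gffutils.create_db(
            str(gtf_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises heterogeneous parse errors
        raise AnnotationError(f"failed to parse GTF {gtf_path}: {exc}") from exc

    genes: dict[str, GeneModel] = {}
    for gf in db.features_of_type("gene"):
        gid = gf.attributes["gene_id"][0]
        genes[gid] = GeneModel(gene_id=gid, contig=gf.seqid, strand=gf.strand)
    for tf in db.features_of_type("transcript"):
        gid = tf.attributes["gene_id"][0]
        tid = tf.attributes["transcript_id"][0]
        if gid not in genes:
            genes[gid] = GeneModel(gene_id=gid, contig=tf.seqid, strand=tf.strand)
        exons = []
        for ex in db.children(tf, featuretype="exon", order_by="start"):
            if ex.seqid != tf.seqid:
                raise AnnotationError(
                    f"exon on contig {ex.seqid} outside transcript {tid} contig {tf.seqid}"
                )
            exons.append((ex.start, ex.end))
        t = TranscriptModel(
            transcript_id=tid, gene_id=gid, contig=tf.seqid, strand=tf.strand, exons=exons
        )
        cds = [(c.start, c.end) for c in db.children(tf, featuretype="CDS")]
        if cds:
            g_lo = min(s for s, _ in cds)
            g_hi = max(e for _, e in cds)
            # transcript coords of the CDS boundaries; stop codon included
            if t.strand == "+":
                t.cds_start, t.cds_end = t.genomic_to_tx(g_lo), t.genomic_to_tx(g_hi)
            else:
                t.cds_start, t.cds_end = t.genomic_to_tx(g_hi), t.genomic_to_tx(g_lo)
            if (t.cds_end - t.cds_start + 1) % 3 != 0:
                raise AnnotationError(f"{tid}: CDS length not divisible by 3")
        genes[gid].transcripts.append(t)
    return genes


def read_expression_table(path: str | Path) -> dict[str, float]:
    """TSV with header ``gene_id<TAB>tpm`` -> {gene_id: tpm}."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "tpm"} <= set(df.columns):
        raise AnnotationError(f"{path}: expected columns gene_id, tpm")
    if (df["tpm"] < 0).any():
        raise AnnotationError(f"{path}: negative TPM values")
    return dict(zip(df["gene_id"], df["tpm"].astype(float)))


def load_annotation(
    gtf_path: str | Path, expression_table: str | Path | None = None
) -> AnnotationIndex:
    """Parse a GTF (+ optional TPM table) into a cross-linked AnnotationIndex.

    Genes absent from the expression table get tpm = 0 and are therefore
    excluded by any ``tpm > gate`` filter downstream.
    """
    genes = _parse_gtf(gtf_path)
    if expression_table is not None:
        tpm = read_expression_table(expression_table)
        for gid, gene in genes.items():
            gene.tpm = tpm.get(gid, 0.0)
    return AnnotationIndex(genes)


def validate_against_genome(idx: AnnotationIndex, genome: GenomeSequence) -> None:
    """Check every exon lies within its contig; raise AnnotationError if not."""
    for gene in idx.genes.values():
        if gene.contig not in genome:
            raise AnnotationError(f"{gene.gene_id}: contig {gene.contig} not in genome")
        clen = genome.length(gene.contig)
        for t in gene.transcripts:
            for s, e in t.exons:
                if s < 1 or e > clen:
                    raise AnnotationError(
                        f"{t.transcript_id}: exon {s}-{e} outside contig {gene.contig}"
                    )
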