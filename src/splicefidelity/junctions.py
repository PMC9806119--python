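"""Splice-junction catalogues and the high-confidence unannotated filter.

Reads STAR ``SJ.out.tab``-style junction tables, classifies each canonical
junction against the annotated junction/site universe, and applies the
10%-of-max selection rule: within each robustly expressed gene (TPM > 10),
an unannotated junction is kept when its uniquely mapping read count is at
least 10% of the read count of that gene's highest-depth annotated junction
observed in the same sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotation import (
    AnnotationIndex,
    JunctionKey,
    acceptor_site,
    donor_site,
)

log = logging.getLogger(__name__)

STATUS_ANNOTATED = "annotated"
STATUS_NOVEL_PAIRING = "both_sites_annotated_novel_pairing"
STATUS_DONOR_ONLY = "donor_only_annotated"
STATUS_ACCEPTOR_ONLY = "acceptor_only_annotated"
STATUS_NEITHER = "neither_annotated"

UNANNOTATED_STATUSES = frozenset(
    {STATUS_NOVEL_PAIRING, STATUS_DONOR_ONLY, STATUS_ACCEPTOR_ONLY, STATUS_NEITHER}
)

_STRAND_CODE = {0: ".", 1: "+", 2: "-"}
#: STAR motif codes 1 (GT/AG) and 2 (CT/AC) are the canonical GT-AG pattern
#: on the plus and minus strand respectively.
_CANONICAL_MOTIFS = {1: "+", 2: "-"}


class JunctionTableError(ValueError):
    """Raised for malformed junction tables."""


@dataclass
class SpliceJunction:
    """A strand-aware intron interval with read support (1-based inclusive)."""

    contig: str
    intron_start: int
    intron_end: int
    strand: str
    canonical: bool
    unique_reads: int
    multi_reads: int = 0
    max_overhang: int = 0
    assigned_gene: str | None = None
    status: str | None = None

    def __post_init__(self) -> None:
        if self.intron_start > self.intron_end:
            raise JunctionTableError(
                f"intron_start {self.intron_start} > intron_end {self.intron_end}"
            )
        if self.unique_reads < 0 or self.multi_reads < 0:
            raise JunctionTableError("negative read counts")

    @property
    def key(self) -> JunctionKey:
        return (self.contig, self.intron_start, self.intron_end, self.strand)


def read_junction_table(path: str | Path) -> list[SpliceJunction]:
    """Parse a 9-column STAR ``SJ.out.tab`` dialect file.

    Columns: contig, intron start, intron end, strand code (0/1/2), motif
    code (0-6), annotated flag, unique reads, multimapping reads, max
    overhang. Strand code 0 (undetermined) is resolved from a canonical
    motif when possible. Non-canonical rows are retained but flagged.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    if df.shape[1] != 9:
        raise JunctionTableError(f"{path}: expected 9 columns, got {df.shape[1]}")
    out = []
    for row in df.itertuples(index=False):
        contig, start, end, strand_code, motif, _ann, uniq, multi, overhang = row
        strand = _STRAND_CODE.get(int(strand_code))
        if strand is None:
            raise JunctionTableError(f"{path}: bad strand code {strand_code}")
        canonical = int(motif) in _CANONICAL_MOTIFS
        if strand == "." and canonical:
            strand = _CANONICAL_MOTIFS[int(motif)]
        out.append(
            SpliceJunction(
                contig=str(contig),
                intron_start=int(start),
                intron_end=int(end),
                strand=strand,
                canonical=canonical,
                unique_reads=int(uniq),
                multi_reads=int(multi),
                max_overhang=int(overhang),
            )
        )
    return out


def classify_junction(j: SpliceJunction, idx: AnnotationIndex) -> str:
    """Annotation status of one junction against the annotated universe.

    ``annotated`` on an exact junction-tuple match; otherwise the status
    records which of the two splice sites (donor/acceptor, strand-aware)
    appear in the annotated site sets.
    """
    key = j.key
    if key in idx.junctions:
        return STATUS_ANNOTATED
    donor_known = donor_site(key) in idx.donors
    acceptor_known = acceptor_site(key) in idx.acceptors
    if donor_known and acceptor_known:
        return STATUS_NOVEL_PAIRING
    if donor_known:
        return STATUS_DONOR_ONLY
    if acceptor_known:
        return STATUS_ACCEPTOR_ONLY
    return STATUS_NEITHER


def annotate_junctions(
    junctions: list[SpliceJunction], idx: AnnotationIndex
) -> list[SpliceJunction]:
    """Assign genes and statuses in place; returns the same list.

    Junctions with undetermined strand are left unassigned (and logged), as
    are junctions overlapping no same-strand gene.
    """
    skipped = 0
    for j in junctions:
        if j.strand == ".":
            skipped += 1
            continue
        j.assigned_gene = idx.assign_gene(j.contig, j.intron_start, j.intron_end, j.strand)
        if j.assigned_gene is None:
            skipped += 1
            continue
        j.status = classify_junction(j, idx)
    if skipped:
        log.warning("%d junctions left unclassified (no strand or no gene)", skipped)
    return junctions


@dataclass
class UnannotatedCallSet:
    """High-confidence unannotated junctions for one sample."""

    sample_id: str
    kept: list[SpliceJunction]
    #: per gene, the max unique-read depth over observed annotated junctions
    max_annotated_depth: dict[str, int]
    genes_with_unannotated: set[str] = field(default_factory=set)
    tpm_gate: float = 10.0
    fraction: float = 0.1


def select_high_confidence_unannotated(
    junctions: list[SpliceJunction],
    idx: AnnotationIndex,
    *,
    sample_id: str = "sample",
    tpm_gate: float = 10.0,
    fraction: float = 0.1,
) -> UnannotatedCallSet:
    """Apply the 10%-of-max rule within expressed genes.

    Only genes with tpm > ``tpm_gate`` are considered. Per gene, D is the
    maximum unique-read count over the gene's *annotated* junctions observed
    in this sample; unannotated canonical junctions with unique_reads >=
    ``fraction``*D are kept ("at least 10%" is inclusive). Genes with no
    observed annotated junction reads (D undefined or 0) are skipped.
    """
    annotate_junctions(junctions, idx)
    max_depth: dict[str, int] = {}
    for j in junctions:
        if j.status == STATUS_ANNOTATED and j.assigned_gene is not None:
            g = j.assigned_gene
            max_depth[g] = max(max_depth.get(g, 0), j.unique_reads)
    kept = []
    for j in junctions:
        if not j.canonical or j.status not in UNANNOTATED_STATUSES:
            continue
        g = j.assigned_gene
        if g is None or idx.genes[g].tpm <= tpm_gate:
            continue
        d = max_depth.get(g, 0)
        if d <= 0:
            continue
        if j.unique_reads >= fraction * d:
            kept.append(j)
    call_set = UnannotatedCallSet(
        sample_id=sample_id,
        kept=kept,
        max_annotated_depth=max_depth,
        genes_with_unannotated={j.assigned_gene for j in kept},
        tpm_gate=tpm_gate,
        fraction=fraction,
    )
    log.info(
        "%s: %d junctions read, %d kept unannotated in %d genes",
        sample_id,
        len(junctions),
        len(kept),
        len(call_set.genes_with_unannotated),
    )
    return call_set


def gene_unannotated_proportion(call_set: UnannotatedCallSet, idx: AnnotationIndex) -> float:
    """Fraction of eligible genes carrying >= 1 kept unannotated junction.

    Eligible genes: multi-exon, tpm > gate, and >= 1 annotated junction with
    observed reads in the sample (so the 10%-of-max denominator is defined).
    """
    eligible = {
        g
        for g in idx.multi_exon_genes(call_set.tpm_gate)
        if call_set.max_annotated_depth.get(g, 0) > 0
    }
    if not eligible:
        raise ValueError("no eligible expressed genes; proportion undefined")
    return len(call_set.genes_with_unannotated & eligible) / len(eligible)


def consistent_unannotated_genes(call_sets: list[UnannotatedCallSet]) -> set[str]:
    """Genes with unannotated splicing in *all* replicates (set intersection)."""
    if not call_sets:
        return set()
    out = set(call_sets[0].genes_with_unannotated)
    for cs in call_sets[1:]:
        out &= cs.genes_with_unannotated
    return out


def call_set_to_frame(junctions: list[SpliceJunction], call_set: UnannotatedCallSet) -> pd.DataFrame:
    """Long-format per-junction table (stable output schema)."""
    kept_keys = {j.key for j in call_set.kept}
    rows = [
        {
            "contig": j.contig,
            "intron_start": j.intron_start,
            "intron_end": j.intron_end,
            "strand": j.strand,
            "status": j.status if j.status else "unclassified",
            "unique_reads": j.unique_reads,
            "gene_id": j.assigned_gene if j.assigned_gene else "",
            "kept": j.key in kept_keys,
        }
        for j in junctions
    ]
    return pd.DataFrame(rows)
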