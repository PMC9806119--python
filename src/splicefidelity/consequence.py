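"""Consequence classification of skipped-exon events.

A skipped exon that overlaps the coding sequence either preserves the
reading frame (CDS-overlapping length divisible by 3) or shifts it.
Frame-shifting skips are scanned for a premature termination codon (PTC) in
the new reading frame; when the PTC lies more than 50 nt upstream of the
final exon-exon junction of the skipped isoform, the event is called
potentially NMD-targeting (the classical exon-junction-complex distance
rule). In-frame skips are mapped to protein coordinates and intersected
with a user-supplied conserved-domain table.

Distances are measured as the number of nucleotides between the last base
of the stop codon and the last base of the exon upstream of the junction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotation import AnnotationIndex, GenomeSequence, TranscriptModel, transcript_sequence

log = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}

FRAME_IN = "in_frame"
FRAME_SHIFT = "frameshift"
FRAME_NONCODING = "noncoding"


def classify_frame_effect(exon_length: int, in_cds: bool) -> str:
    """Frame consequence of removing ``exon_length`` coding nucleotides.

    For exons partially overlapping the CDS, pass the CDS-overlapping length
    (see :func:`cds_overlap_length`): only coding bases shift the frame.
    """
    if exon_length <= 0:
        raise ValueError("exon_length must be positive")
    if not in_cds:
        return FRAME_NONCODING
    return FRAME_IN if exon_length % 3 == 0 else FRAME_SHIFT


def cds_overlap_length(t: TranscriptModel, exon_index: int) -> int:
    """Number of coding bases in the exon at ``exon_index`` (tx orientation)."""
    if not t.is_coding:
        return 0
    a, b = t.exon_tx_offsets()[exon_index]
    return max(0, min(b, t.cds_end) - max(a, t.cds_start) + 1)


@dataclass
class SkippedIsoform:
    """A transcript with one internal exon removed, CDS offsets remapped."""

    transcript_id: str
    gene_id: str
    skipped_exon: tuple[int, int]
    skipped_index: int
    sequence: str
    #: transcript coords of the last base before each exon-exon junction
    junction_positions: list[int]
    cds_start: int | None
    #: remapped transcript coord of the first base of the parent's stop codon
    annotated_stop_start: int | None
    start_lost: bool = False
    stop_lost: bool = False


def construct_skipped_isoform(
    t: TranscriptModel, exon_index: int, genome: GenomeSequence
) -> SkippedIsoform:
    """Remove an internal exon and rebuild sequence, junctions and CDS offsets.

    ``exon_index`` is 0-based in transcript orientation; first/last exons
    cannot be skipped (the flanking junctions would not both exist).
    """
    if exon_index <= 0 or exon_index >= len(t.exons) - 1:
        raise ValueError(
            f"{t.transcript_id}: exon {exon_index} is not internal; skip unsupported"
        )
    offsets = t.exon_tx_offsets()
    a, b = offsets[exon_index]
    skip_len = b - a + 1
    parent_seq = transcript_sequence(t, genome)
    new_seq = parent_seq[: a - 1] + parent_seq[b:]

    new_exons = [ex for i, ex in enumerate(t.exons) if i != exon_index]
    junctions, pos = [], 0
    for s, e in new_exons[:-1]:
        pos += e - s + 1
        junctions.append(pos)

    cds_start = t.cds_start
    stop_start = t.cds_end - 2 if t.is_coding else None
    start_lost = stop_lost = False
    if t.is_coding:
        # remap CDS start
        if b < t.cds_start:
            cds_start = t.cds_start - skip_len
        elif a <= t.cds_start <= b:
            start_lost, cds_start = True, None
        # remap the annotated stop codon [stop_start, stop_start + 2]
        if b < stop_start:
            stop_start -= skip_len
        elif a <= stop_start + 2 and b >= stop_start:
            stop_lost, stop_start = True, None
    else:
        cds_start = None

    return SkippedIsoform(
        transcript_id=t.transcript_id,
        gene_id=t.gene_id,
        skipped_exon=t.exons[exon_index],
        skipped_index=exon_index,
        sequence=new_seq,
        junction_positions=junctions,
        cds_start=cds_start,
        annotated_stop_start=stop_start,
        start_lost=start_lost,
        stop_lost=stop_lost,
    )


def scan_for_ptc(iso: SkippedIsoform) -> int | None:
    """First in-frame stop codon strictly upstream of the remapped annotated
    stop, as a 1-based transcript coordinate of the codon's first base.

    Returns ``None`` when translation reaches the annotated stop (or no stop
    exists). Isoforms whose start codon was destroyed are not scannable.
    """
    if iso.cds_start is None:
        if iso.start_lost:
            raise ValueError(f"{iso.transcript_id}: CDS start lost; no PTC scan")
        raise ValueError(f"{iso.transcript_id}: non-coding isoform; no PTC scan")
    s = iso.cds_start
    n = len(iso.sequence)
    while s + 2 <= n:
        codon = iso.sequence[s - 1 : s + 2]
        if codon in STOP_CODONS:
            if iso.annotated_stop_start is None:
                return s  # annotated stop destroyed: any in-frame stop is premature
            return s if s < iso.annotated_stop_start else None
        s += 3
    return None


def is_nmd_targeting(
    ptc_position: int,
    iso: SkippedIsoform,
    rule_distance: int = 50,
    junction_rule: str = "last",
) -> bool:
    """Distance rule: PTC more than ``rule_distance`` nt upstream of a junction.

    ``junction_rule='last'`` (default) tests the final exon-exon junction —
    the canonical exon-junction-complex rule; ``'any'`` accepts any junction
    downstream of the PTC. Single-junction-free isoforms are never targets.
    """
    if not iso.junction_positions:
        return False
    ptc_end = ptc_position + 2
    if junction_rule == "last":
        candidates = [iso.junction_positions[-1]]
    elif junction_rule == "any":
        candidates = iso.junction_positions
    else:
        raise ValueError(f"unknown junction_rule {junction_rule!r}")
    return any(j - ptc_end > rule_distance for j in candidates)


@dataclass
class DomainTable:
    """Protein-coordinate conserved-domain intervals (1-based inclusive)."""

    domains: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DomainTable":
        df = pd.read_csv(path, sep="\t")
        required = {"protein_id", "domain_id", "aa_start", "aa_end"}
        if not required <= set(df.columns):
            raise ValueError(f"{path}: expected columns {sorted(required)}")
        table = cls()
        for row in df.itertuples(index=False):
            if row.aa_start > row.aa_end:
                raise ValueError(f"{path}: inverted domain interval {row.domain_id}")
            table.domains.setdefault(str(row.protein_id), []).append(
                (str(row.domain_id), int(row.aa_start), int(row.aa_end))
            )
        return table

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"protein_id": pid, "domain_id": d, "aa_start": s, "aa_end": e}
            for pid, doms in sorted(self.domains.items())
            for d, s, e in doms
        ]
        return pd.DataFrame(rows, columns=["protein_id", "domain_id", "aa_start", "aa_end"])


def exon_protein_span(t: TranscriptModel, exon_index: int) -> tuple[int, int] | None:
    """Amino-acid interval encoded by an exon, rounded outward to whole codons.

    Exons starting mid-codon (phase != 0) include the junction-spanning
    codon on both sides. ``None`` when the exon does not overlap the CDS.
    """
    if not t.is_coding:
        return None
    a, b = t.exon_tx_offsets()[exon_index]
    lo = max(a, t.cds_start)
    hi = min(b, t.cds_end)
    if lo > hi:
        return None
    protein_len = (t.cds_end - t.cds_start + 1) // 3 - 1  # stop codon excluded
    aa_start = (lo - t.cds_start) // 3 + 1
    aa_end = (hi - t.cds_start) // 3 + 1
    return max(1, aa_start), min(protein_len, aa_end) if protein_len >= 1 else aa_end


def domain_restoration(
    t: TranscriptModel, exon_index: int, domains: DomainTable
) -> list[str]:
    """Domain ids overlapping the skipped exon's protein span by >= 1 aa.

    The protein id convention is the transcript id. Proteins absent from the
    table yield an empty list (with a warning).
    """
    span = exon_protein_span(t, exon_index)
    if span is None:
        return []
    if t.transcript_id not in domains.domains:
        log.warning("protein %s absent from domain table", t.transcript_id)
        return []
    aa_start, aa_end = span
    return [
        d
        for d, s, e in domains.domains[t.transcript_id]
        if s <= aa_end and e >= aa_start
    ]


@dataclass
class ConsequenceCall:
    event_id: str
    transcript_id: str
    frame_effect: str
    nmd_targeting: bool = False
    ptc_position: int | None = None
    distance_to_reference_junction: int | None = None
    affected_domains: list[str] = field(default_factory=list)
    start_lost: bool = False


def classify_skip(
    t: TranscriptModel,
    exon_index: int,
    genome: GenomeSequence,
    domains: DomainTable | None = None,
    *,
    event_id: str | None = None,
    rule_distance: int = 50,
    junction_rule: str = "last",
) -> ConsequenceCall:
    """Full consequence call for skipping one internal exon of one transcript."""
    eid = event_id or f"{t.transcript_id}:skip{exon_index}"
    overlap = cds_overlap_length(t, exon_index)
    effect = classify_frame_effect(
        overlap if overlap > 0 else (t.exons[exon_index][1] - t.exons[exon_index][0] + 1),
        in_cds=overlap > 0,
    )
    call = ConsequenceCall(event_id=eid, transcript_id=t.transcript_id, frame_effect=effect)
    if effect == FRAME_NONCODING:
        return call
    iso = construct_skipped_isoform(t, exon_index, genome)
    if iso.start_lost:
        call.start_lost = True
        return call
    if effect == FRAME_IN:
        if domains is not None:
            call.affected_domains = domain_restoration(t, exon_index, domains)
        return call
    ptc = scan_for_ptc(iso)
    if ptc is not None:
        call.ptc_position = ptc
        if iso.junction_positions:
            call.distance_to_reference_junction = iso.junction_positions[-1] - (ptc + 2)
        call.nmd_targeting = is_nmd_targeting(
            ptc, iso, rule_distance=rule_distance, junction_rule=junction_rule
        )
    return call


def classify_event_across_isoforms(
    idx: AnnotationIndex,
    gene_id: str,
    exon: tuple[int, int],
    genome: GenomeSequence,
    domains: DomainTable | None = None,
    *,
    rule_distance: int = 50,
    junction_rule: str = "last",
) -> list[ConsequenceCall]:
    """Evaluate every transcript containing ``exon`` as an internal exon.

    The event-level rollup treats the event as NMD-targeting when any
    containing isoform yields a qualifying PTC.
    """
    calls = []
    for t in idx.genes[gene_id].transcripts:
        for i, ex in enumerate(t.exons):
            if ex == exon and 0 < i < len(t.exons) - 1:
                calls.append(
                    classify_skip(
                        t,
                        i,
                        genome,
                        domains,
                        rule_distance=rule_distance,
                        junction_rule=junction_rule,
                    )
                )
    return calls


def rollup_label(calls: list[ConsequenceCall]) -> str:
    """Single event label: ``nmd`` > ``domain`` > ``neither``.

    Each altered exon is counted once: NMD-targeting if any isoform
    qualifies, else domain-affecting if any in-frame isoform hits a domain,
    else neither.
    """
    if any(c.nmd_targeting for c in calls):
        return "nmd"
    if any(c.frame_effect == FRAME_IN and c.affected_domains for c in calls):
        return "domain"
    return "neither"


def calls_to_frame(calls: list[ConsequenceCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "event_id": c.event_id,
                "transcript_id": c.transcript_id,
                "frame_effect": c.frame_effect,
                "nmd_targeting": c.nmd_targeting,
                "ptc_position": c.ptc_position,
                "distance_to_reference_junction": c.distance_to_reference_junction,
                "affected_domains": ",".join(c.affected_domains),
                "start_lost": c.start_lost,
            }
            for c in calls
        ]
    )
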