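"""Exon inclusion levels (psi), the exon-commitment score, and differential
exon usage.

The inclusion level of a skipped exon is the length-normalised ratio

    psi = (I / len_inc) / (I / len_inc + S / len_skip)

with junction-only counting: I is the sum of reads on the two inclusion
junctions (effective length 2), S the reads on the single skipping junction
(effective length 1). A sample's exon commitment score is the proportion of
quantified, non-redundant exons that are essentially always included
(psi > 0.99) or always excluded (psi < 0.01).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .annotation import AnnotationIndex, TranscriptModel, enumerate_introns, junction_key

log = logging.getLogger(__name__)


def exon_inclusion_level(
    inclusion_reads: float,
    skip_reads: float,
    len_inclusion: float = 2.0,
    len_skip: float = 1.0,
) -> float:
    """Length-normalised psi. Undefined (ValueError) when I + S = 0."""
    if inclusion_reads < 0 or skip_reads < 0:
        raise ValueError("negative read counts")
    if inclusion_reads + skip_reads == 0:
        raise ValueError("psi undefined for I = S = 0; exclude the event")
    inc = inclusion_reads / len_inclusion
    return inc / (inc + skip_reads / len_skip)


@dataclass
class ExonEvent:
    """A skipped-exon event with junction read support."""

    event_id: str
    gene_id: str
    contig: str
    strand: str
    exon: tuple[int, int]
    upstream_exon: tuple[int, int]
    downstream_exon: tuple[int, int]
    inclusion_reads: int
    skip_reads: int
    transcript_id: str | None = None
    #: index of the skipped exon within the parent transcript (tx orientation)
    exon_index: int | None = None

    @property
    def psi(self) -> float | None:
        if self.inclusion_reads + self.skip_reads == 0:
            return None
        return exon_inclusion_level(self.inclusion_reads, self.skip_reads)

    @property
    def exon_key(self) -> tuple[str, int, int, str]:
        return (self.contig, self.exon[0], self.exon[1], self.strand)


def extract_exon_events(
    junction_reads: dict[tuple[str, int, int, str], int],
    idx: AnnotationIndex,
) -> list[ExonEvent]:
    """Enumerate skipped-exon events from the annotation and count support.

    For every internal exon of every transcript, the two flanking introns
    define the inclusion junctions and their outer boundaries the skipping
    junction. Events with zero total support are dropped (psi undefined).
    """
    events: list[ExonEvent] = []
    seen: set[tuple[str, str, tuple[int, int], tuple[int, int], tuple[int, int]]] = set()
    for gene in idx.genes.values():
        for t in gene.transcripts:
            if len(t.exons) < 3:
                continue
            introns = enumerate_introns(t)
            for i in range(1, len(t.exons) - 1):
                up_exon, exon, down_exon = t.exons[i - 1], t.exons[i], t.exons[i + 1]
                j_up = junction_key(t.contig, introns[i - 1], t.strand)
                j_down = junction_key(t.contig, introns[i], t.strand)
                lo = min(introns[i - 1][0], introns[i][0])
                hi = max(introns[i - 1][1], introns[i][1])
                j_skip = (t.contig, lo, hi, t.strand)
                dedup = (gene.gene_id, t.contig, up_exon, exon, down_exon)
                if dedup in seen:
                    continue
                seen.add(dedup)
                inc = junction_reads.get(j_up, 0) + junction_reads.get(j_down, 0)
                skip = junction_reads.get(j_skip, 0)
                if inc + skip == 0:
                    continue
                events.append(
                    ExonEvent(
                        event_id=f"{gene.gene_id}:{t.contig}:{exon[0]}-{exon[1]}:{t.strand}"
                        f":{up_exon[0]}-{down_exon[1]}",
                        gene_id=gene.gene_id,
                        contig=t.contig,
                        strand=t.strand,
                        exon=exon,
                        upstream_exon=up_exon,
                        downstream_exon=down_exon,
                        inclusion_reads=inc,
                        skip_reads=skip,
                        transcript_id=t.transcript_id,
                        exon_index=i,
                    )
                )
    return events


def collapse_duplicate_exons(events: list[ExonEvent]) -> list[ExonEvent]:
    """One record per distinct skipped exon, keeping the minimum psi.

    When the same exon is skipped by multiple alternative junction pairs the
    minimum reported inclusion level wins.
    """
    best: dict[tuple[str, int, int, str], ExonEvent] = {}
    for ev in events:
        if ev.psi is None:
            continue
        cur = best.get(ev.exon_key)
        if cur is None or ev.psi < cur.psi:
            best[ev.exon_key] = ev
    return [best[k] for k in sorted(best)]


@dataclass
class CommitmentResult:
    sample_id: str
    n_included_committed: int
    n_excluded_committed: int
    n_total: int

    @property
    def score(self) -> float:
        return (self.n_included_committed + self.n_excluded_committed) / self.n_total


def exon_commitment_score(
    events: list[ExonEvent],
    idx: AnnotationIndex | None = None,
    *,
    sample_id: str = "sample",
    tpm_gate: float = 10.0,
    hi: float = 0.99,
    lo: float = 0.01,
    min_depth: int = 10,
) -> CommitmentResult:
    """Commitment score: (#{psi > hi} + #{psi < lo}) / total, strict bounds.

    Events are restricted to genes with tpm > gate (when an index is given),
    to total junction depth >= ``min_depth``, and duplicates are collapsed to
    the minimum psi before counting.
    """
    pool = [ev for ev in events if ev.inclusion_reads + ev.skip_reads >= min_depth]
    if idx is not None:
        pool = [ev for ev in pool if idx.genes[ev.gene_id].tpm > tpm_gate]
    pool = collapse_duplicate_exons(pool)
    if not pool:
        raise ValueError("no quantifiable exon events; commitment score undefined")
    n_in = sum(1 for ev in pool if ev.psi > hi)
    n_out = sum(1 for ev in pool if ev.psi < lo)
    return CommitmentResult(
        sample_id=sample_id,
        n_included_committed=n_in,
        n_excluded_committed=n_out,
        n_total=len(pool),
    )


@dataclass
class DifferentialEvent:
    event_id: str
    psi_1: float
    psi_2: float
    p_value: float
    fdr: float | None = None

    @property
    def inc_level_difference(self) -> float:
        return self.psi_1 - self.psi_2


def pool_events(replicates: list[list[ExonEvent]]) -> dict[str, ExonEvent]:
    """Sum junction counts across replicates, matched by event_id."""
    pooled: dict[str, ExonEvent] = {}
    for rep in replicates:
        for ev in rep:
            cur = pooled.get(ev.event_id)
            if cur is None:
                pooled[ev.event_id] = replace(ev)
            else:
                cur.inclusion_reads += ev.inclusion_reads
                cur.skip_reads += ev.skip_reads
    return pooled


def differential_inclusion(
    events_1: list[ExonEvent] | dict[str, ExonEvent],
    events_2: list[ExonEvent] | dict[str, ExonEvent],
) -> list[DifferentialEvent]:
    """Two-sided Fisher exact test on pooled (I, S) counts per event + BH.

    Events present in only one condition are skipped (logged). Delta-psi is
    the difference of the length-normalised inclusion levels.
    """
    d1 = events_1 if isinstance(events_1, dict) else {e.event_id: e for e in events_1}
    d2 = events_2 if isinstance(events_2, dict) else {e.event_id: e for e in events_2}
    shared = sorted(set(d1) & set(d2))
    n_skipped = len(set(d1) ^ set(d2))
    if n_skipped:
        log.info("differential_inclusion: %d events present in one condition only", n_skipped)
    out = []
    for eid in shared:
        e1, e2 = d1[eid], d2[eid]
        if e1.psi is None or e2.psi is None:
            continue
        _, p = fisher_exact(
            [[e1.inclusion_reads, e1.skip_reads], [e2.inclusion_reads, e2.skip_reads]],
            alternative="two-sided",
        )
        out.append(DifferentialEvent(event_id=eid, psi_1=e1.psi, psi_2=e2.psi, p_value=p))
    if out:
        _, fdrs, _, _ = multipletests([e.p_value for e in out], method="fdr_bh")
        for ev, q in zip(out, fdrs):
            ev.fdr = float(q)
    return out


def events_to_frame(
    diffs: list[DifferentialEvent],
    pooled_1: dict[str, ExonEvent] | None = None,
    pooled_2: dict[str, ExonEvent] | None = None,
) -> pd.DataFrame:
    """rMATS-like long-format output table."""
    rows = []
    for d in diffs:
        row = {
            "event_id": d.event_id,
            "IncLevel1": d.psi_1,
            "IncLevel2": d.psi_2,
            "IncLevelDifference": d.inc_level_difference,
            "PValue": d.p_value,
            "FDR": d.fdr,
        }
        for label, pooled in (("1", pooled_1), ("2", pooled_2)):
            if pooled and d.event_id in pooled:
                ev = pooled[d.event_id]
                row[f"IJC_{label}"] = ev.inclusion_reads
                row[f"SJC_{label}"] = ev.skip_reads
                row["gene_id"] = ev.gene_id
        rows.append(row)
    return pd.DataFrame(rows)
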