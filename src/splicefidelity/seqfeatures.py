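"""Sequence-feature profiles of event sets: lengths, GC content, and
splice-site strength under a log-odds position-weight-matrix scorer.

Window conventions follow the MaxEntScan layout so externally computed
MaxEntScan scores can be slotted in per site: the donor window is 9 nt
(last 3 exonic + first 6 intronic bases), the acceptor window 23 nt (last
20 intronic + 3 exonic bases), both read in transcript orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .annotation import (
    AnnotationError,
    AnnotationIndex,
    GenomeSequence,
    JunctionKey,
    enumerate_introns,
    junction_key,
)
from .inclusion import ExonEvent
from .retention import IntronRecord

log = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
DONOR_LEN = 9  # 3 exonic + 6 intronic
ACCEPTOR_LEN = 23  # 20 intronic + 3 exonic


def gc_content(seq: str) -> float:
    """(G + C) / non-N bases; undefined (ValueError) for empty or all-N."""
    seq = seq.upper()
    informative = sum(1 for b in seq if b != "N")
    if informative == 0:
        raise ValueError("GC content undefined for empty or all-N sequence")
    return sum(1 for b in seq if b in "GC") / informative


def donor_window(genome: GenomeSequence, key: JunctionKey) -> str:
    """9-nt donor window of a junction, in transcript orientation."""
    contig, start, end, strand = key
    if strand == "+":
        return genome.fetch(contig, start - 3, start + 5, "+")
    return genome.fetch(contig, end - 5, end + 3, "-")


def acceptor_window(genome: GenomeSequence, key: JunctionKey) -> str:
    """23-nt acceptor window of a junction, in transcript orientation."""
    contig, start, end, strand = key
    if strand == "+":
        return genome.fetch(contig, end - 19, end + 3, "+")
    return genome.fetch(contig, start - 3, start + 19, "-")


@dataclass
class SpliceSiteModel:
    """Column-stochastic PWMs for donor/acceptor sites + background."""

    donor_pwm: np.ndarray  # (4, 9)
    acceptor_pwm: np.ndarray  # (4, 23)
    background: np.ndarray  # (4,)
    pseudocount: float = 1.0

    def score(self, window: str, kind: str) -> float:
        return splice_site_score(self, window, kind)


def train_pwm_from_annotation(
    idx: AnnotationIndex, genome: GenomeSequence, pseudocount: float = 1.0
) -> SpliceSiteModel:
    """Estimate donor/acceptor PWMs from every annotated junction.

    Sites whose window runs off the contig are skipped with a warning. The
    background is the genome's overall base composition.
    """
    donor_counts = np.zeros((4, DONOR_LEN))
    acceptor_counts = np.zeros((4, ACCEPTOR_LEN))
    skipped = 0
    for key in sorted(idx.junctions):
        for counts, extract in (
            (donor_counts, donor_window),
            (acceptor_counts, acceptor_window),
        ):
            try:
                window = extract(genome, key)
            except AnnotationError:
                skipped += 1
                continue
            for pos, base in enumerate(window):
                i = _BASE_INDEX.get(base)
                if i is not None:
                    counts[i, pos] += 1
    if donor_counts.sum() == 0:
        raise ValueError("no resolvable annotated splice sites to train on")
    if skipped:
        log.warning("%d splice-site windows ran off a contig and were skipped", skipped)

    bg_counts = np.zeros(4)
    for seq in genome.contigs.values():
        for base in BASES:
            bg_counts[_BASE_INDEX[base]] += seq.count(base)
    background = bg_counts / bg_counts.sum()

    def normalise(counts: np.ndarray) -> np.ndarray:
        counts = counts + pseudocount
        return counts / counts.sum(axis=0, keepdims=True)

    return SpliceSiteModel(
        donor_pwm=normalise(donor_counts),
        acceptor_pwm=normalise(acceptor_counts),
        background=background,
        pseudocount=pseudocount,
    )


def splice_site_score(model: SpliceSiteModel, window: str, kind: str) -> float:
    """Sum over positions of log2(p_model / p_background); N contributes 0."""
    if kind == "donor":
        pwm, expected = model.donor_pwm, DONOR_LEN
    elif kind == "acceptor":
        pwm, expected = model.acceptor_pwm, ACCEPTOR_LEN
    else:
        raise ValueError(f"unknown site kind {kind!r}")
    if len(window) != expected:
        raise ValueError(f"{kind} window must be {expected} nt, got {len(window)}")
    score = 0.0
    for pos, base in enumerate(window.upper()):
        i = _BASE_INDEX.get(base)
        if i is None:
            continue
        score += np.log2(pwm[i, pos] / model.background[i])
    return float(score)


def _gap(a: tuple[int, int], b: tuple[int, int]) -> tuple[int, int]:
    """Genomic interval strictly between two disjoint intervals."""
    lo, hi = sorted([a, b])
    return (lo[1] + 1, hi[0] - 1)


@dataclass
class EventFeatureSummary:
    label: str
    table: pd.DataFrame
    n_events: int = 0
    n_baseline: int = 0


def _summarise(
    label: str,
    set_values: dict[str, list[float]],
    baseline_values: dict[str, list[float]],
) -> EventFeatureSummary:
    rows = []
    features = [f for f in set_values if set_values[f]]
    for feat in features:
        sv = np.asarray(set_values[feat], dtype=float)
        bv = np.asarray(baseline_values.get(feat, []), dtype=float)
        if bv.size and (sv.size > 1 or bv.size > 1):
            try:
                p = float(mannwhitneyu(sv, bv, alternative="two-sided").pvalue)
            except ValueError:  # identical constant samples
                p = 1.0
        else:
            p = np.nan
        rows.append(
            {
                "feature": feat,
                "set_mean": sv.mean(),
                "set_median": float(np.median(sv)),
                "baseline_mean": bv.mean() if bv.size else np.nan,
                "baseline_median": float(np.median(bv)) if bv.size else np.nan,
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["p_adj"] = np.minimum(df["p_value"] * len(df), 1.0)  # Bonferroni
    return EventFeatureSummary(
        label=label,
        table=df,
        n_events=max((len(v) for v in set_values.values()), default=0),
        n_baseline=max((len(v) for v in baseline_values.values()), default=0),
    )


def _exon_site_features(
    contig: str,
    strand: str,
    up_exon: tuple[int, int],
    exon: tuple[int, int],
    down_exon: tuple[int, int],
    genome: GenomeSequence,
    model: SpliceSiteModel | None,
) -> dict[str, float]:
    up_intron = _gap(up_exon, exon)
    down_intron = _gap(exon, down_exon)
    # transcript orientation: on the minus strand the genomically-downstream
    # intron is the upstream one
    if strand == "-":
        up_intron, down_intron = down_intron, up_intron
        up_exon, down_exon = down_exon, up_exon
    feats = {
        "exon_length": exon[1] - exon[0] + 1,
        "upstream_exon_length": up_exon[1] - up_exon[0] + 1,
        "downstream_exon_length": down_exon[1] - down_exon[0] + 1,
        "upstream_intron_length": up_intron[1] - up_intron[0] + 1,
        "downstream_intron_length": down_intron[1] - down_intron[0] + 1,
    }
    if model is not None:
        up_key = junction_key(contig, up_intron, strand)
        down_key = junction_key(contig, down_intron, strand)
        try:
            feats["upstream_exon_donor_score"] = model.score(
                donor_window(genome, up_key), "donor"
            )
            feats["skipped_exon_acceptor_score"] = model.score(
                acceptor_window(genome, up_key), "acceptor"
            )
            feats["skipped_exon_donor_score"] = model.score(
                donor_window(genome, down_key), "donor"
            )
            feats["downstream_exon_acceptor_score"] = model.score(
                acceptor_window(genome, down_key), "acceptor"
            )
        except AnnotationError:
            pass
    return feats


def _collect(rows: list[dict[str, float]]) -> dict[str, list[float]]:
    out: dict[str, list[float]] = {}
    for row in rows:
        for k, v in row.items():
            out.setdefault(k, []).append(v)
    return out


def exon_event_feature_summary(
    events: list[ExonEvent],
    idx: AnnotationIndex,
    genome: GenomeSequence,
    model: SpliceSiteModel | None = None,
    *,
    label: str = "events",
    tpm_gate: float = 10.0,
) -> EventFeatureSummary:
    """Feature profile of a skipped-exon event set vs the annotation baseline.

    The baseline is every annotated internal exon of expressed (tpm > gate)
    genes; each feature is compared by a two-sided Mann-Whitney test with
    Bonferroni correction across features.
    """
    if not events:
        raise ValueError("empty event set")
    set_rows = [
        _exon_site_features(
            ev.contig, ev.strand, ev.upstream_exon, ev.exon, ev.downstream_exon, genome, model
        )
        for ev in events
    ]
    base_rows = []
    for gid in sorted(idx.multi_exon_genes(tpm_gate)):
        for t in idx.genes[gid].transcripts:
            for i in range(1, len(t.exons) - 1):
                base_rows.append(
                    _exon_site_features(
                        t.contig, t.strand, t.exons[i - 1], t.exons[i], t.exons[i + 1],
                        genome, model,
                    )
                )
    return _summarise(label, _collect(set_rows), _collect(base_rows))


def _intron_features(
    contig: str,
    intron: tuple[int, int],
    strand: str,
    genome: GenomeSequence,
    model: SpliceSiteModel | None,
) -> dict[str, float]:
    feats = {
        "intron_length": intron[1] - intron[0] + 1,
        "intron_gc": gc_content(genome.fetch(contig, intron[0], intron[1], strand)),
    }
    if model is not None:
        key = junction_key(contig, intron, strand)
        try:
            feats["donor_score"] = model.score(donor_window(genome, key), "donor")
            feats["acceptor_score"] = model.score(acceptor_window(genome, key), "acceptor")
        except AnnotationError:
            pass
    return feats


def intron_feature_summary(
    records: list[IntronRecord],
    idx: AnnotationIndex,
    genome: GenomeSequence,
    model: SpliceSiteModel | None = None,
    *,
    label: str = "introns",
    tpm_gate: float = 10.0,
) -> EventFeatureSummary:
    """Length/GC/site-strength profile of an intron set vs annotated introns."""
    if not records:
        raise ValueError("empty intron set")
    set_rows = [
        _intron_features(r.contig, (r.intron_start, r.intron_end), r.strand, genome, model)
        for r in records
    ]
    base_rows = []
    for gid in sorted(idx.multi_exon_genes(tpm_gate)):
        for t in idx.genes[gid].transcripts:
            for intron in enumerate_introns(t):
                base_rows.append(_intron_features(t.contig, intron, t.strand, genome, model))
    return _summarise(label, _collect(set_rows), _collect(base_rows))
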