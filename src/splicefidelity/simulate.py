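"""Synthetic fixture bundles with known ground truth.

Generates a toy genome, Ensembl-dialect GTF, per-gene TPM table, per-sample
STAR-style junction tables, per-intron coverage tables and a protein-domain
table, all deterministic under a seed. Every pipeline stage can therefore be
tested against known per-exon inclusion levels (psi*), per-intron retention
ratios (r*), injected unannotated junctions with class labels, and
constructed NMD boundary cases.

Each gene carries one designated skippable internal exon; a second annotated
transcript lacking that exon makes the skipping junction part of the
annotated universe, so the unannotated-junction channel is controlled purely
by the injected junctions. Junction depths are negative binomial
(overdispersed, as in real RNA-seq); inclusion reads are allocated
binomially with a weight w = 2 psi / (1 + psi) that inverts the
length-normalised psi formula, making the estimated psi unbiased for psi*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (
    AnnotationIndex,
    GeneModel,
    GenomeSequence,
    JunctionKey,
    TranscriptModel,
    enumerate_introns,
    junction_key,
)
from .consequence import STOP_CODONS, DomainTable

CLASS_NOVEL_PAIRING = "both_annotated_novel_pairing"
CLASS_HEMI = "hemi_annotated"
CLASS_FULLY_NOVEL = "fully_novel"
INJECTION_CLASSES = (CLASS_NOVEL_PAIRING, CLASS_HEMI, CLASS_FULLY_NOVEL)


@dataclass
class ConditionProfile:
    """Study-condition parameters for one simulated cell state."""

    name: str
    #: fraction of expressed multi-exon genes given an injected unannotated junction
    unannotated_gene_fraction: float = 0.3
    #: fraction of designated exons with psi* in {0, 1}
    committed_fraction: float = 0.5
    #: committed exons are fully included with this probability (else excluded)
    committed_include_prob: float = 0.7
    #: Beta(a, b) for uncommitted psi*
    psi_beta: tuple[float, float] = (1.5, 1.5)
    #: Beta(a, b) for true per-intron retention r*
    retention_beta: tuple[float, float] = (0.8, 4.0)
    n_replicates: int = 2


@dataclass
class SimulationConfig:
    seed: int
    n_genes: int = 60
    exons_per_gene: tuple[int, int] = (4, 7)
    exon_length: tuple[int, int] = (60, 150)
    intron_length: tuple[int, int] = (80, 250)
    utr5_length: tuple[int, int] = (6, 30)
    utr3_min: int = 12
    exonic_gc: float = 0.52
    intronic_gc: float = 0.42
    intergenic_gc: float = 0.40
    intergenic_gap: tuple[int, int] = (100, 250)
    minus_strand_fraction: float = 0.4
    expressed_fraction: float = 0.9
    tpm_expressed: tuple[float, float] = (15.0, 200.0)
    tpm_silent: tuple[float, float] = (0.0, 5.0)
    #: fraction of designated skippable exons that shift the reading frame
    frameshift_fraction: float = 0.5
    #: fraction of coding genes given a conserved domain over the skipped exon
    domain_fraction: float = 0.7
    depth_mean: float = 120.0
    depth_dispersion: float = 0.1
    #: injected junction depth as a fraction of the gene's max annotated depth
    unannotated_depth_fraction: tuple[float, float] = (0.12, 0.5)
    #: mix of (novel pairing, hemi-annotated, fully novel) injected classes
    class_mix: tuple[float, float, float] = (0.4, 0.35, 0.25)
    #: engineered frameshift genes with PTC at exactly these distances from
    #: the last junction of the skipped isoform (exercises the >50 nt rule)
    boundary_nmd_distances: tuple[int, ...] = (50, 51)
    conditions: list[ConditionProfile] = field(
        default_factory=lambda: [ConditionProfile(name="A"), ConditionProfile(name="B")]
    )

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for frac in (
            self.minus_strand_fraction,
            self.expressed_fraction,
            self.frameshift_fraction,
            self.domain_fraction,
        ):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must be in [0, 1]")
        if self.exons_per_gene[0] < 4:
            raise ValueError("need >= 4 exons per gene for internal-skip NMD geometry")


def paper_shape_config(seed: int, n_genes: int = 60) -> SimulationConfig:
    """Preset contrasting a blood-naive-B-cell-like state (condition A: 30%
    of expressed genes with unannotated junctions, low exon commitment, high
    intron retention) with a differentiated-like state (condition B: 5%,
    high commitment, low retention)."""
    return SimulationConfig(
        seed=seed,
        n_genes=n_genes,
        conditions=[
            ConditionProfile(
                name="A",
                unannotated_gene_fraction=0.30,
                committed_fraction=0.35,
                psi_beta=(1.5, 1.5),
                retention_beta=(1.3, 2.2),
                n_replicates=2,
            ),
            ConditionProfile(
                name="B",
                unannotated_gene_fraction=0.05,
                committed_fraction=0.90,
                psi_beta=(2.0, 2.0),
                retention_beta=(0.5, 8.0),
                n_replicates=2,
            ),
        ],
    )


@dataclass
class GroundTruth:
    expressed: set[str] = field(default_factory=set)
    tpm: dict[str, float] = field(default_factory=dict)
    #: designated skippable exon per gene (genomic interval + strand)
    skip_exon: dict[str, tuple[str, int, int, str]] = field(default_factory=dict)
    frame_class: dict[str, str] = field(default_factory=dict)
    psi_true: dict[str, dict[str, float]] = field(default_factory=dict)
    retention_true: dict[str, dict[JunctionKey, float]] = field(default_factory=dict)
    injected: dict[str, dict[JunctionKey, str]] = field(default_factory=dict)
    injected_genes: dict[str, set[str]] = field(default_factory=dict)


@dataclass
class SimulatedGene:
    gene_id: str
    contig: str
    strand: str
    full: TranscriptModel
    skipped: TranscriptModel
    skip_index: int
    frameshift: bool


@dataclass
class SimulatedAnnotation:
    cfg: SimulationConfig
    genome: GenomeSequence
    index: AnnotationIndex
    genes: list[SimulatedGene]
    domain_table: DomainTable
    truth: GroundTruth


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return list(rng.choice(list("ACGT"), size=n, p=p))


def _nonstop_codon(rng: np.random.Generator, gc: float) -> str:
    while True:
        codon = "".join(_random_bases(rng, 3, gc))
        if codon not in STOP_CODONS:
            return codon


def _random_gene_layout(cfg: SimulationConfig, rng: np.random.Generator, frameshift: bool):
    n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    exon_lens = [
        int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1)) for _ in range(n_exons)
    ]
    # skip index leaves >= 2 exons downstream so a junction can follow a PTC
    skip_index = int(rng.integers(1, n_exons - 2)) if n_exons > 4 else 1
    want_mod = 0 if not frameshift else int(rng.integers(1, 3))
    exon_lens[skip_index] += (want_mod - exon_lens[skip_index]) % 3
    intron_lens = [
        int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1))
        for _ in range(n_exons - 1)
    ]
    utr5 = int(rng.integers(cfg.utr5_length[0], cfg.utr5_length[1] + 1))
    total = sum(exon_lens)
    coding = total - utr5 - cfg.utr3_min
    coding -= coding % 3
    utr3 = total - utr5 - coding
    # keep the start codon in exon 1 and the stop codon in the last exon
    assert utr5 + 3 <= exon_lens[0] and utr3 + 3 <= exon_lens[-1]
    return exon_lens, intron_lens, skip_index, utr5, utr3, coding


def _build_random_gene_seq(
    cfg: SimulationConfig, rng: np.random.Generator, exon_lens, utr5, coding
) -> str:
    """Transcript (exonic) sequence with a clean CDS: ATG + non-stop codons + TAA."""
    total = sum(exon_lens)
    n_mid = coding // 3 - 2
    cds = "ATG" + "".join(_nonstop_codon(rng, cfg.exonic_gc) for _ in range(n_mid)) + "TAA"
    utr3_len = total - utr5 - coding
    return (
        "".join(_random_bases(rng, utr5, cfg.exonic_gc))
        + cds
        + "".join(_random_bases(rng, utr3_len, cfg.exonic_gc))
    )


def _build_boundary_tx_seq(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    exon_lens: list[int],
    distance: int,
) -> tuple[str, int, int]:
    """Engineered 4-exon transcript sequence for an NMD boundary fixture.

    Skipping exon 2 (0-based index 1; length = 1 mod 3) shifts the frame and
    the first stop met in the new frame sits exactly ``distance`` nt upstream
    of the skipped isoform's final exon-exon junction. Returns
    (sequence, cds_start_tx, cds_end_tx), 1-based transcript coordinates.
    """
    l0, l1, l2, l3 = exon_lens
    total = l0 + l1 + l2 + l3
    # skipped-isoform coordinates: junctions at l0 and l0+l2; PTC start s
    s = l0 + l2 - distance - 2
    assert l0 < s and s + 2 <= l0 + l2, "PTC must lie inside exon 3"
    c = 5 + ((s - 5) % 3)  # CDS start, in frame with the engineered PTC
    # annotated stop in exon 4, in the reference frame
    e3_start = l0 + l1 + l2 + 1
    p = e3_start + ((c - e3_start) % 3) + 30
    assert p + 2 <= total - 3

    parent: list[str] = []
    skipped: list[str] = []  # parent minus exon 2, grown in lockstep

    forced = {c: "A", c + 1: "T", c + 2: "G", p: "T", p + 1: "A", p + 2: "A"}
    ptc_parent = s + l1  # the engineered PTC bases, in parent coordinates
    forced.update({ptc_parent: "T", ptc_parent + 1: "A", ptc_parent + 2: "A"})
    # forced codons never collide with the other frame's codons: the frame
    # shift is 1 or 2, and no stop codon has T mid-codon-with-A-end or starts
    # with A, so out-of-frame overlaps of TAA cannot create a stop

    for pos in range(1, total + 1):
        in_skipped = pos <= l0 or pos > l0 + l1
        for _attempt in range(64):
            base = forced.get(pos) or _random_bases(rng, 1, cfg.exonic_gc)[0]
            ok = True
            # parent frame: no stop inside the CDS before the annotated stop
            if c <= pos < p and (pos - c + 1) % 3 == 0 and pos - 2 >= c:
                codon = "".join(parent[pos - 3 : pos - 1]) + base
                if codon in STOP_CODONS:
                    ok = False
            # skipped frame: no stop before the engineered PTC
            if ok and in_skipped:
                sp = pos if pos <= l0 else pos - l1
                if c <= sp < s and (sp - c + 1) % 3 == 0 and sp - 2 >= c:
                    codon = "".join(skipped[sp - 3 : sp - 1]) + base
                    if codon in STOP_CODONS:
                        ok = False
            if ok:
                break
            assert pos not in forced, "forced base rejected; geometry bug"
        parent.append(base)
        if in_skipped:
            skipped.append(base)
    return "".join(parent), c, p + 2


def _place_gene(
    gene_id: str,
    contig: str,
    strand: str,
    offset: int,
    exon_lens: list[int],
    intron_lens: list[int],
    tx_seq: str,
    cds_start: int,
    cds_end: int,
    skip_index: int,
    frameshift: bool,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[str, SimulatedGene]:
    """Assemble the genomic block for one gene and its transcript models.

    ``offset`` is the 0-based genomic offset where the block starts. Returns
    (genomic block sequence, SimulatedGene).
    """
    from Bio.Seq import Seq

    pieces, tx_pos = [], 0
    fwd_exons = []  # forward-orientation offsets within the block
    block_pos = 0
    for i, elen in enumerate(exon_lens):
        pieces.append(tx_seq[tx_pos : tx_pos + elen])
        fwd_exons.append((block_pos, block_pos + elen - 1))
        tx_pos += elen
        block_pos += elen
        if i < len(intron_lens):
            ilen = intron_lens[i]
            middle = "".join(_random_bases(rng, ilen - 4, cfg.intronic_gc))
            pieces.append("GT" + middle + "AG")
            block_pos += ilen
    block = "".join(pieces)
    if strand == "-":
        block = str(Seq(block).reverse_complement())
        L = len(block)
        genomic_exons = [
            (offset + L - 1 - e + 1, offset + L - 1 - s + 1) for s, e in fwd_exons
        ]
    else:
        genomic_exons = [(offset + s + 1, offset + e + 1) for s, e in fwd_exons]

    full = TranscriptModel(
        transcript_id=f"{gene_id}_t1",
        gene_id=gene_id,
        contig=contig,
        strand=strand,
        exons=list(genomic_exons),
        cds_start=cds_start,
        cds_end=cds_end,
    )
    skipped = TranscriptModel(
        transcript_id=f"{gene_id}_t2",
        gene_id=gene_id,
        contig=contig,
        strand=strand,
        exons=[ex for i, ex in enumerate(genomic_exons) if i != skip_index],
    )
    return block, SimulatedGene(
        gene_id=gene_id,
        contig=contig,
        strand=strand,
        full=full,
        skipped=skipped,
        skip_index=skip_index,
        frameshift=frameshift,
    )


def _draw_injected_junction(
    gene: SimulatedGene, cls: str, annotated: set[JunctionKey], rng: np.random.Generator
) -> JunctionKey | None:
    """A canonical-looking unannotated junction of the requested class."""
    t = gene.full
    introns = enumerate_introns(t)  # transcript order
    contig, strand = t.contig, t.strand

    def span(donor_intron, acceptor_intron) -> JunctionKey:
        if strand == "+":
            return (contig, donor_intron[0], acceptor_intron[1], strand)
        return (contig, acceptor_intron[0], donor_intron[1], strand)

    if cls == CLASS_NOVEL_PAIRING:
        n = len(introns)
        pairs = [(a, b) for a in range(n) for b in range(a + 1, n)]
        rng.shuffle(pairs)
        for a, b in pairs:
            key = span(introns[a], introns[b])
            if key not in annotated:
                return key
        return None
    # hemi and fully novel sit inside one sufficiently long intron
    order = list(rng.permutation(len(introns)))
    for i in order:
        lo, hi = introns[i]
        if hi - lo + 1 < 60:
            continue
        if cls == CLASS_HEMI:
            off = int(rng.integers(25, hi - lo - 10))
            if strand == "+":
                return (contig, lo, lo + off, strand)  # annotated donor, novel acceptor
            return (contig, hi - off, hi, strand)
        off1 = int(rng.integers(10, hi - lo - 30))
        off2 = int(rng.integers(off1 + 15, hi - lo - 5))
        return (contig, lo + off1, lo + off2, strand)
    return None


def simulate_annotation(cfg: SimulationConfig) -> SimulatedAnnotation:
    """Build the genome, annotation, domain table and fixed ground truth.

    Fully deterministic under ``cfg.seed``; junction/coverage sampling for
    individual samples happens separately (also seeded).
    """
    rng = np.random.default_rng(cfg.seed)
    contig = "chrS"
    parts: list[str] = []
    offset = 0
    sim_genes: list[SimulatedGene] = []

    n_random = cfg.n_genes - len(cfg.boundary_nmd_distances)
    if n_random < 1:
        raise ValueError("n_genes too small for the configured boundary fixtures")

    for g in range(cfg.n_genes):
        gap = int(rng.integers(cfg.intergenic_gap[0], cfg.intergenic_gap[1] + 1))
        parts.append("".join(_random_bases(rng, gap, cfg.intergenic_gc)))
        offset += gap
        gene_id = f"G{g + 1:04d}"
        if g >= n_random:
            # engineered NMD boundary gene (always plus strand, 4 exons)
            distance = cfg.boundary_nmd_distances[g - n_random]
            exon_lens = [80, 70, max(90, distance + 10), 120]
            intron_lens = [
                int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1))
                for _ in range(3)
            ]
            tx_seq, c, e = _build_boundary_tx_seq(cfg, rng, exon_lens, distance)
            block, sg = _place_gene(
                gene_id, contig, "+", offset, exon_lens, intron_lens,
                tx_seq, c, e, 1, True, cfg, rng,
            )
        else:
            frameshift = bool(rng.random() < cfg.frameshift_fraction)
            exon_lens, intron_lens, skip_index, utr5, _utr3, coding = _random_gene_layout(
                cfg, rng, frameshift
            )
            tx_seq = _build_random_gene_seq(cfg, rng, exon_lens, utr5, coding)
            strand = "-" if rng.random() < cfg.minus_strand_fraction else "+"
            block, sg = _place_gene(
                gene_id, contig, strand, offset, exon_lens, intron_lens,
                tx_seq, utr5 + 1, utr5 + coding, skip_index, frameshift, cfg, rng,
            )
        parts.append(block)
        offset += len(block)
        sim_genes.append(sg)
    parts.append("".join(_random_bases(rng, 200, cfg.intergenic_gc)))
    genome = GenomeSequence({contig: "".join(parts)})

    genes = {
        sg.gene_id: GeneModel(
            gene_id=sg.gene_id,
            contig=sg.contig,
            strand=sg.strand,
            transcripts=[sg.full, sg.skipped],
        )
        for sg in sim_genes
    }
    index = AnnotationIndex(genes)

    truth = GroundTruth()
    n_expressed = round(cfg.expressed_fraction * cfg.n_genes)
    expressed_ids = [sg.gene_id for sg in sim_genes][:n_expressed]
    truth.expressed = set(expressed_ids)
    for sg in sim_genes:
        if sg.gene_id in truth.expressed:
            tpm = float(rng.uniform(*cfg.tpm_expressed))
        else:
            tpm = float(rng.uniform(*cfg.tpm_silent))
        truth.tpm[sg.gene_id] = tpm
        genes[sg.gene_id].tpm = tpm
        ex = sg.full.exons[sg.skip_index]
        truth.skip_exon[sg.gene_id] = (sg.contig, ex[0], ex[1], sg.strand)
        truth.frame_class[sg.gene_id] = "frameshift" if sg.frameshift else "in_frame"

    # domains over the designated skipped exon of in-frame coding genes
    domain_table = DomainTable()
    from .consequence import exon_protein_span

    for sg in sim_genes:
        if rng.random() >= cfg.domain_fraction:
            continue
        span = exon_protein_span(sg.full, sg.skip_index)
        if span is None:
            continue
        pad = int(rng.integers(0, 8))
        domain_table.domains.setdefault(sg.full.transcript_id, []).append(
            (f"DOM_{sg.gene_id}", max(1, span[0] - pad), span[1] + pad)
        )

    # per-condition fixed truth: psi*, r*, injected junctions
    for cond in cfg.conditions:
        psi: dict[str, float] = {}
        ret: dict[JunctionKey, float] = {}
        for sg in sim_genes:
            if rng.random() < cond.committed_fraction:
                psi[sg.gene_id] = 1.0 if rng.random() < cond.committed_include_prob else 0.0
            else:
                psi[sg.gene_id] = float(rng.beta(*cond.psi_beta))
            for intron in enumerate_introns(sg.full):
                ret[junction_key(sg.contig, intron, sg.strand)] = float(
                    rng.beta(*cond.retention_beta)
                )
        truth.psi_true[cond.name] = psi
        truth.retention_true[cond.name] = ret

        eligible = [g for g in expressed_ids]
        n_inject = round(cond.unannotated_gene_fraction * len(eligible))
        chosen = list(rng.choice(eligible, size=n_inject, replace=False))
        injected: dict[JunctionKey, str] = {}
        by_gene = {sg.gene_id: sg for sg in sim_genes}
        for gid in chosen:
            cls = INJECTION_CLASSES[
                int(rng.choice(len(INJECTION_CLASSES), p=list(cfg.class_mix)))
            ]
            key = _draw_injected_junction(by_gene[gid], cls, index.junctions, rng)
            if key is None:
                key = _draw_injected_junction(
                    by_gene[gid], CLASS_FULLY_NOVEL, index.junctions, rng
                )
                cls = CLASS_FULLY_NOVEL
            injected[key] = cls
        truth.injected[cond.name] = injected
        truth.injected_genes[cond.name] = set(chosen)

    return SimulatedAnnotation(
        cfg=cfg,
        genome=genome,
        index=index,
        genes=sim_genes,
        domain_table=domain_table,
        truth=truth,
    )


def _negbin(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if dispersion <= 0:
        return int(rng.poisson(mean))
    n = 1.0 / dispersion
    return int(rng.negative_binomial(n, n / (n + mean)))


def psi_to_inclusion_weight(psi: float) -> float:
    """Binomial weight w with E[(I/2) / (I/2 + S)] = psi for I ~ Bin(n, w).

    Inverts the length-normalised psi formula: w = 2 psi / (1 + psi).
    """
    return 2.0 * psi / (1.0 + psi)


def simulate_junction_counts(
    sim: SimulatedAnnotation, condition: str, rng: np.random.Generator
) -> dict[JunctionKey, int]:
    """One sample's junction read counts (annotated + injected unannotated)."""
    cfg = sim.cfg
    truth = sim.truth
    counts: dict[JunctionKey, int] = {}
    for sg in sim.genes:
        introns = enumerate_introns(sg.full)
        keys = [junction_key(sg.contig, iv, sg.strand) for iv in introns]
        k = sg.skip_index
        skip_key = junction_key(
            sg.contig,
            (
                min(introns[k - 1][0], introns[k][0]),
                max(introns[k - 1][1], introns[k][1]),
            ),
            sg.strand,
        )
        psi = truth.psi_true[condition][sg.gene_id]
        n = _negbin(rng, cfg.depth_mean, cfg.depth_dispersion)
        inc = int(rng.binomial(n, psi_to_inclusion_weight(psi))) if n else 0
        up = int(rng.binomial(inc, 0.5)) if inc else 0
        counts[keys[k - 1]] = counts.get(keys[k - 1], 0) + up
        counts[keys[k]] = counts.get(keys[k], 0) + (inc - up)
        counts[skip_key] = counts.get(skip_key, 0) + (n - inc)
        for i, key in enumerate(keys):
            if i in (k - 1, k):
                continue
            counts[key] = counts.get(key, 0) + _negbin(rng, cfg.depth_mean, cfg.depth_dispersion)
    # injected unannotated junctions, pinned to a fraction of the gene's
    # observed max annotated depth so the 10%-of-max filter keeps them
    gene_of = {}
    for sg in sim.genes:
        for iv in enumerate_introns(sg.full):
            gene_of[junction_key(sg.contig, iv, sg.strand)] = sg.gene_id
    max_depth: dict[str, int] = {}
    for key, reads in counts.items():
        gid = gene_of.get(key)
        if gid is not None:
            max_depth[gid] = max(max_depth.get(gid, 0), reads)
    by_gene = {sg.gene_id: sg for sg in sim.genes}
    for key, _cls in truth.injected[condition].items():
        gid = sim.index.assign_gene(key[0], key[1], key[2], key[3])
        if gid is None or max_depth.get(gid, 0) == 0:
            continue
        frac = float(rng.uniform(*cfg.unannotated_depth_fraction))
        counts[key] = max(1, int(np.ceil(frac * max_depth[gid])))
    _ = by_gene
    return {k: v for k, v in counts.items() if v > 0}


def junction_counts_to_sj_frame(counts: dict[JunctionKey, int]) -> pd.DataFrame:
    """STAR ``SJ.out.tab``-dialect table (9 columns, no header)."""
    rows = []
    for (contig, start, end, strand), reads in sorted(counts.items()):
        strand_code = 1 if strand == "+" else 2
        motif = 1 if strand == "+" else 2  # GT-AG / CT-AC
        rows.append((contig, start, end, strand_code, motif, 0, reads, 0, 30))
    return pd.DataFrame(rows)


def simulate_intron_coverage(
    sim: SimulatedAnnotation,
    condition: str,
    counts: dict[JunctionKey, int],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-intron mean-coverage table consistent with true retention r*.

    Given the sampled spliced reads s on the exact-spanning junction, the
    intronic depth is Poisson with mean s * r / (1 - r), so the expected
    retention ratio depth / (depth + s) is r* up to ratio-estimator error.
    """
    rows = []
    retention = sim.truth.retention_true[condition]
    for sg in sim.genes:
        for intron in enumerate_introns(sg.full):
            key = junction_key(sg.contig, intron, sg.strand)
            r = retention.get(key)
            if r is None:
                continue
            spliced = counts.get(key, 0)
            r = min(r, 0.95)
            depth = float(rng.poisson(spliced * r / (1.0 - r))) if spliced and r > 0 else 0.0
            rows.append(
                {
                    "gene_id": sg.gene_id,
                    "contig": key[0],
                    "intron_start": key[1],
                    "intron_end": key[2],
                    "strand": key[3],
                    "mean_depth": depth,
                }
            )
    return pd.DataFrame(rows)


def write_gtf(sim: SimulatedAnnotation, path: Path) -> None:
    lines = []
    for sg in sim.genes:
        gid = sg.gene_id
        s, e = GeneModel(gid, sg.contig, sg.strand, [sg.full, sg.skipped]).span
        lines.append(
            f"{sg.contig}\tsim\tgene\t{s}\t{e}\t.\t{sg.strand}\t.\tgene_id \"{gid}\";"
        )
        for t in (sg.full, sg.skipped):
            ts, te = t.span
            attrs = f'gene_id "{gid}"; transcript_id "{t.transcript_id}";'
            lines.append(f"{sg.contig}\tsim\ttranscript\t{ts}\t{te}\t.\t{t.strand}\t.\t{attrs}")
            for xs, xe in sorted(t.exons):
                lines.append(f"{sg.contig}\tsim\texon\t{xs}\t{xe}\t.\t{t.strand}\t.\t{attrs}")
            if t.is_coding:
                offsets = t.exon_tx_offsets()
                for (xs, xe), (a, b) in zip(t.exons, offsets):
                    lo, hi = max(a, t.cds_start), min(b, t.cds_end)
                    if lo > hi:
                        continue
                    if t.strand == "+":
                        gs, ge = xs + (lo - a), xs + (hi - a)
                    else:
                        gs, ge = xe - (hi - a), xe - (lo - a)
                    lines.append(
                        f"{sg.contig}\tsim\tCDS\t{gs}\t{ge}\t.\t{t.strand}\t.\t{attrs}"
                    )
    path.write_text("\n".join(lines) + "\n")


def write_fasta(genome: GenomeSequence, path: Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass
class BundlePaths:
    root: Path
    genome: Path
    gtf: Path
    expression: Path
    domains: Path
    ground_truth: Path
    junction_tables: dict[tuple[str, int], Path]
    coverage_tables: dict[tuple[str, int], Path]
    sim: SimulatedAnnotation


def write_fixture_bundle(cfg: SimulationConfig, outdir: str | Path) -> BundlePaths:
    """Emit the full fixture bundle (FASTA/GTF/TSV/SJ tables) to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = simulate_annotation(cfg)
    rng = np.random.default_rng(cfg.seed + 1)

    genome_path = outdir / "genome.fa"
    write_fasta(sim.genome, genome_path)
    gtf_path = outdir / "annotation.gtf"
    write_gtf(sim, gtf_path)

    expr_path = outdir / "expression.tsv"
    pd.DataFrame(
        sorted(sim.truth.tpm.items()), columns=["gene_id", "tpm"]
    ).to_csv(expr_path, sep="\t", index=False)

    domains_path = outdir / "domains.tsv"
    sim.domain_table.to_frame().to_csv(domains_path, sep="\t", index=False)

    junction_tables: dict[tuple[str, int], Path] = {}
    coverage_tables: dict[tuple[str, int], Path] = {}
    for cond in cfg.conditions:
        for rep in range(1, cond.n_replicates + 1):
            counts = simulate_junction_counts(sim, cond.name, rng)
            sj_path = outdir / f"sj_{cond.name}_{rep}.tab"
            junction_counts_to_sj_frame(counts).to_csv(
                sj_path, sep="\t", header=False, index=False
            )
            junction_tables[(cond.name, rep)] = sj_path
            cov_path = outdir / f"coverage_{cond.name}_{rep}.tsv"
            simulate_intron_coverage(sim, cond.name, counts, rng).to_csv(
                cov_path, sep="\t", index=False
            )
            coverage_tables[(cond.name, rep)] = cov_path

    truth_path = outdir / "ground_truth.tsv"
    rows = []
    for cond, psi in sim.truth.psi_true.items():
        for gid, val in sorted(psi.items()):
            rows.append(("psi", cond, gid, "", f"{val:.6f}"))
    for cond, ret in sim.truth.retention_true.items():
        for key, val in sorted(ret.items()):
            rows.append(
                ("retention", cond, "", f"{key[0]}:{key[1]}-{key[2]}:{key[3]}", f"{val:.6f}")
            )
    for cond, inj in sim.truth.injected.items():
        for key, cls in sorted(inj.items()):
            rows.append(
                ("injected_junction", cond, "", f"{key[0]}:{key[1]}-{key[2]}:{key[3]}", cls)
            )
    for gid, cls in sorted(sim.truth.frame_class.items()):
        rows.append(("frame_class", "", gid, "", cls))
    pd.DataFrame(
        rows, columns=["record", "condition", "gene_id", "key", "value"]
    ).to_csv(truth_path, sep="\t", index=False)

    return BundlePaths(
        root=outdir,
        genome=genome_path,
        gtf=gtf_path,
        expression=expr_path,
        domains=domains_path,
        ground_truth=truth_path,
        junction_tables=junction_tables,
        coverage_tables=coverage_tables,
        sim=sim,
    )
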