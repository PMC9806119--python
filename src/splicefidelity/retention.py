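"""Intron retention ratios and the gene-level high-retention metric.

The retention ratio of an intron is

    IR = intronic_depth / (intronic_depth + spliced_reads)

where intronic_depth is the mean per-base coverage over the intron and
spliced_reads the uniquely mapping reads on the junction exactly spanning
it. A gene counts as high-retention when at least one of its introns has
IR > 0.25 (strict); the sample metric is the proportion of such genes among
expressed genes (TPM > 10) with at least one scorable intron.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .annotation import AnnotationIndex
from .inclusion import DifferentialEvent

log = logging.getLogger(__name__)


def intron_retention_ratio(intronic_depth: float, spliced_reads: float) -> float:
    """IR ratio in [0, 1]; undefined (ValueError) when both inputs are 0."""
    if intronic_depth < 0 or spliced_reads < 0:
        raise ValueError("negative evidence")
    total = intronic_depth + spliced_reads
    if total == 0:
        raise ValueError("IR ratio undefined for zero depth and zero spliced reads")
    return intronic_depth / total


@dataclass
class IntronRecord:
    gene_id: str
    contig: str
    intron_start: int
    intron_end: int
    strand: str
    intronic_depth: float
    spliced_reads: int

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.contig, self.intron_start, self.intron_end, self.strand)

    @property
    def ir_ratio(self) -> float | None:
        if self.intronic_depth + self.spliced_reads == 0:
            return None
        return intron_retention_ratio(self.intronic_depth, self.spliced_reads)


def read_intron_coverage(path: str | Path) -> pd.DataFrame:
    """Per-intron mean-coverage TSV: gene_id, contig, intron_start, intron_end,
    strand, mean_depth."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "contig", "intron_start", "intron_end", "strand", "mean_depth"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return df


def build_intron_records(
    coverage: pd.DataFrame,
    junction_reads: dict[tuple[str, int, int, str], int],
) -> list[IntronRecord]:
    """Join intron coverage with exact-spanning junction reads.

    Only introns whose flanking junction is detected in the sample (present
    in the junction table) are scorable.
    """
    records = []
    for row in coverage.itertuples(index=False):
        key = (str(row.contig), int(row.intron_start), int(row.intron_end), str(row.strand))
        if key not in junction_reads:
            continue
        records.append(
            IntronRecord(
                gene_id=str(row.gene_id),
                contig=key[0],
                intron_start=key[1],
                intron_end=key[2],
                strand=key[3],
                intronic_depth=float(row.mean_depth),
                spliced_reads=junction_reads[key],
            )
        )
    return records


@dataclass
class RetentionResult:
    sample_id: str
    n_genes_high_retention: int
    n_genes_expressed: int

    @property
    def proportion(self) -> float:
        return self.n_genes_high_retention / self.n_genes_expressed


def gene_retention_metric(
    records: list[IntronRecord],
    idx: AnnotationIndex | None = None,
    *,
    sample_id: str = "sample",
    threshold: float = 0.25,
    tpm_gate: float = 10.0,
) -> RetentionResult:
    """Proportion of expressed genes with >= 1 intron at IR > threshold.

    The threshold is strict (IR exactly at the threshold does not flag the
    gene). Denominator: genes above the TPM gate with >= 1 scorable intron.
    """
    scorable: dict[str, list[float]] = {}
    for r in records:
        if idx is not None and idx.genes[r.gene_id].tpm <= tpm_gate:
            continue
        if r.ir_ratio is None:
            continue
        scorable.setdefault(r.gene_id, []).append(r.ir_ratio)
    if not scorable:
        raise ValueError("no scorable expressed genes; retention metric undefined")
    flagged = sum(1 for ratios in scorable.values() if any(ir > threshold for ir in ratios))
    return RetentionResult(
        sample_id=sample_id,
        n_genes_high_retention=flagged,
        n_genes_expressed=len(scorable),
    )


def differential_retention(
    records_1: list[IntronRecord], records_2: list[IntronRecord]
) -> list[DifferentialEvent]:
    """Per-intron IR difference with a Fisher exact test on rounded evidence.

    The 2x2 table opposes rounded intronic depth vs spliced reads between
    conditions; BH correction across introns. Introns absent from one
    condition are skipped.
    """
    d1 = {r.key: r for r in records_1}
    d2 = {r.key: r for r in records_2}
    shared = sorted(set(d1) & set(d2))
    out = []
    for key in shared:
        r1, r2 = d1[key], d2[key]
        if r1.ir_ratio is None or r2.ir_ratio is None:
            continue
        _, p = fisher_exact(
            [
                [round(r1.intronic_depth), r1.spliced_reads],
                [round(r2.intronic_depth), r2.spliced_reads],
            ],
            alternative="two-sided",
        )
        out.append(
            DifferentialEvent(
                event_id=f"{key[0]}:{key[1]}-{key[2]}:{key[3]}",
                psi_1=r1.ir_ratio,
                psi_2=r2.ir_ratio,
                p_value=p,
            )
        )
    if out:
        _, fdrs, _, _ = multipletests([e.p_value for e in out], method="fdr_bh")
        for ev, q in zip(out, fdrs):
            ev.fdr = float(q)
    return out


def records_to_frame(records: list[IntronRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "contig": r.contig,
                "intron_start": r.intron_start,
                "intron_end": r.intron_end,
                "strand": r.strand,
                "intronic_depth": r.intronic_depth,
                "spliced_reads": r.spliced_reads,
                "ir_ratio": r.ir_ratio,
            }
            for r in records
        ]
    )
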