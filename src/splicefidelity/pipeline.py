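"""End-to-end pipeline orchestration with a YAML config and a run manifest.

Stages: junction catalogue -> exon inclusion/commitment -> intron retention
-> consequence calls -> overlap statistics -> sequence features. Every
stage writes one TSV; the manifest records every threshold, convention
choice and input checksum so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import junctions as jx
from .annotation import GenomeSequence, load_annotation
from .consequence import DomainTable, classify_event_across_isoforms, calls_to_frame, rollup_label
from .inclusion import (
    differential_inclusion,
    events_to_frame,
    exon_commitment_score,
    extract_exon_events,
    pool_events,
)
from .overlap import junction_set_from_keys, pairwise_long_format
from .retention import (
    build_intron_records,
    differential_retention,
    gene_retention_metric,
    read_intron_coverage,
    records_to_frame,
)
from .seqfeatures import exon_event_feature_summary, train_pwm_from_annotation

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, thresholds and convention switches for one pipeline run.

    Threshold defaults are the analysis' printed gates: TPM > 10 for robust
    expression, the 10%-of-max unannotated-junction rule, commitment bounds
    0.99/0.01, IR threshold 0.25, FDR 0.05 (0.0005 for high-confidence
    cross-dataset junction comparisons), and the 50-nt NMD distance rule.
    """

    annotation: str = ""
    genome: str = ""
    expression: str = ""
    #: condition name -> list of SJ.out.tab paths (replicates)
    junction_tables: dict[str, list[str]] = field(default_factory=dict)
    #: condition name -> list of intron coverage TSVs (replicates)
    coverage_tables: dict[str, list[str]] = field(default_factory=dict)
    domains: str = ""

    tpm_gate: float = 10.0
    unannotated_fraction: float = 0.1
    commit_hi: float = 0.99
    commit_lo: float = 0.01
    ir_threshold: float = 0.25
    fdr: float = 0.05
    fdr_high_confidence: float = 0.0005
    nmd_distance: int = 50
    min_event_depth: int = 10
    shared_proportion_denominator: str = "union"
    nmd_junction_rule: str = "last"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for name in ("tpm_gate", "unannotated_fraction", "ir_threshold", "fdr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("commit_hi", "commit_lo"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for path in self._input_paths():
            if not Path(path).exists():
                raise FileNotFoundError(path)

    def _input_paths(self) -> list[str]:
        paths = [p for p in (self.annotation, self.genome, self.expression, self.domains) if p]
        for reps in self.junction_tables.values():
            paths.extend(reps)
        for reps in self.coverage_tables.values():
            paths.extend(reps)
        return paths


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> Path:
    """Execute all stages; returns the result directory.

    On stage failure partial outputs are preserved and the manifest records
    the failure point before the exception propagates.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {f"config.{k}": str(v) for k, v in asdict(cfg).items()}
    for path in cfg._input_paths():
        manifest[f"sha256.{Path(path).name}"] = _sha256(path)

    def write_manifest(status: str) -> None:
        manifest["status"] = status
        with open(outdir / "manifest.txt", "w") as fh:
            for k in sorted(manifest):
                fh.write(f"{k}={manifest[k]}\n")

    stage = "load"
    try:
        idx = load_annotation(cfg.annotation, cfg.expression)
        genome = GenomeSequence.from_fasta(cfg.genome)
        domains = DomainTable.from_tsv(cfg.domains) if cfg.domains else None

        stage = "junctions"
        call_sets: dict[tuple[str, int], jx.UnannotatedCallSet] = {}
        sample_counts: dict[tuple[str, int], dict] = {}
        junction_rows = []
        for cond, paths in sorted(cfg.junction_tables.items()):
            for rep, path in enumerate(paths, start=1):
                parsed = jx.read_junction_table(path)
                cs = jx.select_high_confidence_unannotated(
                    parsed,
                    idx,
                    sample_id=f"{cond}_{rep}",
                    tpm_gate=cfg.tpm_gate,
                    fraction=cfg.unannotated_fraction,
                )
                call_sets[(cond, rep)] = cs
                sample_counts[(cond, rep)] = {j.key: j.unique_reads for j in parsed}
                prop = jx.gene_unannotated_proportion(cs, idx)
                junction_rows.append(
                    {
                        "sample": cs.sample_id,
                        "condition": cond,
                        "n_junctions": len(parsed),
                        "n_kept_unannotated": len(cs.kept),
                        "n_genes_with_unannotated": len(cs.genes_with_unannotated),
                        "gene_unannotated_proportion": prop,
                    }
                )
                df = jx.call_set_to_frame(parsed, cs)
                df.to_csv(outdir / f"junctions_{cond}_{rep}.tsv", sep="\t", index=False)
        pd.DataFrame(junction_rows).to_csv(
            outdir / "junction_summary.tsv", sep="\t", index=False
        )

        stage = "inclusion"
        per_condition_events = {}
        commitment_rows = []
        for (cond, rep), counts in sorted(sample_counts.items()):
            events = extract_exon_events(counts, idx)
            per_condition_events.setdefault(cond, []).append(events)
            res = exon_commitment_score(
                events,
                idx,
                sample_id=f"{cond}_{rep}",
                tpm_gate=cfg.tpm_gate,
                hi=cfg.commit_hi,
                lo=cfg.commit_lo,
                min_depth=cfg.min_event_depth,
            )
            commitment_rows.append(
                {
                    "sample": res.sample_id,
                    "condition": cond,
                    "n_included_committed": res.n_included_committed,
                    "n_excluded_committed": res.n_excluded_committed,
                    "n_total": res.n_total,
                    "commitment_score": res.score,
                }
            )
        pd.DataFrame(commitment_rows).to_csv(
            outdir / "commitment_summary.tsv", sep="\t", index=False
        )

        conds = sorted(per_condition_events)
        diffs = []
        if len(conds) >= 2:
            pooled_1 = pool_events(per_condition_events[conds[0]])
            pooled_2 = pool_events(per_condition_events[conds[1]])
            diffs = differential_inclusion(pooled_1, pooled_2)
            events_to_frame(diffs, pooled_1, pooled_2).to_csv(
                outdir / "differential_inclusion.tsv", sep="\t", index=False
            )

        stage = "retention"
        retention_rows = []
        per_condition_records = {}
        for cond, paths in sorted(cfg.coverage_tables.items()):
            for rep, path in enumerate(paths, start=1):
                counts = sample_counts.get((cond, rep), {})
                records = build_intron_records(read_intron_coverage(path), counts)
                per_condition_records.setdefault(cond, records)
                res = gene_retention_metric(
                    records,
                    idx,
                    sample_id=f"{cond}_{rep}",
                    threshold=cfg.ir_threshold,
                    tpm_gate=cfg.tpm_gate,
                )
                retention_rows.append(
                    {
                        "sample": res.sample_id,
                        "condition": cond,
                        "n_genes_high_retention": res.n_genes_high_retention,
                        "n_genes_expressed": res.n_genes_expressed,
                        "proportion": res.proportion,
                    }
                )
                records_to_frame(records).to_csv(
                    outdir / f"retention_{cond}_{rep}.tsv", sep="\t", index=False
                )
        if retention_rows:
            pd.DataFrame(retention_rows).to_csv(
                outdir / "retention_summary.tsv", sep="\t", index=False
            )
        rconds = sorted(per_condition_records)
        if len(rconds) >= 2:
            rdiffs = differential_retention(
                per_condition_records[rconds[0]], per_condition_records[rconds[1]]
            )
            pd.DataFrame(
                [
                    {
                        "intron": d.event_id,
                        "ir_1": d.psi_1,
                        "ir_2": d.psi_2,
                        "ir_difference": d.inc_level_difference,
                        "p_value": d.p_value,
                        "fdr": d.fdr,
                    }
                    for d in rdiffs
                ]
            ).to_csv(outdir / "differential_retention.tsv", sep="\t", index=False)

        stage = "consequence"
        all_events = {
            ev.event_id: ev
            for reps in per_condition_events.values()
            for events in reps
            for ev in events
        }
        significant = {d.event_id for d in diffs if d.fdr is not None and d.fdr < cfg.fdr}
        target_events = [all_events[eid] for eid in sorted(significant)] or list(
            all_events.values()
        )
        call_rows = []
        for ev in target_events:
            calls = classify_event_across_isoforms(
                idx,
                ev.gene_id,
                ev.exon,
                genome,
                domains,
                rule_distance=cfg.nmd_distance,
                junction_rule=cfg.nmd_junction_rule,
            )
            if not calls:
                continue
            df = calls_to_frame(calls)
            df.insert(0, "rollup", rollup_label(calls))
            df.insert(0, "event", ev.event_id)
            call_rows.append(df)
        if call_rows:
            pd.concat(call_rows, ignore_index=True).to_csv(
                outdir / "consequence.tsv", sep="\t", index=False
            )

        stage = "overlap"
        sets = []
        universe = set()
        for cs in call_sets.values():
            universe |= {j.key for j in cs.kept}
        for (cond, rep), cs in sorted(call_sets.items()):
            sets.append(
                junction_set_from_keys(cs.sample_id, {j.key for j in cs.kept}, universe)
            )
        if len(sets) >= 2 and universe:
            pairwise_long_format(
                sets, denominator=cfg.shared_proportion_denominator
            ).to_csv(outdir / "overlap.tsv", sep="\t", index=False)

        stage = "features"
        model = train_pwm_from_annotation(idx, genome)
        if target_events:
            summary = exon_event_feature_summary(
                target_events, idx, genome, model, label="events", tpm_gate=cfg.tpm_gate
            )
            summary.table.to_csv(outdir / "features_events.tsv", sep="\t", index=False)
    except Exception:
        manifest["failed_stage"] = stage
        write_manifest("failed")
        raise
    write_manifest("ok")
    return outdir
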