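"""End-to-end orchestration: filter -> classify -> structure -> expression
-> co-expression, driven by one flat config, with a JSON run report.

Each stage writes its outputs as it completes, so a failing stage
leaves the earlier outputs on disk; the error names the failing stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .annotation import (
    GenomeAnnotation,
    GenomeSequence,
    group_loci,
    read_gff3,
    read_gtf,
    write_gtf,
)
from .classify import (
    assign_names,
    class_table,
    classify_all,
    records_table,
    write_bed12,
)
from .coding_filter import FilterConfig, read_evidence_file, run_cascade
from .coexpression import assign_neighbors, bin_counts, coexpression_test, neighbor_table
from .expression import call_specific, read_fpkm
from .structure import summarize

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Flat configuration of the full pipeline (CLI flags override file values)."""

    lnc_gtf: str
    reference: str  # GTF or GFF3 (by extension)
    genome_fasta: str
    outdir: str
    fpkm_tsv: str | None = None
    evidence: dict[str, str] = field(default_factory=dict)  # label -> path
    name_prefix: str = "BPH"
    min_length: int = 200
    min_exons: int = 2
    max_orf: int = 300
    evidence_max_evalue: float = 1e-3
    specific_hi: float = 3.0
    specific_lo: float = 1.0
    specific_fold: float = 10.0
    diff_p_cut: float = 0.01
    diff_q_cut: float = 0.05
    strong_r: float = 0.8
    n_random_pairs: int = 1000
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _read_reference(path: str) -> GenomeAnnotation:
    if str(path).endswith((".gff", ".gff3")):
        ts = read_gff3(path)
    else:
        ts = read_gtf(path, require_strand=True)
    return GenomeAnnotation.from_transcripts(ts)


def run_all(cfg: RunConfig) -> dict:
    """Run every stage; returns (and writes) the JSON-able run report."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "tool": "lncloc",
        "version": __version__,
        "config": asdict(cfg),
        "stages": {},
    }

    def finish(stage: str, payload: dict) -> None:
        report["stages"][stage] = payload
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)

    # ---- filter --------------------------------------------------------
    try:
        transcripts = read_gtf(cfg.lnc_gtf)
        genome = GenomeSequence(cfg.genome_fasta)
        evidence = [
            read_evidence_file(path, label, max_evalue=cfg.evidence_max_evalue)
            for label, path in sorted(cfg.evidence.items())
        ]
        fcfg = FilterConfig(
            min_length=cfg.min_length, min_exons=cfg.min_exons, max_orf=cfg.max_orf
        )
        survivors, freport = run_cascade(transcripts, genome, evidence, fcfg)
        write_gtf(survivors, outdir / "lncrna_candidates.gtf")
        finish(
            "filter",
            {
                "n_input": freport.n_input,
                "n_survivors": freport.n_survivors,
                "steps": freport.to_rows(),
                "stale_evidence": freport.stale_evidence,
            },
        )
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("filter", exc) from exc

    # ---- classify ------------------------------------------------------
    try:
        ann = _read_reference(cfg.reference)
        records = classify_all(survivors, ann)
        loci = group_loci(survivors)
        records = assign_names(records, loci, prefix=cfg.name_prefix)
        records_table(records).to_csv(
            outdir / "classification.tsv", sep="\t", index=False
        )
        class_table(records).to_csv(outdir / "class_table.tsv", sep="\t", index=False)
        write_bed12(records, outdir / "lncrna.bed")
        write_gtf(
            survivors,
            outdir / "lncrna_named.gtf",
            extra_attrs={
                r.transcript_id: {
                    "lnc_class": r.lnc_class.value,
                    "assigned_name": r.assigned_name,
                }
                for r in records
            },
        )
        finish(
            "classify",
            {
                "n_records": len(records),
                "n_loci": len(loci),
                "class_counts": {
                    r["class"]: int(r["count"])
                    for r in class_table(records).to_dict("records")
                }
                if records
                else {},
            },
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("classify", exc) from exc

    # ---- structure -----------------------------------------------------
    try:
        if survivors:
            summary = summarize(survivors, loci)
            with open(outdir / "structure_summary.json", "w") as fh:
                json.dump(summary.to_dict(), fh, indent=2)
            finish("structure", summary.to_dict())
        else:
            finish("structure", {"n_transcripts": 0})
    except Exception as exc:  # noqa: BLE001
        raise StageError("structure", exc) from exc

    # ---- expression ----------------------------------------------------
    fpkm = None
    try:
        if cfg.fpkm_tsv:
            fpkm = read_fpkm(cfg.fpkm_tsv)
            calls = call_specific(
                fpkm.loc[fpkm.index.intersection([t.transcript_id for t in survivors])],
                hi=cfg.specific_hi,
                lo=cfg.specific_lo,
                fold=cfg.specific_fold,
            ) if survivors else []
            with open(outdir / "specific_calls.tsv", "w") as fh:
                fh.write("transcript_id\tsample\tfpkm\tmax_other\n")
                for c in calls:
                    fh.write(
                        f"{c.transcript_id}\t{c.sample_id}\t{c.value:.6g}\t"
                        f"{c.max_other:.6g}\n"
                    )
            finish("expression", {"n_specific_calls": len(calls)})
        else:
            finish("expression", {"skipped": "no FPKM matrix supplied"})
    except Exception as exc:  # noqa: BLE001
        raise StageError("expression", exc) from exc

    # ---- co-expression -------------------------------------------------
    try:
        if cfg.fpkm_tsv and survivors:
            assignments = assign_neighbors(survivors, ann)
            pairs = [
                (a.lnc_id, a.nearest_gene_id)
                for a in assignments
                if a.nearest_gene_id is not None
            ]
            payload: dict[str, Any] = {"bin_counts": bin_counts(assignments)}
            gene_ids = [g for g in ann.genes if g in set(map(str, fpkm.index))]
            usable = [
                p for p in pairs if p[0] in fpkm.index and p[1] in fpkm.index
            ]
            if len(usable) >= 2 and len(gene_ids) >= 2:
                result = coexpression_test(
                    usable,
                    fpkm,
                    gene_ids=gene_ids,
                    n_random=max(cfg.n_random_pairs, len(usable)),
                    seed=cfg.seed,
                    strong_threshold=cfg.strong_r,
                )
                payload.update(result.summary())
                neighbor_table(assignments, result).to_csv(
                    outdir / "neighbors.tsv", sep="\t", index=False
                )
            else:
                neighbor_table(assignments).to_csv(
                    outdir / "neighbors.tsv", sep="\t", index=False
                )
                payload["skipped_test"] = "too few expression-usable pairs"
            finish("coexpression", payload)
        else:
            finish("coexpression", {"skipped": "no FPKM matrix or no survivors"})
    except Exception as exc:  # noqa: BLE001
        raise StageError("coexpression", exc) from exc

    return report
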