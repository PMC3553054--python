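"""One-shot pipeline runner: demux → map → call → filter → annotate → tree.

Every stage reads and writes files, so stages are independently re-runnable;
the runner simply chains them with a validated configuration and records
per-stage counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import annotate as annotate_mod
from . import popgen
from .enzymes import get_enzyme
from .mapping import build_index, map_reads
from .readproc import SampleSheet, process_fastq
from .variants import (
    FilterParams,
    build_pileup,
    discover_variants,
    filter_variants,
    het_correction,
    write_vcf,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All paths and stage parameters for an end-to-end run."""

    reference: str
    fastq: str
    sheet: str
    out_dir: str
    gff: str | None = None
    enzyme: str = "ApeKI"
    min_read_length: int = 25
    mapper_k: int = 31
    mapper_max_mismatch: int = 2
    filters: FilterParams = field(default_factory=FilterParams)
    drop_het: bool = True
    flank: int = 5000
    bootstrap: int = 0
    seed: int = 0

    def validate(self) -> None:
        for label, path in [
            ("reference", self.reference),
            ("fastq", self.fastq),
            ("sheet", self.sheet),
        ]:
            if not Path(path).exists():
                raise FileNotFoundError(f"{label} path does not exist: {path}")
        if self.gff is not None and not Path(self.gff).exists():
            raise FileNotFoundError(f"gff path does not exist: {self.gff}")
        get_enzyme(self.enzyme)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        filt = {
            k: raw.pop(k)
            for k in ("min_depth", "max_missing_fraction", "min_maf")
            if k in raw
        }
        cfg = cls(**raw)
        if filt:
            cfg.filters = FilterParams(**filt)
        return cfg


@dataclass
class PipelineResult:
    vcf: Path
    annotated_vcf: Path | None
    summary: dict
    tree_newick: Path | None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages; artifacts land in ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    enzyme = get_enzyme(config.enzyme)
    sheet = SampleSheet.from_tsv(config.sheet)
    counts: dict[str, object] = {}

    logger.info("stage demux: %s", config.fastq)
    per_sample, run_summary = process_fastq(
        config.fastq, sheet, enzyme, out_dir=out / "demux", min_length=config.min_read_length
    )
    counts["raw_reads"] = run_summary.total_raw
    counts["processed_reads"] = run_summary.total_processed

    logger.info("stage map: building k=%d index", config.mapper_k)
    index = build_index(config.reference, k=config.mapper_k)
    alignments = []
    for sample, reads in per_sample.items():
        alns, tallies = map_reads(reads, index, config.mapper_max_mismatch)
        alignments.extend(alns)
        run_summary.mapped[sample] = tallies["mapped"]
    counts["mapped_reads"] = run_summary.total_mapped
    run_summary.to_frame().to_csv(out / "run_summary.tsv", sep="\t", index=False)

    logger.info("stage call: pileup over %d alignments", len(alignments))
    pileup = build_pileup(alignments, index.ref)
    records = discover_variants(pileup, index.ref, sheet.samples, config.filters)
    counts["raw_variants"] = len(records)
    records, tallies = filter_variants(records, config.filters)
    counts["filter_tallies"] = tallies
    if config.drop_het:
        records = het_correction(records)
    counts["filtered_variants"] = len(records)
    vcf_path = out / "variants.vcf"
    write_vcf(records, index.ref, sheet.samples, vcf_path)

    annotated_path = None
    if config.gff is not None:
        logger.info("stage annotate: %s", config.gff)
        models = annotate_mod.parse_gff3(config.gff)
        annotations = annotate_mod.annotate_variants(
            records, models, index.ref, config.flank
        )
        annotate_mod.annotation_summary(annotations).to_csv(
            out / "annotation_summary.tsv", sep="\t", index=False
        )
        annotated_path = out / "variants.annotated.vcf"
        write_vcf(records, index.ref, sheet.samples, annotated_path)

    tree_path = None
    if records and len(sheet.samples) >= 3:
        matrix = popgen.GenotypeMatrix.from_records(records, sheet.samples)
        dm = popgen.p_distance(matrix)
        dm.to_frame().to_csv(out / "distances.tsv", sep="\t")
        tree_path = out / "tree.nwk"
        if config.bootstrap > 0 and len(sheet.samples) >= 4:
            tree, _ = popgen.bootstrap_consensus(matrix, B=config.bootstrap, seed=config.seed)
        else:
            tree = popgen.neighbor_joining(dm)
        tree.write(str(tree_path))

    with open(out / "stage_counts.json", "w") as fh:
        json.dump(counts, fh, indent=2)
    return PipelineResult(
        vcf=vcf_path,
        annotated_vcf=annotated_path,
        summary=counts,
        tree_newick=tree_path,
    )
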