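"""SNP effect classification against GFF3 gene models.

Each SNP is assigned exactly one structural category — splice site, 5'/3'
UTR, exon, intron inside genes; upstream/downstream (within a 5 kb flank,
strand-aware) or plain intergenic outside — with coding SNPs further
classified as synonymous, nonsynonymous or stop-gained by translating the
reference and alternate codons of the spliced CDS.  The splice window is the
first/last 2 bases of each intron; overlap ties resolve by the priority
SPLICE > UTR > EXON > INTRON, overlapping genes to the gene yielding the
highest-priority category (ties to the smallest gene_id); isoforms collapse
to the longest CDS per gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio.Seq import Seq

from .enzymes import revcomp
from .variants import VariantRecord

__all__ = [
    "GeneModel",
    "SnpAnnotation",
    "parse_gff3",
    "classify_snp",
    "coding_effect",
    "annotate_variants",
    "annotation_summary",
]

logger = logging.getLogger(__name__)

SPLICE_WINDOW = 2  # intron bases at each junction treated as splice site
DEFAULT_FLANK = 5000

CATEGORIES = (
    "SPLICE_SITE",
    "UTR5",
    "UTR3",
    "EXON",
    "INTRON",
    "UPSTREAM_5KB",
    "DOWNSTREAM_5KB",
    "INTERGENIC",
)
_PRIORITY = {c: i for i, c in enumerate(CATEGORIES)}
GENIC = frozenset({"SPLICE_SITE", "UTR5", "UTR3", "EXON", "INTRON"})

Interval = tuple[int, int]  # 0-based half-open


@dataclass
class GeneModel:
    """A stranded gene reduced to one representative isoform."""

    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    start: int  # 0-based
    end: int  # exclusive
    exons: list[Interval] = field(default_factory=list)
    cds: list[tuple[int, int, int]] = field(default_factory=list)  # (start, end, phase)
    partial: bool = False

    def __post_init__(self) -> None:
        self.exons.sort()
        self.cds.sort()
        for (a0, b0), (a1, b1) in zip(self.exons, self.exons[1:]):
            if a1 < b0:
                raise ValueError(f"{self.gene_id}: overlapping exons")

    @property
    def introns(self) -> list[Interval]:
        return [
            (b0, a1) for (_, b0), (a1, _) in zip(self.exons, self.exons[1:]) if a1 > b0
        ]

    @property
    def cds_intervals(self) -> list[Interval]:
        return [(a, b) for a, b, _ in self.cds]

    @property
    def cds_length(self) -> int:
        return sum(b - a for a, b in self.cds_intervals)

    @property
    def utr5(self) -> list[Interval]:
        return self._utrs()[0]

    @property
    def utr3(self) -> list[Interval]:
        return self._utrs()[1]

    def _utrs(self) -> tuple[list[Interval], list[Interval]]:
        """Exonic minus CDS, split 5' vs 3' by strand orientation."""
        if not self.cds:
            return [], []
        cds_lo = min(a for a, _ in self.cds_intervals)
        cds_hi = max(b for _, b in self.cds_intervals)
        before, after = [], []
        for a, b in self.exons:
            if a < cds_lo:
                before.append((a, min(b, cds_lo)))
            if b > cds_hi:
                after.append((max(a, cds_hi), b))
        return (before, after) if self.strand == "+" else (after, before)

    def cds_sequence(self, reference: dict[str, str]) -> str:
        """Spliced CDS on the coding strand, phase of the first segment applied."""
        chrom_seq = reference[self.chrom]
        parts = [chrom_seq[a:b] for a, b in self.cds_intervals]
        if self.strand == "+":
            seq = "".join(parts)
            phase = self.cds[0][2]
        else:
            seq = "".join(revcomp(p) for p in reversed(parts))
            phase = self.cds[-1][2]
        return seq[phase:]

    def genomic_to_cds(self, pos: int) -> int | None:
        """0-based position within the spliced, phase-trimmed coding sequence."""
        offset = 0
        if self.strand == "+":
            phase = self.cds[0][2] if self.cds else 0
            for a, b in self.cds_intervals:
                if a <= pos < b:
                    return offset + (pos - a) - phase
                offset += b - a
        else:
            phase = self.cds[-1][2] if self.cds else 0
            for a, b in reversed(self.cds_intervals):
                if a <= pos < b:
                    return offset + (b - 1 - pos) - phase
                offset += b - a
        return None


@dataclass(frozen=True)
class SnpAnnotation:
    category: str
    coding_effect: str  # SYNONYMOUS | NONSYNONYMOUS | STOP_GAINED | NA
    gene_id: str | None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def parse_gff3(path: str | Path) -> list[GeneModel]:
    """Parse GFF3 gene/mRNA/exon/CDS features into gene models.

    Multiple isoforms collapse to the mRNA with the longest CDS.  Models
    whose total CDS length is not divisible by 3 are flagged partial and
    excluded from codon-effect computation.
    """
    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        best: GeneModel | None = None
        for mrna in db.children(gene, featuretype=("mRNA", "transcript")):
            exons = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")]
            cds = [
                (f.start - 1, f.end, int(f.frame) if f.frame not in (None, ".") else 0)
                for f in db.children(mrna, featuretype="CDS")
            ]
            if not exons and not cds:
                continue
            if not exons:  # CDS-only annotations: treat CDS as exons
                exons = [(a, b) for a, b, _ in cds]
            model = GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                start=gene.start - 1,
                end=gene.end,
                exons=exons,
                cds=sorted(cds),
            )
            model.partial = model.cds_length % 3 != 0
            if best is None or model.cds_length > best.cds_length:
                best = model
        if best is not None:
            models.append(best)
        else:
            logger.warning("gene %s has no usable mRNA children; skipped", gene.id)
    return models


def _in(pos: int, intervals: Iterable[Interval]) -> bool:
    return any(a <= pos < b for a, b in intervals)


def _categorize_within(pos: int, model: GeneModel) -> str | None:
    if not (model.start <= pos < model.end):
        return None
    for a, b in model.introns:
        if a <= pos < b:
            if pos < a + SPLICE_WINDOW or pos >= b - SPLICE_WINDOW:
                return "SPLICE_SITE"
    if _in(pos, model.utr5):
        return "UTR5"
    if _in(pos, model.utr3):
        return "UTR3"
    if _in(pos, model.exons):
        return "EXON"
    if _in(pos, model.introns):
        return "INTRON"
    # inside the gene span but in no annotated segment (sparse annotations)
    return "INTRON"


def classify_snp(
    variant: VariantRecord,
    models: Sequence[GeneModel],
    reference: dict[str, str] | None = None,
    flank: int = DEFAULT_FLANK,
) -> SnpAnnotation:
    """Assign one structural category (and coding effect if exonic-CDS).

    Flanks are measured from the gene-span boundary, strand-aware and
    inclusive at exactly ``flank`` bp; a SNP outside every gene and flank is
    INTERGENIC.
    """
    chrom_models = [m for m in models if m.chrom == variant.chrom]
    if not chrom_models and models:
        logger.warning("no gene models on %s; SNP classified INTERGENIC", variant.chrom)
    pos = variant.pos

    best: tuple[int, str, GeneModel] | None = None
    for m in chrom_models:
        cat = _categorize_within(pos, m)
        if cat is None:
            continue
        key = (_PRIORITY[cat], m.gene_id)
        if best is None or key < (best[0], best[2].gene_id):
            best = (_PRIORITY[cat], cat, m)
    if best is not None:
        _, cat, model = best
        effect = "NA"
        if cat == "EXON" and _in(pos, model.cds_intervals):
            if reference is not None:
                effect = coding_effect(variant, model, reference)
        return SnpAnnotation(cat, effect, model.gene_id)

    # outside all genes: nearest gene decides upstream/downstream
    nearest: tuple[int, str, str] | None = None  # (distance, gene_id, category)
    for m in chrom_models:
        if pos < m.start:
            dist = m.start - pos
            cat = "UPSTREAM_5KB" if m.strand == "+" else "DOWNSTREAM_5KB"
        else:
            dist = pos - (m.end - 1)
            cat = "DOWNSTREAM_5KB" if m.strand == "+" else "UPSTREAM_5KB"
        if dist <= flank and (nearest is None or (dist, m.gene_id) < nearest[:2]):
            nearest = (dist, m.gene_id, cat)
    if nearest is not None:
        return SnpAnnotation(nearest[2], "NA", nearest[1])
    return SnpAnnotation("INTERGENIC", "NA", None)


def coding_effect(
    variant: VariantRecord, model: GeneModel, reference: dict[str, str]
) -> str:
    """SYNONYMOUS / NONSYNONYMOUS / STOP_GAINED for a biallelic-per-alt SNP.

    Multi-allelic SNPs evaluate each alternate allele and report the worst
    effect (STOP_GAINED > NONSYNONYMOUS > SYNONYMOUS).  Returns "NA" with a
    warning for partial CDS models.
    """
    if model.partial:
        logger.warning("%s: partial CDS; coding effect NA", model.gene_id)
        return "NA"
    if variant.type != "SNP":
        return "NA"
    cds_pos = model.genomic_to_cds(variant.pos)
    if cds_pos is None or cds_pos < 0:
        return "NA"
    cds_seq = model.cds_sequence(reference)
    codon_i, within = divmod(cds_pos, 3)
    codon = cds_seq[codon_i * 3 : codon_i * 3 + 3]
    if len(codon) < 3:
        return "NA"
    severity = {"SYNONYMOUS": 0, "NONSYNONYMOUS": 1, "STOP_GAINED": 2}
    worst = None
    for alt in variant.alts:
        alt_base = alt if model.strand == "+" else revcomp(alt)
        alt_codon = codon[:within] + alt_base + codon[within + 1 :]
        ref_aa = str(Seq(codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        if alt_aa == "*" and ref_aa != "*":
            eff = "STOP_GAINED"
        elif alt_aa == ref_aa:
            eff = "SYNONYMOUS"
        else:
            eff = "NONSYNONYMOUS"
        if worst is None or severity[eff] > severity[worst]:
            worst = eff
    return worst or "NA"


def annotate_variants(
    records: Sequence[VariantRecord],
    models: Sequence[GeneModel],
    reference: dict[str, str] | None = None,
    flank: int = DEFAULT_FLANK,
) -> list[SnpAnnotation]:
    """Classify every record, storing ANN=category|gene|effect on each."""
    annotations = []
    for rec in records:
        ann = classify_snp(rec, models, reference, flank)
        rec.annotations["ANN"] = f"{ann.category}|{ann.gene_id or '.'}|{ann.coding_effect}"
        annotations.append(ann)
    return annotations


def annotation_summary(annotations: Sequence[SnpAnnotation]) -> pd.DataFrame:
    """Category percentages plus genic/intergenic and SYN/NONSYN splits.

    Upstream/downstream are sub-labels of the intergenic compartment;
    percentages within each partition sum to 100.
    """
    if not annotations:
        return pd.DataFrame(columns=["partition", "label", "count", "percent"])
    n = len(annotations)
    rows = []
    for cat in CATEGORIES:
        count = sum(1 for a in annotations if a.category == cat)
        rows.append(("category", cat, count, 100.0 * count / n))
    genic = sum(1 for a in annotations if a.category in GENIC)
    rows.append(("compartment", "GENIC", genic, 100.0 * genic / n))
    rows.append(("compartment", "INTERGENIC", n - genic, 100.0 * (n - genic) / n))
    coding = [a for a in annotations if a.coding_effect != "NA"]
    if coding:
        syn = sum(1 for a in coding if a.coding_effect == "SYNONYMOUS")
        nonsyn = len(coding) - syn  # amino-acid change or stop gain
        stop = sum(1 for a in coding if a.coding_effect == "STOP_GAINED")
        rows.append(("coding", "SYNONYMOUS", syn, 100.0 * syn / len(coding)))
        rows.append(("coding", "NONSYNONYMOUS_OR_STOP", nonsyn, 100.0 * nonsyn / len(coding)))
        rows.append(("coding", "STOP_GAINED", stop, 100.0 * stop / len(coding)))
    return pd.DataFrame(rows, columns=["partition", "label", "count", "percent"])
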