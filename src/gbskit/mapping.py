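"""Placement of processed reads on the reference at unique locations.

Two routes are supported: a built-in exact k-mer mapper for desk-scale
references (seed with the first k-mer on both strands, extend by direct
comparison allowing a bounded number of substitutions, no gaps), and import
of externally produced SAM where "unique location" is operationalized as a
primary, mapped record with MAPQ above a threshold.  Reads matching more
than one location are never emitted as alignments.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pysam
from Bio import SeqIO

from .enzymes import revcomp
from .readproc import ProcessedRead

__all__ = ["Alignment", "KmerIndex", "build_index", "map_read", "map_reads", "import_sam"]

logger = logging.getLogger(__name__)

#: cigar operations modelled: M (match/mismatch), I (insertion), D (deletion)
Cigar = tuple[tuple[str, int], ...]


@dataclass(frozen=True)
class Alignment:
    """A uniquely placed read."""

    read_id: str
    sample_id: str
    chrom: str
    pos: int  # 0-based leftmost reference position
    strand: str  # "+" or "-"
    cigar: Cigar
    seq: str  # read sequence in reference orientation

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.cigar if op in "MD")

    @property
    def end(self) -> int:
        return self.pos + self.ref_span


class KmerIndex:
    """Canonical k-mer index of a reference (desk-scale, in memory)."""

    def __init__(self, reference: dict[str, str], k: int = 31):
        self.k = k
        self.ref = {c: s.upper() for c, s in reference.items()}
        self.index: dict[str, list[tuple[str, int]]] = {}
        if not self.ref:
            raise ValueError("cannot index an empty reference")
        for chrom, seq in self.ref.items():
            if len(seq) < k:
                warnings.warn(f"contig {chrom} shorter than k={k}; skipped")
                continue
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if "N" in kmer:
                    continue
                canon = min(kmer, revcomp(kmer))
                self.index.setdefault(canon, []).append((chrom, pos))

    @classmethod
    def from_fasta(cls, path: str | Path, k: int = 31) -> "KmerIndex":
        ref: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in ref:
                raise ValueError(f"duplicate contig name {rec.id!r} in {path}")
            ref[rec.id] = str(rec.seq).upper()
        return cls(ref, k=k)


def build_index(reference: dict[str, str] | str | Path, k: int = 31) -> KmerIndex:
    """Build a :class:`KmerIndex` from a FASTA path or a name→sequence dict."""
    if isinstance(reference, (str, Path)):
        return KmerIndex.from_fasta(reference, k=k)
    return KmerIndex(reference, k=k)


def _mismatches(a: str, b: str, limit: int) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


def map_read(
    read: ProcessedRead, index: KmerIndex, max_mismatch: int = 2
) -> Alignment | str:
    """Map one read; returns an Alignment or ``"ambiguous"`` / ``"unmapped"``.

    Seeds with up to three non-overlapping k-mers (offsets 0, k, 2k) on both
    strands and extends each candidate by direct comparison allowing
    ``max_mismatch`` substitutions; by pigeonhole, a read of length >= 3k
    with at most two mismatches always retains one clean seed.
    Substitution-only: reads carrying indels relative to the reference will
    not place with the built-in mapper (use SAM import for indel discovery).
    """
    seq = read.seq
    k = index.k
    if len(seq) < k:
        return "unmapped"
    rc = revcomp(seq)
    candidates: set[tuple[str, int, str]] = set()
    for off in (0, k, 2 * k):
        if off + k > len(seq):
            break
        qk = seq[off : off + k]
        if "N" in qk:
            continue
        for chrom, pos in index.index.get(min(qk, revcomp(qk)), ()):
            window = index.ref[chrom][pos : pos + k]
            if window == qk:
                candidates.add((chrom, pos - off, "+"))
            if window == revcomp(qk):
                candidates.add((chrom, pos - (len(seq) - off - k), "-"))
    hits: list[tuple[str, int, str]] = []
    for chrom, start, strand in candidates:
        ref = index.ref[chrom]
        if start < 0 or start + len(seq) > len(ref):
            continue
        probe = seq if strand == "+" else rc
        if _mismatches(probe, ref[start : start + len(seq)], max_mismatch) <= max_mismatch:
            hits.append((chrom, start, strand))
    hits = sorted(set(hits))
    if not hits:
        return "unmapped"
    if len(hits) > 1:
        return "ambiguous"
    chrom, pos, strand = hits[0]
    return Alignment(
        read_id=read.source_read_id,
        sample_id=read.sample_id,
        chrom=chrom,
        pos=pos,
        strand=strand,
        cigar=(("M", len(seq)),),
        seq=seq if strand == "+" else revcomp(seq),
    )


def map_reads(
    reads: Iterable[ProcessedRead], index: KmerIndex, max_mismatch: int = 2
) -> tuple[list[Alignment], dict[str, int]]:
    """Map a batch of reads; returns alignments and {unmapped, ambiguous, mapped} tallies."""
    alignments: list[Alignment] = []
    tallies = {"mapped": 0, "ambiguous": 0, "unmapped": 0}
    for read in reads:
        result = map_read(read, index, max_mismatch)
        if isinstance(result, Alignment):
            alignments.append(result)
            tallies["mapped"] += 1
        else:
            tallies[result] += 1
    return alignments, tallies


def _cigar_from_pysam(cigartuples) -> Cigar:
    ops = []
    for op, n in cigartuples:
        if op == 0:  # M
            ops.append(("M", n))
        elif op == 1:  # I
            ops.append(("I", n))
        elif op == 2:  # D
            ops.append(("D", n))
        elif op == 4:  # S: soft clip, not modelled — treat as hard error
            raise ValueError("soft-clipped SAM records are not supported")
        else:
            raise ValueError(f"unsupported cigar operation code {op}")
    return tuple(ops)


def import_sam(
    path: str | Path,
    min_mapq: int = 20,
    reference_names: Iterable[str] | None = None,
    sample_id: str | None = None,
) -> Iterator[Alignment]:
    """Stream uniquely mapped alignments from a SAM file.

    Keeps primary, mapped records with MAPQ >= ``min_mapq`` and no
    secondary/supplementary flags.  Sample identity is taken from the RG tag
    when present, else ``sample_id``.  Raises if the SAM header's reference
    names disagree with ``reference_names`` when given.
    """
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        if reference_names is not None:
            have = set(sam.references)
            want = set(reference_names)
            if not want <= have:
                raise ValueError(
                    f"SAM header references {sorted(have)} do not cover expected {sorted(want)}"
                )
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            sid = sample_id
            if rec.has_tag("RG"):
                sid = rec.get_tag("RG")
            yield Alignment(
                read_id=rec.query_name,
                sample_id=sid or "sample",
                chrom=rec.reference_name,
                pos=rec.reference_start,
                strand="-" if rec.is_reverse else "+",
                cigar=_cigar_from_pysam(rec.cigartuples),
                seq=rec.query_sequence,
            )
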