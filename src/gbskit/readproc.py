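"""Raw-read grooming, barcode demultiplexing and adapter clipping.

A well-formed GBS read is ``barcode + restriction-site remnant + insert``;
short inserts read through into the distal remnant and then the common
adapter.  Processing therefore (1) assigns each read to a sample by exact
longest-prefix barcode match, (2) validates that the bases after the barcode
match the enzyme remnant (ApeKI: C[AT]GC), (3) clips adapter read-through
immediately after the distal remnant, and (4) discards reads shorter than a
minimum length or containing N.
"""

from __future__ import annotations

import gzip
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import pandas as pd

from .enzymes import RestrictionEnzyme

__all__ = [
    "COMMON_ADAPTER_PREFIX",
    "SampleSheet",
    "ReadRecord",
    "ProcessedRead",
    "RunSummary",
    "demultiplex",
    "clip_adapter",
    "quality_filter",
    "process_fastq",
    "downsample_reads",
]

#: First bases of the common adapter as they appear in a read-through read
#: (reverse complement of the adapter's ligation strand).
COMMON_ADAPTER_PREFIX = "AGATCGGAAGAGC"

MIN_ADAPTER_EVIDENCE = 5  # exact adapter-prefix bases required to clip mid-read


@dataclass(frozen=True)
class SampleSheet:
    """Sample-to-barcode assignments.

    Barcodes must be unique, 4-8 bp over ACGT, and prefix-free (no barcode a
    prefix of another) so that longest-prefix matching is unambiguous.
    """

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        samples = [s for s, _ in self.entries]
        barcodes = [b for _, b in self.entries]
        if len(set(samples)) != len(samples):
            raise ValueError("sample_ids must be unique")
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("barcodes must be unique")
        for b in barcodes:
            if not (4 <= len(b) <= 8) or set(b) - set("ACGT"):
                raise ValueError(f"barcode {b!r} must be 4-8 bases over ACGT")
        for a in barcodes:
            for b in barcodes:
                if a != b and b.startswith(a):
                    raise ValueError(f"barcode {a!r} is a prefix of {b!r}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        entries = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                sample_id, barcode = line.split("\t")[:2]
                entries.append((sample_id, barcode.upper()))
        return cls(tuple(entries))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sample_id, barcode in self.entries:
                fh.write(f"{sample_id}\t{barcode}\n")

    @property
    def barcode_to_sample(self) -> dict[str, str]:
        return {b: s for s, b in self.entries}

    @property
    def samples(self) -> list[str]:
        return [s for s, _ in self.entries]


@dataclass(frozen=True)
class ReadRecord:
    id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")


@dataclass(frozen=True)
class ProcessedRead:
    """A demultiplexed read: barcode removed, remnant retained (genomic)."""

    sample_id: str
    seq: str
    qual: str
    source_read_id: str


@dataclass
class RunSummary:
    """Per-sample read accounting: raw → processed → mapped."""

    raw: dict[str, int] = field(default_factory=dict)
    processed: dict[str, int] = field(default_factory=dict)
    mapped: dict[str, int] = field(default_factory=dict)
    unassigned: dict[str, int] = field(default_factory=dict)  # reason → count
    dropped: dict[str, int] = field(default_factory=dict)  # reason → count

    @property
    def total_raw(self) -> int:
        return sum(self.raw.values()) + sum(self.unassigned.values())

    @property
    def total_processed(self) -> int:
        return sum(self.processed.values())

    @property
    def total_mapped(self) -> int:
        return sum(self.mapped.values())

    def percent_processed(self, sample: str | None = None) -> float:
        """Processed/raw x 100, rounded to 2 decimals (per sample or overall)."""
        if sample is None:
            raw = sum(self.raw.values())
            proc = self.total_processed
        else:
            raw, proc = self.raw.get(sample, 0), self.processed.get(sample, 0)
        return round(100.0 * proc / raw, 2) if raw else 0.0

    def percent_mapped(self, sample: str | None = None) -> float:
        """Mapped/processed x 100, rounded to 2 decimals."""
        if sample is None:
            proc, mapped = self.total_processed, self.total_mapped
        else:
            proc, mapped = self.processed.get(sample, 0), self.mapped.get(sample, 0)
        return round(100.0 * mapped / proc, 2) if proc else 0.0

    def to_frame(self) -> pd.DataFrame:
        samples = sorted(set(self.raw) | set(self.processed) | set(self.mapped))
        return pd.DataFrame(
            {
                "sample": samples,
                "raw_reads": [self.raw.get(s, 0) for s in samples],
                "processed_reads": [self.processed.get(s, 0) for s in samples],
                "processed_pct": [self.percent_processed(s) for s in samples],
                "mapped_reads": [self.mapped.get(s, 0) for s in samples],
                "mapped_pct": [self.percent_mapped(s) for s in samples],
            }
        )


def _open_maybe_gzip(path: str | Path, mode: str = "rt") -> TextIO:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def parse_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream a FASTQ file (optionally gzipped), validating record layout."""
    with _open_maybe_gzip(path) as fh:
        recno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            recno += 1
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise ValueError(f"malformed FASTQ record #{recno} in {path}")
            if len(seq) != len(qual):
                raise ValueError(f"malformed FASTQ record #{recno} in {path}: seq/qual length")
            yield ReadRecord(header[1:].split()[0], seq.upper(), qual)


def write_fastq(reads: Iterable[ReadRecord | ProcessedRead], path: str | Path) -> int:
    n = 0
    with _open_maybe_gzip(path, "wt") as fh:
        for r in reads:
            rid = r.id if isinstance(r, ReadRecord) else r.source_read_id
            fh.write(f"@{rid}\n{r.seq}\n+\n{r.qual}\n")
            n += 1
    return n


def demultiplex(
    read: ReadRecord, sheet: SampleSheet, enzyme: RestrictionEnzyme
) -> tuple[str, ProcessedRead] | tuple[None, str]:
    """Assign a read to a sample by barcode + remnant layout check.

    Returns ``(sample_id, ProcessedRead)`` on success, else ``(None, reason)``
    with reason ``"no_barcode"`` or ``"bad_remnant"``.  The barcode is
    removed; the remnant stays on the read (it is genomic sequence).
    """
    barcode_map = sheet.barcode_to_sample
    match = None
    for barcode, sample in barcode_map.items():
        if read.seq.startswith(barcode):
            match = (barcode, sample)
            break  # prefix-free sheet: at most one match
    if match is None:
        return None, "no_barcode"
    barcode, sample = match
    rest = read.seq[len(barcode) :]
    if not enzyme.remnant_regex.match(rest):
        return None, "bad_remnant"
    return sample, ProcessedRead(
        sample_id=sample,
        seq=rest,
        qual=read.qual[len(barcode) :],
        source_read_id=read.id,
    )


def clip_adapter(
    seq: str,
    qual: str,
    enzyme: RestrictionEnzyme,
    adapter_prefix: str = COMMON_ADAPTER_PREFIX,
) -> tuple[str, str]:
    """Clip adapter read-through, keeping the distal restriction remnant.

    Scans for (remnant pattern) followed by adapter evidence: at least
    MIN_ADAPTER_EVIDENCE exact adapter-prefix bases mid-read, or an
    adapter-prefix run (however short) flush at the read end; a remnant
    flush at the read end is likewise accepted (the fragment ended exactly
    at the read's last base).  The read is truncated immediately after the
    distal remnant.  The remnant at position 0 (the read's own 5' remnant)
    is never a clipping signal.
    """
    pat = enzyme.remnant_regex
    m_len = len(enzyme.remnant)
    for pos in range(1, len(seq) - m_len + 1):
        if not pat.match(seq, pos):
            continue
        after = seq[pos + m_len :]
        if not after:  # remnant flush at read end: nothing to remove
            break
        take = min(len(after), len(adapter_prefix))
        if adapter_prefix.startswith(after[:take]) and (
            take >= MIN_ADAPTER_EVIDENCE or take == len(after)
        ):
            end = pos + m_len
            return seq[:end], qual[:end]
    return seq, qual


def quality_filter(read: ProcessedRead, min_length: int = 25) -> str | None:
    """Return a drop reason (``"too_short"`` / ``"contains_N"``) or None to keep."""
    if len(read.seq) < min_length:
        return "too_short"
    if "N" in read.seq:
        return "contains_N"
    return None


def process_fastq(
    fastq_paths: Iterable[str | Path] | str | Path,
    sheet: SampleSheet,
    enzyme: RestrictionEnzyme,
    out_dir: str | Path | None = None,
    min_length: int = 25,
    adapter_prefix: str = COMMON_ADAPTER_PREFIX,
) -> tuple[dict[str, list[ProcessedRead]], RunSummary]:
    """Demultiplex → clip → filter a run; optionally write per-sample FASTQ.

    Returns the per-sample processed reads and a :class:`RunSummary` whose
    totals satisfy assigned + unassigned = raw.
    """
    if isinstance(fastq_paths, (str, Path)):
        fastq_paths = [fastq_paths]
    per_sample: dict[str, list[ProcessedRead]] = {s: [] for s in sheet.samples}
    summary = RunSummary(
        raw={s: 0 for s in sheet.samples},
        processed={s: 0 for s in sheet.samples},
    )
    for path in fastq_paths:
        for read in parse_fastq(path):
            sample, result = demultiplex(read, sheet, enzyme)
            if sample is None:
                summary.unassigned[result] = summary.unassigned.get(result, 0) + 1
                continue
            summary.raw[sample] += 1
            proc: ProcessedRead = result
            seq, qual = clip_adapter(proc.seq, proc.qual, enzyme, adapter_prefix)
            proc = ProcessedRead(sample, seq, qual, proc.source_read_id)
            reason = quality_filter(proc, min_length)
            if reason is not None:
                summary.dropped[reason] = summary.dropped.get(reason, 0) + 1
                continue
            summary.processed[sample] += 1
            per_sample[sample].append(proc)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sample, reads in per_sample.items():
            write_fastq(reads, out_dir / f"{sample}.fq")
    return per_sample, summary


def downsample_reads(
    reads: Iterable[ReadRecord],
    n_reads: int | None = None,
    fraction: float | None = None,
    seed: int = 0,
) -> list[ReadRecord]:
    """Uniform random subsample without replacement, reproducible by seed.

    Models reduced per-sample sequencing effort at higher multiplex levels
    (e.g. 2 M → 1 M → 0.5 M reads/sample for 96- → 192- → 384-plex).
    """
    pool = list(reads)
    if n_reads is None:
        if fraction is None or not 0 < fraction <= 1:
            raise ValueError("provide n_reads or fraction in (0, 1]")
        n_reads = round(len(pool) * fraction)
    if n_reads > len(pool):
        raise ValueError(f"requested {n_reads} reads but only {len(pool)} available")
    rng = random.Random(seed)
    idx = sorted(rng.sample(range(len(pool)), n_reads))
    return [pool[i] for i in idx]
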