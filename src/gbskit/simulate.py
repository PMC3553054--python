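"""Synthetic GBS experiment generator with full ground truth.

Emulates, computationally, the structure of a multiplexed single-end GBS
run: a small reference with restriction sites planted at a target density,
truth SNPs/indels with per-sample diploid genotypes, and barcoded reads
taken from the cut ends of internal restriction fragments with
Poisson-distributed per-fragment depth, adapter read-through on short
fragments, and uniform substitution error.  Every read carries provenance
(sample, fragment, end, truth alignment), so each pipeline stage can be
scored against truth.  All randomness flows from a single seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .digest import Fragment, digest_sequence, find_cut_sites, selective_subset
from .enzymes import BUILTIN_ENZYMES, RestrictionEnzyme, expand_iupac, revcomp
from .readproc import COMMON_ADAPTER_PREFIX, ReadRecord, SampleSheet
from .variants import (
    AlleleKey,
    GenotypeCall,
    GenotypeCode,
    VariantRecord,
    _allele_strings,
    write_vcf,
)

__all__ = [
    "SimConfig",
    "TruthSet",
    "simulate_reference",
    "simulate_genotypes",
    "simulate_reads",
    "simulate_selective",
    "simulate_experiment",
    "evaluate_recovery",
]

#: Bases a read runs into after the distal remnant on short fragments.
ADAPTER_READTHROUGH = COMMON_ADAPTER_PREFIX + "GTCGGTGTAGATCTCGGTGGTCGCCGTATCATT" * 4

_BASES = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic GBS experiment.

    Defaults model a desk-scale analogue of an eight-sample ApeKI pilot:
    fragments averaging ~250 bp (most fall in the 100-400 bp amplifiable
    window), 100 bp reads, mean depth 5 reads per fragment per sample, and
    genotype class priors of 55% reference-homozygous, 40% alternate-
    homozygous, 5% heterozygous at variant sites.  Indels default to 5% of
    planted variants when ``n_indels`` is set accordingly by the caller.
    """

    seed: int
    n_contigs: int = 2
    contig_length: int = 30_000
    enzyme: RestrictionEnzyme = BUILTIN_ENZYMES["ApeKI"]
    mean_fragment: int = 250
    n_samples: int = 8
    barcodes: tuple[str, ...] | None = None
    n_snps: int = 200
    n_indels: int = 0
    hom_ref_fraction: float = 0.55
    hom_alt_fraction: float = 0.40
    het_fraction: float = 0.05
    read_length: int = 100
    mean_depth: float = 5.0
    error_rate: float = 0.0
    adapter_read_through: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if min(self.n_contigs, self.contig_length, self.n_samples, self.n_snps) < 0:
            raise ValueError("counts must be non-negative")
        total = self.hom_ref_fraction + self.hom_alt_fraction + self.het_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError("genotype class fractions must sum to 1")
        if self.mean_fragment < len(self.enzyme.recognition) + 8:
            raise ValueError("mean_fragment too small for the recognition site")

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_samples)]

    def sheet(self) -> SampleSheet:
        barcodes = self.barcodes
        if barcodes is None:
            pool = []
            for i in range(self.n_samples):
                # fixed-length barcodes are automatically prefix-free
                b = ""
                x = i
                for _ in range(3):
                    b += _BASES[x % 4]
                    x //= 4
                pool.append(b + "GT")
            barcodes = tuple(pool)
        return SampleSheet(tuple(zip(self.sample_ids, barcodes)))


@dataclass(frozen=True)
class TruthVariant:
    chrom: str
    pos: int
    ref_key: str  # reference base at pos (allele key)
    alt_key: AlleleKey
    type: str  # SNP | INDEL


@dataclass
class TruthSet:
    """Reference, truth genotypes and read provenance for one simulation."""

    config: SimConfig
    reference: dict[str, str]
    fragments: dict[str, list[Fragment]]
    variants: list[TruthVariant]
    genotypes: dict[str, list[GenotypeCode]] = field(default_factory=dict)
    provenance: pd.DataFrame | None = None
    reads: list[ReadRecord] = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return self.config.sample_ids

    def internal_fragments(self) -> list[Fragment]:
        return [f for frags in self.fragments.values() for f in frags if f.internal]

    def truth_records(self) -> list[VariantRecord]:
        """Truth genotypes as VariantRecords (VCF-style allele strings)."""
        records = []
        for vi, tv in enumerate(self.variants):
            ref_str, mapping = _allele_strings(
                self.reference[tv.chrom], tv.pos, [tv.ref_key, tv.alt_key]
            )
            calls = {}
            for s in self.samples:
                code = self.genotypes[s][vi]
                if code is GenotypeCode.HOM_REF:
                    alleles: tuple = (mapping[tv.ref_key],)
                elif code is GenotypeCode.HOM_ALT:
                    alleles = (mapping[tv.alt_key],)
                else:
                    alleles = tuple(
                        sorted((mapping[tv.ref_key], mapping[tv.alt_key]))
                    )
                calls[s] = GenotypeCall(code, alleles, depth=0)
            records.append(
                VariantRecord(
                    chrom=tv.chrom,
                    pos=tv.pos,
                    ref=ref_str,
                    alts=(mapping[tv.alt_key],),
                    type=tv.type,
                    calls=calls,
                )
            )
        return sorted(records, key=lambda r: (r.chrom, r.pos))

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write ref.fa, truth.vcf, reads.fq, sheet.tsv, provenance.tsv."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "reference": out / "ref.fa",
            "truth_vcf": out / "truth.vcf",
            "reads": out / "reads.fq",
            "sheet": out / "sheet.tsv",
            "provenance": out / "provenance.tsv",
        }
        with open(paths["reference"], "w") as fh:
            for chrom, seq in self.reference.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        write_vcf(self.truth_records(), self.reference, self.samples, paths["truth_vcf"])
        from .readproc import write_fastq

        write_fastq(self.reads, paths["reads"])
        self.config.sheet().to_tsv(paths["sheet"])
        if self.provenance is not None:
            self.provenance.to_csv(paths["provenance"], sep="\t", index=False)
        return paths

    def write_truth_sam(self, path: str | Path) -> None:
        """Write the true alignments of the processed (genomic) read parts.

        Reads are emitted at their provenance coordinates with MAPQ 60 and an
        RG tag carrying the sample, providing an oracle input for SAM import.
        """
        header = {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [
                {"SN": chrom, "LN": len(seq)} for chrom, seq in self.reference.items()
            ],
            "RG": [{"ID": s, "SM": s} for s in self.samples],
        }
        chrom_ids = {chrom: i for i, chrom in enumerate(self.reference)}
        with pysam.AlignmentFile(str(path), "w", header=header) as sam:
            for row in self.provenance.itertuples():
                rec = pysam.AlignedSegment(sam.header)
                rec.query_name = row.read_id
                rec.query_sequence = row.ref_oriented_seq
                rec.query_qualities = pysam.qualitystring_to_array(
                    "I" * len(row.ref_oriented_seq)
                )
                rec.reference_id = chrom_ids[row.chrom]
                rec.reference_start = row.ref_start
                rec.cigarstring = row.cigar
                rec.mapping_quality = 60
                rec.flag = 16 if row.end == "R" else 0
                rec.set_tag("RG", row.sample)
                sam.write(rec)


# --- reference ---------------------------------------------------------------


def simulate_reference(config: SimConfig) -> dict[str, str]:
    """Random contigs with enzyme sites planted at the target density.

    Site spacing is exponential with mean ``mean_fragment`` (minimum gap one
    recognition length + 3 bp), and spurious recognition matches elsewhere
    are removed by rejection resampling, so digesting the output recovers
    exactly the planted sites.
    """
    rng = random.Random(config.seed)
    enzyme = config.enzyme
    site_choices = expand_iupac(enzyme.recognition)
    site_len = len(enzyme.recognition)
    min_gap = site_len + 3
    reference: dict[str, str] = {}
    for ci in range(config.n_contigs):
        seq = [rng.choice(_BASES) for _ in range(config.contig_length)]
        planted: list[int] = []
        pos = int(rng.expovariate(1.0 / config.mean_fragment)) + min_gap
        while pos + site_len < config.contig_length - min_gap:
            site = rng.choice(site_choices)
            seq[pos : pos + site_len] = site
            planted.append(pos)
            gap = max(int(rng.expovariate(1.0 / config.mean_fragment)), min_gap)
            pos += gap
        sequence = _reject_spurious_sites("".join(seq), enzyme, planted, rng)
        reference[f"chr{ci + 1}"] = sequence
    return reference


def _reject_spurious_sites(
    seq: str, enzyme: RestrictionEnzyme, planted: list[int], rng: random.Random
) -> str:
    site_len = len(enzyme.recognition)
    protected = set()
    for p in planted:
        protected.update(range(p, p + site_len))
    chars = list(seq)
    planted_set = set(planted)
    for _ in range(200):
        matches = [m.start() for m in enzyme.site_regex.finditer("".join(chars))]
        spurious = [m for m in matches if m not in planted_set]
        if not spurious:
            break
        for m in spurious:
            editable = [
                i for i in range(m, m + site_len) if i not in protected and i < len(chars)
            ]
            if not editable:
                continue
            i = rng.choice(editable)
            chars[i] = rng.choice([b for b in _BASES if b != chars[i]])
    else:
        raise RuntimeError("could not eliminate spurious restriction sites")
    return "".join(chars)


# --- truth variants ----------------------------------------------------------

#: minimum spacing between planted variants; keeps any single read from
#: spanning more than two substitutions (the built-in mapper's tolerance)
MIN_VARIANT_SPACING = 55


#: shortest fragment window that accepts truth variants: any covering read
#: must keep at least one variant-free seed k-mer for the built-in mapper
MIN_PLANT_WINDOW = 64


def _capture_zones(frag: Fragment, config: SimConfig) -> list[tuple[int, int]]:
    """Reference intervals of a fragment coverable by reads from its ends.

    A read entering from the left covers ``[insert_start, insert_start+cov)``
    and from the right ``[insert_end-cov, insert_end)`` where ``cov`` is the
    genomic read capacity; zones are shrunk by small safety margins and stay
    clear of both recognition sites.
    """
    enzyme = config.enzyme
    m = len(enzyme.remnant)
    sheet = config.sheet()
    bc_len = max(len(b) for _, b in sheet.entries)
    core_len = config.read_length - bc_len
    insert_start = frag.start
    insert_end = frag.end + enzyme.overhang_shift
    window = insert_end - insert_start
    if window < MIN_PLANT_WINDOW:
        return []
    cov = min(core_len, window)
    lo = insert_start + m + 2
    hi = insert_end - m - 8
    if hi <= lo:
        return []
    left = (lo, min(insert_start + cov - 2, hi))
    right = (max(insert_end - cov + 2, lo), hi)
    if right[0] <= left[1]:  # the two reaches overlap: one merged zone
        return [(lo, hi)]
    zones = []
    if left[1] > left[0]:
        zones.append(left)
    if right[1] > right[0]:
        zones.append(right)
    return zones


def simulate_genotypes(config: SimConfig, reference: dict[str, str]) -> TruthSet:
    """Plant truth SNPs/indels inside read-capturable fragment zones and draw
    per-sample genotypes from the configured class fractions.

    Every variant is guaranteed at least one non-reference genotype across
    the cohort (an all-reference draw is redrawn), since a variant observed
    in no sample is undiscoverable by construction.
    """
    rng = random.Random(config.seed + 1)
    fragments = {
        chrom: digest_sequence(seq, config.enzyme, chrom=chrom)
        for chrom, seq in reference.items()
    }
    truth = TruthSet(config=config, reference=reference, fragments=fragments, variants=[])
    candidates: list[tuple[str, int]] = []
    for chrom, frags in fragments.items():
        for f in frags:
            if not f.internal:
                continue
            for lo, hi in _capture_zones(f, config):
                candidates.extend((chrom, p) for p in range(lo, hi))
    rng.shuffle(candidates)
    chosen: list[tuple[str, int]] = []
    used: dict[str, list[int]] = {}
    n_wanted = config.n_snps + config.n_indels
    for chrom, p in candidates:
        if len(chosen) >= n_wanted:
            break
        if any(abs(p - q) < MIN_VARIANT_SPACING for q in used.get(chrom, ())):
            continue
        chosen.append((chrom, p))
        used.setdefault(chrom, []).append(p)
    if len(chosen) < n_wanted:
        raise ValueError(
            f"only {len(chosen)} variant positions available for {n_wanted} requested"
        )
    chosen.sort()
    indel_slots = set(
        rng.sample(range(len(chosen)), config.n_indels) if config.n_indels else []
    )
    for vi, (chrom, pos) in enumerate(chosen):
        ref_base = reference[chrom][pos]
        if vi in indel_slots:
            size = rng.randint(1, 5)
            if rng.random() < 0.5:
                alt_key: AlleleKey = ("I", "".join(rng.choice(_BASES) for _ in range(size)))
            else:
                alt_key = ("D", size)
            vtype = "INDEL"
        else:
            alt_key = rng.choice([b for b in _BASES if b != ref_base])
            vtype = "SNP"
        truth.variants.append(TruthVariant(chrom, pos, ref_base, alt_key, vtype))

    codes = (GenotypeCode.HOM_REF, GenotypeCode.HOM_ALT, GenotypeCode.HET)
    weights = (config.hom_ref_fraction, config.hom_alt_fraction, config.het_fraction)
    truth.genotypes = {s: [] for s in config.sample_ids}
    for _ in truth.variants:
        while True:
            draw = rng.choices(codes, weights=weights, k=config.n_samples)
            if any(c is not GenotypeCode.HOM_REF for c in draw):
                break
        for s, c in zip(config.sample_ids, draw):
            truth.genotypes[s].append(c)
    return truth


# --- reads -------------------------------------------------------------------


def _build_haplotype(
    ref_insert: str, insert_start: int, variants: list[tuple[int, str, AlleleKey]]
) -> tuple[str, list[tuple[str, int]]]:
    """Apply variants (ref_pos, ref_base, alt_key) to an insert sequence.

    Returns the haplotype sequence and cigar-style ops (M/I/D runs) mapping
    it back to the reference insert, in reference orientation.
    """
    seq_parts: list[str] = []
    ops: list[tuple[str, int]] = []

    def push(op: str, n: int) -> None:
        if n <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    cur = 0  # position within ref_insert
    for pos, ref_base, alt in sorted(variants):
        rel = pos - insert_start
        if isinstance(alt, str):  # SNP
            seq_parts.append(ref_insert[cur:rel] + alt)
            push("M", rel - cur + 1)
            cur = rel + 1
        elif alt[0] == "I":
            seq_parts.append(ref_insert[cur : rel + 1] + alt[1])
            push("M", rel - cur + 1)
            push("I", len(alt[1]))
            cur = rel + 1
        else:  # deletion of alt[1] bases after the anchor
            seq_parts.append(ref_insert[cur : rel + 1])
            push("M", rel - cur + 1)
            push("D", alt[1])
            cur = rel + 1 + alt[1]
    seq_parts.append(ref_insert[cur:])
    push("M", len(ref_insert) - cur)
    return "".join(seq_parts), ops


def _slice_ops(
    ops: list[tuple[str, int]], hap_lo: int, hap_hi: int
) -> tuple[list[tuple[str, int]], int]:
    """Cigar ops for haplotype interval [hap_lo, hap_hi) and its ref offset."""
    out: list[tuple[str, int]] = []
    hap, ref = 0, 0
    ref_offset = None
    for op, n in ops:
        if op == "D":
            # a deletion sits between haplotype bases; keep it when strictly
            # inside the sliced interval
            if hap_lo < hap < hap_hi:
                out.append((op, n))
            ref += n
            continue
        # M or I consume haplotype
        lo = max(hap, hap_lo)
        hi = min(hap + n, hap_hi)
        if lo < hi:
            if ref_offset is None:
                ref_offset = ref + (lo - hap) if op == "M" else ref
            out.append((op, hi - lo))
        hap += n
        if op == "M":
            ref += n
        if hap >= hap_hi:
            break
    # merge adjacent same ops and drop leading/trailing D
    merged: list[tuple[str, int]] = []
    for op, n in out:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    while merged and merged[0][0] == "D":
        merged.pop(0)
    while merged and merged[-1][0] == "D":
        merged.pop()
    return merged, ref_offset if ref_offset is not None else 0


def simulate_reads(config: SimConfig, truth: TruthSet) -> TruthSet:
    """Generate multiplexed barcoded reads with provenance (in place)."""
    return _generate_reads(config, truth, truth.internal_fragments(), config.mean_depth)


def simulate_selective(config: SimConfig, truth: TruthSet, selective: str) -> TruthSet:
    """Reads restricted to a selective-base fragment subset, holding the
    total read budget constant so retained fragments gain depth.

    This is the in-silico analogue of amplifying with a common primer that
    extends ``selective`` bases past the remnant into the insert.
    """
    all_internal = truth.internal_fragments()
    retained = selective_subset(all_internal, selective)
    if not retained:
        raise ValueError(f"no fragments retained for selective bases {selective!r}")
    boosted = config.mean_depth * len(all_internal) / len(retained)
    clone = replace(truth)
    clone.reads = []
    return _generate_reads(config, clone, retained, boosted)


def _generate_reads(
    config: SimConfig,
    truth: TruthSet,
    fragments: Sequence[Fragment],
    mean_depth: float,
) -> TruthSet:
    rng = random.Random(config.seed + 2)
    nprng = np.random.default_rng(config.seed + 3)
    enzyme = config.enzyme
    sheet = config.sheet()
    barcode_of = {s: b for s, b in sheet.entries}
    var_by_chrom: dict[str, list[tuple[int, TruthVariant]]] = {}
    for vi, tv in enumerate(truth.variants):
        var_by_chrom.setdefault(tv.chrom, []).append((vi, tv))

    site_len = len(enzyme.recognition)
    offset = enzyme.cut_offset
    reads: list[ReadRecord] = []
    prov_rows: list[dict] = []
    counter = 0
    for frag in fragments:
        chrom_seq = truth.reference[frag.chrom]
        # union window spanning both flanking recognition sites in full; a
        # read entering from either end then both starts and (on read-through)
        # ends with remnant-matching bases, the layout the clipper expects
        insert_start = frag.start - offset
        insert_end = frag.end + site_len - offset
        ref_insert = chrom_seq[insert_start:insert_end]
        frag_vars = [
            (vi, tv)
            for vi, tv in var_by_chrom.get(frag.chrom, [])
            if insert_start <= tv.pos < insert_end
        ]
        for sample in config.sample_ids:
            depth = nprng.poisson(mean_depth)
            if depth == 0:
                continue
            # up to two haplotypes per sample for this fragment
            haps: dict[int, tuple[str, list[tuple[str, int]]]] = {}

            def haplotype(which: int):
                if which not in haps:
                    chosen = []
                    for vi, tv in frag_vars:
                        code = truth.genotypes[sample][vi]
                        use_alt = code is GenotypeCode.HOM_ALT or (
                            code is GenotypeCode.HET and which == 1
                        )
                        if use_alt:
                            chosen.append((tv.pos, tv.ref_key, tv.alt_key))
                    haps[which] = _build_haplotype(ref_insert, insert_start, chosen)
                return haps[which]

            for _ in range(depth):
                which = rng.randint(0, 1)
                hap_seq, ops = haplotype(which)
                end = rng.choice("LR")
                barcode = barcode_of[sample]
                core_len = config.read_length - len(barcode)
                # each end's window drops the far `offset` bases of the union
                # so the oriented read starts exactly at its cut remnant
                window = len(hap_seq) - offset
                cov = min(core_len, window)
                if end == "L":
                    core = hap_seq[offset : offset + cov]
                    hap_lo, hap_hi = offset, offset + cov
                else:
                    core = revcomp(hap_seq[:window])[:cov]
                    hap_lo, hap_hi = window - cov, window
                if len(core) < core_len and config.adapter_read_through:
                    core += ADAPTER_READTHROUGH[: core_len - len(core)]
                read_seq = barcode + core
                if config.error_rate > 0:
                    read_seq = "".join(
                        rng.choice([b for b in _BASES if b != ch])
                        if ch in _BASES and rng.random() < config.error_rate
                        else ch
                        for ch in read_seq
                    )
                counter += 1
                read_id = f"r{counter:07d}"
                reads.append(ReadRecord(read_id, read_seq, "I" * len(read_seq)))
                sliced, ref_off = _slice_ops(ops, hap_lo, hap_hi)
                genomic = read_seq[len(barcode) : len(barcode) + cov]
                ref_oriented = genomic if end == "L" else revcomp(genomic)
                prov_rows.append(
                    {
                        "read_id": read_id,
                        "sample": sample,
                        "chrom": frag.chrom,
                        "frag_start": frag.start,
                        "frag_end": frag.end,
                        "end": end,
                        "hap": which,
                        "ref_start": insert_start + ref_off,
                        "cigar": "".join(f"{n}{op}" for op, n in sliced),
                        "ref_oriented_seq": ref_oriented,
                    }
                )
    order = list(range(len(reads)))
    rng.shuffle(order)
    truth.reads = [reads[i] for i in order]
    prov = pd.DataFrame([prov_rows[i] for i in order])
    truth.provenance = prov
    return truth


def simulate_experiment(config: SimConfig) -> TruthSet:
    """Reference → truth genotypes → reads, in one call."""
    reference = simulate_reference(config)
    truth = simulate_genotypes(config, reference)
    return simulate_reads(config, truth)


# --- scoring -----------------------------------------------------------------


def evaluate_recovery(
    called: Sequence[VariantRecord], truth: TruthSet
) -> dict[str, float]:
    """Score called variants against truth.

    Returns site recovery (fraction of truth sites with a called record at
    the same position), genotype concordance (fraction of non-missing called
    genotypes at truth sites equal to the truth allele set), and the false
    discovery count (called sites not in truth).
    """
    truth_records = {(r.chrom, r.pos): r for r in truth.truth_records()}
    called_by_pos = {(r.chrom, r.pos): r for r in called}
    n_sites_found = sum(1 for k in truth_records if k in called_by_pos)
    n_geno = n_match = 0
    for key, trec in truth_records.items():
        crec = called_by_pos.get(key)
        if crec is None:
            continue
        for s in truth.samples:
            ccall = crec.calls.get(s)
            if ccall is None or ccall.code is GenotypeCode.MISSING:
                continue
            n_geno += 1
            tcall = trec.calls[s]
            if frozenset(ccall.alleles) == frozenset(tcall.alleles):
                n_match += 1
    false_sites = sum(1 for k in called_by_pos if k not in truth_records)
    return {
        "site_recovery": n_sites_found / len(truth_records) if truth_records else 1.0,
        "genotype_concordance": n_match / n_geno if n_geno else 1.0,
        "n_truth_sites": len(truth_records),
        "n_called_sites": len(called_by_pos),
        "false_sites": false_sites,
        "n_genotypes_compared": n_geno,
    }
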