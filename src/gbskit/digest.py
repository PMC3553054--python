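"""In silico restriction digestion and enzyme-suitability profiling.

Because GBS omits a size-selection step, the choice of enzyme determines the
fraction of restriction fragments short enough to amplify and sequence.  This
module digests a reference genome with a (possibly degenerate) enzyme,
tabulates fragment size distributions, and models selective-base subsetting —
the complexity-reduction mechanism in which the amplification primer extends
one or two bases past the restriction-site remnant into the insert, so only
fragments whose insert begins with those bases are amplified.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .enzymes import RestrictionEnzyme, revcomp

__all__ = [
    "Fragment",
    "DigestProfile",
    "find_cut_sites",
    "digest_sequence",
    "profile_digest",
    "selective_subset",
]

logger = logging.getLogger(__name__)

_VALID_SEQ = frozenset("ACGTN")


def _normalize_seq(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID_SEQ
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class Fragment:
    """A restriction fragment as a half-open genomic interval.

    ``left_internal`` / ``right_internal`` hold the first insert bases seen
    by a sequencing read entering from the respective end (i.e. the bases
    immediately following the restriction-site remnant on the read), which is
    what selective amplification primers interrogate.  ``None`` at a
    chromosome terminus.  ``internal`` is True iff both ends are cut sites;
    only internal fragments receive adapters at both ends and are amplifiable
    in GBS.
    """

    chrom: str
    start: int
    end: int
    left_internal: str | None
    right_internal: str | None
    internal: bool

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DigestProfile:
    """Summary of an in silico digest of a whole reference."""

    enzyme: RestrictionEnzyme
    per_chrom_counts: dict[str, int]
    size_histogram: tuple[np.ndarray, np.ndarray]  # (counts, bin_edges)
    n_total: int
    n_internal: int
    n_in_range: int
    fraction_in_range: float
    size_range: tuple[int, int]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"chrom": list(self.per_chrom_counts), "fragments": list(self.per_chrom_counts.values())}
        )


def find_cut_sites(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Cut positions (0-based, between-base) of all forward-strand site matches.

    Overlapping degenerate matches each yield a cut; matches spanning an
    ``N`` in the subject do not fire; duplicate cut positions are collapsed.
    """
    seq = _normalize_seq(seq)
    if not seq:
        return []
    cuts = sorted({m.start() + enzyme.cut_offset for m in enzyme.site_regex.finditer(seq)})
    if "N" in seq:
        logger.debug("sequence contains N runs; sites spanning N skipped")
    return cuts


def _internal_bases(seq: str, cut: int, side: str, enzyme: RestrictionEnzyme, width: int = 2) -> str:
    """First ``width`` insert bases read from one fragment end.

    Left end: the read enters forward, covering remnant then
    ``seq[cut+m : cut+m+width]``.  Right end: the read enters on the bottom
    strand; after the remnant it covers the reverse complement of the bases
    just inside the insert boundary, which sits ``cut_offset`` bases left of
    the nominal cut.
    """
    m = len(enzyme.remnant)
    if side == "left":
        return seq[cut + m : cut + m + width]
    hi = cut - enzyme.cut_offset
    return revcomp(seq[max(hi - width, 0) : hi])


def digest_sequence(seq: str, enzyme: RestrictionEnzyme, chrom: str = "seq") -> list[Fragment]:
    """Digest one sequence into fragments tiling ``[0, len(seq))``."""
    seq = _normalize_seq(seq)
    if not seq:
        return []
    cuts = find_cut_sites(seq, enzyme)
    bounds = [0, *cuts, len(seq)]
    frags: list[Fragment] = []
    for i, (start, end) in enumerate(zip(bounds[:-1], bounds[1:])):
        if start == end:  # cut flush at a terminus
            continue
        left_cut = i > 0
        right_cut = i < len(bounds) - 2
        frags.append(
            Fragment(
                chrom=chrom,
                start=start,
                end=end,
                left_internal=_internal_bases(seq, start, "left", enzyme) if left_cut else None,
                right_internal=_internal_bases(seq, end, "right", enzyme) if right_cut else None,
                internal=left_cut and right_cut,
            )
        )
    return frags


def digest_fasta(path: str | Path, enzyme: RestrictionEnzyme) -> dict[str, list[Fragment]]:
    """Digest every sequence of a FASTA file."""
    per_chrom: dict[str, list[Fragment]] = {}
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        per_chrom[rec.id] = digest_sequence(str(rec.seq), enzyme, chrom=rec.id)
        n += 1
    if n == 0:
        raise ValueError(f"no sequences found in FASTA {path}")
    return per_chrom


def profile_digest(
    reference: str | Path,
    enzyme: RestrictionEnzyme,
    size_range: tuple[int, int] = (100, 400),
    bins: Sequence[int] | int = 50,
) -> DigestProfile:
    """Digest a reference FASTA and summarise fragment counts and sizes.

    ``fraction_in_range`` is computed over internal fragments only: terminal
    fragments cannot acquire adapters at both ends and are never sequenced in
    GBS.  Terminal fragments are still counted in ``n_total`` and the
    histogram.
    """
    per_chrom = digest_fasta(reference, enzyme)
    sizes = []
    internal_sizes = []
    counts = {}
    for chrom, frags in per_chrom.items():
        counts[chrom] = len(frags)
        for f in frags:
            sizes.append(f.length)
            if f.internal:
                internal_sizes.append(f.length)
    lo, hi = size_range
    n_in_range = sum(1 for s in internal_sizes if lo <= s <= hi)
    if internal_sizes:
        fraction = n_in_range / len(internal_sizes)
    else:
        warnings.warn("no internal fragments; fraction_in_range reported as 0")
        fraction = 0.0
    hist = np.histogram(sizes, bins=bins)
    return DigestProfile(
        enzyme=enzyme,
        per_chrom_counts=counts,
        size_histogram=hist,
        n_total=len(sizes),
        n_internal=len(internal_sizes),
        n_in_range=n_in_range,
        fraction_in_range=fraction,
        size_range=(lo, hi),
    )


def selective_subset(fragments: Iterable[Fragment], selective: str) -> list[Fragment]:
    """Internal fragments amplifiable with ``selective`` extra primer bases.

    Adapter ligation is orientation-agnostic, so the selective primer can act
    at either fragment end: a fragment is retained when at least one of its
    insert-facing flanks begins with ``selective``.  The empty string models
    the standard protocol and returns all internal fragments.
    """
    selective = selective.upper()
    if len(selective) > 2 or set(selective) - set("ACGT"):
        raise ValueError("selective bases must be 0-2 characters over ACGT")
    out = []
    for f in fragments:
        if not f.internal:
            continue
        if not selective:
            out.append(f)
            continue
        for flank in (f.left_internal, f.right_internal):
            if flank is not None and flank.startswith(selective):
                out.append(f)
                break
    return out
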