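"""Restriction enzyme definitions and IUPAC pattern handling.

GBS protocols are anchored on a single restriction enzyme whose recognition
site may be degenerate (e.g. ApeKI, G^CWGC).  The enzyme drives every stage of
the toolkit: in silico digestion, validation of the remnant at the start of
demultiplexed reads, and adapter clipping of read-through fragments.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "IUPAC_CODES",
    "RestrictionEnzyme",
    "BUILTIN_ENZYMES",
    "get_enzyme",
    "load_enzyme_table",
]

#: IUPAC nucleotide codes mapped to the set of concrete bases they stand for.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "W": frozenset("AT"),
    "S": frozenset("CG"),
    "M": frozenset("AC"),
    "K": frozenset("GT"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTNWSMKRYBDHV", "TGCANWSKMYRVHDB")


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_regex(pattern: str) -> str:
    """Translate an IUPAC pattern into a plain regex over ACGT.

    Ambiguity codes become character classes; an ``N`` in the *subject*
    sequence never matches because classes contain only concrete bases.
    """
    out = []
    for ch in pattern:
        try:
            bases = sorted(IUPAC_CODES[ch])
        except KeyError:
            raise ValueError(f"invalid IUPAC character {ch!r} in pattern {pattern!r}")
        out.append(bases[0] if len(bases) == 1 else "[" + "".join(bases) + "]")
    return "".join(out)


def expand_iupac(pattern: str) -> list[str]:
    """All concrete ACGT sequences matching an IUPAC pattern."""
    seqs = [""]
    for ch in pattern:
        bases = IUPAC_CODES.get(ch)
        if bases is None:
            raise ValueError(f"invalid IUPAC character {ch!r} in pattern {pattern!r}")
        seqs = [s + b for s in seqs for b in sorted(bases)]
    return seqs


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A type II restriction enzyme as used in a GBS protocol.

    Parameters
    ----------
    name
        Enzyme name, e.g. ``"ApeKI"``.
    recognition
        Uppercase IUPAC recognition pattern, e.g. ``"GCWGC"``.
    cut_offset
        Bases from the pattern start to the top-strand cut
        (``0 <= cut_offset <= len(recognition)``); ApeKI G^CWGC has offset 1.

    The *remnant* — the genomic bases every properly prepared read begins
    with after the barcode — is ``recognition[cut_offset:]``.  Only
    degenerate-palindromic patterns are accepted: scanning is performed on
    the forward strand only, which is lossless exactly when the recognition
    pattern equals its own reverse complement as an IUPAC base-set pattern.
    """

    name: str
    recognition: str
    cut_offset: int
    remnant: str = field(init=False)

    def __post_init__(self) -> None:
        rec = self.recognition.upper()
        if not rec:
            raise ValueError("recognition pattern must be non-empty")
        for ch in rec:
            if ch not in IUPAC_CODES:
                raise ValueError(
                    f"invalid IUPAC character {ch!r} in recognition {rec!r}"
                )
        if not 0 <= self.cut_offset <= len(rec):
            raise ValueError("cut_offset must lie within the recognition pattern")
        if revcomp(rec) != rec:
            raise ValueError(
                f"{self.name}: recognition {rec!r} is not a degenerate palindrome; "
                "forward-strand-only scanning would miss bottom-strand sites"
            )
        object.__setattr__(self, "recognition", rec)
        object.__setattr__(self, "remnant", rec[self.cut_offset :])

    @property
    def remnant_regex(self) -> re.Pattern:
        return re.compile(iupac_regex(self.remnant))

    @property
    def site_regex(self) -> re.Pattern:
        # lookahead so overlapping degenerate matches each fire
        return re.compile("(?=" + iupac_regex(self.recognition) + ")")

    @property
    def overhang_shift(self) -> int:
        """Top-strand distance from a fragment's nominal end (the cut of the
        next site) to the end of the double-stranded insert after ligation.

        For a palindromic site the bottom-strand cut mirrors the top-strand
        cut, so the insert extends ``len(recognition) - 2 * cut_offset``
        bases past the nominal fragment end (negative for 3'-overhang
        enzymes such as PstI).
        """
        return len(self.recognition) - 2 * self.cut_offset


#: Enzymes commonly evaluated for GBS, with REBASE recognition conventions.
BUILTIN_ENZYMES: dict[str, RestrictionEnzyme] = {
    "ApeKI": RestrictionEnzyme("ApeKI", "GCWGC", 1),
    "PstI": RestrictionEnzyme("PstI", "CTGCAG", 5),
    "MseI": RestrictionEnzyme("MseI", "TTAA", 1),
}


def get_enzyme(name: str) -> RestrictionEnzyme:
    """Look up a bundled enzyme by name (case-sensitive)."""
    try:
        return BUILTIN_ENZYMES[name]
    except KeyError:
        known = ", ".join(sorted(BUILTIN_ENZYMES))
        raise KeyError(f"unknown enzyme {name!r}; bundled enzymes: {known}")


def load_enzyme_table(path: str | Path) -> dict[str, RestrictionEnzyme]:
    """Read a user enzyme table (TSV: name, recognition, cut_offset)."""
    table: dict[str, RestrictionEnzyme] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            name, recognition, cut_offset = row[0], row[1], int(row[2])
            table[name] = RestrictionEnzyme(name, recognition, cut_offset)
    return table
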