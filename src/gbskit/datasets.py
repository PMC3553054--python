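"""Published summary tables from the eight-cultivar soybean GBS pilot.

These small tables are the printed per-sample read accounting, Sanger
validation counts and selective-amplification run statistics of the pilot
experiment this toolkit models.  They serve as worked-example inputs for the
accounting, concordance and protocol-comparison operations; the toolkit
recomputes every derived figure (totals, percentages, changes) from these
raw counts at run time.
"""

from __future__ import annotations

import pandas as pd

from .popgen import ConcordanceTable, RunSummaryStats

__all__ = [
    "pilot_run_summary",
    "sanger_validation_counts",
    "selective_amplification_runs",
]


def pilot_run_summary() -> pd.DataFrame:
    """Per-cultivar raw read counts with processed/mapped percentages.

    Eight soybean cultivars sequenced single-end in one 48-plex lane; the
    printed grand total of raw reads is 5,535,843 and is *not* stored here —
    it is recomputed by summing this column.
    """
    return pd.DataFrame(
        {
            "sample": [
                "Maple Donovan",
                "Toma",
                "S19-90",
                "Williams 82",
                "PS46RR",
                "TGx1989-53F",
                "TGx1990-67F",
                "Ocepara-4",
            ],
            "raw_reads": [
                540_827,
                805_460,
                763_541,
                877_607,
                578_458,
                440_636,
                526_300,
                1_003_014,
            ],
            "processed_pct": [98.77, 98.75, 98.77, 98.77, 98.76, 98.76, 98.76, 98.76],
            "mapped_pct": [82.58, 85.58, 84.64, 86.96, 85.23, 83.47, 85.60, 84.64],
        }
    )


def sanger_validation_counts() -> dict[str, ConcordanceTable]:
    """Sanger-validation concordance counts stratified by genotype class.

    24 SNP loci re-sequenced in two panels of eight cultivars; counts are
    (AA, AB, BB) = (reference-homozygous, heterozygous, alternate-homozygous)
    concordant and discordant genotype calls.
    """
    return {
        "set_a": ConcordanceTable.from_counts((115, 3, 71), (0, 1, 2)),
        "set_b": ConcordanceTable.from_counts((111, 9, 67), (0, 5, 0)),
    }


def selective_amplification_runs() -> dict[str, RunSummaryStats]:
    """SNP counts and mean depths under selective-amplification protocols.

    Keys: ``standard`` (no selective base, 2 M reads/sample), ``ac_2m``
    (AC selective primer, 2 M reads), ``ac_1m`` / ``ac_0p5m`` (AC primer at
    halved / quartered reads per sample, emulating 192- and 384-plex).
    """
    return {
        "standard": RunSummaryStats(snp_count=6_252, mean_depth=11.7),
        "ac_2m": RunSummaryStats(snp_count=8_652, mean_depth=25.2),
        "ac_1m": RunSummaryStats(snp_count=6_846, mean_depth=16.0),
        "ac_0p5m": RunSummaryStats(snp_count=5_082, mean_depth=10.0),
    }
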