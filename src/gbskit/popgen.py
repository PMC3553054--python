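"""Pairwise diversity, neighbor-joining trees and concordance statistics.

Distances between samples are p-distances over genotype calls: the fraction
of shared non-missing sites at which the genotypes differ, with a
heterozygote counting 0.5 against either homozygote.  Trees come from the
classic Saitou–Nei neighbor-joining agglomeration with deterministic
tie-breaking (smallest label pair) and Kuhner–Felsenstein clamping of
negative branch lengths; bootstrap support resamples SNP sites with
replacement and summarises replicates by majority-rule consensus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .variants import GenotypeCode, VariantRecord

__all__ = [
    "GenotypeMatrix",
    "DistanceMatrix",
    "pairwise_informative",
    "p_distance",
    "neighbor_joining",
    "bootstrap_consensus",
    "ConcordanceTable",
    "genotype_concordance",
    "RunSummaryStats",
    "RunComparison",
    "compare_runs",
]


@dataclass
class GenotypeMatrix:
    """Samples x sites matrix of genotype calls as allele sets.

    ``data[i][j]`` is a frozenset of allele strings (1 for homozygous, 2 for
    heterozygous) or None for missing.  Multi-allelic sites work allele-wise:
    two genotypes differ fully when their allele sets are disjoint, by half
    when they share one allele.
    """

    samples: list[str]
    sites: list[tuple[str, int, str, tuple[str, ...]]]  # (chrom, pos, ref, alts)
    data: list[list[frozenset[str] | None]]

    @classmethod
    def from_records(
        cls, records: Sequence[VariantRecord], samples: Sequence[str] | None = None
    ) -> "GenotypeMatrix":
        if samples is None:
            samples = sorted({s for r in records for s in r.calls}) if records else []
        sites = [(r.chrom, r.pos, r.ref, r.alts) for r in records]
        data: list[list[frozenset[str] | None]] = []
        for s in samples:
            row: list[frozenset[str] | None] = []
            for r in records:
                call = r.calls.get(s)
                if call is None or call.code is GenotypeCode.MISSING:
                    row.append(None)
                else:
                    row.append(frozenset(str(a) for a in call.alleles))
            data.append(row)
        return cls(list(samples), sites, data)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def diff_array(self) -> np.ndarray:
        """(n_pairs, n_sites) per-site difference: 0 / 0.5 / 1, NaN if missing.

        Pairs are enumerated in ``itertools.combinations`` order over samples.
        """
        n = self.n_samples
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        out = np.full((len(pairs), self.n_sites), np.nan)
        for p, (i, j) in enumerate(pairs):
            for k in range(self.n_sites):
                a, b = self.data[i][k], self.data[j][k]
                if a is None or b is None:
                    continue
                if a == b:
                    out[p, k] = 0.0
                elif a & b:
                    out[p, k] = 0.5
                else:
                    out[p, k] = 1.0
        return out


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with sample labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("diagonal must be zero")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def _pair_stats(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    diff = matrix.diff_array()
    shared = (~np.isnan(diff)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        diffs = np.nansum(diff, axis=1)
    return diffs, shared


def pairwise_informative(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-pair count of shared non-missing sites at which genotypes differ.

    Heterozygote/homozygote half-differences count as differing sites here
    (the genotypes are not identical).
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least two samples")
    diff = matrix.diff_array()
    n = matrix.n_samples
    rows = []
    p = 0
    for i in range(n):
        for j in range(i + 1, n):
            col = diff[p]
            rows.append(
                (
                    matrix.samples[i],
                    matrix.samples[j],
                    int(np.nansum(col > 0)),
                    int((~np.isnan(col)).sum()),
                )
            )
            p += 1
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "differing", "shared"])


def p_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """p-distance matrix: differing / compared over shared non-missing sites."""
    diffs, shared = _pair_stats(matrix)
    n = matrix.n_samples
    values = np.zeros((n, n))
    p = 0
    for i in range(n):
        for j in range(i + 1, n):
            if shared[p] == 0:
                raise ValueError(
                    f"samples {matrix.samples[i]!r} and {matrix.samples[j]!r} "
                    "share no non-missing sites"
                )
            values[i, j] = values[j, i] = diffs[p] / shared[p]
            p += 1
    return DistanceMatrix(list(matrix.samples), values)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Q-matrix ties break toward the lexicographically smallest (label, label)
    pair (a merged node carries the smaller of its children's labels).
    Negative branch lengths are clamped to zero with the deficit moved to
    the sibling branch.  Returns an unrooted tree as a TreeNode with a
    trifurcating root.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    labels = list(dm.labels)
    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    D = dm.values.copy()

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return li, max(lj, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                pair = tuple(sorted((labels[i], labels[j])))
                key = (q, pair)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        li, lj = clamp(li, lj)
        nodes[i].length = li
        nodes[j].length = lj
        new = TreeNode(children=[nodes[i], nodes[j]])
        new_dist = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[: m - 2, : m - 2] = D[np.ix_(keep, keep)]
        D2[-1, : m - 2] = D2[: m - 2, -1] = new_dist[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]

    # resolve the last three nodes around a central vertex (three-point formulas)
    (a, b, c) = nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    a.length, b.length, c.length = (max(x, 0.0) for x in (la, lb, lc))
    return TreeNode(children=[a, b, c])


def _bipartitions(tree: TreeNode, taxa: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each normalized to the side excluding the
    lexicographically smallest taxon."""
    ref = min(taxa)
    out = set()
    for node in tree.non_tips():
        if node.is_root():
            continue
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = taxa - side
        if 1 < len(side) < len(taxa) - 1:
            out.add(side)
    return out


def bootstrap_consensus(
    matrix: GenotypeMatrix, B: int = 1000, seed: int = 0
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """Majority-rule consensus of NJ trees over site-bootstrap replicates.

    Sites are resampled with replacement B times; each replicate's p-distance
    matrix is fed to :func:`neighbor_joining`; bipartitions appearing in more
    than half the replicates are retained, labelled with their support
    (replicate fraction, as internal node names on a 0-100 scale).
    """
    if matrix.n_samples < 4:
        raise ValueError("bootstrap consensus needs at least 4 samples")
    rng = np.random.default_rng(seed)
    diff = matrix.diff_array()
    taxa = frozenset(matrix.samples)
    n = matrix.n_samples
    counts: dict[frozenset[str], int] = {}
    for _ in range(B):
        idx = rng.integers(0, matrix.n_sites, size=matrix.n_sites)
        sub = diff[:, idx]
        shared = (~np.isnan(sub)).sum(axis=1)
        if (shared == 0).any():
            raise ValueError("a bootstrap replicate left a pair with no shared sites")
        dvec = np.nansum(sub, axis=1) / shared
        values = np.zeros((n, n))
        p = 0
        for i in range(n):
            for j in range(i + 1, n):
                values[i, j] = values[j, i] = dvec[p]
                p += 1
        tree = neighbor_joining(DistanceMatrix(list(matrix.samples), values))
        for bip in _bipartitions(tree, taxa):
            counts[bip] = counts.get(bip, 0) + 1
    supports = {bip: c / B for bip, c in counts.items() if c / B > 0.5}

    # build the consensus tree: star topology refined by retained bipartitions
    root = TreeNode(children=[TreeNode(name=s) for s in sorted(matrix.samples)])
    ref = min(taxa)
    for bip, support in sorted(supports.items(), key=lambda kv: (-kv[1], sorted(kv[0]))):
        # find the smallest current node whose tip set contains the clade
        target = None
        for node in root.postorder(include_self=True):
            if node.is_tip():
                continue
            tips = frozenset(t.name for t in node.tips())
            if bip <= tips and (target is None or len(tips) < len(target[1])):
                target = (node, tips)
        node = target[0]

        def tipset(ch: TreeNode) -> frozenset[str]:
            return frozenset([ch.name]) if ch.is_tip() else frozenset(t.name for t in ch.tips())

        move = [ch for ch in node.children if tipset(ch) <= bip]
        if len(move) < 2 or len(move) == len(node.children):
            continue  # already present or incompatible arrangement
        for ch in move:
            node.remove(ch)
        new = TreeNode(name=f"{100 * support:.1f}", children=move)
        node.append(new)
    return root, supports


@dataclass
class ConcordanceTable:
    """Genotype validation counts stratified by call class (AA/AB/BB)."""

    concordant: dict[str, int]
    discordant: dict[str, int]

    STRATA = ("AA", "AB", "BB")

    @property
    def total_concordant(self) -> int:
        return sum(self.concordant.values())

    @property
    def total_discordant(self) -> int:
        return sum(self.discordant.values())

    @property
    def percent_validated(self) -> float:
        total = self.total_concordant + self.total_discordant
        if total == 0:
            raise ValueError("no comparable genotype pairs")
        return round(100.0 * self.total_concordant / total, 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": list(self.STRATA),
                "concordant": [self.concordant.get(s, 0) for s in self.STRATA],
                "discordant": [self.discordant.get(s, 0) for s in self.STRATA],
            }
        )

    @classmethod
    def from_counts(
        cls, concordant: Sequence[int], discordant: Sequence[int]
    ) -> "ConcordanceTable":
        """Build from (AA, AB, BB) count triples, e.g. a published table row."""
        return cls(
            dict(zip(cls.STRATA, concordant)), dict(zip(cls.STRATA, discordant))
        )


_CLASS_OF = {
    GenotypeCode.HOM_REF: "AA",
    GenotypeCode.HET: "AB",
    GenotypeCode.HOM_ALT: "BB",
}


def genotype_concordance(
    calls_a: Mapping[tuple, object], calls_b: Mapping[tuple, object]
) -> ConcordanceTable:
    """Concordance of two call sets over identical (sample, site) keys.

    Values may be GenotypeCall objects or hashable genotype representations;
    pairs where either side is missing are excluded.  Stratification follows
    the first call set's class.
    """
    if set(calls_a) != set(calls_b):
        offenders = sorted(set(calls_a) ^ set(calls_b))[:10]
        raise ValueError(f"call sets have mismatched keys, e.g. {offenders}")
    conc = {s: 0 for s in ConcordanceTable.STRATA}
    disc = {s: 0 for s in ConcordanceTable.STRATA}
    for key in calls_a:
        a, b = calls_a[key], calls_b[key]
        code_a = getattr(a, "code", None)
        if code_a is GenotypeCode.MISSING or a is None or b is None:
            continue
        code_b = getattr(b, "code", None)
        if code_b is GenotypeCode.MISSING:
            continue
        stratum = _CLASS_OF[code_a] if code_a is not None else "AA"
        val_a = frozenset(a.alleles) if code_a is not None else a
        val_b = frozenset(b.alleles) if code_b is not None else b
        if val_a == val_b:
            conc[stratum] += 1
        else:
            disc[stratum] += 1
    return ConcordanceTable(conc, disc)


@dataclass(frozen=True)
class RunSummaryStats:
    """Headline statistics of one run/protocol: SNP count and mean depth."""

    snp_count: int
    mean_depth: float | None = None


@dataclass(frozen=True)
class RunComparison:
    """Percent changes from run a to run b, rounded to 1 decimal."""

    snp_count_a: int
    snp_count_b: int
    snp_pct_change: float
    depth_a: float | None
    depth_b: float | None
    depth_pct_change: float | None

    @property
    def snp_ratio(self) -> float:
        return self.snp_count_b / self.snp_count_a

    @property
    def depth_ratio(self) -> float | None:
        if self.depth_a and self.depth_b is not None:
            return self.depth_b / self.depth_a
        return None


def compare_runs(a: RunSummaryStats, b: RunSummaryStats) -> RunComparison:
    """Percent change of SNP count and depth between two protocols/runs."""
    if a.snp_count == 0:
        raise ValueError("baseline run has zero SNPs")
    snp_pct = round(100.0 * (b.snp_count - a.snp_count) / a.snp_count, 1)
    depth_pct = None
    if a.mean_depth and b.mean_depth is not None:
        depth_pct = round(100.0 * (b.mean_depth - a.mean_depth) / a.mean_depth, 1)
    return RunComparison(
        snp_count_a=a.snp_count,
        snp_count_b=b.snp_count,
        snp_pct_change=snp_pct,
        depth_a=a.mean_depth,
        depth_b=b.mean_depth,
        depth_pct_change=depth_pct,
    )
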