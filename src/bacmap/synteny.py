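"""Window-based anchoring of contigs onto comparator genome sequences.

BES and probe-source hits are chained per contig and chromosome by 1-D single
linkage: consecutive hit positions less than the window apart join one chain,
and chains supported by two or more distinct queries become synteny anchors.
Gene-density tracks and coverage/enrichment statistics operate on 200-kb bins.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "QueryKind",
    "Hit",
    "HitTable",
    "SyntenyAnchor",
    "DensityTrack",
    "filter_repetitive_queries",
    "anchor_to_genome",
    "anchor_coverage",
    "gene_density",
    "density_enrichment",
    "cb_coverage",
]


class SyntenyError(ValueError):
    pass


class QueryKind(str, Enum):
    BES = "BES"
    PROBE_SOURCE = "PROBE_SOURCE"


@dataclass(frozen=True)
class Hit:
    query_id: str
    query_kind: QueryKind
    target_chrom: str
    target_pos: int  # 0-based bp


@dataclass
class HitTable:
    hits: list
    query_to_contig: dict = field(default_factory=dict)
    chrom_lengths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for h in self.hits:
            length = self.chrom_lengths.get(h.target_chrom)
            if length is not None and not (0 <= h.target_pos < length):
                raise SyntenyError(
                    f"hit {h.query_id!r} at {h.target_pos} outside "
                    f"{h.target_chrom} (length {length})"
                )


@dataclass(frozen=True)
class SyntenyAnchor:
    contig_id: int
    target_chrom: str
    start: int
    end: int
    queries: frozenset

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise SyntenyError("anchor start > end")
        if len(self.queries) < 2:
            raise SyntenyError("anchor needs >= 2 distinct supporting queries")


def filter_repetitive_queries(table: HitTable, max_hits: int = 9) -> HitTable:
    """Remove queries with more than ``max_hits`` hits on this genome
    (``>= max_hits+1`` hits marks the query repetitive)."""
    tally: dict = defaultdict(int)
    for h in table.hits:
        tally[h.query_id] += 1
    keep = [h for h in table.hits if tally[h.query_id] <= max_hits]
    return HitTable(keep, dict(table.query_to_contig), dict(table.chrom_lengths))


def anchor_to_genome(table: HitTable, window: int) -> list:
    """Chain filtered hits into synteny anchors.

    Per contig and target chromosome, hit positions are single-linked when
    consecutive positions are strictly less than ``window`` apart; chains with
    at least two distinct queries become anchors spanning [min pos, max pos].
    """
    if window <= 0:
        raise SyntenyError("window must be positive")
    grouped: dict = defaultdict(list)
    for h in table.hits:
        ctg = table.query_to_contig.get(h.query_id)
        if ctg is None:
            continue
        grouped[(ctg, h.target_chrom)].append(h)
    anchors = []
    for (ctg, chrom), hits in sorted(grouped.items()):
        hits.sort(key=lambda h: (h.target_pos, h.query_id))
        chain = [hits[0]]
        for h in hits[1:]:
            if h.target_pos - chain[-1].target_pos < window:
                chain.append(h)
            else:
                anchors.extend(_emit(ctg, chrom, chain))
                chain = [h]
        anchors.extend(_emit(ctg, chrom, chain))
    return anchors


def _emit(ctg, chrom, chain):
    queries = frozenset(h.query_id for h in chain)
    if len(queries) < 2:
        return []
    return [SyntenyAnchor(
        ctg, chrom,
        min(h.target_pos for h in chain),
        max(h.target_pos for h in chain),
        queries,
    )]


def _union_length(intervals: Iterable) -> int:
    total, cur_s, cur_e = 0, None, None
    for s, e in sorted(intervals):
        if cur_s is None:
            cur_s, cur_e = s, e
        elif s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
    if cur_s is not None:
        total += cur_e - cur_s
    return total


def anchor_coverage(anchors: Iterable, chrom_lengths: Mapping) -> float:
    """Fraction of the comparator genome covered by the union of anchor
    intervals."""
    genome = sum(chrom_lengths.values())
    if genome <= 0:
        raise SyntenyError("total chromosome length must be positive")
    by_chrom: dict = defaultdict(list)
    for a in anchors:
        by_chrom[a.target_chrom].append((a.start, a.end))
    covered = sum(_union_length(iv) for iv in by_chrom.values())
    return covered / genome


@dataclass
class DensityTrack:
    bin_size: int
    counts: dict  # chrom -> np.ndarray of gene counts per bin

    def total_genes(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))


def gene_density(
    genes: Iterable, chrom_lengths: Mapping, bin_size: int = 200_000
) -> DensityTrack:
    """Count genes per ``bin_size`` window; a gene belongs to the bin holding
    its start coordinate.  ``genes`` yields ``(chrom, start, end)``."""
    counts = {
        chrom: np.zeros(max(1, math.ceil(length / bin_size)), dtype=int)
        for chrom, length in chrom_lengths.items()
    }
    for chrom, start, _end in genes:
        if chrom not in counts:
            raise SyntenyError(f"gene on unknown chromosome {chrom!r}")
        counts[chrom][start // bin_size] += 1
    return DensityTrack(bin_size, counts)


def density_enrichment(
    anchors: Iterable, track: DensityTrack, top_fraction: float = 0.30
):
    """Gene-density enrichment of anchor-covered bins.

    Returns a dict with the mean density of covered vs uncovered bins, the
    fraction of the highest-density ``top_fraction`` of bins that is covered,
    and the covered fraction of all bins.  A bin counts as covered when any
    anchor interval overlaps it.
    """
    chroms = sorted(track.counts)
    covered = {c: np.zeros(len(track.counts[c]), dtype=bool) for c in chroms}
    for a in anchors:
        if a.target_chrom not in covered:
            continue
        b0 = a.start // track.bin_size
        b1 = min(a.end // track.bin_size, len(covered[a.target_chrom]) - 1)
        covered[a.target_chrom][b0:b1 + 1] = True

    dens = np.concatenate([track.counts[c] for c in chroms]) if chroms else np.array([])
    cov = np.concatenate([covered[c] for c in chroms]) if chroms else np.array([], bool)
    n = len(dens)
    if n == 0:
        return {
            "mean_density_covered": 0.0, "mean_density_uncovered": 0.0,
            "top_bin_coverage": 0.0, "overall_bin_coverage": 0.0,
        }
    # ties broken by chromosome/bin order: stable sort on descending density
    order = np.argsort(-dens, kind="stable")
    n_top = math.ceil(top_fraction * n)
    top_idx = order[:n_top]
    return {
        "mean_density_covered": float(dens[cov].mean()) if cov.any() else 0.0,
        "mean_density_uncovered": float(dens[~cov].mean()) if (~cov).any() else 0.0,
        "top_bin_coverage": float(cov[top_idx].mean()) if n_top else 0.0,
        "overall_bin_coverage": float(cov.mean()),
    }


def cb_coverage(contigs: Iterable, genome_bp: float, avg_band_bp: float = 4097) -> float:
    """Physical genome fraction implied by total consensus-band length."""
    if genome_bp <= 0 or avg_band_bp <= 0:
        raise SyntenyError("genome_bp and avg_band_bp must be positive")
    total = sum(ctg.cb_length for ctg in contigs)
    return total * avg_band_bp / genome_bp
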