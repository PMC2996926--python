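"""Anchoring contigs onto a consensus genetic map from hybridization evidence.

Repetitive probes and promiscuous BACs are filtered first; a contig is
anchored when at least one mapped marker hits two or more of its member BACs
("weak anchors" from single BAC-probe pairs are reported but never place a
contig).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

from .overgo import ProbeClass

__all__ = [
    "GeneticMap",
    "AnchorRecord",
    "ContigClass",
    "filter_hybridization",
    "anchor_contigs",
    "anchor_summary",
    "classify_contigs",
    "flag_organelle",
]


class AnchoringError(ValueError):
    pass


@dataclass(frozen=True)
class MapLocus:
    marker_id: str
    group: int
    cm: float


@dataclass
class GeneticMap:
    """Consensus map: loci of (marker, homologous group, position cM)."""

    loci: list
    n_groups: int = 13

    def __post_init__(self) -> None:
        for locus in self.loci:
            if not (1 <= locus.group <= self.n_groups):
                raise AnchoringError(
                    f"group {locus.group} of {locus.marker_id!r} outside "
                    f"1..{self.n_groups}"
                )
            if locus.cm < 0:
                raise AnchoringError(f"negative cM for {locus.marker_id!r}")

    def by_marker(self) -> dict:
        out = defaultdict(list)
        for locus in self.loci:
            out[locus.marker_id].append(locus)
        return dict(out)


@dataclass(frozen=True)
class AnchorRecord:
    contig_id: int
    marker_id: str
    group: int
    cm: float
    supporting_bacs: int

    @property
    def weak(self) -> bool:
        return self.supporting_bacs == 1


def filter_hybridization(
    matrix: Mapping, probe_max: int = 29, bac_max: int = 7
):
    """Drop repetitive probes (hits > ``probe_max``) and promiscuous BACs
    (distinct probes > ``bac_max``); returns the surviving (probe, BAC) pairs
    plus per-probe and per-BAC tallies.
    """
    probe_tally = {p: len(set(bacs)) for p, bacs in matrix.items()}
    keep_probes = {p for p, n in probe_tally.items() if n <= probe_max}
    bac_tally: dict = defaultdict(set)
    for p in keep_probes:
        for bac in matrix[p]:
            bac_tally[bac].add(p)
    keep_bacs = {b for b, probes in bac_tally.items() if len(probes) <= bac_max}
    pairs = sorted(
        (p, b) for p in keep_probes for b in set(matrix[p]) if b in keep_bacs
    )
    return pairs, probe_tally, {b: len(v) for b, v in bac_tally.items()}


def anchor_contigs(assembly, pairs: Iterable, genetic_map: GeneticMap):
    """Anchor records for every (marker-on-map, contig) incidence.

    ``supporting_bacs`` counts distinct member BACs of the contig hit by the
    marker; records with a single supporting BAC are weak and do not anchor.
    Hits to singleton BACs are returned separately.
    """
    by_marker = genetic_map.by_marker()
    contig_of = assembly.contig_of()
    hits: dict = defaultdict(set)
    singleton_hits = []
    for probe, bac in pairs:
        if probe not in by_marker:
            continue
        ctg = contig_of.get(bac)
        if ctg is None:
            singleton_hits.append((probe, bac))
        else:
            hits[(probe, ctg)].add(bac)
    records = []
    for (probe, ctg), bacs in sorted(hits.items()):
        for locus in by_marker[probe]:
            records.append(
                AnchorRecord(ctg, probe, locus.group, locus.cm, len(bacs))
            )
    return records, singleton_hits


def anchor_summary(records: Iterable, genetic_map: GeneticMap) -> pd.DataFrame:
    """Per-homologous-group table: loci on map, anchoring markers, anchored
    contig records and the average contigs anchored per marker."""
    strong = [r for r in records if not r.weak]
    rows = []
    for group in range(1, genetic_map.n_groups + 1):
        loci = [l for l in genetic_map.loci if l.group == group]
        g_rec = [r for r in strong if r.group == group]
        markers = sorted({r.marker_id for r in g_rec})
        n_rec = len({(r.marker_id, r.contig_id) for r in g_rec})
        rows.append({
            "group": group,
            "loci": len(loci),
            "anchoring_markers": len(markers),
            "anchored_contig_records": n_rec,
            "contigs_per_marker": (n_rec / len(markers)) if markers else 0.0,
        })
    return pd.DataFrame(rows)


class ContigClass(str, Enum):
    REPEAT_ONLY = "REPEAT_ONLY"
    LOWCOPY_ENRICHED = "LOWCOPY_ENRICHED"
    MIXED = "MIXED"
    UNPROBED = "UNPROBED"


def classify_contigs(assembly, contig_probes: Mapping, probe_classes: Mapping):
    """Classify each contig by the copy-number classes of its probes.

    REPEAT_ONLY when every probe is moderate/high copy; LOWCOPY_ENRICHED when
    strictly more than 60% of the probes are low copy; UNPROBED with none.
    """
    out = {}
    for ctg in assembly.contigs:
        probes = sorted(set(contig_probes.get(ctg.contig_id, ())))
        if not probes:
            out[ctg.contig_id] = ContigClass.UNPROBED
            continue
        n_low = sum(
            1 for p in probes if probe_classes[p].cls is ProbeClass.LOW
        )
        if n_low == 0:
            out[ctg.contig_id] = ContigClass.REPEAT_ONLY
        elif n_low / len(probes) > 0.60:
            out[ctg.contig_id] = ContigClass.LOWCOPY_ENRICHED
        else:
            out[ctg.contig_id] = ContigClass.MIXED
    return out


def flag_organelle(
    assembly, organelle_hits: Iterable, min_evidence: int = 2
) -> set:
    """Flag contigs with >= ``min_evidence`` distinct member-derived sequences
    (BES or probe sources) matching the organelle reference.

    ``organelle_hits`` yields ``(query_id, clone_id)`` pairs.
    """
    contig_of = assembly.contig_of()
    per_contig: dict = defaultdict(set)
    for query_id, clone_id in organelle_hits:
        ctg = contig_of.get(clone_id)
        if ctg is not None:
            per_contig[ctg].add(query_id)
    return {ctg for ctg, queries in per_contig.items()
            if len(queries) >= min_evidence}
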