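"""Pooled overgo design and deconvolution.

Probes sit on a k x k grid and each probe is hybridized in exactly three
pools: its row, its column and its (row+col) mod k diagonal.  A BAC's positive
pool set is deconvolved back to probe assignments by exact minimal-cover
enumeration over the candidate grid cells whose three pools are all positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "PoolDesign",
    "PoolHits",
    "ProbeAssignment",
    "AssignmentStatus",
    "ProbeClass",
    "ProbeClassification",
    "build_pool_design",
    "deconvolve",
    "deconvolve_bac",
    "classify_probe",
    "design_overgos",
]


class OvergoError(ValueError):
    pass


class AssignmentStatus(str, Enum):
    UNIQUE = "UNIQUE"
    AMBIGUOUS = "AMBIGUOUS"
    INCONSISTENT = "INCONSISTENT"


@dataclass
class PoolDesign:
    grid_k: int
    probe_positions: dict            # probe_id -> (row, col)
    pools: dict                      # pool_id -> frozenset of probe_ids
    diagonal_convention: str = "sum"  # "sum": (r+c) mod k; "diff": (r-c) mod k

    def pools_of(self, probe_id) -> tuple:
        r, c = self.probe_positions[probe_id]
        return (f"ROW_{r}", f"COL_{c}", f"DIAG_{self._diag(r, c)}")

    def _diag(self, r: int, c: int) -> int:
        if self.diagonal_convention == "sum":
            return (r + c) % self.grid_k
        return (r - c) % self.grid_k

    def cell_pools(self, r: int, c: int) -> frozenset:
        return frozenset({f"ROW_{r}", f"COL_{c}", f"DIAG_{self._diag(r, c)}"})


@dataclass
class PoolHits:
    positives: dict                  # bac_id -> set of positive pool ids
    membrane_id: str = "M1"
    noise: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ProbeAssignment:
    bac_id: str
    probes: frozenset
    status: AssignmentStatus
    alternatives: tuple = ()


def build_pool_design(
    probe_ids: Sequence, grid_k: int = 24, diagonal_convention: str = "sum"
) -> PoolDesign:
    """Fill the grid row-major and emit the 3*k row/column/diagonal pools."""
    if len(probe_ids) > grid_k * grid_k:
        raise OvergoError(
            f"{len(probe_ids)} probes exceed a {grid_k}x{grid_k} grid"
        )
    if diagonal_convention not in ("sum", "diff"):
        raise OvergoError("diagonal_convention must be 'sum' or 'diff'")
    positions = {}
    for i, pid in enumerate(probe_ids):
        positions[pid] = (i // grid_k, i % grid_k)
    design = PoolDesign(grid_k, positions, {}, diagonal_convention)
    pools: dict = {f"ROW_{r}": set() for r in range(grid_k)}
    pools.update({f"COL_{c}": set() for c in range(grid_k)})
    pools.update({f"DIAG_{d}": set() for d in range(grid_k)})
    for pid in probe_ids:
        for pool in design.pools_of(pid):
            pools[pool].add(pid)
    design.pools = {k: frozenset(v) for k, v in pools.items()}
    return design


def _minimal_covers(candidates: Sequence, cover_sets: Mapping, universe: frozenset):
    """All irredundant covers of ``universe`` by the candidates' pool sets.

    Branch on each candidate covering the first uncovered pool, then filter to
    irredundant, deduplicated covers.  Candidate counts are tiny in practice
    (bounded by the number of positive rows x columns)."""
    results = set()

    def rec(chosen: frozenset, covered: frozenset):
        missing = universe - covered
        if not missing:
            results.add(chosen)
            return
        pool = sorted(missing)[0]
        for cand in candidates:
            if pool in cover_sets[cand]:
                rec(chosen | {cand}, covered | cover_sets[cand])

    rec(frozenset(), frozenset())
    minimal = []
    for cover in results:
        redundant = False
        for el in cover:
            rest = frozenset().union(*(cover_sets[o] for o in cover if o != el)) \
                if len(cover) > 1 else frozenset()
            if universe <= rest:
                redundant = True
                break
        if not redundant:
            minimal.append(cover)
    # drop strict supersets of other minimal covers
    minimal = [
        c for c in minimal
        if not any(o < c for o in minimal)
    ]
    return sorted(minimal, key=lambda c: (len(c), sorted(c)))


def deconvolve_bac(design: PoolDesign, positive_pools: Iterable):
    """Deconvolve one BAC's positive pool set.

    Candidates are grid cells whose row, column and diagonal pools are all
    positive; retained probe sets are minimal covers of the positive pools.
    """
    pos = frozenset(positive_pools)
    unknown = pos - set(design.pools)
    if unknown:
        raise OvergoError(f"unknown pool ids: {sorted(unknown)}")
    if not pos:
        return frozenset(), AssignmentStatus.UNIQUE, ()
    occupied = {v: k for k, v in design.probe_positions.items()}
    rows = [int(p.split("_")[1]) for p in pos if p.startswith("ROW_")]
    cols = [int(p.split("_")[1]) for p in pos if p.startswith("COL_")]
    candidates, cover_sets = [], {}
    for r in rows:
        for c in cols:
            if (r, c) not in occupied:
                continue
            cell = design.cell_pools(r, c)
            if cell <= pos:
                pid = occupied[(r, c)]
                candidates.append(pid)
                cover_sets[pid] = cell
    candidates.sort()
    covers = _minimal_covers(candidates, cover_sets, pos)
    if not covers:
        return frozenset(), AssignmentStatus.INCONSISTENT, ()
    if len(covers) == 1:
        return covers[0], AssignmentStatus.UNIQUE, tuple(covers)
    return covers[0], AssignmentStatus.AMBIGUOUS, tuple(covers)


def deconvolve(design: PoolDesign, hits: PoolHits) -> dict:
    """Deconvolve every BAC of a scored membrane; returns
    ``bac_id -> ProbeAssignment``."""
    out = {}
    for bac_id in sorted(hits.positives):
        probes, status, alts = deconvolve_bac(design, hits.positives[bac_id])
        out[bac_id] = ProbeAssignment(bac_id, probes, status, alts)
    return out


class ProbeClass(str, Enum):
    LOW = "LOW"
    MODERATE = "MODERATE"
    HIGH = "HIGH"


@dataclass(frozen=True)
class ProbeClassification:
    cls: ProbeClass
    assembly_excluded: bool
    anchoring_excluded: bool


def classify_probe(total_hits: int) -> ProbeClassification:
    """Copy-number class of a probe from its total BAC hits.

    Low copy <= 29 hits, highly repetitive >= 100, moderate in between.
    Probes with > 50 hits are excluded from assembly relaxation; probes with
    >= 30 hits are excluded from anchoring.
    """
    if total_hits < 0:
        raise OvergoError("total_hits must be >= 0")
    if total_hits <= 29:
        cls = ProbeClass.LOW
    elif total_hits >= 100:
        cls = ProbeClass.HIGH
    else:
        cls = ProbeClass.MODERATE
    return ProbeClassification(
        cls,
        assembly_excluded=total_hits > 50,
        anchoring_excluded=total_hits >= 30,
    )


def design_overgos(
    source: str, length: int = 40, gc_min: float = 0.40, gc_max: float = 0.60
):
    """Non-overlapping candidate overgo windows tiled across ``source``.

    Windows containing N are rejected; GC content is computed over ACGT only
    and must fall within ``[gc_min, gc_max]``.  Returns ``(start, sequence)``
    tuples.
    """
    seq = source.upper()
    if set(seq) - set("ACGTN"):
        raise OvergoError("sequence must be over {A,C,G,T,N}")
    out = []
    for start in range(0, len(seq) - length + 1, length):
        window = seq[start:start + length]
        if "N" in window:
            continue
        gc = (window.count("G") + window.count("C")) / length
        if gc_min <= gc <= gc_max:
            out.append((start, window))
    return out
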