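"""FPC-style contig assembly with evidence-aware cutoff relaxation.

Clone overlaps are accepted when the Sulston score of their tolerance-matched
band counts falls at or below an effective cutoff; contigs are the connected
components of the accepted-overlap graph.  Shared hybridization markers (or
co-membership in an HICF contig) relax the cutoff by denary intervals, and a
finalization pass performs DQ splitting, end-to-end merging, singleton
adoption and burying of near-identical clones.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

from .config import PipelineConfig
from .fingerprint import (
    BandProfile,
    FingerprintError,
    Method,
    ScoreParams,
    effective_cutoff,
    match_count,
    min_match_threshold_pair,
    sulston_score,
)

__all__ = [
    "MarkerKind",
    "EvidenceMarker",
    "Contig",
    "Assembly",
    "Stage",
    "PipelineResult",
    "assemble",
    "build_cb_map",
    "dq_split",
    "end_merge",
    "adopt_singletons",
    "bury_clones",
    "detect_cross_well",
    "detect_band_outliers",
    "select_terminal_clones",
    "hicf_pseudomarkers",
    "run_integrated_pipeline",
]


class AssemblyError(ValueError):
    pass


class MarkerKind(str, Enum):
    PROBE = "PROBE"
    HICF_CONTIG = "HICF_CONTIG"


class Stage(str, Enum):
    PRELIM_AGAROSE = "PRELIM_AGAROSE"
    HICF_ONLY = "HICF_ONLY"
    INTEGRATED = "INTEGRATED"
    FINAL = "FINAL"


@dataclass(frozen=True)
class EvidenceMarker:
    """A probe or HICF-contig pseudo-marker with its clone hit set."""

    marker_id: str
    kind: MarkerKind
    clones: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "clones", frozenset(self.clones))
        if not self.clones:
            raise AssemblyError(f"marker {self.marker_id!r} has an empty clone set")


@dataclass
class Contig:
    contig_id: int
    members: list  # list of (clone_id, cb_offset)
    cb_length: int
    q_clones: set = field(default_factory=set)
    buried: dict = field(default_factory=dict)  # child -> parent
    terminal_clones: tuple = ((), ())

    @property
    def clone_ids(self) -> list:
        return [cid for cid, _ in self.members]

    @property
    def size(self) -> int:
        return len(self.members)

    def unburied(self) -> list:
        return [cid for cid, _ in self.members if cid not in self.buried]


@dataclass
class Assembly:
    stage: Stage
    contigs: list
    singletons: set
    provenance: dict = field(default_factory=dict)

    def contig_of(self) -> dict:
        out = {}
        for ctg in self.contigs:
            for cid in ctg.clone_ids:
                out[cid] = ctg.contig_id
        return out

    def clone_ids(self) -> set:
        out = set(self.singletons)
        for ctg in self.contigs:
            out.update(ctg.clone_ids)
        return out

    def validate_partition(self, expected: Iterable) -> None:
        """Each clone must sit in exactly one contig or the singleton list."""
        seen = []
        for ctg in self.contigs:
            seen.extend(ctg.clone_ids)
        seen.extend(self.singletons)
        if len(seen) != len(set(seen)):
            raise AssemblyError("clone assigned to more than one place")
        if set(seen) != set(expected):
            raise AssemblyError("partition does not cover the clone set")


@dataclass
class PipelineResult:
    final: Assembly
    stages: dict
    log: list


# ---------------------------------------------------------------------------
# pairwise machinery


def _profiles_dict(profiles) -> dict:
    if isinstance(profiles, Mapping):
        return dict(profiles)
    return {p.clone_id: p for p in profiles}


def _threshold_cache(params: ScoreParams):
    cache = {}

    def thr(n_a: int, n_b: int, cutoff: float):
        key = (min(n_a, n_b), max(n_a, n_b), cutoff)
        if key not in cache:
            p = ScoreParams(params.tolerance, params.gel_length, cutoff)
            cache[key] = min_match_threshold_pair(key[0], key[1], p)
        return cache[key]

    return thr


def candidate_pairs(items: Sequence, tolerance: int, min_m: int):
    """Indices of item pairs that could share >= ``min_m`` tolerance-matched
    bands.  ``items`` is a sequence of band tuples.  Uses a quantized-band
    count-product upper bound, so no qualifying pair is ever dropped."""
    n = len(items)
    if n < 2 or min_m is None:
        return []
    w = tolerance + 1
    rows, cols = [], []
    for idx, bands in enumerate(items):
        for b in bands:
            k = int(b) // w
            rows.append(idx)
            cols.append(k)
            rows.append(idx)
            cols.append(k + 1)
    if not rows:
        return []
    m = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int32), (rows, cols)),
        shape=(n, max(cols) + 1),
    )
    prod = (m @ m.T).tocoo()
    mask = (prod.data >= min_m) & (prod.row < prod.col)
    return list(zip(prod.row[mask].tolist(), prod.col[mask].tolist()))


def _min_possible_threshold(counts: Iterable, thr: Callable, cutoff: float):
    vals = sorted(set(counts))
    best = None
    for i, a in enumerate(vals):
        for b in vals[i:]:
            t = thr(a, b, cutoff)
            if t is not None and (best is None or t < best):
                best = t
    return best


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


# ---------------------------------------------------------------------------
# CB map layout


def build_cb_map(member_ids: Sequence, profiles: Mapping, params: ScoreParams):
    """Greedy seeded consensus-band layout for one contig.

    Returns ``(offsets, cb_length, q_clones)``.  The consensus starts from the
    best-matching clone pair and grows by each inserted clone's unmatched
    bands; offsets form the staircase implied by unshared band counts.  A
    clone is flagged Q when fewer than half of its bands align at its anchor
    placement, i.e. against its best-matching fellow member (a chimera's bands
    can never co-locate on one consensus stretch, so its best single anchor
    covers well under half of them).
    """
    tol = params.tolerance
    ids = sorted(member_ids)
    if not ids:
        raise AssemblyError("contig must have at least one member")
    bands = {cid: profiles[cid].bands for cid in ids}
    if len(ids) == 1:
        return {ids[0]: 0}, len(bands[ids[0]]), set()

    # seed: pair with the most matched bands (ties towards smallest ids)
    best = None
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            m = match_count(bands[a], bands[b], tol)
            if best is None or m > best[0]:
                best = (m, a, b)
    m0, sa, sb = best
    offsets = {sa: 0, sb: max(0, len(bands[sa]) - m0)}
    consensus = _merge_bands(list(bands[sa]), bands[sb], tol)

    remaining = [c for c in ids if c not in offsets]
    while remaining:
        pick, pick_m = None, -1
        for c in remaining:
            m = match_count(bands[c], consensus, tol)
            if m > pick_m:
                pick, pick_m = c, m
        # anchor the new clone to its best-matching placed member
        anchor, am = None, -1
        for placed in offsets:
            m = match_count(bands[pick], bands[placed], tol)
            if m > am:
                anchor, am = placed, m
        offsets[pick] = offsets[anchor] + max(0, len(bands[anchor]) - am)
        consensus = _merge_bands(consensus, bands[pick], tol)
        remaining.remove(pick)

    lo = min(offsets.values())
    offsets = {c: o - lo for c, o in offsets.items()}

    q_clones = set()
    for c in ids:
        n = len(bands[c])
        if not n:
            continue
        best = max(
            match_count(bands[c], bands[o], tol) for o in ids if o != c
        )
        if best < 0.5 * n:
            q_clones.add(c)
    return offsets, len(consensus), q_clones


def _merge_bands(consensus: list, new_bands: Sequence, tol: int) -> list:
    """Consensus grows by the new clone's unmatched bands (tolerance dedup)."""
    _, pairs = _greedy_pairs(new_bands, consensus, tol)
    matched = {i for i, _ in pairs}
    merged = list(consensus) + [b for i, b in enumerate(new_bands) if i not in matched]
    merged.sort()
    return merged


def _greedy_pairs(a: Sequence, b: Sequence, tol: int):
    pairs = []
    i = j = 0
    while i < len(a) and j < len(b):
        d = a[i] - b[j]
        if d > tol:
            j += 1
        elif d < -tol:
            i += 1
        else:
            pairs.append((i, j))
            i += 1
            j += 1
    return len(pairs), pairs


def _terminals(ctg: Contig, profiles: Mapping, per_end: int = 2) -> tuple:
    live = [(cid, off) for cid, off in ctg.members if cid not in ctg.buried]
    if not live:
        live = list(ctg.members)
    left = sorted(live, key=lambda t: (t[1], t[0]))
    right = sorted(
        live, key=lambda t: (-(t[1] + profiles[t[0]].n), t[0])
    )
    return (
        tuple(cid for cid, _ in left[:per_end]),
        tuple(cid for cid, _ in right[:per_end]),
    )


def _make_contigs(components, profiles, params, per_end=2):
    comps = sorted(components, key=min)
    contigs = []
    for idx, comp in enumerate(comps, start=1):
        offsets, cb_len, q = build_cb_map(comp, profiles, params)
        members = sorted(offsets.items(), key=lambda t: (t[1], t[0]))
        ctg = Contig(idx, members, cb_len, q)
        ctg.terminal_clones = _terminals(ctg, profiles, per_end)
        contigs.append(ctg)
    return contigs


# ---------------------------------------------------------------------------
# assembly


def assemble(
    profiles,
    evidence: Iterable = (),
    params: ScoreParams = ScoreParams(),
    *,
    relax_floor: float | None = None,
    assembly_max_hits: int = 50,
    terminal_map: Mapping | None = None,
    forced_singletons: Iterable = (),
    stage: Stage = Stage.PRELIM_AGAROSE,
) -> Assembly:
    """Single-linkage contig assembly over accepted pairwise overlaps.

    ``evidence`` markers relax the pairwise cutoff by denary intervals (probe
    markers only when their total hits <= ``assembly_max_hits``).  When
    ``terminal_map`` maps clone ids to their previous-stage contig ids,
    HICF co-membership relaxes joins between terminal clones of *distinct*
    previous contigs by exactly two denary intervals; for all other pairs it
    counts as one shared marker.
    """
    prof = _profiles_dict(profiles)
    if not prof:
        raise AssemblyError("empty profile set")
    methods = {p.method for p in prof.values()}
    if len(methods) > 1:
        raise FingerprintError("profiles mix fingerprinting methods")
    forced = set(forced_singletons)

    eligible = sorted(
        cid for cid, p in prof.items() if p.n >= 2 and cid not in forced
    )
    thr = _threshold_cache(params)
    base = params.cutoff
    uf = _UnionFind(eligible)
    joins = []

    items = [prof[cid].bands for cid in eligible]
    min_m = _min_possible_threshold(
        (len(b) for b in items), thr, base
    )
    edge_pairs = set()
    if min_m is not None:
        for i, j in candidate_pairs(items, params.tolerance, min_m):
            a, b = eligible[i], eligible[j]
            m = match_count(items[i], items[j], params.tolerance)
            t = thr(len(items[i]), len(items[j]), base)
            if t is not None and m >= t:
                uf.union(a, b)
                edge_pairs.add((a, b))
                joins.append(
                    (a, b, sulston_score(len(items[i]), len(items[j]), m, params), base, m)
                )

    # evidence-relaxed pairs
    elig_set = set(eligible)
    probe_shared = defaultdict(int)
    hicf_shared = set()
    for marker in evidence:
        if marker.kind is MarkerKind.PROBE and len(marker.clones) > assembly_max_hits:
            continue
        clones = sorted(marker.clones & elig_set)
        for i, a in enumerate(clones):
            for b in clones[i + 1:]:
                if marker.kind is MarkerKind.PROBE:
                    probe_shared[(a, b)] += 1
                else:
                    hicf_shared.add((a, b))

    for pair in sorted(set(probe_shared) | hicf_shared):
        if pair in edge_pairs:
            continue
        a, b = pair
        s = probe_shared.get(pair, 0)
        cut = effective_cutoff(base, s, relax_floor) if s else base
        if pair in hicf_shared:
            is_terminal_pair = (
                terminal_map is not None
                and a in terminal_map
                and b in terminal_map
                and terminal_map[a] != terminal_map[b]
            )
            if is_terminal_pair:
                cut = max(cut, min(base * 100.0, relax_floor or 1.0))
            else:
                cut = max(cut, effective_cutoff(base, s + 1, relax_floor))
        if cut <= base:
            continue
        pa, pb = prof[a], prof[b]
        m = match_count(pa.bands, pb.bands, params.tolerance)
        t = thr(pa.n, pb.n, cut)
        if t is not None and m >= t:
            uf.union(a, b)
            edge_pairs.add(pair)
            joins.append((a, b, sulston_score(pa.n, pb.n, m, params), cut, m))

    comps = defaultdict(list)
    for cid in eligible:
        comps[uf.find(cid)].append(cid)
    contig_comps = [sorted(c) for c in comps.values() if len(c) >= 2]
    contigs = _make_contigs(contig_comps, prof, params)
    in_contig = {cid for ctg in contigs for cid in ctg.clone_ids}
    singletons = set(prof) - in_contig

    asm = Assembly(
        stage=stage,
        contigs=contigs,
        singletons=singletons,
        provenance={
            "stage": stage.value,
            "cutoff": base,
            "tolerance": params.tolerance,
            "gel_length": params.gel_length,
            "relax_floor": relax_floor,
            "assembly_max_hits": assembly_max_hits,
            "n_contigs": len(contigs),
            "n_singletons": len(singletons),
            "joins": joins,
            "forced_singletons": sorted(forced),
        },
    )
    asm.validate_partition(prof)
    return asm


# ---------------------------------------------------------------------------
# finalization


def dq_split(assembly: Assembly, profiles, params: ScoreParams) -> Assembly:
    """Split every contig holding >= 2 Q clones by reassembling its members at
    ten-fold stricter cutoffs until each piece has at most one Q clone."""
    prof = _profiles_dict(profiles)
    comps, extra_singletons, n_splits = [], set(), 0

    def _split(member_ids, cutoff):
        nonlocal n_splits
        next_cut = cutoff / 10.0
        if next_cut < 1e-300:
            comps.append(sorted(member_ids))
            return
        sub = assemble(
            {cid: prof[cid] for cid in member_ids},
            params=ScoreParams(params.tolerance, params.gel_length, next_cut),
        )
        n_splits += 1
        extra_singletons.update(sub.singletons)
        for ctg in sub.contigs:
            if len(ctg.q_clones) >= 2:
                _split(ctg.clone_ids, next_cut)
            else:
                comps.append(ctg.clone_ids)

    for ctg in assembly.contigs:
        if len(ctg.q_clones) >= 2:
            _split(ctg.clone_ids, params.cutoff)
        else:
            comps.append(ctg.clone_ids)

    contigs = _make_contigs(comps, prof, params)
    singletons = set(assembly.singletons) | extra_singletons
    out = Assembly(
        stage=assembly.stage,
        contigs=contigs,
        singletons=singletons,
        provenance={**assembly.provenance, "dq_splits": n_splits},
    )
    out.validate_partition(assembly.clone_ids())
    return out


def end_merge(
    assembly: Assembly, profiles, params: ScoreParams, floor: float = 1e-6
) -> Assembly:
    """Recursive end-to-end merging, lowering the cutoff one denary step at a
    time from ``params.cutoff`` down to ``floor``.  Only terminal clones (two
    per end) are tested; merged contigs are re-laid-out."""
    prof = _profiles_dict(profiles)
    comps = [list(ctg.clone_ids) for ctg in assembly.contigs]
    terms = [list(ctg.terminal_clones[0]) + list(ctg.terminal_clones[1])
             for ctg in assembly.contigs]
    n_merges = 0

    cutoff = params.cutoff
    while cutoff <= floor * (1 + 1e-9):
        step = ScoreParams(params.tolerance, params.gel_length, cutoff)
        thr = _threshold_cache(step)
        merged_something = True
        while merged_something:
            merged_something = False
            cands = []
            for i in range(len(comps)):
                for j in range(i + 1, len(comps)):
                    best = None
                    for a in terms[i]:
                        for b in terms[j]:
                            pa, pb = prof[a], prof[b]
                            if pa.n < 2 or pb.n < 2:
                                continue
                            m = match_count(pa.bands, pb.bands, step.tolerance)
                            t = thr(pa.n, pb.n, cutoff)
                            if t is not None and m >= t:
                                s = sulston_score(pa.n, pb.n, m, step)
                                if best is None or s < best:
                                    best = s
                    if best is not None:
                        cands.append((best, i, j))
            if cands:
                cands.sort()
                used = set()
                for _, i, j in cands:
                    if i in used or j in used:
                        continue
                    comps[i] = sorted(comps[i] + comps[j])
                    comps[j] = []
                    used.update((i, j))
                    n_merges += 1
                comps = [c for c in comps if c]
                # recompute terminals for every surviving component
                terms = []
                for c in comps:
                    offsets, cb_len, q = build_cb_map(c, prof, params)
                    ctg = Contig(0, sorted(offsets.items(), key=lambda t: (t[1], t[0])), cb_len, q)
                    t0 = _terminals(ctg, prof)
                    terms.append(list(t0[0]) + list(t0[1]))
                merged_something = True
        cutoff *= 10.0

    contigs = _make_contigs(comps, prof, params)
    out = Assembly(
        stage=assembly.stage,
        contigs=contigs,
        singletons=set(assembly.singletons),
        provenance={**assembly.provenance, "end_merges": n_merges,
                    "end_merge_floor": floor},
    )
    out.validate_partition(assembly.clone_ids())
    return out


def adopt_singletons(assembly: Assembly, profiles, params: ScoreParams) -> Assembly:
    """Greedy best-first adoption of singletons into contigs, repeated until
    fixpoint.  A singleton joins the contig holding its best accepted overlap
    with any unburied member; clones with < 2 bands are never adopted."""
    prof = _profiles_dict(profiles)
    comps = {ctg.contig_id: list(ctg.clone_ids) for ctg in assembly.contigs}
    buried = {ctg.contig_id: dict(ctg.buried) for ctg in assembly.contigs}
    singles = set(assembly.singletons)
    thr = _threshold_cache(params)
    n_adopted = 0

    changed = True
    while changed:
        changed = False
        cands = []
        member_of = {
            cid: k for k, mem in comps.items() for cid in mem
            if cid not in buried[k]
        }
        member_list = sorted(member_of)
        single_list = sorted(s for s in singles if prof[s].n >= 2)
        if not single_list or not member_list:
            break
        items = [prof[c].bands for c in single_list + member_list]
        ns = len(single_list)
        min_m = _min_possible_threshold(
            (len(b) for b in items), thr, params.cutoff
        )
        if min_m is None:
            break
        for i, j in candidate_pairs(items, params.tolerance, min_m):
            if (i < ns) == (j < ns):
                continue
            si, mi = (i, j) if i < ns else (j, i)
            s_id = single_list[si]
            m_id = member_list[mi - ns]
            pa, pb = prof[s_id], prof[m_id]
            m = match_count(pa.bands, pb.bands, params.tolerance)
            t = thr(pa.n, pb.n, params.cutoff)
            if t is not None and m >= t:
                score = sulston_score(pa.n, pb.n, m, params)
                cands.append((score, s_id, member_of[m_id]))
        if cands:
            cands.sort()
            taken = set()
            for score, s_id, k in cands:
                if s_id in taken:
                    continue
                comps[k].append(s_id)
                singles.discard(s_id)
                taken.add(s_id)
                n_adopted += 1
            changed = bool(taken)

    contigs = _make_contigs([sorted(c) for c in comps.values()], prof, params)
    out = Assembly(
        stage=assembly.stage,
        contigs=contigs,
        singletons=singles,
        provenance={**assembly.provenance, "adopted": n_adopted},
    )
    out.validate_partition(assembly.clone_ids())
    return out


def bury_clones(
    ctg: Contig, profiles, fraction: float = 0.80,
    params: ScoreParams = ScoreParams(),
) -> Contig:
    """Bury a clone into a parent whose band pattern contains >= ``fraction``
    of the child's bands.  Parents must have at least as many bands and are
    never themselves buried, which keeps the burial graph acyclic."""
    prof = _profiles_dict(profiles)
    order = sorted(ctg.clone_ids, key=lambda c: (-prof[c].n, c))
    buried: dict = {}
    for child in reversed(order):  # fewest bands first
        nc = prof[child].n
        if nc == 0:
            continue
        best = None
        for parent in order:
            if parent == child or parent in buried:
                continue
            if prof[parent].n < nc:
                continue
            m = match_count(prof[child].bands, prof[parent].bands, params.tolerance)
            if m >= fraction * nc and (best is None or m > best[0]):
                best = (m, parent)
        if best is not None and child not in buried.values():
            buried[child] = best[1]
    ctg.buried = buried
    ctg.terminal_clones = _terminals(ctg, prof)
    return ctg


# ---------------------------------------------------------------------------
# QC


def detect_cross_well(
    profiles, similarity: float = 0.90,
    params: ScoreParams = ScoreParams(), cross_plate: bool = False,
) -> set:
    """Flag clone pairs with near-identical band patterns in rook-adjacent
    wells of the same plate (possible well-to-well leakage)."""
    prof = _profiles_dict(profiles)
    by_well = {p.well: p for p in prof.values()}
    flagged = set()
    for p in prof.values():
        if p.n < 2:
            continue
        for dr, dc in ((0, 1), (1, 0)):
            other = by_well.get((p.plate, p.well_row + dr, p.well_col + dc))
            if other is None or other.n < 2:
                continue
            m = match_count(p.bands, other.bands, params.tolerance)
            if m >= similarity * max(p.n, other.n):
                flagged.update((p.clone_id, other.clone_id))
    return flagged


def _nearest_rank(values: list, pct: float):
    r = max(1, math.ceil(pct / 100.0 * len(values)))
    return values[r - 1]


def detect_band_outliers(
    profiles, low_pct: float = 5.0, high_pct: float = 5.0
) -> set:
    """Flag clones with band counts strictly beyond the per-batch nearest-rank
    percentiles (suspect chimeras / failed lanes)."""
    prof = _profiles_dict(profiles)
    by_batch = defaultdict(list)
    for p in prof.values():
        by_batch[p.batch].append(p)
    flagged = set()
    for batch, plist in by_batch.items():
        counts = sorted(p.n for p in plist)
        lo = _nearest_rank(counts, low_pct)
        hi = _nearest_rank(counts, 100.0 - high_pct)
        for p in plist:
            if p.n < lo or p.n > hi:
                flagged.add(p.clone_id)
    return flagged


# ---------------------------------------------------------------------------
# HICF targeting / evidence


def select_terminal_clones(
    assembly: Assembly, profiles, k_contigs: int, per_end: int = 2
) -> set:
    """Unburied clones at the extreme CB offsets of each end of the largest
    ``k_contigs`` contigs (ranked by member count, then cb_length, then id)."""
    prof = _profiles_dict(profiles)
    ranked = sorted(
        assembly.contigs, key=lambda c: (-c.size, -c.cb_length, c.contig_id)
    )
    out = set()
    for ctg in ranked[:k_contigs]:
        left, right = _terminals(ctg, prof, per_end)
        out.update(left)
        out.update(right)
    return out


def hicf_pseudomarkers(hicf_assembly: Assembly) -> list:
    """One HICF_CONTIG marker per HICF contig; singletons yield none."""
    return [
        EvidenceMarker(f"HICF_{ctg.contig_id}", MarkerKind.HICF_CONTIG,
                       frozenset(ctg.clone_ids))
        for ctg in hicf_assembly.contigs
    ]


# ---------------------------------------------------------------------------
# integrated pipeline


def run_integrated_pipeline(
    profiles,
    evidence: Iterable = (),
    config: PipelineConfig | None = None,
    hicf_profiles=None,
) -> PipelineResult:
    """The full integrated assembly: QC, preliminary agarose assembly, HICF of
    contig-terminal clones, integrated reassembly with two-denary HICF
    relaxation of terminal joins, DQ splitting, end merging, singleton
    adoption and burying."""
    cfg = config or PipelineConfig()
    prof = _profiles_dict(profiles)
    evidence = list(evidence)
    hicf_prof = _profiles_dict(hicf_profiles) if hicf_profiles else {}
    stages: dict = {}
    log: list = []

    # stage 0: QC
    forced = set()
    if cfg.qc_enabled:
        outliers = detect_band_outliers(prof, cfg.outlier_low_pct, cfg.outlier_high_pct)
        crosswell = detect_cross_well(
            prof, cfg.crosswell_similarity,
            ScoreParams(cfg.prelim_tolerance, cfg.gel_length, cfg.prelim_cutoff),
        )
        forced = outliers | crosswell
        stages["qc"] = {"outliers": sorted(outliers), "cross_well": sorted(crosswell)}
        log.append(("qc", {"outliers": len(outliers), "cross_well": len(crosswell)}))

    # stage 1: preliminary agarose assembly
    prelim_params = ScoreParams(cfg.prelim_tolerance, cfg.gel_length, cfg.prelim_cutoff)
    prelim = assemble(
        prof, evidence, prelim_params,
        relax_floor=cfg.prelim_cutoff * 1e4,
        assembly_max_hits=cfg.assembly_max_hits,
        forced_singletons=forced,
        stage=Stage.PRELIM_AGAROSE,
    )
    stages["prelim"] = prelim
    log.append(("prelim", {"contigs": len(prelim.contigs),
                           "singletons": len(prelim.singletons)}))

    # stage 2: HICF of terminal clones of the largest contigs
    hicf_markers: list = []
    terminal_map = None
    if hicf_prof:
        k = max(1, round(cfg.terminal_fraction * len(prelim.contigs)))
        terminals = select_terminal_clones(prelim, prof, k, cfg.per_end)
        subset = {c: hicf_prof[c] for c in terminals if c in hicf_prof}
        if subset:
            hicf_params = ScoreParams(cfg.hicf_tolerance, cfg.hicf_gel_length,
                                      cfg.hicf_cutoff)
            hicf_asm = assemble(subset, (), hicf_params, stage=Stage.HICF_ONLY)
            hicf_markers = hicf_pseudomarkers(hicf_asm)
            prelim_of = prelim.contig_of()
            terminal_map = {c: prelim_of[c] for c in terminals if c in prelim_of}
            stages["hicf"] = hicf_asm
            log.append(("hicf", {"clones": len(subset),
                                 "contigs": len(hicf_asm.contigs)}))

    # stage 3: integrated reassembly
    int_params = ScoreParams(cfg.integrated_tolerance, cfg.gel_length,
                             cfg.integrated_cutoff)
    integrated = assemble(
        prof, evidence + hicf_markers, int_params,
        relax_floor=cfg.integrated_cutoff * 1e4,
        assembly_max_hits=cfg.assembly_max_hits,
        terminal_map=terminal_map,
        forced_singletons=forced,
        stage=Stage.INTEGRATED,
    )
    stages["integrated"] = integrated
    log.append(("integrated", {"contigs": len(integrated.contigs),
                               "singletons": len(integrated.singletons)}))

    # stages 4-6: DQ split, end merge, adoption
    dq = dq_split(integrated, prof, int_params)
    stages["dq"] = dq
    log.append(("dq_split", {"contigs": len(dq.contigs)}))

    em = end_merge(dq, prof, int_params, floor=cfg.end_merge_floor)
    stages["end_merge"] = em
    log.append(("end_merge", {"contigs": len(em.contigs)}))

    ad = adopt_singletons(em, prof, int_params)
    stages["adopted"] = ad
    log.append(("adopt", {"contigs": len(ad.contigs),
                          "singletons": len(ad.singletons)}))

    # stage 7: bury near-identical clones, final report
    final_contigs = []
    for ctg in ad.contigs:
        final_contigs.append(
            bury_clones(ctg, prof, cfg.burial_fraction, int_params)
        )
    final = Assembly(
        stage=Stage.FINAL,
        contigs=final_contigs,
        singletons=set(ad.singletons),
        provenance={
            **ad.provenance,
            "stage": Stage.FINAL.value,
            "config": cfg.to_dict(),
            "stage_log": [(name, dict(counts)) for name, counts in log],
        },
    )
    final.validate_partition(prof)
    stages["final"] = final
    log.append(("final", {"contigs": len(final.contigs),
                          "singletons": len(final.singletons),
                          "buried": sum(len(c.buried) for c in final.contigs)}))
    return PipelineResult(final=final, stages=stages, log=log)
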