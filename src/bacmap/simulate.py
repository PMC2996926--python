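"""Synthetic genome/BAC-library generator with ground truth for every stage.

Restriction cut sites are drawn once per genome as homogeneous Poisson
processes, so overlapping clones share their internal fragments exactly —
the property fingerprint assembly rests on.  Fragment-size windows are
calibrated so a 100-kb clone yields ~17.4 scoreable agarose bands and ~178
HICF bands across five enzyme channels.  Every draw is deterministic under
``(config, seed)``; module stages derive child generators from the master
seed by fixed offsets.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .fingerprint import BandProfile, Method, ScoreParams
from .overgo import PoolDesign, PoolHits
from .anchoring import GeneticMap, MapLocus
from .synteny import Hit, HitTable, QueryKind

__all__ = [
    "SimConfig",
    "CloneTruth",
    "GenomeTruth",
    "Comparator",
    "EvalMetrics",
    "simulate_genome",
    "simulate_library",
    "digest",
    "make_profiles",
    "simulate_probe_hits",
    "simulate_pool_experiment",
    "simulate_comparator",
    "build_genetic_map",
    "bes_queries",
    "evaluate",
    "anchoring_group_accuracy",
]


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Desk-scale defaults; the published project ran at genome_bp=8.8e8."""

    genome_bp: int = 20_000_000
    repeat_fraction: float = 0.30
    repeat_unit_bp: int = 5_000
    repeat_copy_mean: float = 120.0
    organelle_bp: int = 160_000
    organelle_rate: float = 0.0007
    coverage: float = 10.0
    insert_mean: float = 100_000.0
    insert_sd: float = 5_000.0
    failed_rate: float = 0.035
    chimera_rate: float = 0.0
    crosswell_rate: float = 0.0
    # agarose digestion (HindIII-like 6-cutter)
    agarose_cut_bp: float = 4096.0
    agarose_min_frag: int = 1_000
    agarose_max_frag: int = 20_000
    gel_length: int = 5_000
    # HICF digestion (5 enzyme channels, composite band encoding)
    hicf_channels: int = 5
    hicf_cut_bp: float = 2_350.0
    hicf_min_frag: int = 300
    hicf_max_frag: int = 12_000
    hicf_channel_span: int = 2_000
    # fingerprint noise
    band_dropout: float = 0.0
    band_spurious: float = 0.0
    band_jitter: int = 0
    # probes
    n_probes: int = 200
    repetitive_probe_fraction: float = 0.10
    # genes / genetic map
    gene_every_bp: int = 20_000
    gene_len_bp: int = 2_000
    n_groups: int = 13
    bp_per_cm: int = 600_000
    # comparator genome
    n_wgd: int = 0
    comparator_block_bp: int = 500_000
    comparator_chroms: int = 5
    wgd_retention: float = 0.30
    hit_loss: float = 0.0
    # plates
    plate_rows: int = 16
    plate_cols: int = 24

    def __post_init__(self) -> None:
        for name in ("repeat_fraction", "organelle_rate", "failed_rate",
                     "chimera_rate", "crosswell_rate", "band_dropout",
                     "repetitive_probe_fraction", "wgd_retention", "hit_loss"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SimulationError(f"{name} must be in [0, 1], got {v}")
        for name in ("genome_bp", "organelle_bp", "insert_mean", "coverage",
                     "gel_length", "agarose_cut_bp", "hicf_cut_bp"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")


@dataclass
class CloneTruth:
    clone_id: str
    segments: list          # [(start, end)] on its source; 2 entries if chimeric
    source: str             # "nuclear" | "organelle"
    chimeric: bool = False
    failed: bool = False
    crosswell_copy_of: str | None = None
    plate: int = 0
    well_row: int = 0
    well_col: int = 0

    @property
    def start(self) -> int:
        return self.segments[0][0]

    @property
    def end(self) -> int:
        return self.segments[-1][1]

    def midpoint(self) -> float:
        s, e = self.segments[0]
        return (s + e) / 2.0


@dataclass
class GenomeTruth:
    config: SimConfig
    seed: int
    repeats: list                    # (start, end, family_id)
    genes: list                      # (start, end)
    probe_positions: dict            # probe_id -> sorted list of positions
    agarose_cuts: np.ndarray
    organelle_agarose_cuts: np.ndarray
    hicf_cuts: list                  # per channel np.ndarray (nuclear)
    organelle_hicf_cuts: list
    clones: list = field(default_factory=list)

    def repeat_measured_fraction(self) -> float:
        covered = 0
        last = -1
        for s, e, _ in sorted(self.repeats):
            s = max(s, last)
            if e > s:
                covered += e - s
                last = e
        return covered / self.config.genome_bp


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def _poisson_cuts(rng, length: float, rate_bp: float) -> np.ndarray:
    n = rng.poisson(length / rate_bp)
    return np.sort(rng.uniform(0, length, size=n))


def simulate_genome(cfg: SimConfig, seed: int = 0) -> GenomeTruth:
    """Draw the genome-level truth: repeat families, genes, probe loci and the
    per-enzyme cut-site processes (nuclear and organelle)."""
    rng = _rng(seed, 0)
    g = cfg.genome_bp

    # repeat families placed until the union covers the configured fraction;
    # coverage tracked on a 100-bp mask so copy overlap cannot bias it down
    repeats: list = []
    family = 0
    res = 100
    mask = np.zeros(max(1, g // res), dtype=bool)
    while cfg.repeat_fraction > 0 and mask.mean() < cfg.repeat_fraction:
        copies = max(1, int(rng.poisson(cfg.repeat_copy_mean)))
        starts = rng.integers(0, max(1, g - cfg.repeat_unit_bp), size=copies)
        for s in np.sort(starts):
            repeats.append((int(s), int(s) + cfg.repeat_unit_bp, family))
            mask[int(s) // res:(int(s) + cfg.repeat_unit_bp) // res] = True
            if mask.mean() >= cfg.repeat_fraction:
                break
        family += 1

    def in_repeat(pos: int) -> bool:
        return any(s <= pos < e for s, e, _ in repeats) if repeats else False

    # genes preferentially outside repeats
    genes = []
    for _ in range(g // cfg.gene_every_bp):
        for _attempt in range(4):
            s = int(rng.integers(0, max(1, g - cfg.gene_len_bp)))
            if not in_repeat(s):
                break
        genes.append((s, s + cfg.gene_len_bp))
    genes.sort()

    # probe loci: low-copy probes sit at gene starts, repetitive probes take a
    # fixed offset inside every copy of one repeat family
    by_family: dict = defaultdict(list)
    for s, e, fam in repeats:
        by_family[fam].append(s)
    families = sorted(by_family)
    probe_positions: dict = {}
    n_rep = int(round(cfg.n_probes * cfg.repetitive_probe_fraction))
    for i in range(cfg.n_probes):
        pid = f"P{i:04d}"
        if i < n_rep and families:
            fam = families[i % len(families)]
            offset = int(rng.integers(0, cfg.repeat_unit_bp - 40))
            # sub-sample copies so moderate and high classes both occur
            copies = by_family[fam]
            k = int(rng.integers(2, max(3, len(copies) + 1)))
            chosen = sorted(rng.choice(len(copies), size=min(k, len(copies)),
                                       replace=False).tolist())
            probe_positions[pid] = sorted(copies[j] + offset for j in chosen)
        else:
            if genes:
                gi = int(rng.integers(0, len(genes)))
                probe_positions[pid] = [genes[gi][0]]
            else:
                probe_positions[pid] = [int(rng.integers(0, g))]

    agarose_cuts = _poisson_cuts(rng, g, cfg.agarose_cut_bp)
    org_agarose = _poisson_cuts(rng, cfg.organelle_bp, cfg.agarose_cut_bp)
    hicf_cuts = [_poisson_cuts(rng, g, cfg.hicf_cut_bp)
                 for _ in range(cfg.hicf_channels)]
    org_hicf = [_poisson_cuts(rng, cfg.organelle_bp, cfg.hicf_cut_bp)
                for _ in range(cfg.hicf_channels)]
    return GenomeTruth(cfg, seed, repeats, genes, probe_positions,
                       agarose_cuts, org_agarose, hicf_cuts, org_hicf)


# ---------------------------------------------------------------------------
# library


def simulate_library(truth: GenomeTruth, seed: int = 0) -> list:
    """Place the BAC library and store it on the truth object.

    Clone count is ``coverage * genome / insert_mean``; starts are uniform,
    organelle contaminants and chimeras occur at the configured rates and
    wells fill plate-major.
    """
    cfg = truth.config
    if cfg.genome_bp <= cfg.insert_mean:
        raise SimulationError("genome shorter than one insert")
    rng = _rng(seed, 1)
    n = int(round(cfg.coverage * cfg.genome_bp / cfg.insert_mean))
    wells_per_plate = cfg.plate_rows * cfg.plate_cols
    clones = []
    for i in range(n):
        cid = f"C{i:05d}"
        insert = float(np.clip(rng.normal(cfg.insert_mean, cfg.insert_sd),
                               0.5 * cfg.insert_mean, 1.5 * cfg.insert_mean))
        organelle = rng.random() < cfg.organelle_rate
        chimeric = (not organelle) and rng.random() < cfg.chimera_rate
        if organelle:
            length = min(int(insert), cfg.organelle_bp - 1)
            s = int(rng.integers(0, cfg.organelle_bp - length))
            segments = [(s, s + length)]
            source = "organelle"
        elif chimeric:
            half = int(insert) // 2
            s1 = int(rng.integers(0, cfg.genome_bp - half))
            s2 = int(rng.integers(0, cfg.genome_bp - half))
            segments = [(s1, s1 + half), (s2, s2 + half)]
            source = "nuclear"
        else:
            s = int(rng.integers(0, cfg.genome_bp - int(insert)))
            segments = [(s, s + int(insert))]
            source = "nuclear"
        failed = rng.random() < cfg.failed_rate
        widx = i % wells_per_plate
        clones.append(CloneTruth(
            cid, segments, source, chimeric, failed, None,
            plate=i // wells_per_plate,
            well_row=widx // cfg.plate_cols,
            well_col=widx % cfg.plate_cols,
        ))
    # cross-well contamination: clone takes over its left neighbour's DNA
    for i, clone in enumerate(clones):
        if clone.well_col > 0 and rng.random() < cfg.crosswell_rate:
            donor = clones[i - 1]
            clone.segments = [tuple(seg) for seg in donor.segments]
            clone.source = donor.source
            clone.chimeric = donor.chimeric
            clone.crosswell_copy_of = donor.clone_id
    truth.clones = clones
    return clones


def _fragments(cuts: np.ndarray, segments: Sequence) -> list:
    """Sizes of fully-internal restriction fragments of a clone."""
    out = []
    for s, e in segments:
        lo = np.searchsorted(cuts, s, side="right")
        hi = np.searchsorted(cuts, e, side="left")
        inner = cuts[lo:hi]
        if len(inner) >= 2:
            out.extend(np.diff(inner).tolist())
    return out


def _to_units(sizes, min_frag, max_frag, n_units) -> list:
    units = sorted({
        int(min(n_units, max(1, math.ceil(s * n_units / max_frag))))
        for s in sizes if min_frag <= s <= max_frag
    })
    return units


def digest(truth: GenomeTruth, clone: CloneTruth, method: Method,
           rng: np.random.Generator | None = None) -> BandProfile:
    """In-silico digest of one clone into a scoreable band profile.

    Noise (dropout / spurious bands / jitter) is applied when the config rates
    are non-zero and an ``rng`` is supplied.
    """
    cfg = truth.config
    bands: list = []
    if not clone.failed:
        if method is Method.AGAROSE:
            cuts = (truth.organelle_agarose_cuts if clone.source == "organelle"
                    else truth.agarose_cuts)
            sizes = _fragments(cuts, clone.segments)
            bands = _to_units(sizes, cfg.agarose_min_frag, cfg.agarose_max_frag,
                              cfg.gel_length)
        else:
            span = cfg.hicf_channel_span
            top = span - 10  # keep away from channel edges
            channels = (truth.organelle_hicf_cuts if clone.source == "organelle"
                        else truth.hicf_cuts)
            for ch, cuts in enumerate(channels):
                sizes = _fragments(cuts, clone.segments)
                units = _to_units(sizes, cfg.hicf_min_frag, cfg.hicf_max_frag, top)
                bands.extend(ch * span + u for u in units)
        bands = sorted(set(bands))
        if rng is not None and (cfg.band_dropout or cfg.band_spurious
                                or cfg.band_jitter):
            bands = _apply_noise(bands, cfg, method, rng)
    return BandProfile(
        clone.clone_id, method, tuple(bands),
        plate=clone.plate, well_row=clone.well_row, well_col=clone.well_col,
        batch=clone.plate,
    )


def _apply_noise(bands, cfg, method, rng):
    top = (cfg.gel_length if method is Method.AGAROSE
           else cfg.hicf_channels * cfg.hicf_channel_span)
    out = []
    for b in bands:
        if cfg.band_dropout and rng.random() < cfg.band_dropout:
            continue
        if cfg.band_jitter:
            b = int(np.clip(b + rng.integers(-cfg.band_jitter,
                                             cfg.band_jitter + 1), 1, top))
        out.append(b)
    if cfg.band_spurious:
        for _ in range(rng.poisson(cfg.band_spurious)):
            out.append(int(rng.integers(1, top + 1)))
    return sorted(set(out))


def make_profiles(truth: GenomeTruth, method: Method = Method.AGAROSE,
                  seed: int = 0, clone_ids: Iterable | None = None) -> dict:
    """Digest the whole library (or a subset) into profiles, honouring the
    configured noise rates and cross-well contaminations."""
    rng = _rng(seed, 2 if method is Method.AGAROSE else 3)
    wanted = set(clone_ids) if clone_ids is not None else None
    profiles = {}
    for clone in truth.clones:
        if wanted is not None and clone.clone_id not in wanted:
            continue
        profiles[clone.clone_id] = digest(truth, clone, method, rng)
    return profiles


# ---------------------------------------------------------------------------
# probes, pools, genetic map


def simulate_probe_hits(truth: GenomeTruth) -> dict:
    """probe -> set of BAC ids whose insert contains any copy of the probe."""
    segs = []
    for clone in truth.clones:
        if clone.source != "nuclear":
            continue
        for s, e in clone.segments:
            segs.append((s, e, clone.clone_id))
    segs.sort()
    starts = np.array([s for s, _, _ in segs])
    max_len = max((e - s for s, e, _ in segs), default=0)
    hits: dict = {}
    for pid, positions in sorted(truth.probe_positions.items()):
        found = set()
        for p in positions:
            hi = int(np.searchsorted(starts, p, side="right"))
            lo = int(np.searchsorted(starts, p - max_len, side="left"))
            for s, e, cid in segs[lo:hi]:
                if s <= p < e:
                    found.add(cid)
        hits[pid] = found
    return hits


def simulate_pool_experiment(
    design: PoolDesign, matrix: Mapping, seed: int = 0,
    false_negative: float = 0.0, false_positive: float = 0.0,
) -> PoolHits:
    """Pool-level membrane scoring: a pool lights up for a BAC when any member
    probe truly hits it; then FN/FP noise is applied per (BAC, pool)."""
    rng = _rng(seed, 4)
    positives: dict = defaultdict(set)
    for pid, bacs in sorted(matrix.items()):
        if pid not in design.probe_positions:
            continue
        pools = design.pools_of(pid)
        for bac in bacs:
            positives[bac].update(pools)
    all_pools = sorted(design.pools)
    noisy: dict = {}
    for bac in sorted(positives):
        pools = set()
        for pool in positives[bac]:
            if false_negative and rng.random() < false_negative:
                continue
            pools.add(pool)
        if false_positive:
            for pool in all_pools:
                if pool not in positives[bac] and rng.random() < false_positive:
                    pools.add(pool)
        noisy[bac] = pools
    return PoolHits(dict(noisy))


def build_genetic_map(truth: GenomeTruth) -> GeneticMap:
    """Single-copy probes become mapped markers; the genome splits into
    ``n_groups`` equal linkage groups with cM linear in bp."""
    cfg = truth.config
    span = cfg.genome_bp / cfg.n_groups
    loci = []
    for pid, positions in sorted(truth.probe_positions.items()):
        if len(positions) != 1:
            continue
        pos = positions[0]
        group = min(cfg.n_groups, int(pos // span) + 1)
        cm = (pos - (group - 1) * span) / cfg.bp_per_cm
        loci.append(MapLocus(pid, group, cm))
    return GeneticMap(loci, cfg.n_groups)


def true_group(truth: GenomeTruth, position: float) -> int:
    cfg = truth.config
    span = cfg.genome_bp / cfg.n_groups
    return min(cfg.n_groups, int(position // span) + 1)


# ---------------------------------------------------------------------------
# comparator genomes


@dataclass
class Comparator:
    n_wgd: int
    chrom_lengths: dict
    placements: list   # (src_start, src_end, copy, chrom, tgt_start)
    hit_table: HitTable
    genes: list        # (chrom, start, end)

    def map_position(self, pos: float, copy: int = 0):
        for src_s, src_e, cp, chrom, tgt in self.placements:
            if cp == copy and src_s <= pos < src_e:
                return chrom, int(tgt + (pos - src_s))
        return None

    def invert(self, chrom: str, pos: int):
        for src_s, src_e, cp, tchrom, tgt in self.placements:
            if tchrom == chrom and tgt <= pos < tgt + (src_e - src_s):
                return src_s + (pos - tgt), cp
        return None


def simulate_comparator(truth: GenomeTruth, n_wgd: int | None = None,
                        seed: int = 0) -> Comparator:
    """Shuffle source blocks onto comparator chromosomes, duplicating the
    genome ``2**n_wgd``-fold with per-query gene retention on the extra
    copies, then generate BES/probe-source hit rows through the block map."""
    cfg = truth.config
    if n_wgd is None:
        n_wgd = cfg.n_wgd
    rng = _rng(seed, 5 + n_wgd)
    g = cfg.genome_bp
    block = cfg.comparator_block_bp
    edges = list(range(0, g, block)) + [g]
    blocks = [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
    n_copies = 2 ** n_wgd

    jobs = [(b, cp) for cp in range(n_copies) for b in range(len(blocks))]
    order = rng.permutation(len(jobs))
    offsets = {f"chr{c + 1}": 0 for c in range(cfg.comparator_chroms)}
    placements = []
    for rank, jidx in enumerate(order):
        b, cp = jobs[jidx]
        chrom = f"chr{(rank % cfg.comparator_chroms) + 1}"
        s, e = blocks[b]
        placements.append((s, e, cp, chrom, offsets[chrom]))
        offsets[chrom] += e - s
    chrom_lengths = dict(offsets)

    def place(pos: float, cp: int):
        for src_s, src_e, pcp, chrom, tgt in placements:
            if pcp == cp and src_s <= pos < src_e:
                return chrom, int(tgt + (pos - src_s))
        return None

    # queries: BAC end sequences + probe source loci
    queries = []
    for clone in truth.clones:
        if clone.source != "nuclear" or clone.chimeric:
            continue
        s, e = clone.segments[0]
        queries.append((f"{clone.clone_id}_L", QueryKind.BES, [s]))
        queries.append((f"{clone.clone_id}_R", QueryKind.BES, [e - 1]))
    for pid, positions in sorted(truth.probe_positions.items()):
        queries.append((pid, QueryKind.PROBE_SOURCE, list(positions)))

    hits = []
    for qid, kind, positions in queries:
        for pos in positions:
            for cp in range(n_copies):
                if cp > 0 and rng.random() >= cfg.wgd_retention:
                    continue
                if cfg.hit_loss and rng.random() < cfg.hit_loss:
                    continue
                mapped = place(pos, cp)
                if mapped is not None:
                    hits.append(Hit(qid, kind, mapped[0], mapped[1]))

    genes = []
    for gs, ge in truth.genes:
        for cp in range(n_copies):
            if cp > 0 and rng.random() >= cfg.wgd_retention:
                continue
            mapped = place(gs, cp)
            if mapped is not None:
                genes.append((mapped[0], mapped[1], mapped[1] + (ge - gs)))

    table = HitTable(hits, {}, chrom_lengths)
    return Comparator(n_wgd, chrom_lengths, placements, table, sorted(genes))


def bes_queries(assembly) -> dict:
    """query_id -> contig_id map for BES query names (<clone>_L / <clone>_R)."""
    contig_of = assembly.contig_of()
    out = {}
    for cid, ctg in contig_of.items():
        out[f"{cid}_L"] = ctg
        out[f"{cid}_R"] = ctg
    return out


# ---------------------------------------------------------------------------
# truth-based evaluation


@dataclass
class EvalMetrics:
    precision: float
    recall: float
    purity: float
    n_co_contig_pairs: int
    n_true_pairs: int
    precision_defined: bool


def _overlap_bp(a: CloneTruth, b: CloneTruth) -> int:
    if a.source != b.source:
        return 0
    best = 0
    for s1, e1 in a.segments:
        for s2, e2 in b.segments:
            best = max(best, min(e1, e2) - max(s1, s2))
    return best


def _truth_islands(clones: Sequence, min_overlap: int) -> dict:
    """Connected components of the >=min_overlap true-overlap graph, per
    source, via a sweep over sorted intervals."""
    comp = {}
    label = 0
    for source in ("nuclear", "organelle"):
        segs = sorted(
            (c.segments[0][0], c.segments[0][1], c.clone_id)
            for c in clones if c.source == source and not c.chimeric
        )
        reach = None
        for s, e, cid in segs:
            if reach is None or s > reach - min_overlap:
                label += 1
            comp[cid] = label
            reach = e if reach is None else max(reach, e)
    for c in clones:
        if c.chimeric:
            label += 1
            comp[c.clone_id] = label
    return comp


def evaluate(assembly, truth: GenomeTruth, profiles: Mapping,
             params: ScoreParams, min_overlap: int = 20_000) -> EvalMetrics:
    """Truth-based scoring of an assembly.

    precision: fraction of co-contiged clone pairs that truly overlap by
    >= ``min_overlap`` bp or are connected through a chain of such overlaps
    within their contig.  recall: fraction of true pairs whose matched-band
    count reaches the pair's Sulston acceptance threshold that ended up
    co-contiged.  purity: mean largest-truth-island member fraction.
    """
    from .assembly import candidate_pairs, _threshold_cache  # late import

    clones = {c.clone_id: c for c in truth.clones}
    contig_of = assembly.contig_of()

    # precision over co-contig pairs, via within-contig truth connectivity
    n_pairs = n_correct = 0
    for ctg in assembly.contigs:
        ids = ctg.clone_ids
        idx = {c: i for i, c in enumerate(ids)}
        parent = list(range(len(ids)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                if _overlap_bp(clones[a], clones[b]) >= min_overlap:
                    ra, rb = find(idx[a]), find(idx[b])
                    if ra != rb:
                        parent[rb] = ra
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                n_pairs += 1
                if find(i) == find(j):
                    n_correct += 1
    precision_defined = n_pairs > 0
    precision = (n_correct / n_pairs) if precision_defined else 1.0

    # recall over true pairs at or above the pairwise Sulston threshold
    ids = sorted(profiles)
    items = [profiles[c].bands for c in ids]
    thr = _threshold_cache(params)
    counts = [len(b) for b in items]
    min_m = None
    for i, a in enumerate(sorted(set(counts))):
        for b in sorted(set(counts))[i:]:
            t = thr(a, b, params.cutoff)
            if t is not None and (min_m is None or t < min_m):
                min_m = t
    n_true = n_found = 0
    if min_m is not None:
        from .fingerprint import match_count
        for i, j in candidate_pairs(items, params.tolerance, min_m):
            a, b = ids[i], ids[j]
            if _overlap_bp(clones[a], clones[b]) <= 0:
                continue
            m = match_count(items[i], items[j], params.tolerance)
            t = thr(len(items[i]), len(items[j]), params.cutoff)
            if t is None or m < t:
                continue
            n_true += 1
            if contig_of.get(a) is not None and contig_of.get(a) == contig_of.get(b):
                n_found += 1
    recall = (n_found / n_true) if n_true else 1.0

    # purity against truth islands
    islands = _truth_islands(truth.clones, min_overlap)
    purities = []
    for ctg in assembly.contigs:
        labels = [islands[c] for c in ctg.clone_ids if c in islands]
        if labels:
            top = max(labels.count(l) for l in set(labels))
            purities.append(top / len(labels))
    purity = float(np.mean(purities)) if purities else 1.0

    return EvalMetrics(precision, recall, purity, n_pairs, n_true,
                       precision_defined)


def anchoring_group_accuracy(records: Iterable, assembly,
                             truth: GenomeTruth) -> float:
    """Fraction of anchored contigs whose true linkage group (from the median
    member midpoint) appears among their non-weak anchor groups."""
    clones = {c.clone_id: c for c in truth.clones}
    strong: dict = defaultdict(set)
    for r in records:
        if not r.weak:
            strong[r.contig_id].add(r.group)
    if not strong:
        return 1.0
    by_id = {c.contig_id: c for c in assembly.contigs}
    good = 0
    for ctg_id, groups in strong.items():
        mids = [clones[c].midpoint() for c in by_id[ctg_id].clone_ids
                if clones[c].source == "nuclear"]
        if not mids:
            continue
        tg = true_group(truth, float(np.median(mids)))
        if tg in groups:
            good += 1
    return good / len(strong)
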