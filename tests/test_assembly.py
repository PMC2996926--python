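"""Tests for contig assembly, CB layout, finalization and the pipeline."""

import numpy as np
import pytest

from bacmap.assembly import (
    Assembly,
    AssemblyError,
    EvidenceMarker,
    MarkerKind,
    Stage,
    adopt_singletons,
    assemble,
    build_cb_map,
    bury_clones,
    detect_band_outliers,
    detect_cross_well,
    dq_split,
    end_merge,
    hicf_pseudomarkers,
    run_integrated_pipeline,
    select_terminal_clones,
)
from bacmap.config import PipelineConfig
from bacmap.fingerprint import (
    Method,
    ScoreParams,
    match_count,
    min_match_threshold_pair,
)
from bacmap.simulate import evaluate

from conftest import GRID, profile


def truth_overlap_components(profiles, params):
    """Independent oracle: connected components of the graph joining pairs
    whose matched-band count reaches the pairwise Sulston threshold."""
    ids = sorted(cid for cid, p in profiles.items() if p.n >= 2)
    parent = {c: c for c in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    cache = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            na, nb = profiles[a].n, profiles[b].n
            key = (min(na, nb), max(na, nb))
            if key not in cache:
                cache[key] = min_match_threshold_pair(na, nb, params)
            t = cache[key]
            if t is None:
                continue
            m = match_count(profiles[a].bands, profiles[b].bands,
                            params.tolerance)
            if m >= t:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    comps = {}
    for c in ids:
        comps.setdefault(find(c), set()).add(c)
    return {frozenset(v) for v in comps.values() if len(v) >= 2}


class TestAssemble:
    def test_transitive_chain_forms_one_contig(self, score_params):
        pool = GRID[:26]
        profiles = {
            "c1": profile("c1", pool[0:18]),
            "c2": profile("c2", pool[4:22]),
            "c3": profile("c3", pool[8:26]),
        }
        asm = assemble(profiles, params=score_params)
        assert len(asm.contigs) == 1 and asm.contigs[0].size == 3
        assert not asm.singletons

    def test_marker_relaxation_joins_borderline_pair(self):
        shared = [100 + 30 * k for k in range(11)]
        a = profile("a", sorted(shared + [1000 + 30 * k for k in range(6)]))
        b = profile("b", sorted(shared + [2000 + 30 * k for k in range(6)]))
        params = ScoreParams(7, 5000, 1e-12)
        bare = assemble({"a": a, "b": b}, params=params)
        assert len(bare.contigs) == 0 and bare.singletons == {"a", "b"}
        marker = EvidenceMarker("m1", MarkerKind.PROBE, frozenset({"a", "b"}))
        relaxed = assemble({"a": a, "b": b}, [marker], params,
                           relax_floor=1e-8)
        assert len(relaxed.contigs) == 1

    def test_repetitive_probe_not_used(self):
        shared = [100 + 30 * k for k in range(11)]
        a = profile("a", sorted(shared + [1000 + 30 * k for k in range(6)]))
        b = profile("b", sorted(shared + [2000 + 30 * k for k in range(6)]))
        clones = frozenset({"a", "b"} | {f"z{i}" for i in range(60)})
        marker = EvidenceMarker("rep", MarkerKind.PROBE, clones)
        profiles = {"a": a, "b": b}
        asm = assemble(profiles, [marker], ScoreParams(7, 5000, 1e-12),
                       relax_floor=1e-8, assembly_max_hits=50)
        assert len(asm.contigs) == 0

    def test_components_match_truth_graph(self, small_truth, score_params):
        _, profiles = small_truth
        asm = assemble(profiles, params=score_params)
        got = {frozenset(c.clone_ids) for c in asm.contigs}
        assert got == truth_overlap_components(profiles, score_params)

    def test_empty_profiles_raise(self, score_params):
        with pytest.raises(AssemblyError):
            assemble({}, params=score_params)

    def test_partition_invariant(self, small_truth, score_params):
        _, profiles = small_truth
        asm = assemble(profiles, params=score_params)
        asm.validate_partition(profiles)

    def test_joins_respect_cutoff(self, small_truth, score_params):
        _, profiles = small_truth
        asm = assemble(profiles, params=score_params)
        for a, b, score, cutoff, m in asm.provenance["joins"]:
            assert score <= cutoff

    def test_deterministic(self, small_truth, score_params):
        _, profiles = small_truth
        a1 = assemble(profiles, params=score_params)
        a2 = assemble(profiles, params=score_params)
        assert [c.members for c in a1.contigs] == [c.members for c in a2.contigs]
        assert a1.singletons == a2.singletons

    def test_contig_numbering_by_smallest_member(self, small_truth, score_params):
        _, profiles = small_truth
        asm = assemble(profiles, params=score_params)
        mins = [min(c.clone_ids) for c in asm.contigs]
        assert mins == sorted(mins)

    def test_noise_free_precision_recall(self, small_truth, score_params):
        truth, profiles = small_truth
        asm = assemble(profiles, params=score_params)
        metrics = evaluate(asm, truth, profiles, score_params)
        assert metrics.precision == 1.0
        assert metrics.recall == 1.0


class TestBuildCbMap:
    def test_singleton(self, score_params):
        profiles = {"a": profile("a", GRID[:10])}
        offsets, cb_len, q = build_cb_map(["a"], profiles, score_params)
        assert offsets == {"a": 0} and cb_len == 10 and not q

    def test_identical_pair(self, score_params):
        profiles = {"a": profile("a", GRID[:12]), "b": profile("b", GRID[:12])}
        offsets, cb_len, q = build_cb_map(["a", "b"], profiles, score_params)
        assert cb_len == 12
        assert offsets["a"] == offsets["b"]
        assert not q

    def test_simulated_staircase_bounds(self, small_truth, score_params):
        truth, profiles = small_truth
        clones = sorted(
            (c for c in truth.clones
             if c.source == "nuclear" and not c.failed),
            key=lambda c: c.start,
        )
        stair = clones[10:15]
        ids = [c.clone_id for c in stair]
        offsets, cb_len, _ = build_cb_map(ids, profiles, score_params)
        counts = [profiles[c].n for c in ids]
        assert max(counts) <= cb_len <= sum(counts)
        span = max(c.end for c in stair) - min(c.start for c in stair)
        # average scoreable band size = mean band size over all fingerprinted
        # bands (gel units are bp/4)
        all_units = [u for p in profiles.values() for u in p.bands]
        avg_band_bp = 4.0 * np.mean(all_units)
        assert cb_len == pytest.approx(span / avg_band_bp, rel=0.25)


class TestDqSplit:
    def test_no_q_clones_unchanged(self, score_params):
        profiles = {
            "c1": profile("c1", GRID[0:18]),
            "c2": profile("c2", GRID[4:22]),
        }
        asm = assemble(profiles, params=score_params)
        out = dq_split(asm, profiles, score_params)
        assert [c.clone_ids for c in out.contigs] == \
            [c.clone_ids for c in asm.contigs]

    def test_chimera_bridged_contig_splits(self, chimera_contig, score_params):
        asm = assemble(chimera_contig, params=score_params)
        assert len(asm.contigs) == 1
        merged = asm.contigs[0]
        assert merged.q_clones == {"X1", "X2"}
        out = dq_split(asm, chimera_contig, score_params)
        comps = {frozenset(c.clone_ids) for c in out.contigs}
        assert frozenset({"A1", "A2", "A3"}) in comps
        assert frozenset({"B1", "B2", "B3"}) in comps
        assert {"X1", "X2"} <= out.singletons
        assert all(len(c.q_clones) <= 1 for c in out.contigs)

    def test_never_increases_q_clones(self, chimera_contig, score_params):
        asm = assemble(chimera_contig, params=score_params)
        before = sum(len(c.q_clones) for c in asm.contigs)
        out = dq_split(asm, chimera_contig, score_params)
        assert sum(len(c.q_clones) for c in out.contigs) <= before

    def test_partition_preserved(self, chimera_contig, score_params):
        asm = assemble(chimera_contig, params=score_params)
        dq_split(asm, chimera_contig, score_params).validate_partition(
            chimera_contig)


class TestEndMerge:
    def _stair(self, prefix, pool):
        return {
            f"{prefix}{i + 1}": profile(f"{prefix}{i + 1}",
                                        pool[4 * i:4 * i + 18])
            for i in range(3)
        }

    def test_merges_at_descended_cutoff(self, score_params):
        # terminal pair shares 9 of 18 bands: S ~ 5e-8, above 1e-12 and
        # below the 1e-6 floor
        X = GRID[0:13]
        Y = GRID[18:23]
        Z = GRID[23:32]
        A2 = profile("A2", X + Y)
        B1 = profile("B1", sorted(Y + X[:4] + Z))
        A1 = profile("A1", X + GRID[13:18])
        B2 = profile("B2", sorted(Z + X[:4] + GRID[32:37]))
        profiles = {"A1": A1, "A2": A2, "B1": B1, "B2": B2}
        asm = assemble(profiles, params=score_params)
        assert len(asm.contigs) == 2
        out = end_merge(asm, profiles, score_params, floor=1e-6)
        assert len(out.contigs) == 1

    def test_non_terminal_overlap_not_merged(self, score_params):
        poolA = [100 + 25 * k for k in range(30)]
        poolB = [2000 + 25 * k for k in range(30)]
        profiles = {}
        for i in range(3):
            profiles[f"A{i + 1}"] = profile(f"A{i + 1}", poolA[4 * i:4 * i + 18])
            profiles[f"B{i + 1}"] = profile(f"B{i + 1}", poolB[4 * i:4 * i + 18])
        # middle clones share heavily, terminals share nothing
        mids = sorted(poolA[4:17] + poolB[4:9])
        profiles["A2"] = profile("A2", mids)
        profiles["B2"] = profile("B2", mids)
        asm = assemble(profiles, params=score_params)
        # A2/B2 identical: single linkage puts everything together already —
        # rebuild two contigs without the bridge to test the end rule
        profiles.pop("A2")
        profiles.pop("B2")
        # now: A1/A3 share 10 bands (poolA[8:18]) and B1/B3 likewise; they
        # stay apart at 1e-12 but their cross-contig band sharing is zero
        asm = assemble(profiles, params=ScoreParams(7, 5000, 1e-6))
        assert len(asm.contigs) == 2
        out = end_merge(asm, profiles, ScoreParams(7, 5000, 1e-12), floor=1e-6)
        assert len(out.contigs) == 2

    def test_never_splits(self, small_truth, score_params):
        _, profiles = small_truth
        asm = assemble(profiles, params=score_params)
        out = end_merge(asm, profiles, score_params, floor=1e-6)
        assert len(out.contigs) <= len(asm.contigs)
        before = {frozenset(c.clone_ids) for c in asm.contigs}
        after = {frozenset(c.clone_ids) for c in out.contigs}
        for comp in before:
            assert any(comp <= merged for merged in after)

    @pytest.mark.parametrize("seed", range(20))
    def test_disjoint_regions_never_merged(self, seed):
        from bacmap.simulate import (SimConfig, make_profiles, simulate_genome,
                                     simulate_library)
        cfg = SimConfig(genome_bp=1_500_000, n_probes=20)
        truth = simulate_genome(cfg, seed)
        simulate_library(truth, seed)
        profiles = make_profiles(truth, Method.AGAROSE, seed)
        params = ScoreParams(7, 5000, 1e-12)
        asm = assemble(profiles, params=params)
        out = end_merge(asm, profiles, params, floor=1e-6)
        metrics = evaluate(out, truth, profiles, params)
        assert metrics.precision == 1.0


class TestAdoptSingletons:
    def test_planted_clone_readopted(self, small_truth, score_params):
        _, profiles = small_truth
        asm = assemble(profiles, params=score_params)
        ctg = max(asm.contigs, key=lambda c: c.size)
        victim = ctg.clone_ids[len(ctg.clone_ids) // 2]
        hacked = Assembly(
            asm.stage,
            [c if c is not ctg else _without(c, victim, profiles, score_params)
             for c in asm.contigs],
            set(asm.singletons) | {victim},
            dict(asm.provenance),
        )
        out = adopt_singletons(hacked, profiles, score_params)
        assert victim not in out.singletons
        home = [c for c in out.contigs if victim in c.clone_ids]
        assert home and set(ctg.clone_ids) <= set(home[0].clone_ids)

    def test_low_band_singleton_never_adopted(self, score_params):
        profiles = {
            "c1": profile("c1", GRID[0:18]),
            "c2": profile("c2", GRID[4:22]),
            "tiny": profile("tiny", GRID[0:1]),
        }
        asm = assemble(profiles, params=score_params)
        out = adopt_singletons(asm, profiles, score_params)
        assert "tiny" in out.singletons

    def test_never_evicts(self, small_truth, score_params):
        _, profiles = small_truth
        asm = assemble(profiles, params=score_params)
        out = adopt_singletons(asm, profiles, score_params)
        for before in asm.contigs:
            assert any(set(before.clone_ids) <= set(after.clone_ids)
                       for after in out.contigs)


def _without(ctg, victim, profiles, params):
    from bacmap.assembly import Contig, _terminals, build_cb_map
    ids = [c for c in ctg.clone_ids if c != victim]
    offsets, cb_len, q = build_cb_map(ids, profiles, params)
    out = Contig(ctg.contig_id,
                 sorted(offsets.items(), key=lambda t: (t[1], t[0])), cb_len, q)
    out.terminal_clones = _terminals(out, profiles)
    return out


class TestBury:
    def test_identical_pair_buries_one(self, score_params):
        profiles = {"a": profile("a", GRID[:15]), "b": profile("b", GRID[:15])}
        asm = assemble(profiles, params=score_params)
        ctg = bury_clones(asm.contigs[0], profiles, 0.80, score_params)
        assert len(ctg.buried) == 1

    def test_ninety_percent_subclone_buried(self, score_params):
        from bacmap.assembly import Contig
        parent = profile("p", GRID[:20])
        child = profile("c", GRID[:9] + GRID[40:41])  # 9 of 10 shared
        profiles = {"p": parent, "c": child}
        ctg = Contig(1, [("p", 0), ("c", 0)], 21)
        ctg = bury_clones(ctg, profiles, 0.80, score_params)
        assert ctg.buried == {"c": "p"}

    def test_buried_excluded_from_terminals(self, score_params):
        profiles = {"a": profile("a", GRID[:15]), "b": profile("b", GRID[:15]),
                    "c": profile("c", GRID[3:21])}
        asm = assemble(profiles, params=score_params)
        ctg = bury_clones(asm.contigs[0], profiles, 0.80, score_params)
        child = next(iter(ctg.buried))
        assert child not in ctg.terminal_clones[0]
        assert child not in ctg.terminal_clones[1]

    def test_burial_graph_acyclic(self, score_params):
        rng = np.random.default_rng(11)
        for _ in range(20):
            pool = sorted(rng.choice(np.arange(100, 4000, 25), size=30,
                                     replace=False).tolist())
            profiles = {}
            for i in range(6):
                k = int(rng.integers(10, 25))
                start = int(rng.integers(0, 30 - k))
                profiles[f"c{i}"] = profile(f"c{i}", pool[start:start + k])
            ctg_ids = sorted(profiles)
            from bacmap.assembly import Contig
            ctg = Contig(1, [(c, 0) for c in ctg_ids], 30)
            bury_clones(ctg, profiles, 0.80, score_params)
            # parents are never buried themselves => acyclic by construction
            assert not (set(ctg.buried) & set(ctg.buried.values()))


class TestCrossWell:
    def test_adjacent_copy_flagged(self, score_params):
        bands = GRID[:17]
        profiles = {
            "a": profile("a", bands, plate=0, well_row=0, well_col=0),
            "b": profile("b", bands, plate=0, well_row=0, well_col=1),
        }
        assert detect_cross_well(profiles, 0.90, score_params) == {"a", "b"}

    def test_distant_identical_not_flagged(self, score_params):
        bands = GRID[:17]
        profiles = {
            "a": profile("a", bands, plate=0, well_row=0, well_col=0),
            "b": profile("b", bands, plate=0, well_row=5, well_col=9),
        }
        assert detect_cross_well(profiles, 0.90, score_params) == set()

    def test_no_adjacent_pairs(self, score_params):
        profiles = {
            "a": profile("a", GRID[:10], plate=0, well_col=0),
            "b": profile("b", GRID[20:30], plate=1, well_col=1),
        }
        assert detect_cross_well(profiles, 0.90, score_params) == set()

    def test_simulated_contamination_detected(self):
        from bacmap.simulate import (SimConfig, make_profiles, simulate_genome,
                                     simulate_library)
        cfg = SimConfig(genome_bp=2_000_000, crosswell_rate=0.02, n_probes=20)
        truth = simulate_genome(cfg, 3)
        simulate_library(truth, 3)
        profiles = make_profiles(truth, Method.AGAROSE, 3)
        planted = {c.clone_id for c in truth.clones
                   if c.crosswell_copy_of is not None
                   and profiles[c.clone_id].n >= 2
                   and profiles[c.crosswell_copy_of].n >= 2}
        assert planted, "simulation should plant contaminations at 2%"
        flagged = detect_cross_well(profiles, 0.90, ScoreParams(8, 5000, 1e-10))
        assert planted <= flagged


class TestBandOutliers:
    def test_uniform_counts_empty(self):
        profiles = {f"c{i}": profile(f"c{i}", GRID[:15]) for i in range(40)}
        assert detect_band_outliers(profiles) == set()

    def test_planted_chimera_flagged(self):
        rng = np.random.default_rng(2)
        profiles = {}
        for i in range(60):
            n = int(rng.integers(15, 20))
            vals = sorted(rng.choice(np.arange(100, 5000, 25), size=n,
                                     replace=False).tolist())
            profiles[f"c{i}"] = profile(f"c{i}", vals)
        vals = sorted(rng.choice(np.arange(100, 5000, 25), size=36,
                                 replace=False).tolist())
        profiles["chimera"] = profile("chimera", vals)
        assert "chimera" in detect_band_outliers(profiles)

    def test_nearest_rank_boundaries(self):
        # counts 1..20 in one batch: nearest-rank P5 = 1, P95 = 19; only the
        # count-20 clone is strictly above
        profiles = {
            f"c{i}": profile(f"c{i}", GRID[:i + 1]) for i in range(20)
        }
        assert detect_band_outliers(profiles, 5, 5) == {"c19"}


class TestTerminalSelection:
    def test_four_per_contig(self, score_params):
        pool = [100 + 25 * k for k in range(60)]
        profiles = {
            f"c{i}": profile(f"c{i}", pool[4 * i:4 * i + 18]) for i in range(10)
        }
        asm = assemble(profiles, params=score_params)
        assert len(asm.contigs) == 1
        sel = select_terminal_clones(asm, profiles, 1, per_end=2)
        assert len(sel) == 4

    def test_two_clone_contig_deduplicates(self, score_params):
        profiles = {"a": profile("a", GRID[:18]), "b": profile("b", GRID[2:20])}
        asm = assemble(profiles, params=score_params)
        sel = select_terminal_clones(asm, profiles, 1, per_end=2)
        assert sel == {"a", "b"}

    def test_bounded_by_four_k(self, small_truth, score_params):
        _, profiles = small_truth
        asm = assemble(profiles, params=score_params)
        for k in (1, 3, 10):
            sel = select_terminal_clones(asm, profiles, k, per_end=2)
            assert len(sel) <= 4 * k


class TestHicfPseudomarkers:
    def test_one_marker_per_contig(self, score_params):
        pool = [100 + 25 * k for k in range(26)]
        profiles = {}
        for blk, off in (("a", 0), ("b", 1500), ("c", 3000)):
            shifted = [v + off for v in pool]
            profiles[f"{blk}1"] = profile(f"{blk}1", shifted[0:18])
            profiles[f"{blk}2"] = profile(f"{blk}2", shifted[4:22])
        profiles["solo"] = profile("solo", [4500 + 25 * k for k in range(18)])
        asm = assemble(profiles, params=score_params)
        markers = hicf_pseudomarkers(asm)
        assert len(markers) == 3
        assert all(m.kind is MarkerKind.HICF_CONTIG for m in markers)
        covered = set().union(*(m.clones for m in markers))
        assert covered == {cid for c in asm.contigs for cid in c.clone_ids}
        assert "solo" not in covered


class TestIntegratedPipeline:
    def test_fig1c_merged_in_stage3_not_stage1(self, fig1c):
        profiles, hicf = fig1c
        cfg = PipelineConfig(terminal_fraction=1.0, qc_enabled=False)
        result = run_integrated_pipeline(profiles, [], cfg, hicf)
        prelim = result.stages["prelim"]
        of1 = prelim.contig_of()
        assert len(prelim.contigs) == 2
        assert of1["A2"] != of1["B1"]
        integrated = result.stages["integrated"]
        of3 = integrated.contig_of()
        assert of3["A2"] == of3["B1"]
        assert len(result.final.contigs) == 1

    def test_fig1c_not_merged_by_agarose_only_assembly(self, two_contig_bridge):
        asm = assemble(two_contig_bridge, params=ScoreParams(7, 5000, 1e-12))
        of = asm.contig_of()
        assert len(asm.contigs) == 2
        assert of["A2"] != of["B1"]

    def test_fig1c_hicf_contig_is_the_bridge(self, fig1c):
        _, hicf = fig1c
        hicf_asm = assemble(hicf, params=ScoreParams(3, 10_000, 1e-50),
                            stage=Stage.HICF_ONLY)
        assert len(hicf_asm.contigs) == 1
        assert set(hicf_asm.contigs[0].clone_ids) == {"A2", "B1"}

    def test_empty_hicf_degenerates_to_marker_relaxed_assembly(
            self, two_contig_bridge):
        cfg = PipelineConfig(qc_enabled=False)
        result = run_integrated_pipeline(two_contig_bridge, [], cfg, None)
        assert "hicf" not in result.stages
        direct = assemble(two_contig_bridge, [],
                          ScoreParams(cfg.integrated_tolerance, cfg.gel_length,
                                      cfg.integrated_cutoff),
                          relax_floor=cfg.integrated_cutoff * 1e4)
        got = {frozenset(c.clone_ids) for c in result.stages["integrated"].contigs}
        want = {frozenset(c.clone_ids) for c in direct.contigs}
        assert got == want

    def test_partition_after_every_stage(self, fig1c):
        profiles, hicf = fig1c
        cfg = PipelineConfig(terminal_fraction=1.0, qc_enabled=False)
        result = run_integrated_pipeline(profiles, [], cfg, hicf)
        for name in ("prelim", "integrated", "dq", "end_merge", "adopted",
                     "final"):
            result.stages[name].validate_partition(profiles)

    def test_deterministic(self, fig1c):
        profiles, hicf = fig1c
        cfg = PipelineConfig(terminal_fraction=1.0, qc_enabled=False)
        r1 = run_integrated_pipeline(profiles, [], cfg, hicf)
        r2 = run_integrated_pipeline(profiles, [], cfg, hicf)
        assert [c.members for c in r1.final.contigs] == \
            [c.members for c in r2.final.contigs]

    def test_missing_stage_parameters_rejected(self):
        from bacmap.config import ConfigError
        with pytest.raises(ConfigError):
            PipelineConfig.from_dict({"no_such_parameter": 1})
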