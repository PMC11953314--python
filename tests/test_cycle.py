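import numpy as np
import pytest

from cinsim.cycle import (Cell, CycleParams, g1_generate_dsbs, g1_repair,
                          m_segregate, run_cell_cycle, s_g2_replicate)
from cinsim.graph import GenomeGraph
from cinsim.reference import ReferenceDescriptor

from conftest import per_base_cn


def fresh_cell(ref) -> Cell:
    return Cell(genome=GenomeGraph.diploid(ref))


class TestG1Dsbs:
    def test_no_dsbs_past_nd(self, toy_ref, rng):
        cell = fresh_cell(toy_ref)
        cell.divisions = 1
        n = g1_generate_dsbs(cell, CycleParams(dsb_count=5, n_d=0), rng)
        assert n == 0
        assert not cell.genome.unrepaired_ends()

    def test_biased_chromosome_gets_two_thirds(self, rng):
        # empirical check of p = 2/3 on the focal chromosome
        ref = ReferenceDescriptor.synthetic(n_chromosomes=4, length=50_000,
                                            telomere_length=500)
        hits = focal = 0
        for _ in range(300):
            cell = fresh_cell(ref)
            g1_generate_dsbs(cell, CycleParams(dsb_count=5, bias_chrom="2"),
                             rng)
            for nid in cell.genome.unrepaired_ends():
                node = cell.genome.nodes[nid]
                if node.orient == "+":  # one end per break
                    hits += 1
                    focal += node.chrom == "2"
        assert hits == 1500
        p_hat = focal / hits
        se = np.sqrt((2 / 3) * (1 / 3) / hits)
        assert abs(p_hat - 2 / 3) < 4 * se

    def test_poisson_mode_has_requested_mean(self, toy_ref, rng):
        params = CycleParams(dsb_rate=3.0)
        counts = []
        for _ in range(2000):
            cell = fresh_cell(toy_ref)
            counts.append(g1_generate_dsbs(cell, params, rng))
        se = np.sqrt(3.0 / len(counts))
        assert abs(np.mean(counts) - 3.0) < 3 * se

    def test_positions_avoid_excluded_regions_and_repeats(self, toy_ref, rng):
        cell = fresh_cell(toy_ref)
        g1_generate_dsbs(cell, CycleParams(dsb_count=40), rng)
        coords = []
        for nid in cell.genome.unrepaired_ends():
            n = cell.genome.nodes[nid]
            if n.orient == "+":
                assert not toy_ref.is_excluded(n.chrom, n.coord)
                coords.append((n.chrom, n.hap, n.coord))
        assert len(coords) == len(set(coords))  # infinite sites

    def test_catalog_sampling_without_replacement(self, toy_ref, rng):
        from cinsim.cycle import BreakpointCatalog, CycleError
        cat = BreakpointCatalog(chroms=["1", "1", "2"],
                                positions=[2000, 3000, 2500],
                                weights=[5.0, 1.0, 1.0])
        cell = fresh_cell(toy_ref)
        params = CycleParams(dsb_count=3, dsb_source="catalog", catalog=cat)
        g1_generate_dsbs(cell, params, rng)
        assert {c for c, _ in cell.used_positions} <= {"1", "2"}
        assert len(cell.used_positions) == 3
        with pytest.raises(CycleError):
            g1_generate_dsbs(cell, params, rng)  # exhausted


class TestG1Repair:
    def test_fu_one_leaves_all_ends_broken(self, toy_ref, rng):
        cell = fresh_cell(toy_ref)
        g1_generate_dsbs(cell, CycleParams(dsb_count=3), rng)
        joined = g1_repair(cell, CycleParams(f_u=1.0), rng)
        assert joined == 0
        assert len(cell.genome.unrepaired_ends()) == 6

    def test_single_dsb_rejoins_faithfully_with_certainty(self, toy_ref, rng):
        # only the faithful partner exists, so any p_r > 0 rejoins it
        cell = fresh_cell(toy_ref)
        g1_generate_dsbs(cell, CycleParams(dsb_count=1), rng)
        g1_repair(cell, CycleParams(f_u=0.0, p_r=1.0), rng)
        assert not cell.genome.unrepaired_ends()
        assert not cell.genome.variant_adjacencies()
        assert len(cell.genome.walk_paths()) == 4

    def test_odd_end_count_leaves_one_unrepaired(self, toy_ref, rng):
        # 3 DSBs (6 ends) + one end discarded with its fragment -> 5
        # eligible ends; full repair pairs 2x2 and must leave exactly one
        cell = fresh_cell(toy_ref)
        g1_generate_dsbs(cell, CycleParams(dsb_count=3), rng)
        frag_path = min((p for p in cell.genome.walk_paths()
                         if p.n_telomeres == 1), key=lambda p: p.length)
        kept = [iv for iv in cell.genome.intervals
                if iv not in frag_path.interval_ids]
        cell.genome = cell.genome.extract(kept)
        assert len(cell.genome.unrepaired_ends()) == 5
        g1_repair(cell, CycleParams(f_u=0.0, p_r=1.0), rng)
        assert len(cell.genome.unrepaired_ends()) == 1

    def test_cross_chromosome_pairing_frequencies(self, toy_ref):
        # two DSBs on different chromosomes, p_r = 0: the faithful partner
        # has weight 0, so both joins are inter-chromosomal and the two
        # matchings {h1-h2, t1-t2} / {h1-t2, t1-h2} are equally likely
        # (exact enumeration of the sequential weighted draw)
        rng = np.random.default_rng(777)
        counts = {"same_orient": 0, "cross_orient": 0}
        trials = 600
        for _ in range(trials):
            cell = fresh_cell(toy_ref)
            h1, t1, *_ = cell.genome.dsb_at("1", "A", 2000)
            h2, t2, *_ = cell.genome.dsb_at("2", "A", 3000)
            g1_repair(cell, CycleParams(f_u=0.0, p_r=0.0), rng)
            adj = cell.genome.variant_adjacencies()
            assert len(adj) == 2
            assert all(a.chrom != b.chrom for a, b in adj)
            orients = sorted((a.orient, b.orient) for a, b in adj)
            if orients == [("+", "+"), ("-", "-")]:
                counts["same_orient"] += 1
            else:
                counts["cross_orient"] += 1
        p_hat = counts["same_orient"] / trials
        se = np.sqrt(0.25 / trials)
        assert abs(p_hat - 0.5) < 4 * se

    def test_distance_mode_matches_enumerated_weights(self, toy_ref):
        # three DSBs at 2000, 2100 and 8000 on one homologue; one pair is
        # formed; the probability that it is a "near" join (span <= 101 bp)
        # is enumerated exactly from the reciprocal-distance weights and
        # compared with the empirical frequency
        coords = {"h1": 2000, "t1": 2001, "h2": 2100, "t2": 2101,
                  "h3": 8000, "t3": 8001}
        mates = {"h1": "t1", "t1": "h1", "h2": "t2", "t2": "h2",
                 "h3": "t3", "t3": "h3"}

        def weight(a, b):
            return 0.0 if mates[a] == b else 1.0 / abs(coords[a] - coords[b])

        names = list(coords)
        p_near = 0.0
        for b1 in names:
            ws = {b2: weight(b1, b2) for b2 in names if b2 != b1}
            tot = sum(ws.values())
            near_w = sum(w for b2, w in ws.items()
                         if abs(coords[b1] - coords[b2]) <= 101)
            p_near += (near_w / tot) / len(names)

        rng = np.random.default_rng(99)
        near = 0
        trials = 500
        for _ in range(trials):
            cell = fresh_cell(toy_ref)
            cell.genome.dsb_at("1", "A", 2000)
            cell.genome.dsb_at("1", "A", 2100)
            cell.genome.dsb_at("1", "A", 8000)
            g1_repair(cell, CycleParams(f_u=2.0 / 3.0, p_r=0.0), rng)
            adj = cell.genome.variant_adjacencies()
            assert len(adj) == 1
            a, b = adj[0]
            near += abs(a.coord - b.coord) <= 101
        p_hat = near / trials
        se = np.sqrt(p_near * (1 - p_near) / trials)
        assert abs(p_hat - p_near) < 4 * se


class TestReplication:
    def test_pristine_genome_doubles_without_new_junctions(self, toy_ref, rng):
        cell = fresh_cell(toy_ref)
        content = cell.genome.total_content()
        s_g2_replicate(cell)
        assert cell.genome.total_content() == 2 * content
        assert not cell.genome.variant_adjacencies()
        assert len(cell.genome.walk_paths()) == 8

    def test_sister_fusion_builds_dicentric_foldback(self, toy_ref, rng):
        cell = fresh_cell(toy_ref)
        cell.genome.dsb_at("1", "A", 7000)
        s_g2_replicate(cell)
        dicentrics = [p for p in cell.genome.walk_paths()
                      if p.n_centromeres == 2]
        assert len(dicentrics) == 1
        foldbacks = [a for a, b in cell.genome.variant_adjacencies()
                     if a.sv_type in ("H2HINV", "T2TINV")]
        assert foldbacks

    def test_acentric_telomere_free_fragment_becomes_ecdna(self, toy_ref, rng):
        cell = fresh_cell(toy_ref)
        h1, t1, *_ = cell.genome.dsb_at("1", "A", 1000)
        h2, t2, *_ = cell.genome.dsb_at("1", "A", 3000)
        cell.genome.join(h1, t2)   # excise acentric fragment
        s_g2_replicate(cell)
        ecdna = [p for p in cell.genome.walk_paths() if p.is_ecdna()]
        assert len(ecdna) == 1     # fragment + sister closed into one circle
        assert ecdna[0].length == 2 * 2000


class TestSegregation:
    def test_all_monocentric_daughters_equal_parent(self, toy_ref, rng):
        cell = fresh_cell(toy_ref)
        parent_cn = per_base_cn(cell.genome)
        daughters, log = run_cell_cycle(cell, CycleParams(), rng)
        assert len(daughters) == 2
        for d in daughters:
            cn = per_base_cn(d.genome)
            for key in parent_cn:
                assert np.array_equal(cn[key], parent_cn[key])

    def test_daughters_partition_replicated_content(self, toy_ref, rng):
        cell = fresh_cell(toy_ref)
        g1_generate_dsbs(cell, CycleParams(dsb_count=4), rng)
        g1_repair(cell, CycleParams(f_u=0.5, p_r=0.0), rng)
        pre = per_base_cn(cell.genome)
        rep = s_g2_replicate(cell)
        ga, gb = m_segregate(cell, CycleParams(), rng, rep)
        cn_a, cn_b = per_base_cn(ga), per_base_cn(gb)
        for key in pre:
            assert np.array_equal(cn_a[key] + cn_b[key], 2 * pre[key])

    def test_dicentric_bridge_splits_to_both_daughters(self, toy_ref, rng):
        cell = fresh_cell(toy_ref)
        cell.genome.dsb_at("1", "A", 7000)    # lost right telomere
        rep = s_g2_replicate(cell)
        ga, gb = m_segregate(cell, CycleParams(), rng, rep)
        for g in (ga, gb):
            for p in g.walk_paths():
                assert p.n_centromeres <= 1   # post-M monocentricity

    def test_wgd_doubles_surviving_daughter(self, toy_ref, rng):
        cell = fresh_cell(toy_ref)
        daughters, log = run_cell_cycle(cell, CycleParams(p_w=1.0), rng)
        assert log.wgd and len(daughters) == 1
        assert daughters[0].wgd
        for seg in daughters[0].genome.copy_number_profile().segments:
            assert seg.cn == 2

    def test_at_most_one_wgd_per_lineage(self, toy_ref, rng):
        cell = fresh_cell(toy_ref)
        daughters, _ = run_cell_cycle(cell, CycleParams(p_w=1.0), rng)
        granddaughters, log2 = run_cell_cycle(daughters[0],
                                              CycleParams(p_w=1.0), rng)
        assert not log2.wgd
        assert len(granddaughters) == 2

    def test_fragmentation_gate_half_of_positive_draws(self, toy_ref):
        # the 0.5 gate: with m_l large the Poisson draw is almost surely
        # positive, so fragmentation fires in about half the divisions
        rng = np.random.default_rng(5)
        fired = 0
        trials = 400
        for _ in range(trials):
            cell = fresh_cell(toy_ref)
            cell.genome.dsb_at("1", "A", 7000)
            rep = s_g2_replicate(cell)
            from cinsim.cycle import CycleLog
            log = CycleLog()
            m_segregate(cell, CycleParams(m_l=8.0), rng, rep, log)
            fired += log.bridge_fragmentations
        # the dicentric bridge yields two monocentric derivatives per
        # division, each gated independently
        p_hat = fired / (2 * trials)
        se = np.sqrt(0.25 / (2 * trials))
        assert abs(p_hat - 0.5) < 4 * se

    def test_acentric_chromosome_reciprocal_gain_loss(self, toy_ref):
        # an N_c = 0 derivative is distributed copy by copy: across many
        # trials one daughter sometimes receives both copies
        rng = np.random.default_rng(11)
        both_to_one = 0
        for _ in range(60):
            cell = fresh_cell(toy_ref)
            h, t, *_ = cell.genome.dsb_at("1", "A", 7000)
            # separate the acentric piece and discard bookkeeping of bridge
            rep = s_g2_replicate(cell)
            ga, gb = m_segregate(cell, CycleParams(), rng, rep)
            for g in (ga, gb):
                cn = per_base_cn(g)[("1", "A")]
                if cn[-600] == 2:   # both sister copies of the q-arm piece
                    both_to_one += 1
        assert both_to_one > 0


class TestRepairFidelityLimit:
    def test_perfect_repair_returns_to_reference_every_cycle(self, toy_ref,
                                                             rng):
        # f_u = 0, p_r = 1, one DSB per cycle: the genome re-reaches the
        # pristine state in every generation
        cell = fresh_cell(toy_ref)
        params = CycleParams(dsb_count=1, f_u=0.0, p_r=1.0, n_d=None)
        for _ in range(4):
            daughters, log = run_cell_cycle(cell, params, rng)
            assert log.misrepaired == 0
            cell = daughters[0]
            cn = per_base_cn(cell.genome)
            assert all((v == 1).all() for v in cn.values())
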