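import numpy as np
import pytest

from cinsim.cycle import Cell, CycleParams, run_cell_cycle
from cinsim.graph import CNSegment, GenomeGraph
from cinsim.sumstats import (SVCall, _has_oscillation, _interleaved,
                             compute_summary_stats, count_fusions,
                             detect_chromothripsis, ecdna_count,
                             extract_sv_calls, summarize_ecdna)

from conftest import per_base_cn


def _cell(ref, cid=0) -> Cell:
    return Cell(genome=GenomeGraph.diploid(ref), id=cid)


def _excise_circle(g, chrom, hap, lo, hi):
    """Cut [lo+1, hi] out of a homologue and close it into a circle."""
    h1, _, *_ = g.dsb_at(chrom, hap, lo)
    _, t2, *_ = g.dsb_at(chrom, hap, hi)
    g.join(h1, t2)
    frag = [p for p in g.walk_paths()
            if p.n_telomeres == 0 and not p.circular][0]
    iv = g.intervals[frag.intervals[0][0]]
    g.join(iv.left, iv.right)


class TestSummarizeEcdna:
    def test_no_circles_means_empty(self, toy_ref):
        assert summarize_ecdna(_cell(toy_ref)) == (0, [], [])

    def test_multiset_grouping_of_identical_circles(self, toy_ref):
        cell = _cell(toy_ref)
        _excise_circle(cell.genome, "1", "A", 1000, 3000)
        _excise_circle(cell.genome, "2", "A", 2000, 2500)
        cell.genome.clone_into_self()   # two identical copies of each
        n_types, copies, sizes = summarize_ecdna(cell)
        assert n_types == 2
        assert sorted(copies) == [2, 2]
        assert sorted(sizes) == [500, 2000]

    def test_agrees_with_path_classification(self, toy_ref, rng):
        # after a fragmentation-heavy division, the ecDNA total equals the
        # number of paths passing the circular/acentric/atelomeric test
        cell = _cell(toy_ref)
        params = CycleParams(dsb_count=2, f_u=1.0, m_l=6.0, n_d=0)
        daughters, _ = run_cell_cycle(cell, params, rng)
        for d in daughters:
            n_types, copies, _ = summarize_ecdna(d)
            assert sum(copies) == ecdna_count(d)
            assert n_types <= sum(copies)


class TestCountFusions:
    def test_faithful_repair_only_counts_zero(self, toy_ref, rng):
        cell = _cell(toy_ref)
        params = CycleParams(dsb_count=1, f_u=0.0, p_r=1.0)
        daughters, log = run_cell_cycle(cell, params, rng)
        assert log.fusions == 0
        assert count_fusions(daughters) == 0

    def test_single_sister_fusion_counts_one(self, toy_ref, rng):
        cell = _cell(toy_ref)
        cell.genome.dsb_at("1", "A", 7000)
        from cinsim.cycle import CycleLog, s_g2_replicate
        log = CycleLog()
        s_g2_replicate(cell, log)
        # one DSB -> two telomere-deficient pieces -> two sister fusions,
        # each merging a path with its copy
        assert log.fusions == 2
        assert log.sister_fusions == 2

    def test_chain_of_three_chromosomes_counts_two(self, toy_ref):
        # joining 3 derivatives with 2 junctions reduces the path count by
        # 2: the fusion count equals the path-count difference
        ref3 = type(toy_ref).synthetic(n_chromosomes=3, length=10_000,
                                       telomere_length=500)
        cell = _cell(ref3)
        g = cell.genome
        h1, _, *_ = g.dsb_at("1", "A", 7000)
        h2, t2, *_ = g.dsb_at("2", "A", 7000)
        h3, t3, *_ = g.dsb_at("3", "A", 7000)
        n_broken = len(g.walk_paths())
        # join chr1-head to chr2-tail, chr2-head to chr3-tail
        g.join(h1, t2)
        g.join(h2, t3)
        assert n_broken - len(g.walk_paths()) == 2


class TestChromothripsis:
    def _sv(self, lo, hi, cid=0):
        return SVCall(cell_id=cid, chrom1="1", pos1=lo, orient1="+",
                      hap1="A", chrom2="1", pos2=hi, orient2="-", hap2="A",
                      sv_type="DEL-like")

    def test_pristine_chromosome_negative(self):
        assert not detect_chromothripsis([], [], "1")

    def test_oscillating_profile_with_interleaved_svs_positive(self):
        # six mutually interleaved SVs (staircase) + CN 2,1,2,1,2,1,2
        svs = [self._sv(100 + 50 * i, 400 + 50 * i) for i in range(6)]
        segs = [CNSegment("1", "A", 100 * i + 1, 100 * (i + 1), 2 - i % 2)
                for i in range(7)]
        assert detect_chromothripsis(svs, segs, "1")

    def test_nested_svs_are_not_interleaved(self):
        # perfectly nested spans: oscillation alone is not enough
        svs = [self._sv(100 + 10 * i, 900 - 10 * i) for i in range(6)]
        segs = [CNSegment("1", "A", 100 * i + 1, 100 * (i + 1), 2 - i % 2)
                for i in range(7)]
        assert not detect_chromothripsis(svs, segs, "1")

    def test_interleave_predicate(self):
        assert _interleaved((100, 400), (200, 500))
        assert not _interleaved((100, 500), (200, 300))   # containment
        assert not _interleaved((100, 200), (300, 400))   # disjoint

    def test_oscillation_needs_exactly_two_states(self):
        assert _has_oscillation([2, 1, 2, 1, 2, 1, 2], 7)
        assert _has_oscillation([3, 5, 3, 5, 3, 5, 3], 7)  # any two states
        assert not _has_oscillation([2, 1, 3, 1, 2, 1, 2], 7)
        assert not _has_oscillation([2, 1, 2, 1, 2, 1], 7)


class TestSummaryStats:
    def test_all_normal_population(self, toy_ref):
        cells = [_cell(toy_ref, cid=i) for i in range(5)]
        st = compute_summary_stats(cells, toy_ref, bin_size=1000)
        assert st.wgd_fraction == 0.0
        assert st.pga == 0.0
        assert st.divergence_mean == 0.0
        assert sum(st.breakpoint_spectrum) == 0.0
        assert set(st.sv_fractions.values()) == {0.0}

    def test_single_cell_divergence_flagged(self, toy_ref):
        st = compute_summary_stats([_cell(toy_ref)], toy_ref, bin_size=1000)
        assert st.single_cell and st.divergence_mean == 0.0

    def test_one_aberrant_cell_pga_and_spectrum(self, toy_ref):
        # one of 10 cells deletes (6000, 8000] on 1A via a DEL-like join:
        # PGA and divergence recomputed from the per-base oracle
        cells = [_cell(toy_ref, cid=i) for i in range(10)]
        g = cells[0].genome
        h1, _, *_ = g.dsb_at("1", "A", 6000)
        _, t2, *_ = g.dsb_at("1", "A", 8000)
        g.join(h1, t2)
        frag = [p for p in g.walk_paths() if p.n_telomeres == 0][0]
        cells[0].genome = g.extract(
            [iv for iv in g.intervals if iv not in frag.interval_ids])

        B = 1000
        st = compute_summary_stats(cells, toy_ref, bin_size=B)
        base = per_base_cn(cells[0].genome)
        lost_bins = 0
        total_bins = 0
        for spec in toy_ref:
            n_bins = spec.length // B
            total_bins += n_bins
            for b in range(n_bins):
                chunk = (base[(spec.name, "A")][b * B:(b + 1) * B]
                         + base[(spec.name, "B")][b * B:(b + 1) * B])
                if not np.all(chunk.sum() / B == 2.0):
                    lost_bins += 1
        assert st.pga == pytest.approx(lost_bins / total_bins)
        # both breakpoints private to one cell: all spectrum mass at k=1
        assert st.breakpoint_spectrum[0] == 1.0
        assert sum(st.breakpoint_spectrum) == 1.0

    def test_clonal_sv_concentrates_spectrum_at_k_n(self, toy_ref):
        cells = []
        for i in range(6):
            c = _cell(toy_ref, cid=i)
            h1, _, *_ = c.genome.dsb_at("1", "A", 2000)
            _, t2, *_ = c.genome.dsb_at("1", "A", 4000)
            c.genome.join(h1, t2)
            cells.append(c)
        st = compute_summary_stats(cells, toy_ref, bin_size=1000)
        assert st.breakpoint_spectrum[-1] == 1.0

    def test_spectrum_invariant_to_cell_order(self, toy_ref, rng):
        cells = []
        for i in range(4):
            c = _cell(toy_ref, cid=i)
            if i % 2:
                h1, _, *_ = c.genome.dsb_at("1", "A", 2000 + 100 * i)
                _, t2, *_ = c.genome.dsb_at("1", "A", 4000)
                c.genome.join(h1, t2)
            cells.append(c)
        a = compute_summary_stats(cells, toy_ref, bin_size=1000)
        b = compute_summary_stats(cells[::-1], toy_ref, bin_size=1000)
        assert a.breakpoint_spectrum == b.breakpoint_spectrum
        assert a.pga == b.pga

    def test_bounds_and_monotonicity(self, toy_ref, rng):
        cells = []
        for i in range(6):
            cell = _cell(toy_ref, cid=i)
            daughters, _ = run_cell_cycle(
                cell, CycleParams(dsb_count=2, f_u=0.5, p_r=0.0), rng)
            d = daughters[0]
            d.id = i
            cells.append(d)
        pga_prev = 0.0
        for k in range(1, len(cells) + 1):
            st = compute_summary_stats(cells[:k], toy_ref, bin_size=1000)
            assert 0.0 <= st.pga <= 1.0
            assert 0.0 <= st.divergence_mean <= 1.0
            assert st.pga >= pga_prev      # PGA grows as cells are added
            pga_prev = st.pga
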