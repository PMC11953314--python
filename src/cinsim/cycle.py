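"""One cell cycle: G1 breakage and repair, S/G2 replication, M segregation.

The mechanics follow the interphase/mitosis split of non-homologous
end-joining-driven genome instability:

* **G1** — ``n`` double-strand breaks (fixed count or Poisson with mean
  ``r``) land on chromosomes drawn from a probability vector ``p_c``
  (uniform by default; a focal chromosome may be biased to 2/3), at
  positions uniform over the cell's current genomic material, excluding
  telomeres and centromeres, under an infinite-sites assumption scoped to
  the cell lineage.  A fraction ``1 - f_u`` of the free ends is then
  repaired, either by uniform random pairing or (default) by sampling the
  partner with probability proportional to the reciprocal genomic distance,
  with cross-chromosome distance fixed at 1e9 bp and the same-break partner
  given weight ``p_r``.  Faithful rejoins restore reference adjacencies and
  leave no SV.
* **S/G2** — the genome replicates exactly.  A linear derivative missing a
  telomere is joined to its sister copy at each broken end (fold-back
  head-to-head/tail-to-tail junctions); a derivative missing both telomeres
  thereby circularises, and if it also lacks a centromere it is an ecDNA.
* **M** — replicated derivatives segregate by centromere count ``N_c``:
  monocentric sister pairs split one-per-daughter; acentric material
  (including ecDNA) goes to a uniformly random daughter copy by copy;
  multicentric bridges are broken once between each adjacent centromere
  pair ("simple break"), optionally followed by local fragmentation
  (Poisson(``m_l``) extra breaks per monocentric derivative, applied with
  probability 0.5 when the draw is positive), the pieces scattering
  randomly.  With probability ``p_w`` (at most once per lineage) the cell
  instead undergoes whole-genome doubling: all content passes to one
  daughter, the other dies.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .graph import (VAR_JUNCTION, DerivativePath, GenomeGraph, GraphError,
                    HEAD)
from .reference import ReferenceDescriptor

INTER_CHROM_DISTANCE = 1.0e9  # repair-weight distance across chromosomes


class CycleError(RuntimeError):
    pass


@dataclass
class BreakpointCatalog:
    """Observed breakpoint positions to sample DSB sites from.

    Sampling is without replacement (enforced through the lineage's
    used-position set) and weighted by ``weights`` (e.g. clonal
    prevalence).
    """

    chroms: Sequence[str]
    positions: Sequence[int]
    weights: Sequence[float]

    def __post_init__(self) -> None:
        if not (len(self.chroms) == len(self.positions) == len(self.weights)):
            raise ValueError("catalog columns must have equal length")
        if any(w <= 0 for w in self.weights):
            raise ValueError("catalog weights must be positive")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class CycleParams:
    """All knobs of one cell cycle.

    ``dsb_count`` fixes the per-cycle DSB number; otherwise a Poisson draw
    with mean ``dsb_rate`` is used.  ``n_d`` is the last division index at
    which interphase DSBs still occur (0 = first division only; ``None`` =
    every cycle).
    """

    dsb_count: Optional[int] = None
    dsb_rate: float = 0.0
    bias_chrom: Optional[str] = None
    chrom_probs: Optional[dict[str, float]] = None
    f_u: float = 0.0
    p_r: float = 0.0
    repair_mode: str = "distance"  # 'distance' | 'uniform'
    repair_scope: str = "all"      # 'all' | 'new'
    m_l: float = 0.0
    p_w: float = 0.0
    n_d: Optional[int] = 0
    dsb_source: str = "random"     # 'random' | 'catalog'
    catalog: Optional[BreakpointCatalog] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_u <= 1.0):
            raise ValueError("f_u must be in [0, 1]")
        if not (0.0 <= self.p_r <= 1.0):
            raise ValueError("p_r must be in [0, 1]")
        if not (0.0 <= self.p_w <= 1.0):
            raise ValueError("p_w must be in [0, 1]")
        if self.m_l < 0:
            raise ValueError("m_l must be >= 0")
        if self.repair_mode not in ("distance", "uniform"):
            raise ValueError(f"unknown repair mode {self.repair_mode!r}")
        if self.repair_scope not in ("all", "new"):
            raise ValueError(f"unknown repair scope {self.repair_scope!r}")
        if self.dsb_source == "catalog" and self.catalog is None:
            raise ValueError("catalog source requires a catalog")


@dataclass
class CycleLog:
    """Per-cycle event counts."""

    dsbs: int = 0
    misrepaired: int = 0
    unrepaired_after_g1: int = 0
    fusions: int = 0
    sister_fusions: int = 0
    ecdna_pre_m: int = 0
    bridge_simple_breaks: int = 0
    bridge_fragmentations: int = 0
    wgd: bool = False


@dataclass
class Cell:
    """One cell: genome plus lineage state.

    ``used_positions`` realises the infinite-sites assumption per lineage:
    daughters inherit the set, so no position is broken twice along any
    line of descent.  ``rates`` is filled in by the population layer.
    """

    genome: GenomeGraph
    id: int = -1
    divisions: int = 0
    wgd: bool = False
    used_positions: set[tuple[str, int]] = field(default_factory=set)
    rates: object = None
    logs: list[CycleLog] = field(default_factory=list)
    new_ends: set[int] = field(default_factory=set)


# ---------------------------------------------------------------------------
# G1: break generation


def _chrom_probabilities(params: CycleParams,
                         ref: ReferenceDescriptor) -> dict[str, float]:
    if params.chrom_probs is not None:
        total = sum(params.chrom_probs.values())
        return {c: p / total for c, p in params.chrom_probs.items()}
    names = ref.names
    if params.bias_chrom is not None:
        if params.bias_chrom not in ref:
            raise ValueError(f"bias chromosome {params.bias_chrom!r} not in reference")
        others = [c for c in names if c != params.bias_chrom]
        p_other = (1.0 / 3.0) / len(others) if others else 0.0
        probs = {c: p_other for c in others}
        probs[params.bias_chrom] = 2.0 / 3.0 if others else 1.0
        return probs
    return {c: 1.0 / len(names) for c in names}


def _place_random_dsb(cell: Cell, probs: dict[str, float],
                      rng: np.random.Generator) -> tuple[int, int]:
    """Choose one DSB site: chromosome ~ probs, then uniform over the
    cell's breakable positions on that chromosome, rejecting excluded or
    used positions.  Returns the new (head, tail) node ids."""
    g = cell.genome
    ref = g.ref
    remaining = dict(probs)
    while remaining:
        names = list(remaining)
        p = np.array([remaining[c] for c in names])
        chrom = names[rng.choice(len(names), p=p / p.sum())]
        ivs = [iv for iv in g.intervals.values()
               if iv.chrom == chrom and iv.length >= 2]
        if ivs:
            weights = np.array([iv.length - 1 for iv in ivs], dtype=float)
            weights /= weights.sum()
            for _ in range(2000):
                iv = ivs[rng.choice(len(ivs), p=weights)]
                pos = int(rng.integers(iv.start, iv.end))  # break after pos
                if ref.is_excluded(chrom, pos) or ref.is_excluded(chrom, pos + 1):
                    continue
                if (chrom, pos) in cell.used_positions:
                    continue
                if iv.id not in g.intervals:  # split earlier this cycle
                    break
                cell.used_positions.add((chrom, pos))
                head, tail, _, _ = g.introduce_dsb(iv.id, pos)
                return head, tail
        del remaining[chrom]
    raise CycleError("no feasible DSB position on any chromosome")


def _place_catalog_dsb(cell: Cell, catalog: BreakpointCatalog,
                       rng: np.random.Generator) -> tuple[int, int]:
    g = cell.genome
    eligible = []
    weights = []
    for chrom, pos, w in zip(catalog.chroms, catalog.positions, catalog.weights):
        if (chrom, pos) in cell.used_positions:
            continue
        if g.ref.is_excluded(chrom, pos) or g.ref.is_excluded(chrom, pos + 1):
            continue
        covering = [iv.id for iv in g.intervals.values()
                    if iv.chrom == chrom and iv.start <= pos < iv.end]
        if covering:
            eligible.append((chrom, pos, covering))
            weights.append(w)
    if not eligible:
        raise CycleError("breakpoint catalog exhausted")
    w = np.array(weights, dtype=float)
    chrom, pos, covering = eligible[rng.choice(len(eligible), p=w / w.sum())]
    iv_id = covering[int(rng.integers(len(covering)))]
    cell.used_positions.add((chrom, pos))
    head, tail, _, _ = g.introduce_dsb(iv_id, pos)
    return head, tail


def g1_generate_dsbs(cell: Cell, params: CycleParams,
                     rng: np.random.Generator,
                     log: Optional[CycleLog] = None) -> int:
    """Introduce this cycle's interphase DSBs.  Returns the number placed."""
    log = log if log is not None else CycleLog()
    if params.n_d is not None and cell.divisions > params.n_d:
        return 0
    if params.dsb_count is not None:
        n = params.dsb_count
    else:
        n = int(rng.poisson(params.dsb_rate))
    probs = _chrom_probabilities(params, cell.genome.ref)
    for _ in range(n):
        if params.dsb_source == "catalog":
            head, tail = _place_catalog_dsb(cell, params.catalog, rng)
        else:
            head, tail = _place_random_dsb(cell, probs, rng)
        cell.new_ends.update((head, tail))
        log.dsbs += 1
    return n


# ---------------------------------------------------------------------------
# G1: repair


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[ra] = rb
        return True


def _repair_weight(g: GenomeGraph, b1: int, b2: int, p_r: float) -> float:
    n1, n2 = g.nodes[b1], g.nodes[b2]
    if n1.dsb_mate == n2.id:
        return p_r
    if n1.chrom == n2.chrom and n1.hap == n2.hap:
        return 1.0 / max(abs(n1.coord - n2.coord), 1)
    return 1.0 / INTER_CHROM_DISTANCE


def g1_repair(cell: Cell, params: CycleParams, rng: np.random.Generator,
              log: Optional[CycleLog] = None) -> int:
    """Pair up a fraction ``1 - f_u`` of the eligible free ends.

    Returns the number of junctions formed.  With an odd number of ends to
    repair, one end is left unrepaired.
    """
    log = log if log is not None else CycleLog()
    g = cell.genome
    ends = g.unrepaired_ends()
    if params.repair_scope == "new":
        ends = [e for e in ends if e in cell.new_ends]
    n_pairs = int((1.0 - params.f_u) * len(ends) / 2.0)
    joined = 0
    if n_pairs > 0:
        comp = _UnionFind(list(g.intervals))
        for path in g.walk_paths():
            ids = path.interval_ids
            for a, b in zip(ids, ids[1:]):
                comp.union(a, b)
        if params.repair_mode == "uniform":
            order = [ends[i] for i in rng.permutation(len(ends))]
            chosen = order[: 2 * n_pairs]
            pairs = list(zip(chosen[0::2], chosen[1::2]))
        else:
            pairs = []
            remaining = list(ends)
            for _ in range(n_pairs):
                b1 = remaining.pop(int(rng.integers(len(remaining))))
                if not remaining:
                    break
                w = np.array([_repair_weight(g, b1, b2, params.p_r)
                              for b2 in remaining])
                total = w.sum()
                if total <= 0.0:
                    break  # only the faithful partner remains and p_r = 0
                b2 = remaining.pop(int(rng.choice(len(remaining), p=w / total)))
                pairs.append((b1, b2))
        for b1, b2 in pairs:
            kind = g.join(b1, b2, origin="g1")
            joined += 1
            if kind == VAR_JUNCTION:
                log.misrepaired += 1
                if comp.union(g.nodes[b1].interval, g.nodes[b2].interval):
                    log.fusions += 1
            else:
                comp.union(g.nodes[b1].interval, g.nodes[b2].interval)
    log.unrepaired_after_g1 = len(g.unrepaired_ends())
    return joined


# ---------------------------------------------------------------------------
# S/G2: replication and sister fusion


@dataclass
class ReplicationResult:
    """Sister bookkeeping produced by S/G2.

    ``sister_pairs`` lists ``(original_ids, copy_ids)`` interval-id sets for
    derivatives replicated without fusion; fused derivatives appear as
    single merged paths in the replicated graph.
    """

    sister_pairs: list[tuple[frozenset[int], frozenset[int]]]


def s_g2_replicate(cell: Cell, log: Optional[CycleLog] = None) -> ReplicationResult:
    """Replicate the genome; fuse telomere-deficient linear derivatives to
    their sister copies; double every base."""
    log = log if log is not None else CycleLog()
    g = cell.genome
    pre_paths = g.walk_paths()
    iv_map, node_map = g.clone_into_self()
    sister_pairs = []
    for p in pre_paths:
        if p.circular or p.n_telomeres == 2:
            sister_pairs.append((
                frozenset(p.interval_ids),
                frozenset(iv_map[i] for i in p.interval_ids),
            ))
            continue
        fused = 0
        for end_nid in (p.start_node, p.end_node):
            node = g.nodes[end_nid]
            if not node.telomere:
                g.join(end_nid, node_map[end_nid], origin="sister_fusion")
                fused += 1
        log.sister_fusions += fused
        if fused:
            log.fusions += 1  # merging path and copy into one derivative
    log.ecdna_pre_m = sum(1 for q in g.walk_paths() if q.is_ecdna())
    return ReplicationResult(sister_pairs)


# ---------------------------------------------------------------------------
# M: segregation


def _centromere_occurrences(g: GenomeGraph, seq: list[tuple[int, str]]
                            ) -> list[tuple[int, int]]:
    """Path-offset ranges at which the walk traverses a centromere."""
    occ = []
    off = 0
    for iv_id, orient in seq:
        iv = g.intervals[iv_id]
        cs, ce = g.ref[iv.chrom].centromere
        lo, hi = max(iv.start, cs), min(iv.end, ce)
        if lo <= hi:
            if orient == HEAD:
                occ.append((off + lo - iv.start, off + hi - iv.start))
            else:
                occ.append((off + iv.end - hi, off + iv.end - lo))
        off += iv.length
    occ.sort()
    return occ


class _PathCutter:
    """Applies break offsets to a derivative path.

    A cut "after offset t" severs the walk between path positions ``t`` and
    ``t + 1`` (cyclically for circular paths).  Interval splits keep global
    offsets stable, so cuts may be applied in any order.
    """

    def __init__(self, g: GenomeGraph, path: DerivativePath,
                 used: set[tuple[str, int]]):
        self.g = g
        self.used = used
        self.circular = path.circular
        self.items: list[list] = []  # [iv_id, orient, start_off]
        off = 0
        for iv_id, orient in path.intervals:
            self.items.append([iv_id, orient, off])
            off += g.intervals[iv_id].length
        self.length = off
        self.cuts: list[int] = []

    def _locate(self, t: int) -> int:
        lo, hi = 0, len(self.items) - 1
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if self.items[mid][2] <= t:
                lo = mid
            else:
                hi = mid - 1
        return lo

    def ref_coord(self, t: int) -> tuple[str, int]:
        """Reference (chrom, pos) of the base at path offset ``t``."""
        idx = self._locate(t)
        iv_id, orient, start_off = self.items[idx]
        iv = self.g.intervals[iv_id]
        u = t - start_off
        pos = iv.start + u if orient == HEAD else iv.end - u
        return iv.chrom, pos

    def cut_position_used(self, t: int) -> bool:
        """Would cutting after ``t`` hit an already-broken position?"""
        idx = self._locate(t)
        iv_id, orient, start_off = self.items[idx]
        iv = self.g.intervals[iv_id]
        u = t - start_off
        if u == iv.length - 1:
            return False  # boundary cut reuses existing ends
        j = iv.start + u if orient == HEAD else iv.end - u - 1
        return (iv.chrom, j) in self.used

    def cut(self, t: int) -> None:
        idx = self._locate(t)
        iv_id, orient, start_off = self.items[idx]
        iv = self.g.intervals[iv_id]
        u = t - start_off
        if u == iv.length - 1:
            # boundary: sever junction between this item and the next
            nxt = self.items[(idx + 1) % len(self.items)]
            exit_node = iv.right if orient == HEAD else iv.left
            nxt_iv = self.g.intervals[nxt[0]]
            entry_node = nxt_iv.left if nxt[1] == HEAD else nxt_iv.right
            self.g.break_junction(exit_node, entry_node)
        else:
            j = iv.start + u if orient == HEAD else iv.end - u - 1
            self.used.add((iv.chrom, j))
            _, _, left_iv, right_iv = self.g.introduce_dsb(
                iv_id, j, origin="mitotic")
            if orient == HEAD:
                first, second = left_iv, right_iv
            else:
                first, second = right_iv, left_iv
            first_len = u + 1
            self.items[idx] = [first, orient, start_off]
            self.items.insert(idx + 1, [second, orient, start_off + first_len])
        self.cuts.append(t)

    def fragments(self) -> list[list[int]]:
        """Interval-id lists of the pieces delimited by the applied cuts.

        Every cut boundary coincides with an item boundary after
        :meth:`cut`, so each item belongs to exactly one piece; within-piece
        order is irrelevant to segregation.
        """
        if not self.cuts:
            return [[iv_id for iv_id, _, _ in self.items]]
        cuts = sorted(self.cuts)
        if self.circular:
            piece_starts = sorted({(c + 1) % self.length for c in cuts})
            groups: list[list[int]] = [[] for _ in piece_starts]
            for iv_id, _, s in self.items:
                i = bisect.bisect_right(piece_starts, s) - 1
                if i < 0:
                    i = len(piece_starts) - 1
                groups[i].append(iv_id)
        else:
            groups = [[] for _ in range(len(cuts) + 1)]
            for iv_id, _, s in self.items:
                groups[bisect.bisect_left(cuts, s)].append(iv_id)
        return [grp for grp in groups if grp]


def _choose_cut(rng: np.random.Generator, cutter: _PathCutter,
                lo: int, hi: int) -> Optional[int]:
    """Uniform feasible cut offset in [lo, hi] (cyclic offsets allowed),
    respecting infinite sites."""
    if hi < lo:
        return None
    for _ in range(64):
        t = int(rng.integers(lo, hi + 1)) % cutter.length
        if not cutter.cut_position_used(t):
            return t
    return int(rng.integers(lo, hi + 1)) % cutter.length  # saturated: reuse


def _in_centromere(ref: ReferenceDescriptor, chrom: str, pos: int) -> bool:
    cs, ce = ref[chrom].centromere
    return cs <= pos <= ce


def _break_multicentric(g: GenomeGraph, path: DerivativePath,
                        params: CycleParams, rng: np.random.Generator,
                        used: set[tuple[str, int]], log: CycleLog
                        ) -> list[tuple[list[int], bool]]:
    """Bridge breakage of an ``N_c >= 2`` derivative.

    One simple break lands uniformly between each pair of adjacent
    centromeres; each resulting monocentric derivative may then undergo
    local fragmentation.  Returns ``(interval_ids, has_centromere)`` per
    piece.
    """
    cutter = _PathCutter(g, path, used)
    occ = _centromere_occurrences(g, path.intervals)
    k = len(occ)
    cut_offsets: list[int] = []
    # feasible cut offsets sit strictly between adjacent centromeres so
    # that neither new breakpoint base lands inside a centromere
    if path.circular:
        gaps = []
        for i in range(k):
            lo = occ[i][1] + 1
            hi = occ[(i + 1) % k][0] - 2
            if i == k - 1:
                hi += cutter.length  # wrap
            gaps.append((lo, hi))
    else:
        gaps = [(occ[i][1] + 1, occ[i + 1][0] - 2) for i in range(k - 1)]
    for lo, hi in gaps:
        t = _choose_cut(rng, cutter, lo, hi)
        if t is None:
            continue  # adjacent centromeres with no gap; leave joined
        cut_offsets.append(t % cutter.length)
        log.bridge_simple_breaks += 1
    for t in cut_offsets:
        cutter.cut(t)
    # local fragmentation of each monocentric derivative
    if params.m_l > 0 and cut_offsets:
        cuts = sorted(cutter.cuts)
        if path.circular:
            ranges = [((cuts[i] + 1) % cutter.length,
                       cuts[(i + 1) % len(cuts)]
                       + (cutter.length if i + 1 == len(cuts) else 0))
                      for i in range(len(cuts))]
        else:
            ranges = list(zip([c + 1 for c in [-1] + cuts],
                              cuts + [cutter.length - 1]))
        for lo, hi in ranges:
            n_l = int(rng.poisson(params.m_l))
            if n_l == 0 or rng.random() >= 0.5:
                continue
            log.bridge_fragmentations += 1
            placed = 0
            attempts = 0
            chosen: set[int] = set()
            while placed < n_l and attempts < 20 * n_l + 64:
                attempts += 1
                if hi - 1 < lo:
                    break
                t = int(rng.integers(lo, hi)) % cutter.length  # avoid piece end
                if t in chosen or t in cutter.cuts:
                    continue
                chrom, pos = cutter.ref_coord(t)
                chrom2, pos2 = cutter.ref_coord((t + 1) % cutter.length)
                if _in_centromere(g.ref, chrom, pos) or \
                        _in_centromere(g.ref, chrom2, pos2):
                    continue
                if cutter.cut_position_used(t):
                    continue
                chosen.add(t)
                placed += 1
            for t in chosen:
                cutter.cut(t)
    frags = cutter.fragments()
    out = []
    for frag in frags:
        has_cen = False
        for iv_id in frag:
            iv = g.intervals[iv_id]
            cs, ce = g.ref[iv.chrom].centromere
            if iv.start <= ce and iv.end >= cs:
                has_cen = True
                break
        out.append((frag, has_cen))
    return out


def m_segregate(cell: Cell, params: CycleParams, rng: np.random.Generator,
                replication: ReplicationResult,
                log: Optional[CycleLog] = None
                ) -> tuple[GenomeGraph, Optional[GenomeGraph]]:
    """Distribute the replicated genome into two daughters.

    Returns ``(genome_1, genome_2)``; ``genome_2`` is ``None`` when the
    cell undergoes whole-genome doubling (the sibling dies).
    """
    log = log if log is not None else CycleLog()
    g = cell.genome
    if not cell.wgd and rng.random() < params.p_w:
        log.wgd = True
        return g, None
    paths = g.walk_paths()
    by_ids = {frozenset(p.interval_ids): p for p in paths}
    alloc: tuple[list[int], list[int]] = ([], [])
    handled: set[frozenset[int]] = set()
    for orig_ids, copy_ids in replication.sister_pairs:
        pa = by_ids.get(orig_ids)
        pb = by_ids.get(copy_ids)
        if pa is None or pb is None:
            continue  # defensive; unfused paths are untouched between S and M
        if pa.n_centromeres == 1:
            d = int(rng.integers(2))
            alloc[d].extend(pa.interval_ids)
            alloc[1 - d].extend(pb.interval_ids)
            handled.add(orig_ids)
            handled.add(copy_ids)
    for p in paths:
        key = frozenset(p.interval_ids)
        if key in handled:
            continue
        nc = p.n_centromeres
        if nc <= 1:
            alloc[int(rng.integers(2))].extend(p.interval_ids)
            continue
        pieces = _break_multicentric(g, p, params, rng,
                                     cell.used_positions, log)
        centric = [ids for ids, has_cen in pieces if has_cen]
        acentric = [ids for ids, has_cen in pieces if not has_cen]
        if nc == 2 and len(centric) == 2:
            d = int(rng.integers(2))
            alloc[d].extend(centric[0])
            alloc[1 - d].extend(centric[1])
        else:
            for ids in centric:
                alloc[int(rng.integers(2))].extend(ids)
        for ids in acentric:
            alloc[int(rng.integers(2))].extend(ids)
    g1 = g.extract(alloc[0])
    g2 = g.extract(alloc[1])
    if g.intervals:
        raise CycleError("segregation left unallocated intervals")
    return g1, g2


# ---------------------------------------------------------------------------
# full cycle


def run_cell_cycle(cell: Cell, params: CycleParams,
                   rng: np.random.Generator) -> tuple[list[Cell], CycleLog]:
    """Run G1 -> S/G2 -> M on ``cell``; return daughter cells and the log.

    The parent's genome object is consumed.  Two daughters are returned
    normally; one under whole-genome doubling.
    """
    log = CycleLog()
    cell.new_ends = set()
    g1_generate_dsbs(cell, params, rng, log)
    g1_repair(cell, params, rng, log)
    replication = s_g2_replicate(cell, log)
    ga, gb = m_segregate(cell, params, rng, replication, log)
    wgd_after = cell.wgd or log.wgd
    daughters = []
    for genome in (ga, gb):
        if genome is None:
            continue
        daughters.append(Cell(
            genome=genome,
            divisions=cell.divisions + 1,
            wgd=wgd_after,
            used_positions=set(cell.used_positions),
            logs=cell.logs + [log],
        ))
    return daughters, log
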