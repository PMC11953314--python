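"""Diploid interval adjacency graph.

The genome of one cell is a graph ``G = (V, E)`` whose nodes are breakpoint
ends and whose edges are of three kinds:

* *interval* edges connect the two ends of a contiguous genomic interval
  ``[start, end]`` on one homologue (implicit here: every node belongs to
  exactly one :class:`Interval`);
* *reference* adjacencies join two ends that are adjacent in the reference
  genome (a faithfully repaired break);
* *variant* adjacencies join ends brought together by misrepair, sister
  chromatid fusion or circularisation, and carry an SV-type label.

Every node touches exactly one interval edge and at most one junction
(reference or variant) edge; a node with no junction edge is an unrepaired
break end or a natural telomeric chromosome end.  A derivative chromosome is
a maximal walk alternating between interval and junction edges; circular
walks close with one extra adjacency.

A double-strand break at position ``j`` splits an interval ``[i, k]`` into
``[i, j]`` and ``[j+1, k]``, creating a HEAD node (orientation ``+``, the
right side of ``[i, j]``) and a TAIL node (orientation ``-``, the left side
of ``[j+1, k]``).  Junction orientation pairs, ordered by coordinate,
classify intra-chromosomal SVs: ``-/+`` duplication-like, ``+/-``
deletion-like, ``+/+`` head-to-head inversion, ``-/-`` tail-to-tail
inversion; junctions across chromosomes are inter-chromosomal.

Coordinates are 1-based and closed; total base content is invariant under
breakage and repair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np

from .reference import ReferenceDescriptor

HEAD = "+"
TAIL = "-"

SV_DUP = "DUP-like"
SV_DEL = "DEL-like"
SV_H2H = "H2HINV"
SV_T2T = "T2TINV"
SV_TRA = "INTER-CHR"

#: orientation pair (ordered by coordinate) -> intra-chromosomal SV type
_ORIENT_TO_SV = {
    (TAIL, HEAD): SV_DUP,
    (HEAD, TAIL): SV_DEL,
    (HEAD, HEAD): SV_H2H,
    (TAIL, TAIL): SV_T2T,
}

REF_JUNCTION = "reference"
VAR_JUNCTION = "variant"


class GraphError(ValueError):
    pass


@dataclass(slots=True)
class Node:
    """One breakpoint end.

    ``orient`` is ``+`` (HEAD, right side of its interval) or ``-`` (TAIL,
    left side).  ``telomere`` marks the natural terminal coordinate of a
    chromosome; telomeric nodes never take part in repair.  ``dsb_mate`` is
    the sibling end created by the same break, used to recognise faithful
    rejoins.
    """

    id: int
    chrom: str
    hap: str
    coord: int
    orient: str
    interval: int
    telomere: bool = False
    partner: Optional[int] = None
    junction_kind: Optional[str] = None
    junction_origin: Optional[str] = None
    sv_type: Optional[str] = None
    origin: str = "interphase"
    dsb_mate: Optional[int] = None


@dataclass(slots=True)
class Interval:
    """A contiguous genomic interval on one homologue; ``left``/``right``
    are the node ids at its two ends."""

    id: int
    chrom: str
    hap: str
    start: int
    end: int
    left: int
    right: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class DerivativePath:
    """A derivative chromosome: an ordered, oriented interval walk.

    ``intervals`` lists ``(interval_id, orient)``; orient ``+`` means the
    interval is traversed start→end.  For linear paths ``start_node`` and
    ``end_node`` are the free (junction-less) terminal nodes.
    """

    intervals: list[tuple[int, str]]
    circular: bool
    start_node: Optional[int] = None
    end_node: Optional[int] = None
    n_centromeres: int = 0
    n_telomeres: int = 0
    length: int = 0

    @property
    def interval_ids(self) -> list[int]:
        return [iv for iv, _ in self.intervals]

    def is_ecdna(self) -> bool:
        """Circular, no centromere, no telomere — the ecDNA definition."""
        return self.circular and self.n_centromeres == 0 and self.n_telomeres == 0


def classify_junction(a: Node, b: Node) -> str:
    """SV type of a variant adjacency between ends ``a`` and ``b``.

    Invariant to argument order: endpoints are sorted by (chromosome,
    coordinate) before the orientation pair is read off.
    """
    if a.chrom != b.chrom:
        return SV_TRA
    first, second = sorted((a, b), key=lambda n: (n.coord, n.orient))
    return _ORIENT_TO_SV[(first.orient, second.orient)]


class GenomeGraph:
    """The rearranged diploid genome of one cell.

    Mutating operations (breaks, joins) invalidate the cached path
    decomposition; :meth:`walk_paths` recomputes it on demand.
    """

    def __init__(self, ref: ReferenceDescriptor):
        self.ref = ref
        self.nodes: dict[int, Node] = {}
        self.intervals: dict[int, Interval] = {}
        self._next_id = 0
        self._paths: Optional[list[DerivativePath]] = None

    # -- bookkeeping -------------------------------------------------------

    def _fresh_id(self) -> int:
        self._next_id += 1
        return self._next_id

    def _invalidate(self) -> None:
        self._paths = None

    def total_content(self) -> int:
        """Total base content; conserved by break/repair, doubled by
        replication, partitioned at division."""
        return sum(iv.length for iv in self.intervals.values())

    # -- construction ------------------------------------------------------

    @classmethod
    def diploid(cls, ref: ReferenceDescriptor) -> "GenomeGraph":
        """Pristine diploid genome: one full-length interval per homologue,
        telomeric nodes at both ends."""
        g = cls(ref)
        for spec in ref:
            for hap in ("A", "B"):
                g.add_chromosome(spec.name, hap)
        return g

    def add_chromosome(self, chrom: str, hap: str) -> Interval:
        spec = self.ref[chrom]
        iv_id = self._fresh_id()
        left = Node(self._fresh_id(), chrom, hap, 1, TAIL, iv_id,
                    telomere=True, origin="terminal")
        right = Node(self._fresh_id(), chrom, hap, spec.length, HEAD, iv_id,
                     telomere=True, origin="terminal")
        iv = Interval(iv_id, chrom, hap, 1, spec.length, left.id, right.id)
        self.nodes[left.id] = left
        self.nodes[right.id] = right
        self.intervals[iv_id] = iv
        self._invalidate()
        return iv

    # -- breaks and joins --------------------------------------------------

    def introduce_dsb(self, interval_id: int, pos: int,
                      origin: str = "interphase") -> tuple[int, int, int, int]:
        """Break interval ``[s, e]`` between ``pos`` and ``pos + 1``.

        Returns ``(head_node_id, tail_node_id, left_interval_id,
        right_interval_id)``.  The new ends carry no junction edge; base
        content is conserved.
        """
        iv = self.intervals[interval_id]
        if not (iv.start <= pos < iv.end):
            raise GraphError(
                f"break at {pos} outside splittable range "
                f"[{iv.start},{iv.end - 1}] of interval {interval_id}"
            )
        left_iv_id = self._fresh_id()
        right_iv_id = self._fresh_id()
        head = Node(self._fresh_id(), iv.chrom, iv.hap, pos, HEAD, left_iv_id,
                    origin=origin)
        tail = Node(self._fresh_id(), iv.chrom, iv.hap, pos + 1, TAIL,
                    right_iv_id, origin=origin)
        head.dsb_mate = tail.id
        tail.dsb_mate = head.id
        left_iv = Interval(left_iv_id, iv.chrom, iv.hap, iv.start, pos,
                           iv.left, head.id)
        right_iv = Interval(right_iv_id, iv.chrom, iv.hap, pos + 1, iv.end,
                            tail.id, iv.right)
        self.nodes[iv.left].interval = left_iv_id
        self.nodes[iv.right].interval = right_iv_id
        del self.intervals[interval_id]
        self.intervals[left_iv_id] = left_iv
        self.intervals[right_iv_id] = right_iv
        self.nodes[head.id] = head
        self.nodes[tail.id] = tail
        self._invalidate()
        return head.id, tail.id, left_iv_id, right_iv_id

    def dsb_at(self, chrom: str, hap: str, pos: int) -> tuple[int, int, int, int]:
        """Convenience: break the unique interval covering ``pos`` on the
        given homologue (errors if absent or ambiguous)."""
        hits = [iv for iv in self.intervals.values()
                if iv.chrom == chrom and iv.hap == hap
                and iv.start <= pos < iv.end]
        if len(hits) != 1:
            raise GraphError(
                f"{len(hits)} intervals cover {chrom}{hap}:{pos}; "
                "pass interval_id explicitly"
            )
        return self.introduce_dsb(hits[0].id, pos)

    def break_junction(self, node_a: int, node_b: int) -> None:
        """Remove the junction edge between two nodes (mitotic breakage at
        an existing adjacency)."""
        a, b = self.nodes[node_a], self.nodes[node_b]
        if a.partner != b.id or b.partner != a.id:
            raise GraphError("nodes are not joined")
        for n in (a, b):
            n.partner = None
            n.junction_kind = None
            n.junction_origin = None
            n.sv_type = None
            n.origin = "mitotic"
        self._invalidate()

    def join(self, node_a: int, node_b: int, origin: str = "g1") -> str:
        """Add a junction edge between two free, non-telomeric ends.

        Rejoining the two ends created by the same break restores a
        reference adjacency (equivalent to no break); any other pairing is a
        variant adjacency labelled by :func:`classify_junction`.  Returns
        the junction kind.
        """
        a, b = self.nodes[node_a], self.nodes[node_b]
        if a.id == b.id:
            raise GraphError("cannot join a node to itself")
        for n in (a, b):
            if n.partner is not None:
                raise GraphError(f"node {n.id} already has a junction edge")
            if n.telomere:
                raise GraphError(f"node {n.id} is telomeric")
        faithful = a.dsb_mate == b.id and b.dsb_mate == a.id
        kind = REF_JUNCTION if faithful else VAR_JUNCTION
        a.partner, b.partner = b.id, a.id
        a.junction_kind = b.junction_kind = kind
        a.junction_origin = b.junction_origin = origin
        if kind == VAR_JUNCTION:
            a.sv_type = b.sv_type = classify_junction(a, b)
        self._invalidate()
        return kind

    def unrepaired_ends(self) -> list[int]:
        """Free non-telomeric ends, eligible for repair."""
        return [n.id for n in self.nodes.values()
                if n.partner is None and not n.telomere]

    def variant_adjacencies(self) -> list[tuple[Node, Node]]:
        """Each variant junction once, endpoints ordered canonically."""
        out = []
        for n in self.nodes.values():
            if n.junction_kind == VAR_JUNCTION and n.id < n.partner:
                out.append((n, self.nodes[n.partner]))
        return out

    # -- path decomposition ------------------------------------------------

    def _path_metrics(self, path: DerivativePath) -> None:
        n_cen = 0
        length = 0
        for iv_id, _ in path.intervals:
            iv = self.intervals[iv_id]
            length += iv.length
            cs, ce = self.ref[iv.chrom].centromere
            if iv.start <= ce and iv.end >= cs:  # occurrence-level count
                n_cen += 1
        n_tel = 0
        if not path.circular:
            for nid in (path.start_node, path.end_node):
                if nid is not None and self.nodes[nid].telomere:
                    n_tel += 1
        path.n_centromeres = n_cen
        path.n_telomeres = n_tel
        path.length = length

    def walk_paths(self) -> list[DerivativePath]:
        """Partition all intervals into derivative-chromosome walks.

        Linear paths start and end at junction-less nodes (telomeric ends
        or unrepaired breaks); anything left over is circular.
        """
        if self._paths is not None:
            return self._paths
        paths: list[DerivativePath] = []
        seen: set[int] = set()
        free = sorted(n.id for n in self.nodes.values() if n.partner is None)
        for nid in free:
            node = self.nodes[nid]
            if node.interval in seen:
                continue
            seq: list[tuple[int, str]] = []
            cur = node
            while True:
                iv = self.intervals[cur.interval]
                orient = HEAD if cur.id == iv.left else TAIL
                seq.append((iv.id, orient))
                seen.add(iv.id)
                exit_node = self.nodes[iv.right if orient == HEAD else iv.left]
                if exit_node.partner is None:
                    break
                cur = self.nodes[exit_node.partner]
            paths.append(DerivativePath(seq, circular=False,
                                        start_node=node.id,
                                        end_node=exit_node.id))
        for iv_id in sorted(self.intervals):
            if iv_id in seen:
                continue
            start = self.nodes[self.intervals[iv_id].left]
            seq = []
            cur = start
            while True:
                iv = self.intervals[cur.interval]
                orient = HEAD if cur.id == iv.left else TAIL
                seq.append((iv.id, orient))
                seen.add(iv.id)
                exit_node = self.nodes[iv.right if orient == HEAD else iv.left]
                nxt = self.nodes[exit_node.partner]
                if nxt.id == start.id:
                    break
                cur = nxt
            paths.append(DerivativePath(seq, circular=True))
        for p in paths:
            self._path_metrics(p)
        self._paths = paths
        return paths

    def check_invariants(self) -> None:
        """Assert node-degree and coverage invariants (used in tests)."""
        for n in self.nodes.values():
            iv = self.intervals[n.interval]
            assert n.id in (iv.left, iv.right), f"node {n.id} detached"
            if n.partner is not None:
                assert self.nodes[n.partner].partner == n.id
        covered = [iv for p in self.walk_paths() for iv in p.interval_ids]
        assert sorted(covered) == sorted(self.intervals), \
            "path decomposition must cover every interval exactly once"

    # -- copying / extraction ---------------------------------------------

    def clone_into_self(self) -> tuple[dict[int, int], dict[int, int]]:
        """Duplicate every interval and node in place (DNA replication).

        Returns ``(interval_map, node_map)`` from original to copy ids.
        Junctions are mirrored between copies; ``dsb_mate`` links are
        remapped so a copied break pair still recognises a faithful rejoin.
        """
        iv_map: dict[int, int] = {}
        node_map: dict[int, int] = {}
        orig_nodes = list(self.nodes.values())
        orig_ivs = list(self.intervals.values())
        for iv in orig_ivs:
            iv_map[iv.id] = self._fresh_id()
        for n in orig_nodes:
            node_map[n.id] = self._fresh_id()
        for n in orig_nodes:
            c = Node(node_map[n.id], n.chrom, n.hap, n.coord, n.orient,
                     iv_map[n.interval], telomere=n.telomere,
                     partner=node_map[n.partner] if n.partner is not None else None,
                     junction_kind=n.junction_kind,
                     junction_origin=n.junction_origin,
                     sv_type=n.sv_type, origin=n.origin,
                     dsb_mate=node_map.get(n.dsb_mate)
                     if n.dsb_mate is not None else None)
            self.nodes[c.id] = c
        for iv in orig_ivs:
            c = Interval(iv_map[iv.id], iv.chrom, iv.hap, iv.start, iv.end,
                         node_map[iv.left], node_map[iv.right])
            self.intervals[c.id] = c
        self._invalidate()
        return iv_map, node_map

    def extract(self, interval_ids: Iterable[int]) -> "GenomeGraph":
        """Move the given intervals (and their nodes) into a new graph.

        The interval set must be junction-closed (whole paths).  Ids are
        preserved; the source graph loses the moved components.
        """
        g = GenomeGraph(self.ref)
        ids = set(interval_ids)
        for iv_id in ids:
            iv = self.intervals.pop(iv_id)
            g.intervals[iv_id] = iv
            for nid in (iv.left, iv.right):
                g.nodes[nid] = self.nodes.pop(nid)
        for n in g.nodes.values():
            if n.partner is not None and n.partner not in g.nodes:
                raise GraphError("extract set is not junction-closed")
        g._next_id = self._next_id
        self._invalidate()
        g._invalidate()
        return g

    # -- copy number -------------------------------------------------------

    def copy_number_profile(self) -> "CopyNumberProfile":
        return CopyNumberProfile.from_graph(self)

    def arm_average_cn(self, granularity: str = "arm") -> dict[str, float]:
        """Average total copy number per arm (or per chromosome).

        ``c_i`` for the fitness model: interval coverage summed over both
        haplotypes, divided by region length.  A pristine diploid genome
        gives 2.0 everywhere.
        """
        if granularity == "arm":
            regions = [(a.name, a.chrom, a.start, a.end) for a in self.ref.arms()]
        elif granularity == "chromosome":
            regions = [(c.name, c.name, 1, c.length) for c in self.ref]
        else:
            raise ValueError(f"unknown granularity {granularity!r}")
        by_chrom: dict[str, list[Interval]] = {}
        for iv in self.intervals.values():
            by_chrom.setdefault(iv.chrom, []).append(iv)
        out = {}
        for name, chrom, start, end in regions:
            cov = 0
            for iv in by_chrom.get(chrom, ()):
                lo = max(iv.start, start)
                hi = min(iv.end, end)
                if lo <= hi:
                    cov += hi - lo + 1
            out[name] = cov / (end - start + 1)
        return out


@dataclass
class CNSegment:
    chrom: str
    hap: str
    start: int
    end: int
    cn: int


@dataclass
class CopyNumberProfile:
    """Maximal constant-copy-number segments per homologue.

    Segments tile each homologue completely (zero-copy gaps included);
    adjacent segments differ in copy number.
    """

    ref: ReferenceDescriptor
    segments: list[CNSegment] = field(default_factory=list)

    @classmethod
    def from_graph(cls, g: GenomeGraph) -> "CopyNumberProfile":
        by_hom: dict[tuple[str, str], list[Interval]] = {}
        for iv in g.intervals.values():
            by_hom.setdefault((iv.chrom, iv.hap), []).append(iv)
        segments: list[CNSegment] = []
        for spec in g.ref:
            for hap in ("A", "B"):
                ivs = by_hom.get((spec.name, hap), [])
                events: dict[int, int] = {}
                for iv in ivs:
                    events[iv.start] = events.get(iv.start, 0) + 1
                    events[iv.end + 1] = events.get(iv.end + 1, 0) - 1
                segments.extend(_sweep(spec.name, hap, spec.length, events))
        return cls(g.ref, segments)

    def by_homologue(self, chrom: str, hap: str) -> list[CNSegment]:
        return [s for s in self.segments if s.chrom == chrom and s.hap == hap]

    def bin_matrix(self, bin_size: int) -> dict[tuple[str, str], np.ndarray]:
        """Haplotype-specific bin copy numbers.

        Each segment adds its CN to the bins it fully covers and
        ``CN x overlap / effective_bin_size`` to partially covered end bins,
        where the effective size of the chromosome's trailing bin is clipped
        to the chromosome end (so a pristine homologue is exactly 1.0 in
        every bin).
        """
        return bin_copy_number(self, bin_size)

    def total_bin_matrix(self, bin_size: int) -> dict[str, np.ndarray]:
        """Total (hapA + hapB) bin copy numbers per chromosome."""
        haps = self.bin_matrix(bin_size)
        out: dict[str, np.ndarray] = {}
        for (chrom, _), arr in haps.items():
            if chrom in out:
                out[chrom] = out[chrom] + arr
            else:
                out[chrom] = arr.copy()
        return out


def _sweep(chrom: str, hap: str, length: int,
           events: dict[int, int]) -> list[CNSegment]:
    segs: list[CNSegment] = []
    bounds = sorted(b for b in set(events) | {1, length + 1}
                    if 1 <= b <= length + 1)
    cn = 0
    pos = 1
    for b in bounds:
        if b > pos:
            if segs and segs[-1].cn == cn and segs[-1].end == pos - 1:
                segs[-1] = CNSegment(chrom, hap, segs[-1].start, b - 1, cn)
            else:
                segs.append(CNSegment(chrom, hap, pos, b - 1, cn))
            pos = b
        cn += events.get(b, 0)
    return segs


def bin_copy_number(profile: CopyNumberProfile,
                    bin_size: int) -> dict[tuple[str, str], np.ndarray]:
    """Bin-level haplotype-specific copy numbers from a segment profile."""
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    ref = profile.ref
    out: dict[tuple[str, str], np.ndarray] = {}
    n_bins = {c.name: -(-c.length // bin_size) for c in ref}
    for spec in ref:
        for hap in ("A", "B"):
            out[(spec.name, hap)] = np.zeros(n_bins[spec.name])
    for seg in profile.segments:
        if seg.cn == 0:
            continue
        arr = out[(seg.chrom, seg.hap)]
        length = ref[seg.chrom].length
        b0 = (seg.start - 1) // bin_size
        b1 = (seg.end - 1) // bin_size
        for b in (b0, b1) if b0 != b1 else (b0,):
            lo = b * bin_size + 1
            hi = min((b + 1) * bin_size, length)
            eff = hi - lo + 1
            ov = min(seg.end, hi) - max(seg.start, lo) + 1
            arr[b] += seg.cn * ov / eff
        if b1 > b0 + 1:
            arr[b0 + 1:b1] += seg.cn
    return out
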