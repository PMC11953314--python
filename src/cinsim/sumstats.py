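"""SV calls, complex-event summaries and the ABC feature vector.

The inference feature vector of a population comprises: the fraction of
cells with whole-genome doubling; the fractions of SV calls that are
deletion-like, duplication-like, inverted (head-to-head plus tail-to-tail)
and intra-chromosomal; the breakpoint frequency spectrum (the fraction of
distinct breakpoints carried by exactly ``k`` of the ``N`` cells); the
percentage of genome altered (PGA, total copy number, bins altered from
ploidy in any cell); and the mean and standard deviation of pairwise
divergence between cells (haplotype-specific copy number, bins where the
two cells differ and at least one deviates from its ploidy, normalised by
the total bin count).  Ploidy is 2 (total) / 1 (per haplotype) for normal
cells and 4 / 2 after whole-genome doubling.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .cycle import Cell
from .graph import (SV_DEL, SV_DUP, SV_H2H, SV_T2T, SV_TRA, DerivativePath,
                    GenomeGraph)
from .reference import ReferenceDescriptor

_CN_TOL = 1e-9

DEFAULT_BIN_SIZE = 500_000


@dataclass(frozen=True)
class SVCall:
    """One variant adjacency in one cell."""

    cell_id: int
    chrom1: str
    pos1: int
    orient1: str
    hap1: str
    chrom2: str
    pos2: int
    orient2: str
    hap2: str
    sv_type: str

    @property
    def breakpoints(self) -> tuple[tuple[str, int, str], tuple[str, int, str]]:
        return ((self.chrom1, self.pos1, self.orient1),
                (self.chrom2, self.pos2, self.orient2))


def extract_sv_calls(cell: Cell) -> list[SVCall]:
    """All variant adjacencies of a cell, endpoints in canonical order."""
    calls = []
    for a, b in cell.genome.variant_adjacencies():
        first, second = sorted(
            (a, b), key=lambda n: (n.chrom, n.coord, n.orient))
        calls.append(SVCall(
            cell_id=cell.id,
            chrom1=first.chrom, pos1=first.coord, orient1=first.orient,
            hap1=first.hap,
            chrom2=second.chrom, pos2=second.coord, orient2=second.orient,
            hap2=second.hap,
            sv_type=a.sv_type))
    return calls


# ---------------------------------------------------------------------------
# complex events


def summarize_ecdna(cell: Cell) -> tuple[int, list[int], list[int]]:
    """ecDNA content of one cell.

    Circular acentric atelomeric paths are grouped by identical interval
    content (the multiset of reference intervals they carry); returns
    ``(number of types, copies per type, size in bp per type)``.
    """
    groups: dict[tuple, list[DerivativePath]] = {}
    for p in cell.genome.walk_paths():
        if not p.is_ecdna():
            continue
        ivs = [cell.genome.intervals[iv] for iv in p.interval_ids]
        key = tuple(sorted((iv.chrom, iv.hap, iv.start, iv.end) for iv in ivs))
        groups.setdefault(key, []).append(p)
    n_types = len(groups)
    copies = [len(v) for v in groups.values()]
    sizes = [v[0].length for v in groups.values()]
    return n_types, copies, sizes


def ecdna_count(cell: Cell) -> int:
    """Total number of ecDNA molecules in a cell."""
    return sum(1 for p in cell.genome.walk_paths() if p.is_ecdna())


def count_fusions(cells_or_logs: Iterable) -> int:
    """Total chromosome-fusion events recorded in cycle logs.

    Accepts cells (whose ``logs`` are read) or logs directly.  A fusion is
    any junction event that merged two previously distinct derivative
    chromosomes (G1 inter-path misrepair joins plus S-phase sister
    fusions).
    """
    total = 0
    for item in cells_or_logs:
        logs = item.logs if isinstance(item, Cell) else [item]
        for log in logs:
            total += log.fusions
    return total


def _interleaved(a: tuple[int, int], b: tuple[int, int]) -> bool:
    """Two intra-chromosomal SV intervals interleave iff they cross:
    overlap without containment."""
    (s1, e1), (s2, e2) = sorted((a, b))
    return s1 < s2 < e1 < e2


def detect_chromothripsis(sv_calls: Sequence[SVCall],
                          cn_segments: Sequence,
                          chrom: str) -> bool:
    """Chromothripsis flag for one chromosome of one cell.

    Requires (a) at least six intra-chromosomal SVs forming a set in which
    each member interleaves at least one other, and (b) at least seven
    consecutive copy-number segments oscillating between exactly two
    states.
    """
    spans = [(min(c.pos1, c.pos2), max(c.pos1, c.pos2))
             for c in sv_calls
             if c.chrom1 == chrom and c.chrom2 == chrom]
    linked = set()
    for i, j in itertools.combinations(range(len(spans)), 2):
        if _interleaved(spans[i], spans[j]):
            linked.update((i, j))
    if len(linked) < 6:
        return False
    states = [seg.cn for seg in cn_segments if seg.chrom == chrom]
    return _has_oscillation(states, min_run=7)


def _has_oscillation(states: Sequence[float], min_run: int) -> bool:
    """A run of >= min_run consecutive values alternating between exactly
    two distinct states."""
    n = len(states)
    if n < min_run:
        return False
    run = 1
    for i in range(1, n):
        if abs(states[i] - states[i - 1]) < _CN_TOL:
            run = 1          # equal neighbours: no alternation
        elif run == 1 or abs(states[i] - states[i - 2]) < _CN_TOL:
            run += 1         # alternates with the run's other state
        else:
            run = 2          # new two-state pair starts at i-1
        if run >= min_run:
            return True
    return False


# ---------------------------------------------------------------------------
# summary statistics


@dataclass
class SummaryStats:
    """The ABC feature vector with a fixed component layout."""

    n_cells: int
    wgd_fraction: float
    sv_fractions: dict[str, float]      # DEL/DUP/INV/INTRA
    breakpoint_spectrum: list[float]    # k = 1..n_cells
    pga: float
    divergence_mean: float
    divergence_sd: float
    single_cell: bool = False

    COMPONENTS = ("wgd_fraction", "frac_del", "frac_dup", "frac_inv",
                  "frac_intra")

    def labels(self) -> list[str]:
        return (list(self.COMPONENTS)
                + [f"bp_spectrum_{k}" for k in range(1, self.n_cells + 1)]
                + ["pga", "divergence_mean", "divergence_sd"])

    def to_vector(self) -> np.ndarray:
        return np.array(
            [self.wgd_fraction,
             self.sv_fractions["DEL"], self.sv_fractions["DUP"],
             self.sv_fractions["INV"], self.sv_fractions["INTRA"]]
            + list(self.breakpoint_spectrum)
            + [self.pga, self.divergence_mean, self.divergence_sd])

    def to_json(self) -> str:
        return json.dumps({
            "n_cells": self.n_cells,
            "wgd_fraction": self.wgd_fraction,
            "sv_fractions": self.sv_fractions,
            "breakpoint_spectrum": list(self.breakpoint_spectrum),
            "pga": self.pga,
            "divergence_mean": self.divergence_mean,
            "divergence_sd": self.divergence_sd,
            "single_cell": self.single_cell,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SummaryStats":
        d = json.loads(text)
        return cls(n_cells=d["n_cells"], wgd_fraction=d["wgd_fraction"],
                   sv_fractions=d["sv_fractions"],
                   breakpoint_spectrum=d["breakpoint_spectrum"],
                   pga=d["pga"], divergence_mean=d["divergence_mean"],
                   divergence_sd=d["divergence_sd"],
                   single_cell=d.get("single_cell", False))


def _bin_matrices(cells: Sequence[Cell], ref: ReferenceDescriptor,
                  bin_size: int) -> tuple[np.ndarray, np.ndarray]:
    """(total CN matrix cells x bins, haplotype CN matrix cells x 2*bins)."""
    chroms = ref.names
    totals = []
    haps = []
    for cell in cells:
        prof = cell.genome.copy_number_profile()
        hb = prof.bin_matrix(bin_size)
        hap_vec = np.concatenate([hb[(c, h)] for c in chroms
                                  for h in ("A", "B")])
        tot_vec = np.concatenate([hb[(c, "A")] + hb[(c, "B")]
                                  for c in chroms])
        totals.append(tot_vec)
        haps.append(hap_vec)
    return np.vstack(totals), np.vstack(haps)


def compute_summary_stats(cells: Sequence[Cell], ref: ReferenceDescriptor,
                          bin_size: int = DEFAULT_BIN_SIZE,
                          calls: Optional[list[list[SVCall]]] = None
                          ) -> SummaryStats:
    """Full summary-statistic vector for a set of cells."""
    if not cells:
        raise ValueError("need at least one cell")
    n = len(cells)
    wgd_flags = np.array([c.wgd for c in cells])
    wgd_fraction = float(wgd_flags.mean())

    if calls is None:
        calls = [extract_sv_calls(c) for c in cells]
    pooled = [c for per_cell in calls for c in per_cell]
    n_calls = len(pooled)
    counts = {SV_DEL: 0, SV_DUP: 0, "INV": 0, SV_TRA: 0}
    for c in pooled:
        if c.sv_type in (SV_H2H, SV_T2T):
            counts["INV"] += 1
        else:
            counts[c.sv_type] += 1
    if n_calls:
        sv_fractions = {
            "DEL": counts[SV_DEL] / n_calls,
            "DUP": counts[SV_DUP] / n_calls,
            "INV": counts["INV"] / n_calls,
            "INTRA": (n_calls - counts[SV_TRA]) / n_calls,
        }
    else:
        sv_fractions = {"DEL": 0.0, "DUP": 0.0, "INV": 0.0, "INTRA": 0.0}

    carriers: dict[tuple[str, int, str], set[int]] = {}
    for per_cell, cell in zip(calls, cells):
        for call in per_cell:
            for bp in call.breakpoints:
                carriers.setdefault(bp, set()).add(cell.id)
    spectrum = [0.0] * n
    if carriers:
        for cset in carriers.values():
            k = min(len(cset), n)
            spectrum[k - 1] += 1
        total = sum(spectrum)
        spectrum = [v / total for v in spectrum]

    totals, haps = _bin_matrices(cells, ref, bin_size)
    ploidy_total = np.where(wgd_flags, 4.0, 2.0)[:, None]
    altered = np.abs(totals - ploidy_total) > _CN_TOL
    pga = float(altered.any(axis=0).mean())

    if n >= 2:
        ploidy_hap = np.where(wgd_flags, 2.0, 1.0)[:, None]
        dev = np.abs(haps - ploidy_hap) > _CN_TOL
        divs = []
        for i, j in itertools.combinations(range(n), 2):
            differ = np.abs(haps[i] - haps[j]) > _CN_TOL
            divs.append(float((differ & (dev[i] | dev[j])).mean()))
        divergence_mean = float(np.mean(divs))
        divergence_sd = float(np.std(divs))
        single = False
    else:
        divergence_mean = divergence_sd = 0.0
        single = True

    return SummaryStats(
        n_cells=n, wgd_fraction=wgd_fraction, sv_fractions=sv_fractions,
        breakpoint_spectrum=spectrum, pga=pga,
        divergence_mean=divergence_mean, divergence_sd=divergence_sd,
        single_cell=single)


def mean_fusions_per_cycle(cells: Sequence[Cell]) -> float:
    """Mean chromosome fusions per completed cell cycle across a
    population's lineage logs (each division's log counted once)."""
    seen = set()
    fusions = 0
    cycles = 0
    for cell in cells:
        for log in cell.logs:
            if id(log) in seen:
                continue
            seen.add(id(log))
            fusions += log.fusions
            cycles += 1
    return fusions / cycles if cycles else 0.0


def mean_ecdna_per_cell(cells: Sequence[Cell]) -> float:
    if not cells:
        return 0.0
    return float(np.mean([ecdna_count(c) for c in cells]))
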