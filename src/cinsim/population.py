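"""Birth-death branching process growing one cell to ``N`` cells.

Events are scheduled with a rejection-kinetic Monte Carlo scheme: time
advances by an exponential waiting time with rate ``n * r_max`` (``n``
living cells, ``r_max`` a running upper bound on per-cell total rate), a
uniformly chosen candidate cell is accepted with probability
``(b_i + d_i) / r_max``, and an accepted event is a division with
probability ``b_i / (b_i + d_i)``, otherwise a death.  This is exact for
the target continuous-time process for any upper bound ``r_max``.

Every division runs one full cell cycle (G1 breakage/repair, S/G2
replication, M segregation) on the dividing cell; under selection the two
daughters' rates are recomputed from their arm-level copy numbers.  A
whole-genome-doubling division yields a single surviving daughter.  The
lineage tree (parents, children, event times) is recorded and can be
written as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cycle import Cell, CycleParams, run_cell_cycle
from .fitness import CellRates, FitnessParams, baseline_rates, daughter_rates
from .graph import GenomeGraph
from .reference import ReferenceDescriptor


class PopulationError(RuntimeError):
    pass


@dataclass
class SimulationParams:
    """Everything a population run needs."""

    n_cells: int = 10
    cycle: CycleParams = field(default_factory=CycleParams)
    fitness: FitnessParams = field(default_factory=FitnessParams.neutral)
    birth_rate: Optional[float] = None   # None -> fitness-derived/1.0
    death_rate: float = 0.0
    max_events: int = 10_000_000
    assembly: str = "GRCh38"

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("target cell count must be >= 1")
        if self.max_events <= 0:
            raise ValueError("event guard must be positive")


@dataclass
class LineageRecord:
    parent: Optional[int]
    birth_time: float
    end_time: Optional[float] = None
    children: list[int] = field(default_factory=list)
    fate: str = "alive"  # 'alive' | 'divided' | 'dead' | 'wgd_casualty'


@dataclass
class Population:
    """Result of a branching-process run."""

    cells: dict[int, Cell]                 # living cells
    dead: dict[int, Cell]                  # cells removed by death events
    lineage: dict[int, LineageRecord]
    time: float
    n_events: int
    terminal: str                          # 'reached_n' | 'extinct'
    seed_entropy: Optional[int] = None

    @property
    def alive(self) -> list[Cell]:
        return list(self.cells.values())

    def newick(self) -> str:
        """Lineage tree in Newick; labels are cell ids, branch lengths are
        lifetimes (birth to division/death/now)."""
        end_default = self.time

        def fmt(cid: int) -> str:
            rec = self.lineage[cid]
            end = rec.end_time if rec.end_time is not None else end_default
            length = max(end - rec.birth_time, 0.0)
            if rec.children:
                inner = ",".join(fmt(c) for c in rec.children)
                return f"({inner}){cid}:{length:.6g}"
            return f"{cid}:{length:.6g}"

        roots = [cid for cid, rec in self.lineage.items() if rec.parent is None]
        return ";".join(fmt(r) for r in roots) + ";"


def next_event(cells: dict[int, Cell], r_max: float, time: float,
               rng: np.random.Generator) -> tuple[int, str, float]:
    """One accepted event: returns (cell id, 'birth'|'death', new time).

    Rejected proposals still advance the clock, as required for the
    rejection scheme to sample the exact process.
    """
    ids = list(cells)
    n = len(ids)
    while True:
        time += rng.exponential(1.0 / (n * r_max))
        cid = ids[int(rng.integers(n))]
        rates: CellRates = cells[cid].rates
        if rates.total <= 0.0:
            continue
        if rng.random() >= rates.total / r_max:
            continue
        kind = "birth" if rng.random() < rates.birth / rates.total else "death"
        return cid, kind, time


def run_to_size(params: SimulationParams,
                ref: Optional[ReferenceDescriptor] = None,
                rng: Optional[np.random.Generator] = None,
                seed: Optional[int] = None) -> Population:
    """Grow a population from a single pristine diploid cell to
    ``params.n_cells`` living cells (or extinction).

    Fully reproducible for a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if ref is None:
        ref = ReferenceDescriptor.builtin(params.assembly)
    base = baseline_rates(ref, params.fitness, birth=params.birth_rate,
                          death=params.death_rate)
    root = Cell(genome=GenomeGraph.diploid(ref), id=0, rates=base)
    cells: dict[int, Cell] = {0: root}
    dead: dict[int, Cell] = {}
    lineage: dict[int, LineageRecord] = {0: LineageRecord(None, 0.0)}
    next_id = 1
    time = 0.0
    n_events = 0
    r_max = max(base.total, 1e-12)

    while len(cells) < params.n_cells:
        if not cells:
            return Population(cells, dead, lineage, time, n_events,
                              "extinct", seed_entropy=seed)
        if all(c.rates.total <= 0.0 for c in cells.values()):
            # no further dynamics possible; frozen population
            return Population(cells, dead, lineage, time, n_events,
                              "extinct", seed_entropy=seed)
        cid, kind, time = next_event(cells, r_max, time, rng)
        n_events += 1
        if n_events > params.max_events:
            raise PopulationError(
                f"event guard exceeded ({params.max_events} events)")
        cell = cells.pop(cid)
        rec = lineage[cid]
        rec.end_time = time
        if kind == "death":
            rec.fate = "dead"
            dead[cid] = cell
            continue
        rec.fate = "divided"
        daughters, _log = run_cell_cycle(cell, params.cycle, rng)
        for d in daughters:
            d.id = next_id
            next_id += 1
            d.rates = daughter_rates(d.genome, base, params.fitness)
            r_max = max(r_max, d.rates.total)
            cells[d.id] = d
            lineage[d.id] = LineageRecord(cid, time)
            rec.children.append(d.id)

    for c in cells.values():
        lineage[c.id].fate = "alive"
    return Population(cells, dead, lineage, time, n_events, "reached_n",
                      seed_entropy=seed)
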