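"""Readers and writers for all on-disk formats.

Internally everything is 1-based closed; BED/BEDPE writers convert to
0-based half-open.  Every writer has a matching reader and round-trips are
lossless.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .cycle import BreakpointCatalog, Cell
from .graph import HEAD
from .population import Population
from .reference import (DEFAULT_TELOMERE_LENGTH, ChromSpec,
                        ReferenceDescriptor, ReferenceError_)
from .sumstats import (DEFAULT_BIN_SIZE, SummaryStats, compute_summary_stats,
                       extract_sv_calls)

BEDPE_COLUMNS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
                 "name", "score", "strand1", "strand2", "sv_type"]


# ---------------------------------------------------------------------------
# reference descriptor


def write_reference_descriptor(ref: ReferenceDescriptor, sizes_path,
                               regions_path) -> None:
    """Write a chrom-sizes TSV and a centromere/telomere BED."""
    with open(sizes_path, "w") as fh:
        for spec in ref:
            fh.write(f"{spec.name}\t{spec.length}\n")
    with open(regions_path, "w") as fh:
        for spec in ref:
            cs, ce = spec.centromere
            tl, tr = spec.telomere_left, spec.telomere_right
            fh.write(f"{spec.name}\t{cs - 1}\t{ce}\tcentromere\n")
            fh.write(f"{spec.name}\t{tl[0] - 1}\t{tl[1]}\ttelomere\n")
            fh.write(f"{spec.name}\t{tr[0] - 1}\t{tr[1]}\ttelomere\n")


def read_reference_descriptor(sizes_path=None, regions_path=None,
                              builtin: Optional[str] = None,
                              assembly: str = "synthetic"
                              ) -> ReferenceDescriptor:
    """Load a descriptor from files, or a builtin table by tag."""
    if builtin is not None:
        return ReferenceDescriptor.builtin(builtin)
    sizes = {}
    with open(sizes_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, length = line.split()[:2]
            sizes[name] = int(length)
    cen: dict[str, tuple[int, int]] = {}
    telo: dict[str, list[tuple[int, int]]] = {}
    with open(regions_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, label = line.split()[:4]
            iv = (int(start) + 1, int(end))  # BED -> 1-based closed
            if label == "centromere":
                cen[chrom] = iv
            elif label == "telomere":
                telo.setdefault(chrom, []).append(iv)
            else:
                raise ReferenceError_(f"unknown region label {label!r}")
    chroms = {}
    for name, length in sizes.items():
        if name not in cen:
            raise ReferenceError_(f"chrom {name}: centromere missing")
        tels = sorted(telo.get(name, []))
        if len(tels) != 2:
            raise ReferenceError_(f"chrom {name}: need exactly two telomeres")
        chroms[name] = ChromSpec(name=name, length=length,
                                 centromere=cen[name],
                                 telomere_left=tels[0],
                                 telomere_right=tels[1])
    return ReferenceDescriptor(chroms, assembly=assembly)


# ---------------------------------------------------------------------------
# arm scores and catalogs


def write_arm_scores(scores: dict[str, float], path) -> None:
    with open(path, "w") as fh:
        fh.write("arm\tscore\n")
        for arm, s in scores.items():
            fh.write(f"{arm}\t{s!r}\n")


def load_arm_scores(path) -> dict[str, float]:
    """Read a (arm, score) TSV — works for the published OG-TSG table or
    the bundled synthetic stand-in."""
    df = pd.read_csv(path, sep="\t")
    if not {"arm", "score"} <= set(df.columns):
        raise ValueError("score table needs 'arm' and 'score' columns")
    return dict(zip(df["arm"].astype(str), df["score"].astype(float)))


def write_catalog(cat: BreakpointCatalog, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tweight\n")
        for c, p, w in zip(cat.chroms, cat.positions, cat.weights):
            fh.write(f"{c}\t{p}\t{w!r}\n")


def load_catalog(path) -> BreakpointCatalog:
    df = pd.read_csv(path, sep="\t")
    return BreakpointCatalog(chroms=list(df["chrom"].astype(str)),
                             positions=list(df["pos"].astype(int)),
                             weights=list(df["weight"].astype(float)))


# ---------------------------------------------------------------------------
# population outputs


def sv_calls_frame(cells: list[Cell]) -> pd.DataFrame:
    """BEDPE-shaped table of SV calls (0-based half-open; strands encode
    breakpoint orientations, '+' = HEAD).  ``score`` is the number of cells
    carrying the identical junction."""
    rows = []
    support: dict[tuple, int] = {}
    for cell in cells:
        for call in extract_sv_calls(cell):
            key = (call.chrom1, call.pos1, call.orient1,
                   call.chrom2, call.pos2, call.orient2)
            support[key] = support.get(key, 0) + 1
            rows.append({
                "chrom1": call.chrom1, "start1": call.pos1 - 1,
                "end1": call.pos1,
                "chrom2": call.chrom2, "start2": call.pos2 - 1,
                "end2": call.pos2,
                "name": f"cell{cell.id}",
                "strand1": call.orient1, "strand2": call.orient2,
                "sv_type": call.sv_type,
                "_key": key,
            })
    for row in rows:
        row["score"] = support[row.pop("_key")]
    return pd.DataFrame(rows, columns=BEDPE_COLUMNS)


def cn_segments_frame(cells: list[Cell]) -> pd.DataFrame:
    """Haplotype-specific segment copy numbers, both homologues side by
    side on the union of their segment boundaries."""
    rows = []
    for cell in cells:
        prof = cell.genome.copy_number_profile()
        for spec in cell.genome.ref:
            a = prof.by_homologue(spec.name, "A")
            b = prof.by_homologue(spec.name, "B")
            bounds = sorted({s.start for s in a} | {s.end + 1 for s in a}
                            | {s.start for s in b} | {s.end + 1 for s in b})
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                cn_a = next((s.cn for s in a if s.start <= lo <= s.end), 0)
                cn_b = next((s.cn for s in b if s.start <= lo <= s.end), 0)
                rows.append({"cell_id": cell.id, "chrom": spec.name,
                             "start": lo, "end": hi - 1,
                             "cn_hapA": cn_a, "cn_hapB": cn_b})
    return pd.DataFrame(rows)


def bin_matrix_frame(cells: list[Cell], ref: ReferenceDescriptor,
                     bin_size: int = DEFAULT_BIN_SIZE) -> pd.DataFrame:
    """Total-CN bin matrix, cells as rows."""
    cols = []
    for spec in ref:
        n_bins = -(-spec.length // bin_size)
        cols.extend(f"{spec.name}:{i}" for i in range(n_bins))
    data = []
    for cell in cells:
        prof = cell.genome.copy_number_profile()
        total = prof.total_bin_matrix(bin_size)
        data.append(np.concatenate([total[s.name] for s in ref]))
    return pd.DataFrame(data, index=[c.id for c in cells], columns=cols)


def paths_listing(cells: list[Cell]) -> str:
    """Human-readable derivative-genome listing: one line per path, as a
    chain of oriented reference intervals."""
    lines = []
    for cell in cells:
        lines.append(f"#cell {cell.id} wgd={int(cell.wgd)}")
        for p in cell.genome.walk_paths():
            parts = []
            for iv_id, orient in p.intervals:
                iv = cell.genome.intervals[iv_id]
                parts.append(
                    f"{iv.chrom}{iv.hap}:{iv.start}-{iv.end}{orient}")
            shape = "circular" if p.circular else "linear"
            lines.append(f"{shape}\t" + ",".join(parts))
    return "\n".join(lines) + "\n"


def write_outputs(pop: Population, ref: ReferenceDescriptor, outdir,
                  stats: Optional[SummaryStats] = None,
                  bin_size: int = DEFAULT_BIN_SIZE,
                  config: Optional[dict] = None,
                  seed: Optional[int] = None) -> dict:
    """Write the full output bundle; returns the manifest (also saved)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cells = pop.alive
    if stats is None and cells:
        stats = compute_summary_stats(cells, ref, bin_size)

    sv_calls_frame(cells).to_csv(out / "svs.bedpe", sep="\t", index=False)
    cn_segments_frame(cells).to_csv(out / "cn_segments.tsv", sep="\t",
                                    index=False)
    bin_matrix_frame(cells, ref, bin_size).to_csv(
        out / "cn_bins.tsv", sep="\t", index_label="cell_id")
    (out / "paths.txt").write_text(paths_listing(cells))
    (out / "tree.newick").write_text(pop.newick() + "\n")
    if stats is not None:
        (out / "stats.json").write_text(stats.to_json() + "\n")
    echo = dict(config or {})
    echo["seed"] = seed if seed is not None else pop.seed_entropy
    echo["n_cells"] = len(cells)
    echo["terminal"] = pop.terminal
    (out / "config.yaml").write_text(yaml.safe_dump(echo))

    manifest = {}
    for f in sorted(out.iterdir()):
        if f.name == "manifest.json" or not f.is_file():
            continue
        manifest[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest


def read_summary_stats(path) -> SummaryStats:
    return SummaryStats.from_json(Path(path).read_text())


def write_summary_stats(stats: SummaryStats, path) -> None:
    Path(path).write_text(stats.to_json() + "\n")


def write_posterior(posterior, particles_path, meta_path) -> None:
    df = pd.DataFrame(posterior.particles, columns=list(posterior.names))
    df["weight"] = posterior.weights
    df["distance"] = posterior.distances
    df.to_csv(particles_path, sep="\t", index=False)
    meta = {
        "eps_schedule": posterior.eps_schedule,
        "n_simulations": posterior.n_simulations,
        "converged": posterior.converged,
        "ess": posterior.ess(),
        "mean": dict(zip(posterior.names, posterior.mean().tolist())),
        "sd": dict(zip(posterior.names, posterior.sd().tolist())),
    }
    Path(meta_path).write_text(json.dumps(meta, indent=1) + "\n")
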