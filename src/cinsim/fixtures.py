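"""Deterministic synthetic fixtures: toy genomes, arm scores, catalogs.

All external data the simulator could use (a human reference, the published
OG-TSG arm-score table, an observed breakpoint catalog) have synthetic
stand-ins generated here, so the test suite and the command-line interface
run without any downloads.

The synthetic arm-score table is *calibrated*: the raw scores are scaled so
that the pristine diploid genome's survival probability equals the
published normal-genome value exactly; that constant is written alongside
the table and asserted in tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .cycle import BreakpointCatalog
from .fitness import FITNESS_C, FITNESS_D, FitnessParams, \
    normal_survival_probability
from .ioutils import (write_arm_scores, write_catalog,
                      write_reference_descriptor)
from .reference import ReferenceDescriptor

#: normal-genome survival probability targeted by the calibration
NORMAL_SURVIVAL = 0.9689715


@dataclass
class FixtureSpec:
    """What to generate."""

    n_chromosomes: int = 2
    chrom_length: int = 10_000
    telomere_length: int = 500
    catalog_size: int = 200
    catalog_power: float = 1.5   # power-law exponent for frequency weights


def synthetic_arm_scores(ref: ReferenceDescriptor,
                         seed: int = 20240,
                         target: float = NORMAL_SURVIVAL
                         ) -> tuple[dict[str, float], float]:
    """Arm scores calibrated so the normal genome survives with
    probability ``target``.

    Inverting the survival formula at ``c_i = 2`` for all arms gives the
    required score total ``sum_i s_i = (ln(target) - c) / (2 d)``; random
    standard-normal scores are shifted to that total.  Returns
    ``(scores, declared_constant)`` where the declared constant is the
    survival probability actually computed from the scores (bit-identical
    to what the fitness pipeline returns).
    """
    names = ref.arm_names()
    rng = np.random.default_rng(seed)
    raw = rng.normal(0.0, 1.0, size=len(names))
    total_needed = (math.log(target) - FITNESS_C) / (2.0 * FITNESS_D)
    scores_arr = raw - raw.mean() + total_needed / len(names)
    scores = dict(zip(names, scores_arr.tolist()))
    declared = normal_survival_probability(
        ref, FitnessParams(scores=scores))
    return scores, declared


def synthetic_catalog(ref: ReferenceDescriptor, n_sites: int = 200,
                      seed: int = 20240,
                      power: float = 1.5) -> BreakpointCatalog:
    """Breakpoint catalog with power-law frequency weights, avoiding
    excluded regions."""
    rng = np.random.default_rng(seed)
    names = ref.names
    chroms, positions, weights = [], [], []
    used = set()
    while len(positions) < n_sites:
        chrom = names[int(rng.integers(len(names)))]
        spec = ref[chrom]
        pos = int(rng.integers(1, spec.length))
        if ref.is_excluded(chrom, pos) or ref.is_excluded(chrom, pos + 1):
            continue
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        chroms.append(chrom)
        positions.append(pos)
        weights.append(float((1.0 - rng.random()) ** (-1.0 / power)))
    return BreakpointCatalog(chroms=chroms, positions=positions,
                             weights=weights)


def generate_fixtures(outdir, seed: int = 20240,
                      spec: FixtureSpec | None = None) -> dict[str, str]:
    """Write the full fixture set; deterministic for a fixed seed.

    Returns a mapping of fixture role to file path.
    """
    spec = spec or FixtureSpec()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ref = ReferenceDescriptor.synthetic(
        n_chromosomes=spec.n_chromosomes, length=spec.chrom_length,
        telomere_length=spec.telomere_length)
    files = {
        "chrom_sizes": str(out / "synthetic_chrom_sizes.tsv"),
        "regions": str(out / "synthetic_regions.bed"),
        "arm_scores": str(out / "synthetic_arm_scores.tsv"),
        "arm_scores_meta": str(out / "synthetic_arm_scores.json"),
        "catalog": str(out / "synthetic_breakpoint_catalog.tsv"),
    }
    write_reference_descriptor(ref, files["chrom_sizes"], files["regions"])
    scores, declared = synthetic_arm_scores(ref, seed=seed)
    write_arm_scores(scores, files["arm_scores"])
    Path(files["arm_scores_meta"]).write_text(json.dumps(
        {"normal_survival_probability": declared,
         "seed": seed, "synthetic": True}, indent=1) + "\n")
    write_catalog(synthetic_catalog(ref, spec.catalog_size, seed=seed,
                                    power=spec.catalog_power),
                  files["catalog"])
    return files


# ---------------------------------------------------------------------------
# bundled human-arm fixture (shipped with the package)


def load_bundled_scores() -> tuple[dict[str, float], float]:
    """The packaged synthetic 44-arm score table and its declared
    normal-genome survival constant."""
    data = resources.files("cinsim").joinpath("data")
    scores = {}
    with (data / "synthetic_arm_scores.tsv").open() as fh:
        next(fh)
        for line in fh:
            arm, s = line.split("\t")
            scores[arm] = float(s)
    meta = json.loads((data / "synthetic_arm_scores.json").read_text())
    return scores, meta["normal_survival_probability"]
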