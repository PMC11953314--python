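"""Shared fixtures: toy genomes small enough for brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from cinsim.graph import GenomeGraph
from cinsim.reference import ReferenceDescriptor


@pytest.fixture
def toy_ref() -> ReferenceDescriptor:
    """Two 10-kb chromosomes, 500-bp telomeres, centromere 4500-5500."""
    return ReferenceDescriptor.synthetic(
        n_chromosomes=2, length=10_000, telomere_length=500)


@pytest.fixture
def toy_genome(toy_ref) -> GenomeGraph:
    return GenomeGraph.diploid(toy_ref)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def per_base_cn(genome: GenomeGraph) -> dict[tuple[str, str], np.ndarray]:
    """Brute-force per-base copy number counter (the CN oracle)."""
    out = {}
    for spec in genome.ref:
        for hap in ("A", "B"):
            out[(spec.name, hap)] = np.zeros(spec.length, dtype=int)
    for iv in genome.intervals.values():
        out[(iv.chrom, iv.hap)][iv.start - 1:iv.end] += 1
    return out


def per_base_from_profile(profile) -> dict[tuple[str, str], np.ndarray]:
    """Expand a segment profile back to per-base counts."""
    out = {}
    for spec in profile.ref:
        for hap in ("A", "B"):
            out[(spec.name, hap)] = np.zeros(spec.length, dtype=int)
    for seg in profile.segments:
        out[(seg.chrom, seg.hap)][seg.start - 1:seg.end] += seg.cn
    return out
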