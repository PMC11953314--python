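"""Reference genome descriptors.

A :class:`ReferenceDescriptor` holds, for each autosome, its length and the
coordinates of the centromere and the two telomeric ends.  Double-strand
breaks are never placed inside telomeres or centromeres, and centromere
content decides how derivative chromosomes segregate at mitosis, so these
intervals are the only sequence annotation the simulator needs — no FASTA is
ever read.

Coordinates are 1-based and closed throughout the package.  Built-in tables
for the 22 human autosomes are provided for GRCh38 (default) and GRCh37;
small synthetic genomes used in tests are built with
:meth:`ReferenceDescriptor.synthetic`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

#: default telomere length (bp) at each chromosome end
DEFAULT_TELOMERE_LENGTH = 10_000

# Autosome lengths (bp).
GRCH38_LENGTHS = {
    "1": 248_956_422, "2": 242_193_529, "3": 198_295_559, "4": 190_214_555,
    "5": 181_538_259, "6": 170_805_979, "7": 159_345_973, "8": 145_138_636,
    "9": 138_394_717, "10": 133_797_422, "11": 135_086_622, "12": 133_275_309,
    "13": 114_364_328, "14": 107_043_718, "15": 101_991_189, "16": 90_338_345,
    "17": 83_257_441, "18": 80_373_285, "19": 58_617_616, "20": 64_444_167,
    "21": 46_709_983, "22": 50_818_468,
}

# UCSC centromere-track coordinates, rounded to 100 kb.
GRCH38_CENTROMERES = {
    "1": (121_700_000, 125_100_000), "2": (91_800_000, 96_000_000),
    "3": (87_800_000, 94_000_000), "4": (48_200_000, 51_800_000),
    "5": (46_100_000, 50_000_000), "6": (58_500_000, 59_800_000),
    "7": (58_100_000, 60_100_000), "8": (43_200_000, 47_200_000),
    "9": (42_200_000, 45_500_000), "10": (38_000_000, 41_600_000),
    "11": (51_000_000, 55_800_000), "12": (33_200_000, 37_800_000),
    "13": (16_500_000, 18_900_000), "14": (16_100_000, 18_200_000),
    "15": (17_500_000, 20_500_000), "16": (35_300_000, 38_400_000),
    "17": (22_700_000, 27_400_000), "18": (15_400_000, 21_500_000),
    "19": (24_200_000, 28_100_000), "20": (25_700_000, 30_400_000),
    "21": (10_900_000, 13_000_000), "22": (13_700_000, 17_400_000),
}

GRCH37_LENGTHS = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566,
}

# GRCh37 gap-track centromere intervals (3 Mb gaps).
GRCH37_CENTROMERES = {
    "1": (121_535_434, 124_535_434), "2": (92_326_171, 95_326_171),
    "3": (90_504_854, 93_504_854), "4": (49_660_117, 52_660_117),
    "5": (46_405_641, 49_405_641), "6": (58_830_166, 61_830_166),
    "7": (58_054_331, 61_054_331), "8": (43_838_887, 46_838_887),
    "9": (47_367_679, 50_367_679), "10": (39_254_935, 42_254_935),
    "11": (51_644_205, 54_644_205), "12": (34_856_694, 37_856_694),
    "13": (16_000_000, 19_000_000), "14": (16_000_000, 19_000_000),
    "15": (17_000_000, 20_000_000), "16": (35_335_801, 38_335_801),
    "17": (22_263_006, 25_263_006), "18": (15_460_898, 18_460_898),
    "19": (24_681_782, 27_681_782), "20": (26_369_569, 29_369_569),
    "21": (11_288_129, 14_288_129), "22": (13_000_000, 16_000_000),
}

_BUILTINS = {
    "GRCh38": (GRCH38_LENGTHS, GRCH38_CENTROMERES),
    "GRCh37": (GRCH37_LENGTHS, GRCH37_CENTROMERES),
}


class ReferenceError_(ValueError):
    """Malformed reference descriptor."""


@dataclass(frozen=True)
class ChromSpec:
    """Coordinate annotation for one autosome (1-based, closed intervals)."""

    name: str
    length: int
    centromere: tuple[int, int]
    telomere_left: tuple[int, int]
    telomere_right: tuple[int, int]

    def validate(self) -> None:
        cs, ce = self.centromere
        tl, tr = self.telomere_left, self.telomere_right
        if self.length < 1:
            raise ReferenceError_(f"chrom {self.name}: non-positive length")
        for lo, hi in (self.centromere, tl, tr):
            if not (1 <= lo <= hi <= self.length):
                raise ReferenceError_(
                    f"chrom {self.name}: interval ({lo},{hi}) outside [1,{self.length}]"
                )
        if tl[0] != 1 or tr[1] != self.length:
            raise ReferenceError_(f"chrom {self.name}: telomeres must sit at the ends")
        if cs <= tl[1] or ce >= tr[0]:
            raise ReferenceError_(
                f"chrom {self.name}: centromere overlaps a telomere"
            )


@dataclass(frozen=True)
class Arm:
    """A chromosome arm: everything on one side of the centromere."""

    chrom: str
    arm: str  # 'p' or 'q'
    start: int
    end: int

    @property
    def name(self) -> str:
        return f"{self.chrom}{self.arm}"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class ReferenceDescriptor:
    """Per-autosome lengths plus centromere/telomere intervals.

    Parameters
    ----------
    chromosomes:
        Mapping of chromosome name to :class:`ChromSpec`.
    assembly:
        ``"GRCh38"``, ``"GRCh37"`` or ``"synthetic"``.  The human tags
        require exactly the 22 autosomes; synthetic descriptors may have any
        number of chromosomes (sex chromosomes are never modelled).
    """

    def __init__(self, chromosomes: dict[str, ChromSpec], assembly: str = "synthetic"):
        self.chromosomes = dict(chromosomes)
        self.assembly = assembly
        self.validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def builtin(cls, assembly: str = "GRCh38",
                telomere_length: int = DEFAULT_TELOMERE_LENGTH) -> "ReferenceDescriptor":
        """Built-in human autosome tables (GRCh38 or GRCh37)."""
        try:
            lengths, cens = _BUILTINS[assembly]
        except KeyError:
            raise ReferenceError_(f"unknown builtin assembly {assembly!r}") from None
        chroms = {
            name: ChromSpec(
                name=name, length=ln, centromere=cens[name],
                telomere_left=(1, telomere_length),
                telomere_right=(ln - telomere_length + 1, ln),
            )
            for name, ln in lengths.items()
        }
        return cls(chroms, assembly=assembly)

    @classmethod
    def synthetic(cls, n_chromosomes: int = 2, length: int = 10_000,
                  telomere_length: int = 500,
                  centromere_fraction: float = 0.1) -> "ReferenceDescriptor":
        """Small deterministic genome for tests and toy oracles.

        Chromosomes are named "1".."n", all of the same length, with the
        centromere centred on the chromosome.
        """
        half = int(length * centromere_fraction / 2)
        mid = length // 2
        chroms = {}
        for i in range(1, n_chromosomes + 1):
            name = str(i)
            chroms[name] = ChromSpec(
                name=name, length=length,
                centromere=(mid - half, mid + half),
                telomere_left=(1, telomere_length),
                telomere_right=(length - telomere_length + 1, length),
            )
        return cls(chroms, assembly="synthetic")

    # -- validation & access ----------------------------------------------

    def validate(self) -> None:
        if not self.chromosomes:
            raise ReferenceError_("descriptor has no chromosomes")
        for name, spec in self.chromosomes.items():
            if name != spec.name:
                raise ReferenceError_(f"key {name!r} != spec name {spec.name!r}")
            spec.validate()
        if self.assembly in _BUILTINS and len(self.chromosomes) != 22:
            raise ReferenceError_(
                f"{self.assembly} descriptor must have 22 autosomes, "
                f"got {len(self.chromosomes)}"
            )

    def __iter__(self) -> Iterator[ChromSpec]:
        return iter(self.chromosomes.values())

    def __getitem__(self, name: str) -> ChromSpec:
        return self.chromosomes[name]

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def __len__(self) -> int:
        return len(self.chromosomes)

    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    def total_length(self) -> int:
        return sum(c.length for c in self)

    # -- regions -----------------------------------------------------------

    def is_excluded(self, chrom: str, pos: int) -> bool:
        """True if ``pos`` falls in a telomere or centromere (no DSBs there)."""
        spec = self.chromosomes[chrom]
        for lo, hi in (spec.centromere, spec.telomere_left, spec.telomere_right):
            if lo <= pos <= hi:
                return True
        return False

    def arms(self) -> list[Arm]:
        """p/q arms flanking each centromere, in chromosome order."""
        out = []
        for spec in self:
            cs, ce = spec.centromere
            out.append(Arm(spec.name, "p", 1, cs - 1))
            out.append(Arm(spec.name, "q", ce + 1, spec.length))
        return out

    def arm_names(self) -> list[str]:
        return [a.name for a in self.arms()]

    def __repr__(self) -> str:  # pragma: no cover
        return (f"ReferenceDescriptor({self.assembly}, "
                f"{len(self.chromosomes)} chromosomes)")
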