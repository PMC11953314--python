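"""Copy-number fitness: survival probability, selection coefficient, rates.

A cell's fitness is scored from its arm-level (default) or chromosome-level
average total copy numbers ``c_i`` and per-region oncogene/tumour-suppressor
(OG-TSG) potency scores ``s_i``:

    P_survival = exp(d * sum_i c_i * s_i + c),

with the published constants ``d = 0.00039047`` and ``c = -0.036132164``;
for a normal diploid genome with the published score table this evaluates
to 0.9689715.  The probability that a daughter cell survives is
``alpha = P_survival ** S``, where ``S > 0`` tunes the strength of
selection (monotone for ``S <= 15``).  Each division produces 0, 1 or 2
surviving offspring with probabilities ``(1-alpha)^2``,
``alpha*(1-alpha)``, ``alpha^2``, so the mean offspring number is
``R = alpha * (1 + alpha)`` and the net growth rate obeys
``b - d_rate = ln(alpha * (1 + alpha))``.  The selection coefficient of a
daughter relative to the normal baseline is

    s = ln(alpha1 * (1 + alpha1)) / ln(alpha0 * (1 + alpha0)) - 1,

and the daughter's rates are set so its net growth rate is ``(1 + s)``
times the baseline's, holding the death rate fixed (which keeps birth
rates non-negative for ``s > -1``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .graph import GenomeGraph
from .reference import ReferenceDescriptor

#: published coefficients of the survival-probability model
FITNESS_D = 0.00039047
FITNESS_C = -0.036132164


class FitnessError(ValueError):
    pass


@dataclass
class FitnessParams:
    """Selection model configuration.

    ``scores`` maps region name ("1p", "1q", ... for arm granularity;
    "1", "2", ... for chromosome granularity) to its OG-TSG score.
    ``mode='neutral'`` disables selection entirely (all cells keep the
    baseline rates).
    """

    scores: Mapping[str, float] = field(default_factory=dict)
    S: float = 1.0
    mode: str = "selection"      # 'selection' | 'neutral'
    granularity: str = "arm"     # 'arm' | 'chromosome'
    d: float = FITNESS_D
    c: float = FITNESS_C

    def __post_init__(self) -> None:
        if self.S <= 0:
            raise FitnessError("S must be positive")
        if self.mode not in ("selection", "neutral"):
            raise FitnessError(f"unknown mode {self.mode!r}")
        if self.granularity not in ("arm", "chromosome"):
            raise FitnessError(f"unknown granularity {self.granularity!r}")
        for k, v in self.scores.items():
            if not math.isfinite(v):
                raise FitnessError(f"score for {k} is not finite")

    @classmethod
    def neutral(cls) -> "FitnessParams":
        return cls(mode="neutral")


@dataclass
class CellRates:
    """Birth/death rates of one cell plus its fitness quantities."""

    birth: float
    death: float
    alpha: float = 1.0
    s: float = 0.0
    clamped: bool = False

    @property
    def net(self) -> float:
        return self.birth - self.death

    @property
    def total(self) -> float:
        return self.birth + self.death


def survival_probability(region_cn: Mapping[str, float],
                         params: FitnessParams) -> float:
    """Evaluate the survival-probability formula, clamped to <= 1.

    ``region_cn`` maps region name to its average total copy number; every
    region must have a score.
    """
    total = 0.0
    for name, cn in region_cn.items():
        try:
            s_i = params.scores[name]
        except KeyError:
            raise FitnessError(f"no OG-TSG score for region {name!r}") from None
        total += cn * s_i
    return min(math.exp(params.d * total + params.c), 1.0)


def cell_survival_probability(genome: GenomeGraph,
                              params: FitnessParams) -> float:
    """Survival probability of a cell from its genome graph."""
    return survival_probability(
        genome.arm_average_cn(params.granularity), params)


def normal_survival_probability(ref: ReferenceDescriptor,
                                params: FitnessParams) -> float:
    """Survival probability of the pristine diploid genome (all c_i = 2)."""
    if params.granularity == "arm":
        names = ref.arm_names()
    else:
        names = ref.names
    return survival_probability({n: 2.0 for n in names}, params)


def _log_growth(alpha: float) -> float:
    r = alpha * (1.0 + alpha)
    if r <= 0.0:
        raise FitnessError("alpha*(1+alpha) must be positive")
    val = math.log(r)
    if abs(val) < 1e-12:
        raise FitnessError(
            "alpha*(1+alpha) = 1 (alpha at the golden-ratio root); "
            "selection coefficient undefined")
    return val


def selection_coefficient(alpha0: float, alpha1: float) -> float:
    """Selection coefficient of a daughter (alpha1) vs baseline (alpha0)."""
    for a in (alpha0, alpha1):
        if not (0.0 < a <= 1.0):
            raise FitnessError(f"alpha {a} outside (0, 1]")
    return _log_growth(alpha1) / _log_growth(alpha0) - 1.0


def baseline_rates(ref: ReferenceDescriptor, params: FitnessParams,
                   birth: Optional[float] = None,
                   death: float = 0.0) -> CellRates:
    """Baseline rates of the normal cell.

    Under selection the default birth rate is ``ln(alpha0*(1+alpha0))``
    with zero death rate, so the Eq.-style identity
    ``b - d = ln(alpha*(1+alpha))`` holds exactly along the lineage; in
    neutral mode the (arbitrary) default is birth 1, death 0.
    """
    if params.mode == "neutral":
        return CellRates(birth=1.0 if birth is None else birth, death=death)
    alpha0 = normal_survival_probability(ref, params) ** params.S
    b = _log_growth(alpha0) + death if birth is None else birth
    return CellRates(birth=b, death=death, alpha=alpha0, s=0.0)


def update_rates(baseline: CellRates, s: float,
                 alpha: float = 1.0) -> CellRates:
    """Daughter rates with net growth ``(1+s)`` times the baseline's.

    The death rate is held fixed; a birth rate driven below zero is
    clamped (and flagged), which can occur for strongly deleterious
    karyotypes with ``s < -1``.
    """
    if baseline.net <= 0:
        raise FitnessError("baseline must have positive net growth")
    net = (1.0 + s) * baseline.net
    birth = baseline.death + net
    clamped = birth < 0.0
    if clamped:
        birth = 0.0
    return CellRates(birth=birth, death=baseline.death, alpha=alpha, s=s,
                     clamped=clamped)


def daughter_rates(genome: GenomeGraph, baseline: CellRates,
                   params: FitnessParams) -> CellRates:
    """Full pipeline: genome -> survival probability -> alpha -> s -> rates.

    In neutral mode every daughter keeps the baseline rates (s = 0).
    """
    if params.mode == "neutral":
        return CellRates(birth=baseline.birth, death=baseline.death)
    p = cell_survival_probability(genome, params)
    alpha1 = p ** params.S
    s = selection_coefficient(baseline.alpha, alpha1)
    return update_rates(baseline, s, alpha=alpha1)


def offspring_distribution(alpha: float) -> tuple[float, float, float]:
    """(p0, p1, p2): probabilities of 0/1/2 surviving offspring."""
    return ((1.0 - alpha) ** 2, alpha * (1.0 - alpha), alpha ** 2)
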