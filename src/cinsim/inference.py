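"""Likelihood-free inference of (DSB rate, unrepaired fraction, WGD
probability) by ABC sequential Monte Carlo.

The sampler is the standard SMC scheme for approximate Bayesian
computation: an initial population of particles is drawn from the prior
(every simulated dataset accepted), and each subsequent population resamples
particles from the previous one by importance weight, perturbs them with a
component-wise Gaussian kernel (SD = sqrt(2) times the weighted SD of the
previous population, truncated to the prior support) and accepts a particle
when the distance between its simulated and the observed summary statistics
falls below the current tolerance.  Tolerances follow the median of the
previously accepted distances and the run stops at the target tolerance, at
the simulation budget, or when the tolerance improves by less than 5%
between populations.

The distance is Euclidean over the summary-statistic vector with each
component scaled by ``max(|observed component|, 0.01)``.

Posterior predictive checks re-simulate at parameters drawn from the
weighted posterior and report, per component, whether the observed value
lies within two standard deviations of the predictive distribution; the
fraction of components that do is the fit statistic ``P_w``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .sumstats import SummaryStats

DISTANCE_FLOOR = 0.01


class InferenceError(RuntimeError):
    pass


@dataclass
class Prior:
    """Independent uniform priors, one per parameter."""

    names: Sequence[str]
    lows: Sequence[float]
    highs: Sequence[float]

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.lows) == len(self.highs)):
            raise ValueError("prior columns must have equal length")
        for name, lo, hi in zip(self.names, self.lows, self.highs):
            if not lo < hi:
                raise ValueError(f"prior for {name}: lower must be < upper")
        self.lows = np.asarray(self.lows, dtype=float)
        self.highs = np.asarray(self.highs, dtype=float)

    @classmethod
    def default(cls, dsb_rate_max: float = 50.0) -> "Prior":
        """r ~ U[0, M] (M = 50 or 100), f_u ~ U[0,1], p_w ~ U[0,1]."""
        return cls(names=("dsb_rate", "f_u", "p_w"),
                   lows=(0.0, 0.0, 0.0),
                   highs=(dsb_rate_max, 1.0, 1.0))

    @property
    def dim(self) -> int:
        return len(self.names)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.lows, self.highs)

    def in_support(self, theta: np.ndarray) -> bool:
        return bool(np.all(theta >= self.lows) and np.all(theta <= self.highs))


@dataclass
class SMCConfig:
    """SMC schedule parameters (defaults follow the full-scale protocol:
    500 particles, 1e6 simulations, target tolerance 0.2)."""

    n_particles: int = 500
    max_simulations: int = 1_000_000
    eps_target: float = 0.2
    quantile: float = 0.5
    plateau: float = 0.05       # stop when eps improves by < 5%
    max_populations: int = 30

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        if self.eps_target <= 0:
            raise ValueError("target tolerance must be positive")


@dataclass
class SMCPosterior:
    """Weighted particles approximating the posterior."""

    names: Sequence[str]
    particles: np.ndarray       # (n, dim)
    weights: np.ndarray         # (n,), sums to 1
    distances: np.ndarray       # (n,)
    eps_schedule: list[float]
    n_simulations: int
    converged: bool

    def mean(self) -> np.ndarray:
        return self.weights @ self.particles

    def sd(self) -> np.ndarray:
        mu = self.mean()
        var = self.weights @ (self.particles - mu) ** 2
        return np.sqrt(var)

    def ess(self) -> float:
        return float(1.0 / np.sum(self.weights ** 2))

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        idx = rng.choice(len(self.weights), size=n, p=self.weights)
        return self.particles[idx]


def distance(obs: SummaryStats | np.ndarray,
             sim: SummaryStats | np.ndarray) -> float:
    """Scaled Euclidean distance between two summary-statistic vectors."""
    a = obs.to_vector() if isinstance(obs, SummaryStats) else np.asarray(obs)
    b = sim.to_vector() if isinstance(sim, SummaryStats) else np.asarray(sim)
    if a.shape != b.shape:
        raise InferenceError(
            f"summary-statistic layouts differ: {a.shape} vs {b.shape}")
    scale = np.maximum(np.abs(a), DISTANCE_FLOOR)
    return float(np.sqrt(np.sum(((a - b) / scale) ** 2)))


Simulator = Callable[[np.ndarray, np.random.Generator],
                     Optional[SummaryStats]]


class ABCSMC:
    """ABC SMC driver.

    ``simulator(theta, rng)`` maps a parameter vector to a
    :class:`SummaryStats` (or ``None`` for a failed run, e.g. extinction;
    such runs count against the budget and are rejected).
    """

    def __init__(self, simulator: Simulator, prior: Prior,
                 config: Optional[SMCConfig] = None):
        self.simulator = simulator
        self.prior = prior
        self.config = config if config is not None else SMCConfig()

    # fit-style entry point
    def fit(self, observed: SummaryStats,
            rng: Optional[np.random.Generator] = None,
            seed: Optional[int] = None) -> SMCPosterior:
        if rng is None:
            rng = np.random.default_rng(seed)
        cfg = self.config
        obs_vec = observed.to_vector()
        n_sim = 0

        # population 0: plain prior draws, all finite distances accepted
        thetas, dists = [], []
        while len(thetas) < cfg.n_particles and n_sim < cfg.max_simulations:
            theta = self.prior.sample(rng)
            stats = self.simulator(theta, rng)
            n_sim += 1
            if stats is None:
                continue
            thetas.append(theta)
            dists.append(distance(obs_vec, stats.to_vector()))
        if len(thetas) < 2:
            raise InferenceError(
                "simulation budget exhausted before an initial population "
                "could be formed")
        particles = np.array(thetas)
        distances_ = np.array(dists)
        weights = np.full(len(particles), 1.0 / len(particles))
        eps_schedule: list[float] = []
        eps = float(np.quantile(distances_, cfg.quantile))
        converged = eps <= cfg.eps_target

        for _pop in range(cfg.max_populations):
            if converged or n_sim >= cfg.max_simulations:
                break
            eps = max(eps, cfg.eps_target)
            eps_schedule.append(eps)
            kernel_sd = np.sqrt(2.0) * _weighted_sd(particles, weights)
            kernel_sd = np.maximum(kernel_sd, 1e-9)
            new_parts, new_dists, new_weights = [], [], []
            while len(new_parts) < cfg.n_particles \
                    and n_sim < cfg.max_simulations:
                theta = self._perturb(particles, weights, kernel_sd, rng)
                stats = self.simulator(theta, rng)
                n_sim += 1
                if stats is None:
                    continue
                d = distance(obs_vec, stats.to_vector())
                if d > eps:
                    continue
                new_parts.append(theta)
                new_dists.append(d)
                new_weights.append(
                    _importance_weight(theta, particles, weights, kernel_sd))
            if len(new_parts) < 2:
                warnings.warn("acceptance starved; returning the previous "
                              "population as a partial result")
                break
            particles = np.array(new_parts)
            distances_ = np.array(new_dists)
            w = np.array(new_weights)
            weights = w / w.sum()
            new_eps = float(np.quantile(distances_, cfg.quantile))
            if eps <= cfg.eps_target:
                converged = True
            elif eps > 0 and (eps - new_eps) / eps < cfg.plateau:
                break  # tolerance plateau: < 5% improvement
            eps = new_eps

        return SMCPosterior(
            names=self.prior.names, particles=particles, weights=weights,
            distances=distances_, eps_schedule=eps_schedule,
            n_simulations=n_sim, converged=converged)

    def _perturb(self, particles: np.ndarray, weights: np.ndarray,
                 kernel_sd: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
        for _ in range(1000):
            base = particles[rng.choice(len(particles), p=weights)]
            theta = base + rng.normal(0.0, kernel_sd)
            if self.prior.in_support(theta):
                return theta
        raise InferenceError("perturbation kernel cannot reach prior support")


def _weighted_sd(particles: np.ndarray, weights: np.ndarray) -> np.ndarray:
    mu = weights @ particles
    return np.sqrt(weights @ (particles - mu) ** 2)


def _importance_weight(theta: np.ndarray, particles: np.ndarray,
                       weights: np.ndarray,
                       kernel_sd: np.ndarray) -> float:
    # uniform prior density is constant on support -> weight = 1 / sum_j w_j K;
    # the kernel's normalisation constant cancels after weight normalisation
    z = (theta[None, :] - particles) / kernel_sd[None, :]
    log_k = -0.5 * np.sum(z ** 2, axis=1)
    m = float(log_k.max())
    log_denom = m + np.log(max(float(weights @ np.exp(log_k - m)), 1e-300))
    return float(np.exp(-log_denom))


def run_abc_smc(observed: SummaryStats, prior: Prior, simulator: Simulator,
                config: Optional[SMCConfig] = None,
                seed: Optional[int] = None) -> SMCPosterior:
    """Functional wrapper over :class:`ABCSMC`."""
    return ABCSMC(simulator, prior, config).fit(observed, seed=seed)


# ---------------------------------------------------------------------------
# posterior predictive


@dataclass
class PredictiveResult:
    thetas: np.ndarray
    stats: np.ndarray                 # (n_ok, n_components)
    fusions_per_cycle: list[float] = field(default_factory=list)
    ecdna_per_cell: list[float] = field(default_factory=list)


def posterior_predictive(posterior: SMCPosterior, simulator: Simulator,
                         n: int = 500,
                         rng: Optional[np.random.Generator] = None,
                         seed: Optional[int] = None,
                         extras: Optional[Callable] = None
                         ) -> PredictiveResult:
    """Simulate ``n`` datasets at parameters drawn from the posterior.

    ``extras(stats)`` may capture additional per-draw quantities; by
    default the summary vectors alone are recorded (event rates are
    attached by the population-aware wrapper in the CLI layer).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if len(posterior.weights) == 0:
        raise InferenceError("posterior is empty")
    thetas, vectors = [], []
    for _ in range(n):
        theta = posterior.sample(rng)[0]
        stats = simulator(theta, rng)
        if stats is None:
            continue
        thetas.append(theta)
        vectors.append(stats.to_vector())
    if not vectors:
        raise InferenceError("all predictive simulations failed")
    return PredictiveResult(thetas=np.array(thetas),
                            stats=np.vstack(vectors))


def make_simulator(ref, fitness_params=None, n_cells: int = 10,
                   bin_size: int = 500_000,
                   cycle_defaults=None) -> Simulator:
    """Simulator closure for the default inference setup.

    ``theta = (dsb_rate, f_u, p_w)`` is plugged into a Poisson-DSB cell
    cycle with distance-based repair, ``p_r = 0``, no local fragmentation,
    DSBs at every cycle, and selection strength ``S = 1`` (or neutral if
    ``fitness_params`` is ``None``); the population is grown to
    ``n_cells`` and summarised.  Extinct runs return ``None``.
    """
    from dataclasses import replace as _replace

    from .cycle import CycleParams
    from .fitness import FitnessParams
    from .population import run_to_size, SimulationParams
    from .sumstats import compute_summary_stats

    if fitness_params is None:
        fitness_params = FitnessParams.neutral()
    if cycle_defaults is None:
        cycle_defaults = CycleParams(dsb_rate=0.0, repair_mode="distance",
                                     p_r=0.0, m_l=0.0, n_d=None)

    def simulate(theta: np.ndarray,
                 rng: np.random.Generator) -> Optional[SummaryStats]:
        r, f_u, p_w = (float(theta[0]), float(theta[1]), float(theta[2]))
        cycle = _replace(cycle_defaults, dsb_rate=r,
                         f_u=min(max(f_u, 0.0), 1.0),
                         p_w=min(max(p_w, 0.0), 1.0))
        params = SimulationParams(n_cells=n_cells, cycle=cycle,
                                  fitness=fitness_params)
        pop = run_to_size(params, ref=ref, rng=rng)
        if pop.terminal != "reached_n":
            return None
        return compute_summary_stats(pop.alive, ref, bin_size)

    return simulate


def compute_pw(observed: SummaryStats | np.ndarray,
               predictive: PredictiveResult | np.ndarray) -> float:
    """Fraction of summary-statistic components whose observed value lies
    within two SDs of the posterior predictive distribution.

    A zero-SD component counts as within only when the observation equals
    the predictive mean exactly.
    """
    obs = (observed.to_vector() if isinstance(observed, SummaryStats)
           else np.asarray(observed))
    mat = (predictive.stats if isinstance(predictive, PredictiveResult)
           else np.asarray(predictive))
    if mat.ndim != 2 or mat.shape[1] != obs.shape[0]:
        raise InferenceError("predictive matrix does not match observation")
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0)
    within = np.where(sd > 0.0,
                      np.abs(obs - mean) <= 2.0 * sd,
                      np.abs(obs - mean) == 0.0)
    return float(within.mean())
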