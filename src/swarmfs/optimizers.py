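"""Binary swarm metaheuristics over feature masks.

Four population-based optimizers — whale (WO), grey wolf (GWO), ant colony
(ACO) and particle swarm (PSO) — minimize the wrapper objective of
:mod:`swarmfs.fitness` over the ``2^D - 1`` non-empty feature subsets.
Defaults follow the reference setting: 10 search agents, 50 iterations,
KNN(K=5) fitness.

WO, GWO and PSO search in a continuous position space; a position component
``x_d`` maps to a selection probability through the sigmoid transfer function
``T(x) = 1 / (1 + exp(-x))`` and the mask bit is drawn stochastically
(``bit_d = 1`` iff ``u_d < T(x_d)``), with an all-zero repair that forces the
single highest-probability feature on.  ACO has no natural continuous
position: it is specialized to a per-feature node formulation where each ant
samples features without replacement proportionally to
``tau_j^alpha * eta_j^beta`` (pheromone x heuristic desirability) until a
geometric stopping draw fires.

Update rules, per agent and iteration (t = 0..T-1, a = 2(1 - t/T)):

- WO: with probability 1/2 the spiral (bubble-net) move toward the incumbent
  best, ``x' = x* + |x* - x| e^{b l} cos(2 pi l)`` with ``l ~ U(-1, 1)``;
  otherwise the encircling move ``x' = x* - A |C x* - x|`` with
  ``A = 2 a r1 - a``, ``C = 2 r2``, switching per dimension to a randomly
  chosen agent instead of the best where ``|A| >= 1`` (exploration).
- GWO: the three fittest agents (alpha, beta, delta) each propose a candidate
  ``x_m - A |C x_m - x|``; the new position is the mean of the candidates.
- PSO: ``v' = omega v + c1 r1 (pbest - x) + c2 r2 (gbest - x)`` (clamped),
  ``x' = x + v'``, with inertia omega annealed linearly 0.9 -> 0.4.
- ACO: per-feature pheromone evaporates at rate rho and the iteration-best
  mask deposits ``Q / (fitness + eps)`` on its features, clamped to
  ``[tau_min, tau_max]``.

Every optimizer is elitist: the best mask ever evaluated is tracked and
returned, so the best-so-far trace is non-increasing by construction.
One master seed spawns an independent random substream per agent, so runs
are bit-reproducible and population-size changes do not reshuffle the
surviving agents' draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin, f_classif
from sklearn.utils.validation import check_is_fitted, validate_data

from .data import FeatureMask, FeatureTable
from .fitness import FitnessEvaluator, FitnessSpec

__all__ = [
    "ALGORITHMS",
    "OptimizerConfig",
    "PheromoneState",
    "SearchAgent",
    "Trace",
    "binarize",
    "sigmoid",
    "wo_step",
    "gwo_step",
    "pso_step",
    "aco_feature_prob",
    "aco_construct",
    "aco_update_pheromone",
    "optimize",
    "SwarmFeatureSelector",
]

ALGORITHMS = ("WO", "GWO", "ACO", "PSO")


@dataclass
class OptimizerConfig:
    """Swarm settings; defaults are the reference setting (10 agents, 50 iterations)."""

    algorithm: str = "WO"
    population: int = 10
    iterations: int = 50
    seed: int = 0
    # whale: spiral shape constant b
    wo_spiral_b: float = 1.0
    # ant colony: pheromone/heuristic exponents, evaporation, deposit scale,
    # geometric stopping probability (None -> 2/D, expected subset ~ D/2)
    aco_alpha: float = 1.0
    aco_beta: float = 1.0
    aco_rho: float = 0.2
    aco_q: float = 1.0
    aco_p_stop: float | None = None
    aco_tau_min: float = 0.01
    aco_tau_max: float = 10.0
    # particle swarm: inertia schedule, learning factors, velocity clamp
    pso_omega_start: float = 0.9
    pso_omega_end: float = 0.4
    pso_c1: float = 2.0
    pso_c2: float = 2.0
    pso_v_clamp: float = 6.0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}")
        if self.population < 1:
            raise ValueError("population must be >= 1")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")


@dataclass
class SearchAgent:
    """One candidate solution: continuous position, derived mask, fitness."""

    position: np.ndarray
    mask: FeatureMask | None = None
    fit: float = np.inf
    velocity: np.ndarray | None = None  # PSO only
    pbest_position: np.ndarray | None = None  # PSO only
    pbest_fit: float = np.inf  # PSO only


@dataclass
class PheromoneState:
    """ACO per-feature pheromone tau and heuristic desirability eta."""

    tau: np.ndarray
    eta: np.ndarray

    def __post_init__(self) -> None:
        if (self.tau <= 0).any():
            raise ValueError("pheromone tau must be positive")
        if (self.eta < 0).any():
            raise ValueError("heuristic eta must be non-negative")


@dataclass
class Trace:
    """Per-iteration log: best-so-far fitness, its mask size, evaluation count."""

    best_fitness: list[float] = field(default_factory=list)
    best_mask_size: list[int] = field(default_factory=list)
    n_evaluations: list[int] = field(default_factory=list)

    def append(self, fit: float, size: int, evals: int) -> None:
        self.best_fitness.append(float(fit))
        self.best_mask_size.append(int(size))
        self.n_evaluations.append(int(evals))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(len(self.best_fitness)),
                "best_fitness": self.best_fitness,
                "best_mask_size": self.best_mask_size,
                "n_evaluations": self.n_evaluations,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def binarize(position: np.ndarray, rng: np.random.Generator) -> FeatureMask:
    """Stochastic sigmoid thresholding of a continuous position.

    ``bit_d = 1`` iff ``u_d < T(x_d)`` with ``u_d ~ U(0,1)``.  An all-zero
    outcome is repaired by forcing the single highest-probability feature on.
    """
    t = sigmoid(np.asarray(position, dtype=float))
    bits = (rng.random(len(t)) < t).astype(np.uint8)
    if bits.sum() == 0:
        bits[int(np.argmax(t))] = 1
    return FeatureMask(bits=bits)


# ---------------------------------------------------------------------------
# Per-agent update rules
# ---------------------------------------------------------------------------

def wo_step(
    position: np.ndarray,
    best_position: np.ndarray,
    a: float,
    rng: np.random.Generator,
    others: Sequence[np.ndarray] | None = None,
    spiral_b: float = 1.0,
) -> np.ndarray:
    """One whale move: spiral toward the best, or encircle/explore.

    Draw order: branch probability p, then (spiral) l ~ U(-1,1), or
    (encircling) per-dimension r1, r2 and one random-agent index.
    """
    position = np.asarray(position, dtype=float)
    best_position = np.asarray(best_position, dtype=float)
    p = rng.random()
    if p < 0.5:
        l = rng.uniform(-1.0, 1.0)
        dist = np.abs(best_position - position)
        return best_position + dist * np.exp(spiral_b * l) * np.cos(2.0 * np.pi * l)
    d = len(position)
    r1 = rng.random(d)
    r2 = rng.random(d)
    big_a = 2.0 * a * r1 - a
    big_c = 2.0 * r2
    if others is not None and len(others) > 0:
        rand_ref = np.asarray(others[int(rng.integers(len(others)))], dtype=float)
    else:
        rand_ref = best_position
    # exploit (|A| < 1): move about the best; explore (|A| >= 1): about a random agent
    ref = np.where(np.abs(big_a) < 1.0, best_position, rand_ref)
    return ref - big_a * np.abs(big_c * ref - position)


def gwo_step(
    position: np.ndarray,
    leader_positions: Sequence[np.ndarray],
    a: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One grey-wolf move: mean of the leader-guided candidates.

    Each leader m proposes ``x_m - A |C x_m - x|`` with fresh per-dimension
    ``A = 2 a r1 - a`` and ``C = 2 r2``.  Canonically three leaders (alpha,
    beta, delta); with a smaller population the available ones are used.
    """
    position = np.asarray(position, dtype=float)
    if len(leader_positions) == 0:
        raise ValueError("gwo_step needs at least one leader")
    d = len(position)
    candidates = []
    for leader in leader_positions:
        leader = np.asarray(leader, dtype=float)
        r1 = rng.random(d)
        r2 = rng.random(d)
        big_a = 2.0 * a * r1 - a
        big_c = 2.0 * r2
        dist = np.abs(big_c * leader - position)
        candidates.append(leader - big_a * dist)
    return np.mean(candidates, axis=0)


def pso_step(
    position: np.ndarray,
    velocity: np.ndarray,
    pbest: np.ndarray,
    gbest: np.ndarray,
    omega: float,
    c1: float,
    c2: float,
    v_clamp: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One particle move; returns (new_velocity, new_position)."""
    position = np.asarray(position, dtype=float)
    d = len(position)
    r1 = rng.random(d)
    r2 = rng.random(d)
    v = (
        omega * np.asarray(velocity, dtype=float)
        + c1 * r1 * (np.asarray(pbest, dtype=float) - position)
        + c2 * r2 * (np.asarray(gbest, dtype=float) - position)
    )
    v = np.clip(v, -v_clamp, v_clamp)
    return v, position + v


# ---------------------------------------------------------------------------
# Ant colony primitives
# ---------------------------------------------------------------------------

def aco_feature_prob(
    tau: np.ndarray,
    eta: np.ndarray,
    candidates: np.ndarray,
    alpha: float = 1.0,
    beta: float = 1.0,
) -> np.ndarray:
    """Selection probabilities ``tau_j^alpha eta_j^beta / sum`` over candidates.

    ``candidates`` is a boolean membership vector; probabilities are zero off
    the candidate set and sum to 1 on it.
    """
    candidates = np.asarray(candidates, dtype=bool)
    if not candidates.any():
        raise ValueError("empty candidate set")
    tau = np.asarray(tau, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if (tau[candidates] <= 0).any() or (eta[candidates] <= 0).any():
        raise ValueError("tau and eta must be positive on the candidate set")
    w = np.zeros(len(tau))
    w[candidates] = tau[candidates] ** alpha * eta[candidates] ** beta
    return w / w.sum()


def aco_construct(
    state: PheromoneState,
    p_stop: float,
    rng: np.random.Generator,
    alpha: float = 1.0,
    beta: float = 1.0,
) -> FeatureMask:
    """One ant builds a mask: sample features without replacement until a
    geometric stopping draw fires (or features run out); never empty."""
    d = len(state.tau)
    bits = np.zeros(d, dtype=np.uint8)
    candidates = np.ones(d, dtype=bool)
    while True:
        p = aco_feature_prob(state.tau, state.eta, candidates, alpha, beta)
        j = int(rng.choice(d, p=p))
        bits[j] = 1
        candidates[j] = False
        if not candidates.any():
            break
        if rng.random() < p_stop:
            break
    return FeatureMask(bits=bits)


def aco_update_pheromone(
    state: PheromoneState,
    evaluated: Sequence[tuple[FeatureMask, float]],
    rho: float = 0.2,
    q: float = 1.0,
    tau_min: float = 0.01,
    tau_max: float = 10.0,
    eps: float = 1e-6,
) -> PheromoneState:
    """Evaporate, then let the best evaluated mask deposit ``q/(fit+eps)``."""
    if len(evaluated) == 0:
        raise ValueError("need at least one evaluated mask")
    tau = (1.0 - rho) * state.tau
    best_mask, best_fit = min(evaluated, key=lambda mf: mf[1])
    tau[best_mask.indices()] += q / (best_fit + eps)
    return PheromoneState(tau=np.clip(tau, tau_min, tau_max), eta=state.eta)


def _aco_heuristic(data: FeatureTable) -> np.ndarray:
    """Per-feature desirability: min-max-scaled one-way F statistic, floored
    at 0.01 so every feature keeps a positive sampling weight."""
    f_stat, _ = f_classif(data.values, data.labels.astype(str))
    f_stat = np.nan_to_num(f_stat, nan=0.0, posinf=0.0, neginf=0.0)
    span = f_stat.max() - f_stat.min()
    scaled = (f_stat - f_stat.min()) / span if span > 0 else np.zeros_like(f_stat)
    return 0.01 + 0.99 * scaled


# ---------------------------------------------------------------------------
# The optimization loop
# ---------------------------------------------------------------------------

def optimize(
    data: FeatureTable,
    fitness_spec: FitnessSpec | None = None,
    config: OptimizerConfig | None = None,
    audit_hook: Callable[[Sequence[str]], None] | None = None,
) -> tuple[FeatureMask, Trace]:
    """Run the configured swarm over feature masks; return the best mask ever
    evaluated and the per-iteration trace.

    The trace has ``iterations + 1`` entries (the random initial population
    counts as iteration 0); with ``iterations=0`` the best initial mask is
    returned.  Fully reproducible under ``config.seed``.
    """
    fitness_spec = fitness_spec or FitnessSpec()
    config = config or OptimizerConfig()
    if len(set(data.labels)) < 2:
        raise ValueError("optimization needs a table with >= 2 classes")
    evaluator = FitnessEvaluator(data, fitness_spec, audit_hook=audit_hook)
    d = data.n_features
    pop, iters = config.population, config.iterations

    streams = np.random.SeedSequence(config.seed).spawn(pop + 1)
    global_rng = np.random.default_rng(streams[0])
    agent_rngs = [np.random.default_rng(s) for s in streams[1:]]

    best_mask: FeatureMask | None = None
    best_fit = np.inf
    trace = Trace()

    def consider(mask: FeatureMask, fit: float) -> None:
        nonlocal best_mask, best_fit
        if fit < best_fit:
            best_mask, best_fit = mask, fit

    if config.algorithm == "ACO":
        state = PheromoneState(tau=np.ones(d), eta=_aco_heuristic(data))
        p_stop = config.aco_p_stop if config.aco_p_stop is not None else 2.0 / d
        for t in range(iters + 1):
            evaluated = []
            for i in range(pop):
                mask = aco_construct(
                    state, p_stop, agent_rngs[i], config.aco_alpha, config.aco_beta
                )
                fit = evaluator(mask)
                evaluated.append((mask, fit))
                consider(mask, fit)
            state = aco_update_pheromone(
                state,
                evaluated,
                rho=config.aco_rho,
                q=config.aco_q,
                tau_min=config.aco_tau_min,
                tau_max=config.aco_tau_max,
            )
            trace.append(best_fit, best_mask.n_selected, evaluator.n_evaluations)
        return best_mask, trace

    # continuous-position algorithms: WO, GWO, PSO
    agents = []
    for i in range(pop):
        pos = agent_rngs[i].uniform(-1.0, 1.0, d)
        agent = SearchAgent(position=pos)
        agent.mask = binarize(pos, agent_rngs[i])
        agent.fit = evaluator(agent.mask)
        if config.algorithm == "PSO":
            agent.velocity = np.zeros(d)
            agent.pbest_position = pos.copy()
            agent.pbest_fit = agent.fit
        consider(agent.mask, agent.fit)
        agents.append(agent)
    best_position = min(agents, key=lambda ag: ag.fit).position.copy()
    trace.append(best_fit, best_mask.n_selected, evaluator.n_evaluations)

    for t in range(iters):
        a = 2.0 * (1.0 - t / iters)
        if config.algorithm == "PSO":
            frac = t / max(1, iters - 1)
            omega = config.pso_omega_start + frac * (
                config.pso_omega_end - config.pso_omega_start
            )
        if config.algorithm == "GWO":
            order = np.argsort([ag.fit for ag in agents], kind="stable")
            leaders = [agents[j].position.copy() for j in order[:3]]
        positions_now = [ag.position.copy() for ag in agents]
        for i, agent in enumerate(agents):
            rng = agent_rngs[i]
            if config.algorithm == "WO":
                agent.position = wo_step(
                    positions_now[i],
                    best_position,
                    a,
                    rng,
                    others=positions_now,
                    spiral_b=config.wo_spiral_b,
                )
            elif config.algorithm == "GWO":
                agent.position = gwo_step(positions_now[i], leaders, a, rng)
            else:  # PSO
                agent.velocity, agent.position = pso_step(
                    positions_now[i],
                    agent.velocity,
                    agent.pbest_position,
                    best_position,
                    omega,
                    config.pso_c1,
                    config.pso_c2,
                    config.pso_v_clamp,
                    rng,
                )
            agent.mask = binarize(agent.position, rng)
            agent.fit = evaluator(agent.mask)
            if config.algorithm == "PSO" and agent.fit < agent.pbest_fit:
                agent.pbest_fit = agent.fit
                agent.pbest_position = agent.position.copy()
            if agent.fit < best_fit:
                best_position = agent.position.copy()
            consider(agent.mask, agent.fit)
        trace.append(best_fit, best_mask.n_selected, evaluator.n_evaluations)
    return best_mask, trace


# ---------------------------------------------------------------------------
# scikit-learn estimator facade
# ---------------------------------------------------------------------------

class SwarmFeatureSelector(SelectorMixin, BaseEstimator):
    """Wrapper feature selection by a binary swarm metaheuristic.

    A scikit-learn transformer: ``fit(X, y)`` runs the configured swarm
    (whale, grey-wolf, ant-colony or particle-swarm) minimizing KNN
    classification error plus a subset-size penalty; ``transform(X)`` keeps
    the selected columns.

    Parameters
    ----------
    algorithm : {"WO", "GWO", "ACO", "PSO"}, default "WO"
    n_agents : int, default 10
        Swarm size (number of candidate solutions).
    n_iterations : int, default 50
    k_neighbors : int, default 5
        K of the KNN fitness function.
    error_weight : float, default 0.99
        Weight w of the error term in ``w*err + (1-w)*|S|/D``.
    validation : tuple, default ("holdout", 0.8)
        Internal fitness validation scheme.
    random_state : int, default 0
    optimizer_params : dict, optional
        Extra :class:`OptimizerConfig` fields (e.g. ``aco_rho``).

    Attributes
    ----------
    support_ : bool ndarray of shape (n_features,)
    mask_ : FeatureMask
    trace_ : Trace
    best_fitness_ : float

    Examples
    --------
    >>> sel = SwarmFeatureSelector(algorithm="PSO", n_iterations=10)
    >>> Xt = sel.fit_transform(X, y)   # doctest: +SKIP
    """

    def __init__(
        self,
        algorithm: str = "WO",
        n_agents: int = 10,
        n_iterations: int = 50,
        k_neighbors: int = 5,
        error_weight: float = 0.99,
        validation: tuple = ("holdout", 0.8),
        random_state: int = 0,
        optimizer_params: dict | None = None,
    ):
        self.algorithm = algorithm
        self.n_agents = n_agents
        self.n_iterations = n_iterations
        self.k_neighbors = k_neighbors
        self.error_weight = error_weight
        self.validation = validation
        self.random_state = random_state
        self.optimizer_params = optimizer_params

    def fit(self, X, y):
        X, y = validate_data(self, X, y, dtype=float)
        table = FeatureTable(
            values=X,
            labels=np.asarray(y, dtype=object),
            feature_names=np.array(
                [f"x{j:04d}" for j in range(X.shape[1])], dtype=object
            ),
        )
        fspec = FitnessSpec(
            k_neighbors=self.k_neighbors,
            error_weight=self.error_weight,
            validation=self.validation,
            seed=int(self.random_state),
        )
        config = OptimizerConfig(
            algorithm=self.algorithm,
            population=self.n_agents,
            iterations=self.n_iterations,
            seed=int(self.random_state),
            **(self.optimizer_params or {}),
        )
        mask, trace = optimize(table, fspec, config)
        self.mask_ = mask
        self.trace_ = trace
        self.support_ = mask.bits.astype(bool)
        self.best_fitness_ = trace.best_fitness[-1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_
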