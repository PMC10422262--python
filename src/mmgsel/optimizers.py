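"""Chameleon swarm and grasshopper optimization over a box-bounded space.

Both are population metaheuristics that maximize an arbitrary fitness
callback.  The chameleon swarm algorithm (CSA) runs three phases per
iteration: a prey-search step mixing exploitation (attraction to personal
and global bests) with exploration (decaying random jumps), an eye-rotation
step that rotates each individual about its own coordinate centroid, and a
velocity-based hunt step with a decaying inertia weight.  The grasshopper
optimization algorithm (GOA) moves each individual under summed pairwise
social forces s(r) = f e^(-r/l) - e^(-r) (short-range repulsion, mid-range
attraction) plus attraction to the best solution found, with a linearly
decaying coefficient c shrinking the search.

All randomness flows from a single ``numpy.random.Generator`` seeded in the
config; runs are deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class OptimizerConfig:
    """Population, budget, bounds and per-algorithm parameters.

    CSA defaults (p1, p2, Pp, sensitivity alpha, c1, c2) and GOA defaults
    (f_attract, l_scale, c_max, c_min) follow the algorithms' original
    references.  ``pop_size``/``max_iter`` default to the light budget used
    for wrapper feature selection, where each evaluation trains classifiers.
    """

    dim: int
    pop_size: int = 20
    max_iter: int = 50
    lb: float | np.ndarray = 0.0
    ub: float | np.ndarray = 1.0
    seed: int = 0
    # CSA
    p1: float = 2.0
    p2: float = 2.0
    pp: float = 0.1
    alpha_csa: float = 4.0
    c1: float = 2.0
    c2: float = 1.8
    p_w: float = 1.0
    a_min: float = 1e-6
    # GOA
    f_attract: float = 0.5
    l_scale: float = 1.5
    c_max: float = 1.0
    c_min: float = 1e-5

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        self.lb = np.broadcast_to(np.asarray(self.lb, dtype=float), (self.dim,)).copy()
        self.ub = np.broadcast_to(np.asarray(self.ub, dtype=float), (self.dim,)).copy()
        if np.any(self.lb > self.ub):
            raise ValueError("lb must not exceed ub")


@dataclass
class SwarmState:
    """Positions, velocities, and best-so-far bookkeeping of a swarm."""

    positions: np.ndarray
    velocities: np.ndarray
    velocities_prev: np.ndarray
    personal_best: np.ndarray
    personal_best_fitness: np.ndarray
    global_best: np.ndarray
    global_best_fitness: float
    iteration: int = 0


@dataclass
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    fitness_history: np.ndarray  # best-so-far after init and each iteration
    evaluations: int


def _clamp(x: np.ndarray, cfg: OptimizerConfig) -> np.ndarray:
    return np.clip(x, cfg.lb, cfg.ub)


def initialize_positions(cfg: OptimizerConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniform positions lb + r (ub - lb) in the box, one row per individual."""
    r = rng.random((cfg.pop_size, cfg.dim))
    return cfg.lb + r * (cfg.ub - cfg.lb)


# --------------------------------------------------------------------------
# CSA phases
# --------------------------------------------------------------------------

def csa_mu(t: int, max_iter: int, alpha: float) -> float:
    """Exploration weight mu = exp(-(alpha t / T)^3), decaying from 1."""
    return float(np.exp(-((alpha * t / max_iter) ** 3)))


def csa_search_update(
    state: SwarmState, cfg: OptimizerConfig, rng: np.random.Generator
) -> SwarmState:
    """Prey-search phase: per-element exploit/explore branch.

    With probability 1 - Pp an element moves by
    p1 r2 (P - G) + p2 r1 (G - X); otherwise it takes a decaying random jump
    mu (r3 (ub - lb) + lb) sgn(rand - 0.5).
    """
    x = state.positions
    shape = x.shape
    r = rng.random(shape)
    r1, r2, r3 = rng.random(shape), rng.random(shape), rng.random(shape)
    sgn = np.sign(rng.random(shape) - 0.5)
    mu = csa_mu(state.iteration, cfg.max_iter, cfg.alpha_csa)

    exploit = x + cfg.p1 * r2 * (state.personal_best - state.global_best) \
        + cfg.p2 * r1 * (state.global_best - x)
    explore = x + mu * (r3 * (cfg.ub - cfg.lb) + cfg.lb) * sgn
    state.positions = _clamp(np.where(r >= cfg.pp, exploit, explore), cfg)
    return state


def rotate_about(
    x: np.ndarray, centroid: np.ndarray, dim_a: int, dim_b: int, angle: float
) -> np.ndarray:
    """Givens rotation of ``x`` about ``centroid`` in the (dim_a, dim_b) plane."""
    y = np.array(x, dtype=float) - centroid
    c, s = np.cos(angle), np.sin(angle)
    ya, yb = y[dim_a], y[dim_b]
    y[dim_a] = c * ya - s * yb
    y[dim_b] = s * ya + c * yb
    return y + centroid


def csa_eye_update(
    state: SwarmState, cfg: OptimizerConfig, rng: np.random.Generator
) -> SwarmState:
    """Eye-rotation phase: rotate each individual about its coordinate centroid.

    The rotation matrix is a planar (Givens) rotation in two randomly chosen
    dimensions with angle uniform on [-pi, pi]; being an isometry it
    preserves each individual's distance to its centroid.  In one dimension
    the rotation is the identity.
    """
    if cfg.dim < 2:
        return state
    new = np.empty_like(state.positions)
    for i in range(cfg.pop_size):
        a, b = rng.choice(cfg.dim, size=2, replace=False)
        angle = rng.uniform(-np.pi, np.pi)
        centroid = state.positions[i].mean()
        new[i] = rotate_about(state.positions[i], centroid, int(a), int(b), angle)
    state.positions = _clamp(new, cfg)
    return state


def csa_acceleration(t: int, a_min: float = 1e-6) -> float:
    """Hunt-phase acceleration a = 2590 (1 - e^(-log10 t)), floored at a_min."""
    if t < 1:
        raise ValueError("acceleration defined for t >= 1")
    return max(2590.0 * (1.0 - np.exp(-np.log10(t))), a_min)


def csa_hunt_update(
    state: SwarmState, cfg: OptimizerConfig, rng: np.random.Generator
) -> SwarmState:
    """Hunt phase: velocity update with inertia, then kinematic position step.

    v' = w v + c1 r1 (G - X) + c2 r2 (P - X) with w = (1 - t/T)^(p_w t/T);
    X' = X + (v'^2 - v^2) / (2a).  The acceleration a vanishes at t = 1
    (log10 1 = 0) and is floored to keep the step finite.
    """
    t, tmax = state.iteration, cfg.max_iter
    shape = state.positions.shape
    r1, r2 = rng.random(shape), rng.random(shape)
    frac = t / tmax
    omega = (1.0 - frac) ** (cfg.p_w * frac) if frac < 1.0 else 0.0
    v_old = state.velocities
    v_new = omega * v_old + cfg.c1 * r1 * (state.global_best - state.positions) \
        + cfg.c2 * r2 * (state.personal_best - state.positions)
    a = csa_acceleration(max(t, 1), cfg.a_min)
    state.positions = _clamp(state.positions + (v_new**2 - v_old**2) / (2.0 * a), cfg)
    state.velocities_prev = v_old
    state.velocities = v_new
    return state


# --------------------------------------------------------------------------
# GOA pieces
# --------------------------------------------------------------------------

def goa_social_force(r, f_attract: float = 0.5, l_scale: float = 1.5):
    """Social force s(r) = f e^(-r/l) - e^(-r); > 0 attracts, < 0 repels."""
    r = np.asarray(r, dtype=float)
    out = f_attract * np.exp(-r / l_scale) - np.exp(-r)
    return float(out) if out.ndim == 0 else out


def goa_decay_coefficient(t: int, cfg: OptimizerConfig) -> float:
    """Linear decay c = c_max - t (c_max - c_min) / T_max."""
    if not (0 <= t <= cfg.max_iter):
        raise ValueError("iteration out of range")
    return cfg.c_max - t * (cfg.c_max - cfg.c_min) / cfg.max_iter


def goa_position_update(
    state: SwarmState, cfg: OptimizerConfig, c: float
) -> SwarmState:
    """Move each grasshopper under pairwise social forces plus the target.

    Per dimension d:  X_i^d = c sum_j c (ub_d - lb_d)/2 s(|x_j^d - x_i^d|)
    sgn(x_j^d - x_i^d) + Td_d, with Td the best solution found so far.
    Exact per-dimension ties contribute zero force.  Following the
    algorithm's original reference, distances are remapped into [2, 4)
    (2 + |d| mod 2) before the social force: near the comfort distance the
    force is weak, so a collapsing swarm is not blown apart by the strong
    zero-range repulsion s(0) = f - 1.
    """
    x = state.positions
    # pairwise per-dimension displacements: delta[i, j, d] = x[j, d] - x[i, d]
    delta = x[None, :, :] - x[:, None, :]
    s = goa_social_force(2.0 + np.abs(delta) % 2.0, cfg.f_attract, cfg.l_scale)
    force = np.where(delta != 0.0, s * np.sign(delta), 0.0)
    half_span = (cfg.ub - cfg.lb) / 2.0
    social = c * (c * half_span * force).sum(axis=1)
    state.positions = _clamp(social + state.global_best, cfg)
    return state


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------

def _evaluate(objective, positions: np.ndarray) -> np.ndarray:
    fits = np.empty(len(positions))
    for i, pos in enumerate(positions):
        f = float(objective(pos))
        if not np.isfinite(f):
            raise ValueError(f"objective returned non-finite value at position {pos}")
        fits[i] = f
    return fits


def optimize(objective, algorithm: str, cfg: OptimizerConfig) -> OptimizationResult:
    """Maximize ``objective`` over the box with CSA or GOA.

    Runs ``max_iter`` iterations (CSA: search, eye, hunt; GOA: coefficient
    decay then position update), evaluating the population once per
    iteration plus once at initialization.  Returns the best position and a
    best-so-far fitness trace (length ``max_iter + 1``), which is monotone
    non-decreasing by construction.
    """
    if algorithm not in ("csa", "goa"):
        raise ValueError(f"unknown algorithm {algorithm!r}; expected 'csa' or 'goa'")
    rng = np.random.default_rng(cfg.seed)
    positions = initialize_positions(cfg, rng)
    fits = _evaluate(objective, positions)
    best = int(np.argmax(fits))
    state = SwarmState(
        positions=positions,
        velocities=np.zeros_like(positions),
        velocities_prev=np.zeros_like(positions),
        personal_best=positions.copy(),
        personal_best_fitness=fits.copy(),
        global_best=positions[best].copy(),
        global_best_fitness=float(fits[best]),
        iteration=0,
    )
    history = [state.global_best_fitness]
    evaluations = cfg.pop_size

    for t in range(1, cfg.max_iter + 1):
        state.iteration = t
        if algorithm == "csa":
            csa_search_update(state, cfg, rng)
            csa_eye_update(state, cfg, rng)
            csa_hunt_update(state, cfg, rng)
        else:
            c = goa_decay_coefficient(t, cfg)
            goa_position_update(state, cfg, c)

        fits = _evaluate(objective, state.positions)
        evaluations += cfg.pop_size
        improved = fits > state.personal_best_fitness
        state.personal_best[improved] = state.positions[improved]
        state.personal_best_fitness[improved] = fits[improved]
        best = int(np.argmax(state.personal_best_fitness))
        if state.personal_best_fitness[best] > state.global_best_fitness:
            state.global_best_fitness = float(state.personal_best_fitness[best])
            state.global_best = state.personal_best[best].copy()
        history.append(state.global_best_fitness)

    return OptimizationResult(
        best_position=state.global_best.copy(),
        best_fitness=state.global_best_fitness,
        fitness_history=np.asarray(history),
        evaluations=evaluations,
    )
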