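"""Genetic-algorithm fitting of the simulator to a target bout.

A candidate genome holds the spike-train parameters of the two-channel
model (base amplitude, whip ratio and catch fraction of the first cycle,
half period, onset time, segment delays) together with the free values of
the stiffness profile W(s_j) (head fixed at 1).  The objective is the
Frobenius norm of the difference between the candidate's simulated
spine-angle matrix and the target, after aligning bout onset by
cross-correlating the tail angle.  Parameter bounds are derived from the
target's own kinematics (tail zero crossings give the half-cycle count,
the head-to-tail crossing lag brackets the segment delay, the bend
amplitude brackets the drive amplitude), and a small-population GA with
tournament selection, uniform crossover, Gaussian mutation and elitism
minimizes the objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .neuro import NeuroParams, StiffnessProfile, simulate_bout
from .spine import InvalidInputError, SpineAngleMatrix


class InvalidTargetError(ValueError):
    """Target bout has no detectable cycle structure."""


@dataclass
class GAConfig:
    population: int = 50
    max_generations: int = 50
    crossover_rate: float = 0.9
    crossover_mix: float = 0.5  # per-gene swap probability
    mutation_rate: float = 0.35
    mutation_scale: float = 0.08  # sigma as fraction of bound width
    tournament: int = 4
    plateau_generations: int = 10
    plateau_tol: float = 1e-3  # relative improvement threshold
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 4:
            raise InvalidInputError("population must be >= 4")
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0 <= r <= 1:
                raise InvalidInputError("rates must be in [0, 1]")


@dataclass
class FitResult:
    params: NeuroParams
    stiffness: StiffnessProfile
    objective_trace: np.ndarray  # best objective per generation
    final_objective: float
    genome: np.ndarray


# genome layout: [a0, ratio, catch, hp, t0, d, turn_d, W1..W8]  (W0 = 1)
GENE_NAMES = ["a0", "ratio", "catch", "hp_ms", "t0_ms", "d_ms", "turn_d_ms"] + [
    f"W{j}" for j in range(2, 10)
]


def _active_crossing_times(t: np.ndarray, x: np.ndarray, frac: float = 0.1) -> np.ndarray:
    thr = frac * np.max(np.abs(x))
    s = np.sign(x)
    for i in range(1, s.size):
        if s[i] == 0:
            s[i] = s[i - 1]
    idx = np.nonzero(s[:-1] * s[1:] < 0)[0]
    keep = [i for i in idx if np.abs(x[max(0, i - 10) : i + 10]).max() >= thr]
    return t[np.array(keep, dtype=int)] if keep else np.array([])


def derive_bounds(target: SpineAngleMatrix) -> dict[str, tuple[float, float]]:
    """Kinematic parameter bounds read off the target bout itself.

    The tail-angle zero crossings give the half-cycle count and period;
    the lag between head-segment and tail crossings brackets the
    segment-to-segment delay (+/- 50%); the bend amplitude brackets the
    drive amplitude at [0, 4x] the value implied by max |Δθ|.
    """
    t = target.time_ms
    tail = target.tail_angle()
    if not np.any(np.abs(tail) > 1e-6):
        raise InvalidTargetError("rest target: no tail oscillation")
    tail_cross = _active_crossing_times(t, tail)
    if tail_cross.size < 2:
        raise InvalidTargetError("undetectable cycles in target")
    # k half cycles of tail oscillation produce ~k-1 internal crossings
    n_half = int(tail_cross.size) + 1
    half_period = float(np.median(np.diff(tail_cross)))
    # the body wave travels head to tail: the per-segment delay is the
    # cross-correlation lag between adjacent spine-angle columns
    dt = float(np.median(np.diff(t)))
    lags = []
    for j in range(1, target.n_points - 1):
        a = target.dtheta[:, j] - target.dtheta[:, j].mean()
        b = target.dtheta[:, j + 1] - target.dtheta[:, j + 1].mean()
        xc = np.correlate(b, a, mode="full")
        lag_frames = int(np.argmax(xc)) - (a.size - 1)
        lags.append(lag_frames * dt)
    d_est = float(np.clip(np.median(lags), 0.5 * dt, half_period)) or dt
    amp_implied = float(np.abs(target.dtheta).max())
    return {
        "n_c": (n_half, n_half),
        "a0": (0.0, 4.0 * amp_implied * 0.1),
        "ratio": (1.0, 8.0),
        "catch": (0.0, 1.0),
        "hp_ms": (0.6 * half_period, 1.4 * half_period),
        "t0_ms": (max(t[0], tail_cross[0] - 2.5 * half_period), tail_cross[0]),
        "d_ms": (max(0.5 * d_est, 0.25), 1.5 * d_est),
        "turn_d_ms": (max(0.5 * d_est, 0.25), 2.0 * d_est),
        "W": (0.2, 1.2),
    }


def genome_to_model(
    genome: np.ndarray, n_c: int, start_side: str = "left"
) -> tuple[NeuroParams, StiffnessProfile]:
    a0, ratio, catch, hp, t0, d, turn_d = genome[:7]
    W = np.concatenate([[1.0], genome[7:]])
    tau_f = t0 + hp * np.arange(n_c)
    a = np.full(n_c, a0)
    a[0] *= 0.5
    a[-1] *= 0.5
    boost = (ratio - 1.0) * a0
    if n_c > 1:
        a[1] += boost
    if n_c > 2:
        a[2] += catch * boost
    if n_c > 3:
        a[3] += 0.4 * catch * boost  # ring-down echo, tied to the catch
    d_arr = np.full(n_c, d)
    d_arr[1:3] = turn_d
    p = NeuroParams(
        tau_f_ms=tau_f,
        a=a,
        d_ms=d_arr,
        n_c=n_c,
        burst_ms=0.84 * hp,
        start_side=start_side,
    )
    return p, StiffnessProfile(W=W)


def objective(
    genome: np.ndarray,
    target: SpineAngleMatrix,
    n_c: int,
    dt_ms: float = 2.0,
    start_side: str = "left",
    max_shift: int = 6,
) -> float:
    """Frobenius distance between candidate simulation and target.

    The candidate is simulated on the target's grid and shifted in time
    (cross-correlation of the tail angle, up to ``max_shift`` frames) to
    align bout onset before the norm is taken.
    """
    try:
        p, W = genome_to_model(genome, n_c, start_side)
        sim = simulate_bout(
            p, stiffness=W, dt_ms=dt_ms, duration_ms=float(target.time_ms[-1])
        )
    except Exception:
        return np.inf
    a = sim.dtheta
    b = target.dtheta
    m = min(a.shape[0], b.shape[0])
    a, b = a[:m], b[:m]
    # align onset via best tail-angle cross-correlation shift
    best = np.inf
    for shift in range(-max_shift, max_shift + 1):
        if shift >= 0:
            aa, bb = a[shift:], b[: m - shift]
        else:
            aa, bb = a[: m + shift], b[-shift:]
        cost = float(np.sqrt(np.sum((aa - bb) ** 2)))
        best = min(best, cost)
    return best


def fit_genetic(
    target: SpineAngleMatrix,
    config: GAConfig | None = None,
    dt_ms: float = 2.0,
    start_side: str | None = None,
) -> FitResult:
    """Fit the two-channel model to a target bout by a genetic algorithm.

    Tournament selection, uniform crossover, Gaussian mutation
    clipped to the derived bounds, elitism of one; stops at the
    generation budget or when the best objective improves by less than
    0.1% over ten generations.  Fully deterministic for a fixed seed.
    """
    config = config or GAConfig()
    rng = np.random.default_rng(config.seed)
    bounds = derive_bounds(target)
    n_c = int(bounds["n_c"][0])
    lo = np.array(
        [bounds[k][0] for k in ("a0", "ratio", "catch", "hp_ms", "t0_ms", "d_ms", "turn_d_ms")]
        + [bounds["W"][0]] * 8
    )
    hi = np.array(
        [bounds[k][1] for k in ("a0", "ratio", "catch", "hp_ms", "t0_ms", "d_ms", "turn_d_ms")]
        + [bounds["W"][1]] * 8
    )
    if start_side is None:
        # the whip side is opposite the start side; a right-side whip
        # bends the body toward positive Δθ under the sign convention
        tail = target.tail_angle()
        start_side = "left" if tail[np.argmax(np.abs(tail))] > 0 else "right"

    def evaluate(g: np.ndarray) -> float:
        return objective(g, target, n_c, dt_ms=dt_ms, start_side=start_side)

    pop = rng.uniform(lo, hi, size=(config.population, lo.size))
    costs = np.array([evaluate(g) for g in pop])
    trace = []
    stall = 0
    for gen in range(config.max_generations):
        order = np.argsort(costs)
        best_cost = costs[order[0]]
        trace.append(best_cost)
        if len(trace) > 1:
            improvement = (trace[-2] - best_cost) / max(trace[-2], 1e-300)
            stall = stall + 1 if improvement < config.plateau_tol else 0
            if stall >= config.plateau_generations:
                break
        new_pop = [pop[order[0]].copy()]  # elitism
        while len(new_pop) < config.population:
            parents = []
            for _ in range(2):
                idx = rng.integers(0, config.population, size=config.tournament)
                parents.append(pop[idx[np.argmin(costs[idx])]])
            child = parents[0].copy()
            if rng.random() < config.crossover_rate:
                swap = rng.random(child.size) < config.crossover_mix
                child[swap] = parents[1][swap]
            mutate = rng.random(child.size) < config.mutation_rate
            # anneal the mutation width so late generations refine locally
            frac = 1.0 - gen / max(config.max_generations - 1, 1)
            sigma = config.mutation_scale * (0.2 + 0.8 * frac)
            child[mutate] += (
                sigma * (hi - lo)[mutate] * rng.standard_normal(int(mutate.sum()))
            )
            new_pop.append(np.clip(child, lo, hi))
        pop = np.array(new_pop)
        costs = np.array([evaluate(g) for g in pop])
    order = np.argsort(costs)
    best = pop[order[0]]
    trace.append(costs[order[0]])
    p, W = genome_to_model(best, n_c, start_side)
    # report the best objective per generation as a non-increasing trace
    trace = np.minimum.accumulate(np.array(trace))
    return FitResult(
        params=p,
        stiffness=W,
        objective_trace=trace,
        final_objective=float(trace[-1]),
        genome=best,
    )
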