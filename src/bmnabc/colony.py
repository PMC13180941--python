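"""Binary multi-neighbor artificial bee colony (BMNABC) optimizer.

A colony of ``n`` food sources (binary inclusion masks of length ``d``)
iterates three phases:

* **employed** — global exploration: each bee perturbs its mask toward the
  randomized *average personal best* (APB) of its far neighborhood, the
  bees at or above the mean Hamming distance from it;
* **onlooker** — local exploitation: ``n`` fitness-proportional draws each
  perturb the drawn bee toward the *current position* of the best bee in
  its near neighborhood;
* **scout** — any bee whose abandonment counter exceeds the limit is
  re-initialized uniformly at random (its personal best survives).

Continuous perturbations ``a_ij = phi * (x_ij - target_j)`` are mapped to
bit flips through the transfer function

    S(a_ij) = (1 - exp(-AC_i * T)) + |tanh(a_ij)|

so a stagnating bee (large AC) flips more aggressively, and a bit already
agreeing with its target barely flips at all.  Replacement is greedy with
strict improvement; ties increment the abandonment counter.  The all-zero
mask is assigned fitness 0 without invoking the fitness callable.

Defaults follow the standard configuration for this optimizer family:
population 20, 100 iterations, abandonment limit 10.  The temperature ``T``
sets the stagnation flip floor ``1 - exp(-AC * T)``; it should be
commensurate with ``1/d`` so that a stagnating bee proposes few-bit repairs
rather than mask-scale shuffles (at the default ``T = 0.01`` and the
abandonment limit, the floor is ~0.1, i.e. a handful of flips for masks of
a few dozen groups).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ColonyConfig",
    "FoodSource",
    "RunResult",
    "hamming_distance",
    "partition_neighbors",
    "compute_apb",
    "transfer_probability",
    "binary_update",
    "run",
]


@dataclass(frozen=True)
class ColonyConfig:
    d: int
    n: int = 20
    max_iter: int = 100
    limit: int = 10
    t_temp: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("dimensionality d must be >= 1")
        if self.n < 2:
            raise ValueError("population size n must be >= 2")
        if self.limit < 1:
            raise ValueError("abandonment limit must be >= 1")
        if self.t_temp <= 0:
            raise ValueError("temperature t_temp must be > 0")


@dataclass
class FoodSource:
    """One candidate mask with its bookkeeping (mainly for introspection)."""

    x: np.ndarray
    fitness: float
    pbest: np.ndarray
    pbest_fitness: float
    ac: int = 0


@dataclass
class RunResult:
    best_x: np.ndarray
    best_fitness: float
    history: np.ndarray  # best-so-far fitness after each iteration
    evaluations: int
    colony: list[FoodSource] = field(default_factory=list, repr=False)


def hamming_distance(a: np.ndarray, b: np.ndarray) -> int:
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return int(np.count_nonzero(a != b))


def partition_neighbors(positions: np.ndarray, i: int) -> tuple[np.ndarray, np.ndarray]:
    """Split bee ``i``'s neighbors into (near, far) at the mean Hamming distance.

    far = neighbors strictly beyond the mean distance; near = the rest.
    When no neighbor lies beyond the mean (e.g. all distances equal), the
    single farthest neighbor is forced into the far set — and dropped from
    near, unless that would empty near (with n = 2 the lone neighbor serves
    both roles).
    """
    n = positions.shape[0]
    if n < 2:
        raise ValueError("need at least 2 bees")
    others = np.array([k for k in range(n) if k != i])
    dists = np.count_nonzero(positions[others] != positions[i], axis=1)
    mean = dists.mean()
    far = others[dists > mean]
    near = others[dists <= mean]
    if far.size == 0:
        j = int(np.argmax(dists))
        far = others[[j]]
        if near.size > 1:
            near = others[np.arange(others.size) != j]
    return near, far


def compute_apb(
    pbests: np.ndarray, far: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Randomized average personal best of the far neighborhood, per dimension.

    APB_j = mean_k( U_kj * pbest_kj ) over far neighbors k, with independent
    uniforms U_kj ~ U(0, 1); values lie in [0, 1].
    """
    if far.size == 0:
        raise ValueError("far neighborhood must be nonempty")
    u = rng.random((far.size, pbests.shape[1]))
    return (u * pbests[far]).mean(axis=0)


def transfer_probability(a, ac: int, t_temp: float):
    """S(a) = (1 - exp(-AC * T)) + |tanh(a)|; may exceed 1 (clipped at use)."""
    if t_temp <= 0:
        raise ValueError("t_temp must be > 0")
    if ac < 0:
        raise ValueError("abandonment counter must be >= 0")
    return (1.0 - np.exp(-ac * t_temp)) + np.abs(np.tanh(a))


def binary_update(
    x: np.ndarray, a: np.ndarray, ac: int, t_temp: float, rng: np.random.Generator
) -> np.ndarray:
    """Flip each bit with probability min(S(a_j), 1)."""
    s = transfer_probability(a, ac, t_temp)
    flips = rng.random(x.shape[0]) < s
    return np.where(flips, 1 - x, x).astype(x.dtype)


class _Colony:
    """Mutable optimizer state; phases are methods operating in place."""

    def __init__(self, fitness_fn, cfg: ColonyConfig, rng: np.random.Generator):
        self.fn = fitness_fn
        self.cfg = cfg
        self.rng = rng
        self.evaluations = 0
        self.x = rng.integers(0, 2, size=(cfg.n, cfg.d), dtype=np.int8)
        self.fitness = np.array([self._evaluate(xi) for xi in self.x])
        self.pbest = self.x.copy()
        self.pbest_fitness = self.fitness.copy()
        self.ac = np.zeros(cfg.n, dtype=np.int64)
        k = int(np.argmax(self.pbest_fitness))
        self.best_x = self.pbest[k].copy()
        self.best_fitness = float(self.pbest_fitness[k])

    def _evaluate(self, x: np.ndarray) -> float:
        if not x.any():
            return 0.0  # empty mask: defined sentinel, classifier not invoked
        f = float(self.fn(x))
        self.evaluations += 1
        if not np.isfinite(f):
            raise RuntimeError(f"non-finite fitness for mask {x.tolist()}")
        return f

    def _try_candidate(self, i: int, cand: np.ndarray) -> None:
        f = self._evaluate(cand)
        if f > self.fitness[i]:
            self.x[i] = cand
            self.fitness[i] = f
            self.ac[i] = 0
            if f > self.pbest_fitness[i]:
                self.pbest[i] = cand.copy()
                self.pbest_fitness[i] = f
            if f > self.best_fitness:
                self.best_fitness = f
                self.best_x = cand.copy()
        else:
            self.ac[i] += 1

    def _move(self, i: int, target: np.ndarray) -> None:
        phi = self.rng.random(self.cfg.d)
        a = phi * (self.x[i] - target)
        cand = binary_update(self.x[i], a, int(self.ac[i]), self.cfg.t_temp, self.rng)
        self._try_candidate(i, cand)

    def employed_phase(self) -> None:
        for i in range(self.cfg.n):
            _, far = partition_neighbors(self.x, i)
            apb = compute_apb(self.pbest, far, self.rng)
            self._move(i, apb)

    def onlooker_phase(self) -> None:
        total = self.fitness.sum()
        if total > 0:
            probs = self.fitness / total
        else:
            probs = np.full(self.cfg.n, 1.0 / self.cfg.n)
        draws = self.rng.choice(self.cfg.n, size=self.cfg.n, p=probs)
        for i in draws:
            near, _ = partition_neighbors(self.x, int(i))
            k = int(near[np.argmax(self.fitness[near])])
            self._move(int(i), self.x[k].astype(np.float64))

    def scout_phase(self) -> None:
        for i in range(self.cfg.n):
            if self.ac[i] > self.cfg.limit:
                self.x[i] = self.rng.integers(0, 2, size=self.cfg.d, dtype=np.int8)
                self.fitness[i] = self._evaluate(self.x[i])
                self.ac[i] = 0
                if self.fitness[i] > self.pbest_fitness[i]:
                    self.pbest[i] = self.x[i].copy()
                    self.pbest_fitness[i] = float(self.fitness[i])
                if self.fitness[i] > self.best_fitness:
                    self.best_fitness = float(self.fitness[i])
                    self.best_x = self.x[i].copy()

    def snapshot(self) -> list[FoodSource]:
        return [
            FoodSource(self.x[i].copy(), float(self.fitness[i]), self.pbest[i].copy(),
                       float(self.pbest_fitness[i]), int(self.ac[i]))
            for i in range(self.cfg.n)
        ]


def run(fitness_fn, cfg: ColonyConfig) -> RunResult:
    """Full optimization: init, then max_iter x (employed, onlooker, scout).

    ``fitness_fn`` maps a binary vector to a fitness in [0, 1].  The run is
    deterministic for a fixed ``cfg.seed``, and the best-so-far history is
    non-decreasing by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    col = _Colony(fitness_fn, cfg, rng)
    history = np.empty(cfg.max_iter)
    for it in range(cfg.max_iter):
        col.employed_phase()
        col.onlooker_phase()
        col.scout_phase()
        history[it] = col.best_fitness
    return RunResult(
        col.best_x.copy(), col.best_fitness, history, col.evaluations, col.snapshot()
    )
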