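"""Evolutionary optimization of a linear projection matrix.

The optimizer searches for a real ``d_in x d_out`` matrix ``W`` such that the
projected features ``X @ W`` have maximal class separability, measured by the
silhouette score of the projection against the known class labels.  The search
is a classic real-valued evolutionary loop:

1. initialise a population of matrices with i.i.d. ``N(0, 1/d_in)`` entries;
2. evaluate the silhouette fitness of every candidate;
3. keep the top-performing candidates as parents;
4. breed offspring by elementwise parent averaging (probability ``rho``);
5. perturb offspring with additive Gaussian noise ``N(0, sigma^2)``
   (probability ``mu``);
6. replace the worst-performing candidates with the offspring.

With at least one elite candidate and fitness computed on the full data the
best fitness in the population is non-decreasing across generations.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
import numpy as np

from .silhouette import silhouette

__all__ = [
    "EAConfig",
    "TransformationMatrix",
    "Population",
    "FitnessReport",
    "fitness",
    "init_population",
    "select",
    "crossover",
    "mutate",
    "evolve",
    "transform",
    "save_matrix",
    "load_matrix",
]


@dataclass
class EAConfig:
    """Hyperparameters of the evolutionary search.

    Defaults follow the reference protocol: population of five, mutation rate
    0.8, crossover rate 0.4; the generation limit there was 30,000 but any
    budget may be set.  ``sigma`` (mutation noise sd) has no reference value
    and defaults to 0.1, roughly 10% of the initial weight scale at
    ``d_in`` around 100-1000.
    """

    P: int = 5
    G: int = 30_000
    mu: float = 0.8
    rho: float = 0.4
    sigma: float = 0.1
    elite_count: int = 1
    subsample_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.P < 2:
            raise ValueError("population size P must be >= 2")
        if self.G < 0:
            raise ValueError("generations G must be >= 0")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mutation rate mu must be in [0, 1]")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("crossover rate rho must be in [0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 1 <= self.elite_count < self.P:
            raise ValueError("elite_count must satisfy 1 <= elite_count < P")
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValueError("subsample_fraction must be in (0, 1]")


@dataclass
class TransformationMatrix:
    """A candidate (or final) projection matrix with provenance."""

    W: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)
        if self.W.ndim != 2:
            raise ValueError("W must be 2-D")
        if not np.isfinite(self.W).all():
            raise ValueError("W must be finite")

    @property
    def d_in(self) -> int:
        return self.W.shape[0]

    @property
    def d_out(self) -> int:
        return self.W.shape[1]


@dataclass
class Population:
    candidates: list[np.ndarray]
    fitness: list[float]


@dataclass
class FitnessReport:
    """Per-generation trace; entry 0 describes the initial population."""

    best: list[float] = field(default_factory=list)
    mean: list[float] = field(default_factory=list)
    best_index: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.best)


def fitness(
    W: np.ndarray,
    features: np.ndarray,
    labels: np.ndarray,
    subsample_fraction: float = 1.0,
    rng: np.random.Generator | None = None,
) -> float:
    """Silhouette of ``features @ W`` against ``labels``.

    When ``subsample_fraction < 1`` a random subsample of rows is scored,
    mirroring per-generation patch sampling during large-scale optimization.
    """
    X = np.asarray(features, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    if X.shape[1] != W.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match W rows {W.shape[0]}"
        )
    y = np.asarray(labels)
    if subsample_fraction < 1.0:
        if rng is None:
            raise ValueError("rng required when subsampling")
        n = X.shape[0]
        m = max(2, int(round(n * subsample_fraction)))
        idx = rng.choice(n, size=m, replace=False)
        X, y = X[idx], y[idx]
        if np.unique(y).size < 2:  # resample cannot drop a class silently
            return 0.0
    return silhouette(X @ W, y)


def init_population(
    config: EAConfig,
    d_in: int,
    d_out: int,
    rng: np.random.Generator | None = None,
) -> Population:
    """Population of ``P`` matrices with i.i.d. ``N(0, 1/d_in)`` entries."""
    if d_out >= d_in:
        raise ValueError("d_out must be smaller than d_in")
    if d_out < 1:
        raise ValueError("d_out must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    scale = 1.0 / math.sqrt(d_in)
    candidates = [rng.normal(0.0, scale, size=(d_in, d_out)) for _ in range(config.P)]
    return Population(candidates=candidates, fitness=[math.nan] * config.P)


def select(population: Population, k: int) -> list[int]:
    """Indices of the top-``k`` candidates by fitness (descending).

    Ties are broken toward the lower candidate index.
    """
    P = len(population.candidates)
    if not 1 <= k <= P:
        raise ValueError(f"k must be in [1, {P}]")
    order = sorted(range(P), key=lambda i: (-population.fitness[i], i))
    return order[:k]


def crossover(
    Wp1: np.ndarray, Wp2: np.ndarray, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Elementwise parent mean with probability ``rho``; else a copy of Wp1."""
    Wp1 = np.asarray(Wp1, dtype=np.float64)
    Wp2 = np.asarray(Wp2, dtype=np.float64)
    if Wp1.shape != Wp2.shape:
        raise ValueError("parent shapes differ")
    if rng.random() < rho:
        return (Wp1 + Wp2) / 2.0
    return Wp1.copy()


def mutate(
    W: np.ndarray, mu: float, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Add i.i.d. ``N(0, sigma^2)`` noise with probability ``mu``."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    W = np.asarray(W, dtype=np.float64)
    if rng.random() < mu and sigma > 0:
        return W + rng.normal(0.0, sigma, size=W.shape)
    return W.copy()


def evolve(
    features: np.ndarray,
    labels: np.ndarray,
    config: EAConfig,
    d_out: int = 2,
) -> tuple[TransformationMatrix, FitnessReport]:
    """Run the evolutionary search; returns the best-ever matrix and trace.

    Deterministic for a fixed ``config.seed``.  The fitness trace has
    ``G + 1`` entries (the initial population included).  When
    ``subsample_fraction < 1`` every candidate of a generation is scored on
    the same random subsample, so candidates stay comparable.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    if np.unique(y).size < 2:
        raise ValueError("at least two classes required")
    rng = np.random.default_rng(config.seed)
    d_in = X.shape[1]
    pop = init_population(config, d_in, d_out, rng=rng)
    full = config.subsample_fraction >= 1.0

    report = FitnessReport()
    best_W: np.ndarray | None = None
    best_fit = -np.inf

    n = X.shape[0]
    m_sub = max(2, int(round(n * config.subsample_fraction)))

    n_parents = math.ceil(config.P / 2)
    n_offspring = min(config.P // 2, config.P - config.elite_count)

    for g in range(config.G + 1):
        if full:
            for i in range(config.P):
                if math.isnan(pop.fitness[i]):
                    pop.fitness[i] = silhouette(X @ pop.candidates[i], y)
        else:
            idx = rng.choice(n, size=m_sub, replace=False)
            Xs, ys = X[idx], y[idx]
            degenerate = np.unique(ys).size < 2
            for i in range(config.P):
                pop.fitness[i] = (
                    0.0 if degenerate else silhouette(Xs @ pop.candidates[i], ys)
                )

        gen_best = int(np.argmax(pop.fitness))
        report.best.append(float(pop.fitness[gen_best]))
        report.mean.append(float(np.mean(pop.fitness)))
        report.best_index.append(gen_best)
        if pop.fitness[gen_best] > best_fit:
            best_fit = float(pop.fitness[gen_best])
            best_W = pop.candidates[gen_best].copy()

        if g == config.G:
            break

        parents = select(pop, n_parents)
        pairs = list(itertools.permutations(parents, 2)) or [(parents[0], parents[0])]
        offspring = []
        for j in range(n_offspring):
            i1, i2 = pairs[j % len(pairs)]
            child = crossover(
                pop.candidates[i1], pop.candidates[i2], config.rho, rng
            )
            child = mutate(child, config.mu, config.sigma, rng)
            offspring.append(child)

        # Replace the worst-performing candidates with the offspring.
        survivors = select(pop, config.P - n_offspring)
        new_candidates = [pop.candidates[i] for i in survivors] + offspring
        new_fitness = [pop.fitness[i] for i in survivors] + [math.nan] * n_offspring
        pop = Population(candidates=new_candidates, fitness=new_fitness)

    assert best_W is not None
    result = TransformationMatrix(
        W=best_W,
        provenance={
            "method": "evolutionary",
            "config": {
                "P": config.P,
                "G": config.G,
                "mu": config.mu,
                "rho": config.rho,
                "sigma": config.sigma,
                "elite_count": config.elite_count,
                "subsample_fraction": config.subsample_fraction,
                "seed": config.seed,
            },
            "best_fitness": best_fit,
            "generations_run": config.G,
        },
    )
    return result, report


def transform(features: np.ndarray, W: np.ndarray | TransformationMatrix) -> np.ndarray:
    """Project ``features`` (n x d_in) with ``W`` (d_in x d_out)."""
    if isinstance(W, TransformationMatrix):
        W = W.W
    X = np.asarray(features, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    if X.ndim != 2 or W.ndim != 2 or X.shape[1] != W.shape[0]:
        raise ValueError(
            f"cannot project features of shape {X.shape} with W of shape {W.shape}"
        )
    return X @ W


def save_matrix(matrix: TransformationMatrix, path) -> None:
    """Write a matrix as a one-line JSON header followed by a text payload.

    Floats are serialized with ``repr`` so the round trip is exact.
    """
    header = {
        "format": "evoslide-matrix",
        "version": 1,
        "d_in": matrix.d_in,
        "d_out": matrix.d_out,
        "provenance": matrix.provenance,
    }
    lines = [json.dumps(header)]
    for row in matrix.W:
        lines.append(" ".join(repr(float(v)) for v in row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_matrix(path) -> TransformationMatrix:
    """Inverse of :func:`save_matrix`; validates header against payload."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError("empty matrix file")
    try:
        header = json.loads(lines[0])
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt matrix header: {exc}") from exc
    if header.get("format") != "evoslide-matrix":
        raise ValueError("not an evoslide matrix file")
    rows = [
        [float(tok) for tok in line.split()] for line in lines[1:] if line.strip()
    ]
    W = np.array(rows, dtype=np.float64)
    if W.ndim != 2 or W.shape != (header["d_in"], header["d_out"]):
        raise ValueError(
            f"header dims {(header['d_in'], header['d_out'])} do not match "
            f"payload shape {W.shape}"
        )
    return TransformationMatrix(W=W, provenance=header.get("provenance", {}))
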