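"""Consumer-resource model primitives.

Organisms are haploid asexuals characterised by a vector of resource
affinities ``c_ik`` on the discrete grid {0, 0.1, ..., 1.0}.  Fitness is
Monod (half-saturation) kinetics on ``R`` perfectly substitutable resources,
discounted by a trade-off cost ``D_i`` that penalises high (``sigma1``) and
multiple (``sigma2``) affinities::

    F_i = 1/(1 + D_i) * sum_k c_ik * r_k / (r_k + gamma_k)
    D_i = sum_k (sigma1 * c_ik + sigma2 * [c_ik > 0])

Resources follow chemostat-like dynamics: per-capita influx ``lam``,
proportional decay ``c0``, and consumption equal to the summed per-resource
fitness of the population, integrated one step per simulation update.

Affinities are stored internally as integer tenths (``int8``) so that
repeated mutation can never drift off the grid; they are converted to real
values only inside fitness evaluation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import yaml

__all__ = [
    "SimulationConfig",
    "FitnessBreakdown",
    "as_tenths",
    "as_affinities",
    "cost",
    "fitness",
    "update_resources",
    "mutate",
]

#: number of grid steps between affinity 0 and affinity 1
TENTHS_MAX = 10

ScalarOrVector = Union[float, Sequence[float]]


@dataclass
class SimulationConfig:
    """Parameters of a single simulation run.

    Defaults correspond to the exemplar radiation run: N=1000 organisms on
    R=9 resources, per-trait mutation rate 0.05 with 70% trait-lethals,
    influx 1e-3 per resource per individual, moderate trade-offs
    (sigma1, sigma2) = (1, 0.1), half-saturation 100, decay 0.1, 1% of the
    population replaced per update.
    """

    N: int = 1000
    R: int = 9
    mu: float = 0.05
    gamma: ScalarOrVector = 100.0
    sigma1: float = 1.0
    sigma2: float = 0.1
    lam: ScalarOrVector = 1e-3
    c0: float = 0.1
    trait_lethal_fraction: float = 0.7
    kill_fraction: float = 0.01
    updates: int = 40_000
    seed: int = 0
    init_mode: str = "specialist"
    resource_init: str = "min"
    population_mode: str = "constant"
    #: starting census in variable mode (defaults to N; N itself always sets
    #: the resource influx reference and the constant-mode census)
    initial_population: Optional[int] = None
    #: record the ancestry forest during the run (needed for lineage queries)
    record_ancestry: bool = True
    #: stride (in updates) between trajectory records
    record_stride: int = 100

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must be in [0, 1]")
        if np.any(np.asarray(self.gamma, dtype=float) <= 0):
            raise ValueError("gamma must be > 0")
        if self.sigma1 < 0 or self.sigma2 < 0:
            raise ValueError("sigma1 and sigma2 must be >= 0")
        if np.any(np.asarray(self.lam, dtype=float) <= 0):
            raise ValueError("lam must be > 0")
        if not 0.0 <= self.c0 <= 1.0:
            raise ValueError("c0 must be in [0, 1]")
        if not 0.0 <= self.trait_lethal_fraction <= 1.0:
            raise ValueError("trait_lethal_fraction must be in [0, 1]")
        if not 0.0 < self.kill_fraction < 1.0:
            raise ValueError("kill_fraction must be in (0, 1)")
        if self.updates < 0:
            raise ValueError("updates must be >= 0")
        if self.init_mode not in ("specialist", "generalist"):
            raise ValueError("init_mode must be 'specialist' or 'generalist'")
        if self.resource_init not in ("min", "max"):
            raise ValueError("resource_init must be 'min' or 'max'")
        if self.resource_init == "max" and self.c0 == 0:
            raise ValueError("resource_init='max' requires c0 > 0")
        if self.population_mode not in ("constant", "variable"):
            raise ValueError("population_mode must be 'constant' or 'variable'")
        if self.initial_population is not None:
            if self.initial_population < 1:
                raise ValueError("initial_population must be >= 1")
            if self.population_mode == "constant" and self.initial_population != self.N:
                raise ValueError("constant mode requires initial_population == N")
        for name in ("gamma", "lam"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.ndim not in (0, 1) or (v.ndim == 1 and v.size != self.R):
                raise ValueError(f"{name} must be a scalar or a length-R vector")

    # -- vector views of the (possibly scalar) per-resource parameters -----

    def gamma_vector(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.gamma, dtype=float), (self.R,)).copy()

    def lam_vector(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.lam, dtype=float), (self.R,)).copy()

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for name in ("gamma", "lam"):
            v = d[name]
            if isinstance(v, np.ndarray):
                d[name] = v.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class FitnessBreakdown:
    """Fitness of one organism, decomposed by resource.

    ``total`` is the organism's fitness F_i, ``per_resource`` the vector of
    per-resource contributions F_ik (cost prefactor included, so
    ``total == per_resource.sum()``), and ``cost`` the trade-off term D_i.
    """

    total: float
    per_resource: np.ndarray
    cost: float


# ---------------------------------------------------------------------------
# grid helpers


def as_tenths(affinities) -> np.ndarray:
    """Convert grid affinities (floats) to the internal integer-tenths form.

    Raises ``ValueError`` if any value is off the {0, 0.1, ..., 1.0} grid.
    """
    a = np.asarray(affinities, dtype=float)
    t = np.rint(a * TENTHS_MAX)
    if np.any(t < 0) or np.any(t > TENTHS_MAX) or not np.allclose(
        t / TENTHS_MAX, a, atol=1e-9
    ):
        raise ValueError("affinities must lie on the grid {0, 0.1, ..., 1.0}")
    return t.astype(np.int8)


def as_affinities(tenths) -> np.ndarray:
    """Convert integer tenths back to real affinities."""
    return np.asarray(tenths, dtype=float) / TENTHS_MAX


# ---------------------------------------------------------------------------
# pure model functions


def cost(phenotype, sigma1: float, sigma2: float) -> float:
    """Trade-off cost D_i = sum_k (sigma1*c_ik + sigma2*[c_ik > 0])."""
    t = as_tenths(phenotype)
    return float(sigma1 * t.sum() / TENTHS_MAX + sigma2 * np.count_nonzero(t))


def fitness(
    phenotype,
    resources,
    gamma: ScalarOrVector,
    sigma1: float,
    sigma2: float,
) -> FitnessBreakdown:
    """Monod fitness of one phenotype at the given resource abundances."""
    t = as_tenths(phenotype)
    r = np.asarray(resources, dtype=float)
    if np.any(r < 0):
        raise ValueError("resource abundances must be non-negative")
    c = as_affinities(t)
    d = float(sigma1 * c.sum() + sigma2 * np.count_nonzero(t))
    per_resource = c * r / (r + gamma) / (1.0 + d)
    return FitnessBreakdown(total=float(per_resource.sum()), per_resource=per_resource, cost=d)


def _batch_fitness(pop_tenths, resources, gamma, sigma1, sigma2):
    """Fitness of a whole population (rows = organisms, int8 tenths).

    Returns ``(F, consumption)`` where ``F`` is the length-n fitness vector
    and ``consumption`` the length-R vector sum_i F_ik.  This is the hot
    path of the simulator; it is written as two matrix-vector products.
    """
    c = pop_tenths * (1.0 / TENTHS_MAX)
    d = sigma1 * (1.0 / TENTHS_MAX) * pop_tenths.sum(axis=1) + sigma2 * np.count_nonzero(
        pop_tenths, axis=1
    )
    inv = 1.0 / (1.0 + d)
    w = resources / (resources + gamma)
    f = (c @ w) * inv
    consumption = w * (c.T @ inv)
    return f, consumption


def update_resources(resources, consumption, N: int, lam, c0: float) -> np.ndarray:
    """One forward-Euler step of the resource dynamics.

    ``r_k <- max(0, r_k + N*lam_k - c0*r_k - consumption_k)``.  Influx,
    decay and consumption are applied simultaneously from the pre-update
    state; over-consumption clamps at zero.
    """
    r = np.asarray(resources, dtype=float)
    cons = np.asarray(consumption, dtype=float)
    out = r + N * np.asarray(lam, dtype=float) - c0 * r - cons
    np.maximum(out, 0.0, out=out)
    return out


def _mutate_tenths(pop_tenths: np.ndarray, mu: float, trait_lethal_fraction: float, rng) -> np.ndarray:
    """Mutate a batch of phenotypes in place; return per-row changed flags.

    Every trait of every row mutates independently with probability ``mu``.
    A fraction ``trait_lethal_fraction`` of mutations are trait-lethals that
    reset the affinity to 0; the rest step the affinity by +-0.1 with equal
    probability, clamped to the grid ends (a clamped step is a no-op).
    """
    n = pop_tenths.shape[0]
    changed = np.zeros(n, dtype=bool)
    if mu <= 0.0 or n == 0:
        return changed
    hit = rng.random(pop_tenths.shape) < mu
    if not hit.any():
        return changed
    rows, cols = np.nonzero(hit)
    m = rows.size
    lethal = rng.random(m) < trait_lethal_fraction
    steps = rng.integers(0, 2, size=m) * 2 - 1
    old = pop_tenths[rows, cols]
    new = np.where(
        lethal, 0, np.clip(old.astype(np.int16) + steps, 0, TENTHS_MAX)
    ).astype(np.int8)
    pop_tenths[rows, cols] = new
    changed[rows[new != old]] = True
    return changed


def mutate(phenotype, mu: float, trait_lethal_fraction: float, rng) -> np.ndarray:
    """Return a mutated copy of one phenotype (as real grid affinities)."""
    t = as_tenths(phenotype).reshape(1, -1).copy()
    _mutate_tenths(t, mu, trait_lethal_fraction, rng)
    return as_affinities(t[0])
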