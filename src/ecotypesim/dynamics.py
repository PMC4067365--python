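"""Population process: death-birth turnover, run loop, and state I/O.

Each update, a fixed fraction of the population (default 1%) is removed
uniformly at random and replaced by offspring of surviving parents drawn
with probability proportional to fitness (a death-birth Moran process with
multiple deaths/births per update; at 1% turnover one generation is about
100 updates).  Fitness is evaluated once per update from the pre-update
resource state, and resources are advanced once per update with the
consumption of the pre-update population.

The variable-population-size control removes the same fraction uniformly
but lets every survivor reproduce independently with probability equal to
its fitness (clamped to 1).  The resource influx term N*lam is a property
of the environment, not of the census: it always uses the configured
population-size parameter N, so in variable mode the total supply rate is
fixed while removal and reproduction follow the current count.  This is
what makes a stationary size possible at all -- per-capita fitness then
falls with crowding until it balances the removal rate -- whereas influx
proportional to the current count would cap mean fitness at R*lam
regardless of size.  Extinction is a normal terminal outcome, reported in
the result rather than raised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    SimulationConfig,
    _batch_fitness,
    _mutate_tenths,
    as_affinities,
    update_resources,
)
from .lineage import AncestryForest

__all__ = [
    "PopulationState",
    "RunResult",
    "step_constant",
    "step_variable",
    "run",
    "save_state",
    "load_state",
]

STATE_SCHEMA_VERSION = 1
#: prune the ancestry forest down to ancestors of the living every this many updates
PRUNE_INTERVAL = 1000


@dataclass
class PopulationState:
    """The population at one instant.

    ``tenths`` holds one row of integer-tenth affinities per individual,
    ``ids`` the matching unique individual ids (never reused within a run;
    parent pointers and birth updates live in the ancestry forest).
    """

    tenths: np.ndarray
    ids: np.ndarray
    resources: np.ndarray
    update: int = 0
    next_id: int = 0

    @property
    def n(self) -> int:
        return self.tenths.shape[0]

    def copy(self) -> "PopulationState":
        return PopulationState(
            tenths=self.tenths.copy(),
            ids=self.ids.copy(),
            resources=self.resources.copy(),
            update=self.update,
            next_id=self.next_id,
        )

    def affinities(self) -> np.ndarray:
        """Population affinities as real values (n x R)."""
        return as_affinities(self.tenths)


@dataclass
class RunResult:
    """Everything a completed run produces."""

    final_state: PopulationState
    ancestry: Optional[AncestryForest]
    trajectory: pd.DataFrame
    resource_history: np.ndarray
    config: SimulationConfig
    extinct: bool = False

    def trajectory_tsv(self, path) -> None:
        self.trajectory.to_csv(path, sep="\t", index=False)


def _record_births(forest, child_ids, parent_ids, update, offspring, changed) -> None:
    for j in range(len(child_ids)):
        ph = offspring[j].tobytes() if changed[j] else None
        forest.add(int(child_ids[j]), int(parent_ids[j]), update, ph)


def step_constant(
    state: PopulationState,
    config: SimulationConfig,
    rng,
    forest: Optional[AncestryForest] = None,
) -> PopulationState:
    """Advance one constant-N update in place; returns the same state."""
    _step_constant(state, config, rng, forest,
                   config.gamma_vector(), config.lam_vector())
    return state


def _step_constant(state, config, rng, forest, gamma, lam) -> float:
    """Inner constant-N update; returns the pre-update mean fitness."""
    n = state.n
    pop = state.tenths
    f, cons = _batch_fitness(pop, state.resources, gamma, config.sigma1, config.sigma2)
    k = round(config.kill_fraction * n)
    u = state.update + 1
    if k > 0:
        dead = rng.choice(n, size=k, replace=False)
        w = f.copy()
        w[dead] = 0.0
        total = w.sum()
        if total > 0.0:
            cum = np.cumsum(w)
            parents = np.searchsorted(cum, rng.random(k) * total, side="right")
            np.clip(parents, 0, n - 1, out=parents)
        else:
            # degenerate: all survivors have zero fitness -> uniform choice
            survivors = np.setdiff1d(np.arange(n), dead, assume_unique=False)
            parents = survivors[rng.integers(0, survivors.size, size=k)]
        offspring = pop[parents].copy()
        changed = _mutate_tenths(offspring, config.mu, config.trait_lethal_fraction, rng)
        child_ids = np.arange(state.next_id, state.next_id + k, dtype=np.int64)
        if forest is not None:
            _record_births(forest, child_ids, state.ids[parents], u, offspring, changed)
            forest.alive.difference_update(state.ids[dead].tolist())
            forest.alive.update(child_ids.tolist())
        pop[dead] = offspring
        state.ids[dead] = child_ids
        state.next_id += k
    # influx reference is the configured N (equals the census in a plain
    # constant-N run, but is kept when assaying a variable-mode endpoint)
    state.resources = update_resources(state.resources, cons, config.N, lam, config.c0)
    state.update = u
    return float(f.mean())


def step_variable(
    state: PopulationState,
    config: SimulationConfig,
    rng,
    forest: Optional[AncestryForest] = None,
) -> PopulationState:
    """Advance one variable-N update in place; returns the same state."""
    _step_variable(state, config, rng, forest,
                   config.gamma_vector(), config.lam_vector())
    return state


def _step_variable(state, config, rng, forest, gamma, lam) -> float:
    """Inner variable-N update; returns the pre-update mean fitness."""
    n = state.n
    if n == 0:
        state.update += 1
        return 0.0
    pop = state.tenths
    f, cons = _batch_fitness(pop, state.resources, gamma, config.sigma1, config.sigma2)
    # at least one removal per update: without this floor a census below
    # 1/(2*kill_fraction) would round to zero deaths and freeze forever
    k = max(1, round(config.kill_fraction * n))
    u = state.update + 1
    alive_mask = np.ones(n, dtype=bool)
    if k > 0:
        dead = rng.choice(n, size=min(k, n), replace=False)
        alive_mask[dead] = False
    surv_idx = np.flatnonzero(alive_mask)
    # every survivor reproduces independently with probability min(F, 1)
    p = np.clip(f[surv_idx], 0.0, 1.0)
    repro = surv_idx[rng.random(surv_idx.size) < p]
    offspring = pop[repro].copy()
    changed = _mutate_tenths(offspring, config.mu, config.trait_lethal_fraction, rng)
    child_ids = np.arange(state.next_id, state.next_id + len(repro), dtype=np.int64)
    if forest is not None:
        if k > 0:
            forest.alive.difference_update(state.ids[dead].tolist())
        _record_births(forest, child_ids, state.ids[repro], u, offspring, changed)
        forest.alive.update(child_ids.tolist())
    state.tenths = np.concatenate([pop[surv_idx], offspring], axis=0)
    state.ids = np.concatenate([state.ids[surv_idx], child_ids])
    state.next_id += len(repro)
    # influx reference is the configured N (fixed environmental supply rate)
    state.resources = update_resources(state.resources, cons, config.N, lam, config.c0)
    state.update = u
    return float(f.mean())


def init_state(config: SimulationConfig, forest: Optional[AncestryForest] = None) -> PopulationState:
    """Homogeneous starting population and resource state.

    ``specialist`` starts every organism with affinity 0.1 for the first
    resource only; ``generalist`` with affinity 0.1 for all R resources.
    Resources start at the consumption-free minimum N*lam or maximum
    N*lam/c0.
    """
    n0 = config.initial_population if config.initial_population is not None else config.N
    tenths = np.zeros((n0, config.R), dtype=np.int8)
    if config.init_mode == "specialist":
        tenths[:, 0] = 1
    else:
        tenths[:, :] = 1
    lam = config.lam_vector()
    if config.resource_init == "min":
        resources = config.N * lam
    else:
        resources = config.N * lam / config.c0
    ids = np.arange(n0, dtype=np.int64)
    if forest is not None:
        ph = tenths[0].tobytes()
        for i in range(n0):
            forest.add(i, None, 0, ph)
        forest.alive = set(range(n0))
    return PopulationState(tenths=tenths, ids=ids, resources=resources,
                           update=0, next_id=n0)


def run(config: SimulationConfig, rng=None) -> RunResult:
    """Run a full simulation; bit-for-bit reproducible given (config, seed)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    forest = AncestryForest() if config.record_ancestry else None
    state = init_state(config, forest)
    gamma = config.gamma_vector()
    lam = config.lam_vector()
    step = _step_constant if config.population_mode == "constant" else _step_variable
    resource_history = np.empty((config.updates + 1, config.R))
    resource_history[0] = state.resources
    rows = []
    extinct = False
    stride = max(config.record_stride, 1)
    for u in range(1, config.updates + 1):
        mean_f = step(state, config, rng, forest, gamma, lam)
        resource_history[u] = state.resources
        if u % stride == 0 or u == config.updates:
            rows.append(
                (u, mean_f, *state.resources,
                 len(np.unique(state.tenths, axis=0)) if state.n else 0, state.n)
            )
        if forest is not None and u % PRUNE_INTERVAL == 0:
            forest.prune()
        if state.n == 0:
            extinct = True
            resource_history = resource_history[: u + 1]
            break
    columns = (
        ["update", "mean_fitness"]
        + [f"r_{k + 1}" for k in range(config.R)]
        + ["n_unique_phenotypes", "population_size"]
    )
    trajectory = pd.DataFrame(rows, columns=columns)
    return RunResult(
        final_state=state,
        ancestry=forest,
        trajectory=trajectory,
        resource_history=resource_history,
        config=config,
        extinct=extinct,
    )


# ---------------------------------------------------------------------------
# state (de)serialisation — plain JSON container with a schema version


def save_state(path, state: PopulationState, config: SimulationConfig,
               forest: Optional[AncestryForest] = None) -> None:
    doc = {
        "schema_version": STATE_SCHEMA_VERSION,
        "config": config.to_dict(),
        "update": state.update,
        "next_id": state.next_id,
        "ids": state.ids.tolist(),
        "tenths": state.tenths.tolist(),
        "resources": state.resources.tolist(),
        "ancestry": forest.to_dict() if forest is not None else None,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_state(path):
    """Returns ``(state, config, forest-or-None)``."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != STATE_SCHEMA_VERSION:
        raise ValueError("unsupported state schema version")
    config = SimulationConfig.from_dict(doc["config"])
    state = PopulationState(
        tenths=np.asarray(doc["tenths"], dtype=np.int8),
        ids=np.asarray(doc["ids"], dtype=np.int64),
        resources=np.asarray(doc["resources"], dtype=float),
        update=doc["update"],
        next_id=doc["next_id"],
    )
    forest = AncestryForest.from_dict(doc["ancestry"]) if doc["ancestry"] else None
    return state, config, forest
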