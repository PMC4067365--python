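"""Measurement protocols: ecotype counting and niche breadth.

Ecotypes (stable phenotype lineages, Ecological Species Concept) are
counted by a zero-mutation competition: with the mutation rate forced to
zero no new phenotypes arise and transient ones are competitively excluded,
so the phenotypes that remain and hold steady frequencies are the stably
coexisting ecotypes.  When stability is in doubt, invasion-when-rare
experiments test each member directly: a phenotype maintained by negative
frequency-dependent selection regains frequency after being knocked down to
rarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import SimulationConfig, as_affinities, as_tenths
from .dynamics import PopulationState, _step_constant

__all__ = [
    "AssayResult",
    "zero_mutation_assay",
    "invasion_experiment",
    "niche_breadth",
]

#: phenotypes below this population frequency at assay end are drift debris
ECOTYPE_FREQ_THRESHOLD = 0.005
#: trailing window (updates) over which composition must hold steady
STABILITY_WINDOW = 5000
#: maximum relative frequency change tolerated across the window
STABILITY_REL_CHANGE = 0.20
#: updates between composition snapshots
SNAPSHOT_STRIDE = 250


@dataclass
class AssayResult:
    """Outcome of a zero-mutation competition.

    ``ecotype_phenotypes`` pairs each surviving phenotype (real affinities)
    with its final population frequency, most common first.
    """

    n_ecotypes: int
    niche_breadth: float
    ecotype_phenotypes: List[Tuple[np.ndarray, float]]
    stabilized_at: Optional[int]
    capped: bool


def niche_breadth(state: PopulationState) -> float:
    """Fraction of non-zero affinities in the population.

    B = sum_{i,k} [c_ik > 0] / (N * R); 1/R when every individual uses
    exactly one resource, 1 when every individual uses all of them.
    """
    if state.n == 0:
        raise ValueError("niche breadth is undefined for an empty population")
    return float(np.count_nonzero(state.tenths) / state.tenths.size)


def _composition(pop: np.ndarray) -> Dict[bytes, int]:
    uniq, counts = np.unique(pop, axis=0, return_counts=True)
    return {uniq[i].tobytes(): int(counts[i]) for i in range(len(uniq))}


def _window_stable(history: List[Tuple[int, Dict[bytes, int]]], n: int) -> bool:
    """True when composition held steady over the trailing window.

    Requires: no phenotype lost anywhere in the window, and no
    above-threshold phenotype's frequency changed by more than 20%
    (relative) between the window's ends.
    """
    u_now = history[-1][0]
    start_idx = None
    for i, (u, _) in enumerate(history):
        if u_now - u >= STABILITY_WINDOW:
            start_idx = i
        else:
            break
    if start_idx is None:
        return False
    window = history[start_idx:]
    keys = set(window[0][1])
    for _, comp in window[1:]:
        if set(comp) != keys:
            return False
    first, last = window[0][1], window[-1][1]
    thresh = ECOTYPE_FREQ_THRESHOLD * n
    for key, c0 in first.items():
        if c0 < thresh:
            continue
        if abs(last[key] - c0) / c0 > STABILITY_REL_CHANGE:
            return False
    return True


def zero_mutation_assay(
    state: PopulationState,
    config: SimulationConfig,
    max_updates: int = 80_000,
    rng=None,
) -> AssayResult:
    """Competition at mu=0 until the survivors cannot outcompete each other.

    Continues constant-N dynamics from a copy of ``state`` for the full
    ``max_updates`` competition budget, exiting early only once the
    population is monomorphic (nothing left to exclude).  Slow competitive
    exclusion in near-neutral regimes is drift-paced and indistinguishable
    from coexistence over any short window, so the budget is spent in full
    rather than stopping at apparent stationarity.  ``stabilized_at``
    reports when the set of surviving phenotypes last changed; ``capped``
    is set when the budget ran out while the composition still failed the
    trailing-window steadiness check (no phenotype lost, no above-threshold
    frequency moving more than 20% over 5,000 updates).  Surviving
    phenotypes above the admission frequency threshold are the ecotypes.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    state = state.copy()
    # census is frozen at state.n; config.N is kept as the influx reference
    cfg = config.replace(mu=0.0, population_mode="constant", initial_population=None)
    gamma, lam = cfg.gamma_vector(), cfg.lam_vector()
    start = state.update
    history: List[Tuple[int, Dict[bytes, int]]] = [(start, _composition(state.tenths))]
    stabilized_at = start
    capped = False
    if len(history[0][1]) > 1:
        for u in range(1, max_updates + 1):
            _step_constant(state, cfg, rng, None, gamma, lam)
            if u % SNAPSHOT_STRIDE == 0:
                history.append((state.update, _composition(state.tenths)))
                if set(history[-1][1]) != set(history[-2][1]):
                    stabilized_at = state.update
                # drop snapshots that fell out of the trailing window
                while state.update - history[1][0] >= STABILITY_WINDOW:
                    history.pop(0)
                if len(history[-1][1]) == 1:
                    break
        else:
            capped = not _window_stable(history, state.n)
    comp = _composition(state.tenths)
    n = state.n
    thresh = ECOTYPE_FREQ_THRESHOLD * n
    ecotypes = sorted(
        ((k, c) for k, c in comp.items() if c >= thresh),
        key=lambda kv: -kv[1],
    )
    phenos = [
        (as_affinities(np.frombuffer(k, dtype=np.int8)), c / n) for k, c in ecotypes
    ]
    return AssayResult(
        n_ecotypes=len(phenos),
        niche_breadth=niche_breadth(state),
        ecotype_phenotypes=phenos,
        stabilized_at=stabilized_at,
        capped=capped,
    )


def _largest_remainder_counts(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``."""
    quota = weights / weights.sum() * total
    counts = np.floor(quota).astype(int)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(-(quota - counts))
        counts[order[:short]] += 1
    return counts


def invasion_experiment(
    ecotypes: Sequence,
    focal: int,
    config: SimulationConfig,
    rng=None,
    low_frequency: float = 0.01,
    frequencies: Optional[Sequence[float]] = None,
    max_updates: int = 20_000,
    recovery_factor: float = 2.0,
    sustain_window: int = 500,
) -> bool:
    """Can the focal phenotype invade when rare?

    The focal ecotype starts at ``low_frequency``; the rest of the
    population is split among the other ecotypes in proportion to
    ``frequencies`` (equal shares by default).  Dynamics run at mu=0; the
    experiment succeeds when the focal phenotype's frequency exceeds
    ``recovery_factor`` times its initial frequency for ``sustain_window``
    consecutive updates, and fails on extinction or timeout.
    """
    if len(ecotypes) < 2:
        raise ValueError("invasion experiments need at least two ecotypes")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    n = config.N
    tenths = [as_tenths(p) for p in ecotypes]
    n_focal = max(1, round(low_frequency * n))
    others = [i for i in range(len(tenths)) if i != focal]
    if frequencies is None:
        w = np.ones(len(others))
    else:
        w = np.asarray([frequencies[i] for i in others], dtype=float)
    counts = np.zeros(len(tenths), dtype=int)
    counts[focal] = n_focal
    counts[others] = _largest_remainder_counts(w, n - n_focal)
    pop = np.concatenate(
        [np.tile(tenths[i], (counts[i], 1)) for i in range(len(tenths))], axis=0
    ).astype(np.int8)
    cfg = config.replace(mu=0.0, N=n, population_mode="constant",
                         initial_population=None)
    gamma, lam = cfg.gamma_vector(), cfg.lam_vector()
    resources = n * lam if cfg.resource_init == "min" else n * lam / cfg.c0
    state = PopulationState(
        tenths=pop,
        ids=np.arange(n, dtype=np.int64),
        resources=resources.copy(),
        update=0,
        next_id=n,
    )
    focal_row = tenths[focal]
    # phenotype identity is exact vector equality, so the realized initial
    # count includes any ecotype identical to the focal one
    initial = int(np.all(pop == focal_row, axis=1).sum())
    target = recovery_factor * initial
    above = 0
    for _ in range(max_updates):
        _step_constant(state, cfg, rng, None, gamma, lam)
        count = int(np.all(state.tenths == focal_row, axis=1).sum())
        if count == 0:
            return False
        if count >= target:
            above += 1
            if above >= sustain_window:
                return True
        else:
            above = 0
    return False
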