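"""Ancestry recording and genealogy reconstruction.

Every birth is recorded as a parent pointer; the phenotype is stored only
when the offspring differs from its parent (a phenotype-changing birth), so
a line of descent compresses to its mutational history.  From this forest
we reconstruct most recent common ancestors, lines of descent with
per-mutation selection coefficients, and exact-genealogy phylograms in
Newick form.  Trees here are genealogies, not inferences: branch lengths
are measured in simulation updates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set

import numpy as np

from .core import as_affinities, as_tenths, fitness

__all__ = [
    "AncestryForest",
    "MutationEvent",
    "mrca",
    "line_of_descent",
    "selection_coefficient",
    "phylogram",
]


@dataclass
class MutationEvent:
    """A phenotype-changing birth on a line of descent.

    ``s`` is the selection coefficient of the new phenotype relative to its
    immediate ancestor, evaluated at the resource state into which the
    mutant was born; ``None`` when resources were not supplied, ``nan``
    (undefined) when the ancestor's fitness was zero.
    """

    update: int
    phenotype_after: np.ndarray
    s: Optional[float] = None


class AncestryForest:
    """Append-only parent-pointer records of every birth in a run.

    Records map ``id -> (parent_id, birth_update, phenotype_tenths|None)``;
    a stored phenotype of ``None`` means "same as parent".  Founders have
    ``parent_id`` ``None`` and always carry their phenotype.  ``alive`` is
    maintained by the simulation loop.
    """

    def __init__(self) -> None:
        self._records: Dict[int, tuple] = {}
        self.alive: Set[int] = set()

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, id_: int) -> bool:
        return id_ in self._records

    def add(self, id_: int, parent_id: Optional[int], birth_update: int,
            phenotype_tenths: Optional[bytes] = None) -> None:
        if parent_id is not None:
            pu = self._records[parent_id][1]
            if pu >= birth_update:
                raise ValueError("child must be born after its parent")
        self._records[id_] = (parent_id, birth_update, phenotype_tenths)

    def parent(self, id_: int) -> Optional[int]:
        return self._records[id_][0]

    def birth_update(self, id_: int) -> int:
        return self._records[id_][1]

    def stored_phenotype(self, id_: int) -> Optional[bytes]:
        return self._records[id_][2]

    def phenotype(self, id_: int, R: int) -> np.ndarray:
        """Phenotype of ``id_`` (tenths), following parents if unchanged."""
        node: Optional[int] = id_
        while node is not None:
            ph = self._records[node][2]
            if ph is not None:
                return np.frombuffer(ph, dtype=np.int8, count=R).copy()
            node = self._records[node][0]
        raise ValueError(f"no phenotype recorded on the ancestry of id {id_}")

    def path_to_founder(self, id_: int) -> List[int]:
        """ids from the founder down to ``id_`` (inclusive)."""
        if id_ not in self._records:
            raise KeyError(f"unknown id {id_}")
        path = []
        node: Optional[int] = id_
        while node is not None:
            path.append(node)
            node = self._records[node][0]
        path.reverse()
        return path

    def prune(self, keep_for: Optional[Iterable[int]] = None) -> int:
        """Discard records not ancestral to any of ``keep_for`` (default:
        the alive set).  Returns the number of records removed.  Pruning
        never changes mrca/line_of_descent answers for kept ids."""
        roots = set(keep_for) if keep_for is not None else set(self.alive)
        keep: Set[int] = set()
        for id_ in roots:
            node: Optional[int] = id_
            while node is not None and node not in keep:
                keep.add(node)
                node = self._records[node][0]
        doomed = [i for i in self._records if i not in keep]
        for i in doomed:
            del self._records[i]
        return len(doomed)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "alive": sorted(self.alive),
            "records": {
                str(i): [p, u, ph.hex() if ph is not None else None]
                for i, (p, u, ph) in self._records.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AncestryForest":
        forest = cls()
        for i, (p, u, ph) in d["records"].items():
            forest._records[int(i)] = (
                p,
                u,
                bytes.fromhex(ph) if ph is not None else None,
            )
        forest.alive = set(d["alive"])
        return forest


def mrca(forest: AncestryForest, ids: Sequence[int]) -> Optional[int]:
    """Birth update of the most recent common ancestor of ``ids``.

    Returns ``None`` when the lineages never coalesce within the recorded
    history (descendants of distinct founders).
    """
    ids = list(ids)
    if not ids:
        raise ValueError("ids must be non-empty")
    common: Optional[Set[int]] = None
    for id_ in ids:
        ancestors = set(forest.path_to_founder(id_))
        common = ancestors if common is None else common & ancestors
        if not common:
            return None
    assert common is not None
    return max(forest.birth_update(i) for i in common)


def selection_coefficient(mutant, parent, resources, config) -> float:
    """s = F_mutant / F_parent - 1 at the mutant's birth resource state.

    Returns ``nan`` (undefined) when the parent's fitness is zero.
    """
    fm = fitness(mutant, resources, config.gamma_vector(), config.sigma1, config.sigma2)
    fp = fitness(parent, resources, config.gamma_vector(), config.sigma1, config.sigma2)
    if fp.total == 0.0:
        return float("nan")
    return fm.total / fp.total - 1.0


def line_of_descent(
    forest: AncestryForest,
    id_: int,
    resource_history: Optional[np.ndarray] = None,
    config=None,
) -> List[MutationEvent]:
    """Chronological phenotype-changing events from founder to ``id_``.

    Phenotypically silent reproductions are excluded.  When
    ``resource_history`` (row per update, row 0 = initial state) and the run
    config are given, each event's selection coefficient is evaluated at the
    resource state the mutant was born into (the state at the start of its
    birth update).
    """
    events: List[MutationEvent] = []
    prev_pheno: Optional[np.ndarray] = None
    for node in forest.path_to_founder(id_):
        ph = forest.stored_phenotype(node)
        if ph is None:
            continue
        pheno = as_affinities(np.frombuffer(ph, dtype=np.int8))
        s: Optional[float] = None
        if prev_pheno is not None and resource_history is not None and config is not None:
            u = forest.birth_update(node)
            res = resource_history[max(u - 1, 0)]
            s = selection_coefficient(pheno, prev_pheno, res, config)
        events.append(MutationEvent(forest.birth_update(node), pheno, s))
        prev_pheno = pheno
    return events


def _newick_label(label: str) -> str:
    if any(ch in label for ch in " (),:;'[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


def phylogram(
    forest: AncestryForest,
    ids: Sequence[int],
    observed_update: int,
    labels: Optional[Dict[int, str]] = None,
) -> str:
    """Newick genealogy of ``ids`` with branch lengths in updates.

    Internal nodes sit at coalescence updates (the birth update of the last
    record shared by the subtended leaves); leaves extend to
    ``observed_update``.  Lineages descending from distinct founders are
    joined at a root of age 0.
    """
    ids = list(ids)
    if not ids:
        raise ValueError("ids must be non-empty")
    labels = labels or {}
    paths = {i: forest.path_to_founder(i) for i in ids}

    def leaf(i: int) -> str:
        return _newick_label(labels.get(i, f"id{i}"))

    def build(group: List[int], depth: int, parent_time: int) -> str:
        # all paths in `group` agree on records [0, depth); advance while shared
        while True:
            exhausted = [i for i in group if len(paths[i]) == depth]
            heads = {paths[i][depth] for i in group if len(paths[i]) > depth}
            if exhausted or len(heads) > 1:
                break
            depth += 1
        node_time = forest.birth_update(paths[group[0]][depth - 1]) if depth > 0 else 0
        if len(group) == 1:
            return f"{leaf(group[0])}:{observed_update - parent_time:g}"
        children: List[str] = []
        for i in exhausted:
            children.append(f"{leaf(i)}:{observed_update - node_time:g}")
        by_head: Dict[int, List[int]] = {}
        for i in group:
            if len(paths[i]) > depth:
                by_head.setdefault(paths[i][depth], []).append(i)
        for sub in by_head.values():
            children.append(build(sub, depth, node_time))
        return "(" + ",".join(children) + f"):{node_time - parent_time:g}"

    # the root keeps its own edge (founder age in updates); legal Newick
    return build(ids, 0, 0) + ";"
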