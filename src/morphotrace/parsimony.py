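"""Unordered (Fitch-style) parsimony on a fixed rooted tree.

All characters are treated as unordered and unpolarised; missing (``?``)
and inapplicable (``-``) cells impose no constraint on their tip.  The
tree is used as rooted and may contain polytomies; step counts are exact
for polytomies (unit-cost Sankoff dynamic programme, equivalent to
Hartigan's generalisation of Fitch).

Provided operations:

* :func:`fitch_steps` - minimum number of state changes for one character.
* :func:`mpr_sets` - per-node sets of states occurring in at least one
  most-parsimonious reconstruction (MPR).
* :func:`resolve` - a single MPR under the accelerated (ACCTRAN) or
  delayed (DELTRAN) transformation convention, with its branch-change list.
* :func:`find_synapomorphies` - characters whose ACCTRAN and DELTRAN
  resolutions both place a change to the same derived state on a clade's
  stem branch, flagged "homoplasy-free" when the character traces at its
  conceivable minimum (consistency index 1).
* :func:`brute_force_min_steps` - exhaustive-enumeration oracle for small
  trees (used to validate the dynamic programme).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Literal, Optional, Sequence

from .characters import CharacterMatrix
from .tree import Node, Phylogeny

__all__ = [
    "Reconstruction",
    "BranchChange",
    "SynapomorphyReport",
    "fitch_steps",
    "mpr_sets",
    "resolve",
    "find_synapomorphies",
    "brute_force_min_steps",
]

_STATES = (0, 1, 2, 3)
_INF = 10 ** 9


@dataclass(frozen=True)
class BranchChange:
    """A state change on the branch subtending ``node_id``."""
    node_id: int
    node_label: Optional[str]
    from_state: int
    to_state: int


@dataclass
class Reconstruction:
    char: int
    resolution: str                       # "MPR", "ACCTRAN" or "DELTRAN"
    steps: int
    state_sets: dict[int, frozenset[int]]           # node id -> MPR set
    states: Optional[dict[int, int]] = None         # single-state resolution
    changes: list[BranchChange] = field(default_factory=list)


@dataclass
class SynapomorphyEntry:
    char: int
    derived_state: int
    homoplasy_free: bool


@dataclass
class SynapomorphyReport:
    clade: frozenset[str]
    entries: list[SynapomorphyEntry]

    @property
    def characters(self) -> list[int]:
        return [e.char for e in self.entries]

    @property
    def homoplasy_free_characters(self) -> list[int]:
        return [e.char for e in self.entries if e.homoplasy_free]


# -- internals --------------------------------------------------------------

def _tip_states(matrix: CharacterMatrix, char: int,
                restrict: Optional[set[str]]) -> dict[str, Optional[frozenset[int]]]:
    col = matrix.column(char)
    out: dict[str, Optional[frozenset[int]]] = {}
    for taxon, code in col.items():
        if restrict is not None and taxon not in restrict:
            out[taxon] = None           # tip excluded from the count
        elif code < 0:
            out[taxon] = frozenset(_STATES)   # ?/- give no constraint
        else:
            out[taxon] = frozenset({code})
    return out


def _down_costs(tree: Phylogeny, tips: dict[str, Optional[frozenset[int]]]
                ) -> dict[int, Optional[list[int]]]:
    """cost[v][s] = min changes in the subtree of v given state(v)=s.

    Excluded tips get a ``None`` vector and contribute nothing.
    """
    down: dict[int, Optional[list[int]]] = {}
    for nd in tree.postorder():
        if nd.is_leaf:
            allowed = tips[nd.label]
            if allowed is None:
                down[nd.id] = None
            else:
                down[nd.id] = [0 if s in allowed else _INF for s in _STATES]
        else:
            vecs = [down[c.id] for c in nd.children if down[c.id] is not None]
            if not vecs:
                down[nd.id] = None
                continue
            total = [0, 0, 0, 0]
            for vec in vecs:
                best = min(vec)
                for s in _STATES:
                    total[s] += min(vec[s], best + 1)
            down[nd.id] = total
    return down


def _up_costs(tree: Phylogeny, down: dict[int, Optional[list[int]]]
              ) -> dict[int, list[int]]:
    """cost outside the subtree of v given state(v)=s (for nodes with a
    non-None down vector)."""
    up: dict[int, list[int]] = {}
    root = tree.root
    up[root.id] = [0, 0, 0, 0]
    for nd in tree.preorder():
        if down.get(nd.id) is None and nd is not root:
            continue
        if nd.id not in up:
            continue
        kids = [c for c in nd.children if down.get(c.id) is not None]
        for child in kids:
            # combined[t] = up[nd][t] + sum over other children b of
            #               min_r(down[b][r] + (r != t))
            combined = list(up[nd.id])
            for other in kids:
                if other is child:
                    continue
                vec = down[other.id]
                best = min(vec)
                for t in _STATES:
                    combined[t] += min(vec[t], best + 1)
            cbest = min(combined)
            up[child.id] = [min(combined[s], cbest + 1) for s in _STATES]
    return up


def _no_observed_states(tree: Phylogeny, matrix: CharacterMatrix, char: int,
                        restrict: Optional[set[str]]) -> bool:
    taxa = tree.tip_labels if restrict is None else restrict
    return not matrix.observed_states(char, taxa)


def fitch_steps(tree: Phylogeny, matrix: CharacterMatrix, char: int,
                within: Optional[Iterable[str]] = None) -> int:
    """Minimum number of unordered state changes for ``char`` on ``tree``.

    ``within`` restricts the count to the subtree spanned by the given tip
    labels (all other tips impose no constraint and contribute no steps);
    used e.g. to count steps within the *Pisione* radiation only.
    """
    restrict = set(within) if within is not None else None
    if _no_observed_states(tree, matrix, char, restrict):
        warnings.warn(f"character {char}: no observed states; 0 steps",
                      stacklevel=2)
        return 0
    tips = _tip_states(matrix, char, restrict)
    down = _down_costs(tree, tips)
    return min(down[tree.root.id])


def mpr_sets(tree: Phylogeny, matrix: CharacterMatrix, char: int
             ) -> Reconstruction:
    """Per-node sets of states realised in at least one MPR."""
    if _no_observed_states(tree, matrix, char, None):
        warnings.warn(f"character {char}: no observed states", stacklevel=2)
        sets = {nd.id: frozenset(_STATES) for nd in tree.nodes}
        return Reconstruction(char, "MPR", 0, sets)
    tips = _tip_states(matrix, char, None)
    down = _down_costs(tree, tips)
    up = _up_costs(tree, down)
    total = min(down[tree.root.id])
    sets: dict[int, frozenset[int]] = {}
    for nd in tree.nodes:
        dvec = down.get(nd.id)
        if dvec is None:
            sets[nd.id] = frozenset(_STATES)
            continue
        uvec = up[nd.id]
        sets[nd.id] = frozenset(s for s in _STATES
                                if dvec[s] + uvec[s] == total)
    return Reconstruction(char, "MPR", total, sets)


def resolve(tree: Phylogeny, matrix: CharacterMatrix, char: int,
            mode: Literal["ACCTRAN", "DELTRAN"]) -> Reconstruction:
    """A single most-parsimonious state per node.

    Both modes walk the tree in deterministic preorder, keeping global
    optimality at every branch.  Where a branch admits both "change here"
    and "change later" at equal cost, ACCTRAN changes immediately (placing
    transformations as close to the root as possible, favouring reversals)
    and DELTRAN defers (favouring parallelisms near the tips).  Remaining
    ties break toward the smallest state label, so runs are repeatable.
    """
    mode = mode.upper()
    if mode not in ("ACCTRAN", "DELTRAN"):
        raise ValueError(f"mode must be ACCTRAN or DELTRAN, got {mode!r}")
    if _no_observed_states(tree, matrix, char, None):
        warnings.warn(f"character {char}: no observed states", stacklevel=2)
        states = {nd.id: 0 for nd in tree.nodes}
        return Reconstruction(char, mode, 0, {nd.id: frozenset({0})
                                              for nd in tree.nodes}, states)
    tips = _tip_states(matrix, char, None)
    down = _down_costs(tree, tips)
    up = _up_costs(tree, down)
    total = min(down[tree.root.id])
    mpr = {nd.id: frozenset(s for s in _STATES
                            if down[nd.id] is not None
                            and down[nd.id][s] + up[nd.id][s] == total)
           for nd in tree.nodes if down.get(nd.id) is not None}

    states: dict[int, int] = {}
    changes: list[BranchChange] = []
    for nd in tree.preorder():
        if down.get(nd.id) is None:
            # subtree with no observed data: inherit the parent state
            states[nd.id] = states[nd.parent.id] if nd.parent else 0
            continue
        dvec = down[nd.id]
        if nd is tree.root:
            states[nd.id] = min(mpr[nd.id])
            continue
        p = states[nd.parent.id]
        best = min(min(dvec) + 1, dvec[p])
        cands = [s for s in _STATES
                 if (dvec[s] + (1 if s != p else 0)) == best]
        if p in cands and mode == "DELTRAN":
            choice = p
        elif mode == "ACCTRAN":
            non_parent = [s for s in cands if s != p]
            choice = non_parent[0] if non_parent else p
        else:
            choice = cands[0]
        states[nd.id] = choice
        if choice != p:
            changes.append(BranchChange(nd.id, nd.label, p, choice))
    rec = Reconstruction(char, mode, total,
                         {k: frozenset(v) for k, v in mpr.items()},
                         states, changes)
    assert len(changes) == total, (
        f"resolution lost optimality for character {char}: "
        f"{len(changes)} changes vs {total} steps")
    return rec


# -- synapomorphies ---------------------------------------------------------

def _min_conceivable(matrix: CharacterMatrix, char: int) -> int:
    return max(0, len(matrix.observed_states(char)) - 1)


def find_synapomorphies(tree: Phylogeny, matrix: CharacterMatrix,
                        clade: Iterable[str], meta=None) -> SynapomorphyReport:
    """Characters with an unambiguous change on the clade's stem branch.

    A character is listed when its ACCTRAN and DELTRAN resolutions both
    place a change to the same derived state on the branch subtending the
    clade's most recent common ancestor.  Tips without an observed state
    for a character are pruned before placing that character's changes, so
    that uninformative tips adjacent to the stem cannot smear an otherwise
    unambiguous stem change across two branches.  The ``homoplasy_free``
    flag marks characters that trace at their conceivable minimum number of
    steps (consistency index 1, i.e. each derived state arises once on the
    whole tree with no reversal).
    """
    clade = set(clade)
    if not clade:
        raise ValueError("empty clade")
    if clade >= set(tree.tip_labels):
        raise ValueError("clade must be a proper subset of the tips")
    mrca = tree.mrca(sorted(clade))
    spanned = tree.clade_tip_labels(mrca)
    intruders = spanned - clade
    if intruders:
        raise ValueError(
            f"label set is not monophyletic; the spanned clade also "
            f"contains {sorted(intruders)}")
    entries = []
    for char in range(1, matrix.n_characters + 1):
        col = matrix.column(char)
        observed = {t for t in tree.tip_labels if col[t] >= 0}
        members = sorted(clade & observed)
        if not members or observed <= clade:
            continue            # no data in, or no data outside, the clade
        sub = tree.induced(sorted(observed))
        sub_mrca = sub.mrca(members)
        if sub_mrca is sub.root:
            continue            # clade's stem vanishes after pruning
        acc = resolve(sub, matrix, char, "ACCTRAN")
        dlt = resolve(sub, matrix, char, "DELTRAN")
        acc_change = next((c for c in acc.changes
                           if c.node_id == sub_mrca.id), None)
        dlt_change = next((c for c in dlt.changes
                           if c.node_id == sub_mrca.id), None)
        if acc_change is None or dlt_change is None:
            continue
        if acc_change.to_state != dlt_change.to_state:
            continue
        clean = acc.steps == _min_conceivable(matrix, char)
        entries.append(SynapomorphyEntry(char, acc_change.to_state, clean))
    return SynapomorphyReport(frozenset(clade), entries)


# -- oracle -----------------------------------------------------------------

def brute_force_min_steps(tree: Phylogeny, matrix: CharacterMatrix,
                          char: int) -> int:
    """Exact minimum steps by exhaustive enumeration of internal-node
    assignments.  Only observed states need be enumerated (assigning an
    unobserved state to an internal node can never reduce the unit-cost
    change count).  Refuses instances with more than 12 internal nodes.
    """
    internal = [nd for nd in tree.nodes if not nd.is_leaf]
    if len(internal) > 12:
        raise ValueError(
            f"instance too large for enumeration: {len(internal)} internal "
            "nodes (limit 12)")
    obs = sorted(matrix.observed_states(char))
    if len(obs) <= 1:
        return 0
    col = matrix.column(char)
    tip_allowed = {}
    for nd in tree.nodes:
        if nd.is_leaf:
            code = col[nd.label]
            tip_allowed[nd.id] = obs if code < 0 else [code]
    best = _INF
    for assign in product(obs, repeat=len(internal)):
        states = {nd.id: s for nd, s in zip(internal, assign)}
        cost = 0
        for nd in tree.nodes:
            if nd is tree.root:
                continue
            pstate = states[nd.parent.id]
            if nd.is_leaf:
                cost += min(1 if s != pstate else 0
                            for s in tip_allowed[nd.id])
            else:
                cost += 1 if states[nd.id] != pstate else 0
        best = min(best, cost)
    return best
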