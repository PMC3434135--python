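"""Discrete gene-state characters: parsimony optimization, polarity, events.

Each gene is a four-state character over the species of the tree:

* ``ABSENT``      — no functional copy and no pseudogene found
* ``SINGLE``      — one functional copy
* ``MULTIPLE``    — two or more functional copies (copy number collapsed)
* ``PSEUDOGENE``  — an inactivated copy (stop codon / frameshift)

Ancestral states are reconstructed by minimum-change (Fitch) parsimony,
implemented as unit-cost Sankoff dynamic programming so that polytomies and
custom cost matrices are handled exactly. Where parsimony leaves the ancestral
state ambiguous, explicit polarity rules resolve it: absence is taken as
primitive at the root, a single copy is preferred over multiple copies or a
pseudogene (the most common condition is likely primitive), and other nodes
inherit the parent state when parsimony allows. Resolution never increases
the parsimony score.

State changes along branches are then typed as gene gain, duplication,
pseudogenization, or loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import CladeLookupError, ValidationError
from .tree import Node, TimeTree

__all__ = [
    "State",
    "EventType",
    "GeneStateCharacter",
    "EventRecord",
    "AncestralStateAssignment",
    "fitch_optimize",
    "resolve_polarity",
    "infer_events",
    "applicability",
]


class State(Enum):
    ABSENT = "0"
    SINGLE = "1"
    MULTIPLE = "2+"
    PSEUDOGENE = "P"

    def __repr__(self) -> str:
        return self.name


#: canonical state order used for dynamic-programming vectors
STATE_ORDER: tuple[State, ...] = (
    State.ABSENT,
    State.SINGLE,
    State.MULTIPLE,
    State.PSEUDOGENE,
)
_STATE_INDEX = {s: i for i, s in enumerate(STATE_ORDER)}

#: resolution preference: absent > single > pseudogene > multiple
PREFERENCE_ORDER: tuple[State, ...] = (
    State.ABSENT,
    State.SINGLE,
    State.PSEUDOGENE,
    State.MULTIPLE,
)


class EventType(Enum):
    GAIN = "gain"
    DUPLICATION = "duplication"
    PSEUDOGENIZATION = "pseudogenization"
    LOSS = "loss"

    def __repr__(self) -> str:
        return self.name


#: (parent state, child state) -> event type; identical states mean no event.
EVENT_TABLE: dict[tuple[State, State], EventType] = {
    (State.ABSENT, State.SINGLE): EventType.GAIN,
    (State.ABSENT, State.MULTIPLE): EventType.GAIN,
    (State.SINGLE, State.MULTIPLE): EventType.DUPLICATION,
    (State.SINGLE, State.PSEUDOGENE): EventType.PSEUDOGENIZATION,
    (State.MULTIPLE, State.PSEUDOGENE): EventType.PSEUDOGENIZATION,
    (State.SINGLE, State.ABSENT): EventType.LOSS,
    (State.MULTIPLE, State.ABSENT): EventType.LOSS,
    (State.PSEUDOGENE, State.ABSENT): EventType.LOSS,
    (State.MULTIPLE, State.SINGLE): EventType.LOSS,  # copy-number reduction
    # reactivation of a pseudogene: permitted by the algebra but warned
    (State.PSEUDOGENE, State.SINGLE): EventType.GAIN,
    (State.PSEUDOGENE, State.MULTIPLE): EventType.GAIN,
    # appearance directly as a pseudogene: outside the canonical algebra,
    # counted as a gain and warned
    (State.ABSENT, State.PSEUDOGENE): EventType.GAIN,
}

_REACTIVATIONS = {(State.PSEUDOGENE, State.SINGLE), (State.PSEUDOGENE, State.MULTIPLE)}
_NONCANONICAL = _REACTIVATIONS | {(State.ABSENT, State.PSEUDOGENE)}


@dataclass(frozen=True)
class GeneStateCharacter:
    """Tip states of one gene across species, with optional copy counts."""

    gene: str
    states: Mapping[str, State]
    copy_counts: Optional[Mapping[str, int]] = None

    def __post_init__(self) -> None:
        if self.copy_counts is not None:
            for sp, count in self.copy_counts.items():
                state = self.states.get(sp)
                if state is None:
                    raise ValidationError(
                        f"{self.gene}: copy count for unknown species {sp!r}"
                    )
                ok = (
                    (count == 0 and state is State.ABSENT)
                    or (count == 1 and state in (State.SINGLE, State.PSEUDOGENE))
                    or (count >= 2 and state is State.MULTIPLE)
                )
                if not ok:
                    raise ValidationError(
                        f"{self.gene}/{sp}: copy count {count} inconsistent "
                        f"with state {state.name}"
                    )

    def validate_against(self, tree: TimeTree) -> None:
        leaves = set(tree.leaf_labels)
        extra = set(self.states) - leaves
        if extra:
            raise ValidationError(f"{self.gene}: species not on tree: {sorted(extra)}")
        missing = leaves - set(self.states)
        if missing:
            raise ValidationError(f"{self.gene}: no state for species {sorted(missing)}")


@dataclass(frozen=True)
class EventRecord:
    """One typed state change on a branch (identified by its child node)."""

    gene: str
    branch: int  # child-node id on the tree the events were inferred on
    event_type: EventType
    parent_state: State
    child_state: State


@dataclass
class AncestralStateAssignment:
    """Parsimony reconstruction of one character on one tree.

    ``state_sets`` holds, per node, the set of states attaining the minimal
    subtree cost (the Fitch up-pass sets on binary unit-cost trees);
    ``resolved`` is filled by :func:`resolve_polarity` and always picks a
    member of the node's state set without increasing total cost.
    ``preference_resolved`` lists nodes where the tie was broken by the bare
    preference order (neither forced by parsimony nor inherited / covered by
    the quoted primitive-state rules).
    """

    gene: str
    score: int
    state_sets: dict[int, frozenset[State]]
    costs: dict[int, np.ndarray]
    cost_matrix: Optional[np.ndarray] = None
    resolved: Optional[dict[int, State]] = None
    preference_resolved: set[int] = field(default_factory=set)

    def resolved_state(self, node_id: int) -> State:
        if self.resolved is None:
            raise ValidationError("assignment not yet resolved; call resolve_polarity")
        return self.resolved[node_id]


_BIG = 1e9


def _unit_cost_matrix() -> np.ndarray:
    k = len(STATE_ORDER)
    return np.ones((k, k)) - np.eye(k)


def fitch_optimize(
    tree: TimeTree,
    character: GeneStateCharacter,
    cost_matrix: Optional[np.ndarray] = None,
) -> AncestralStateAssignment:
    """Minimum-change ancestral reconstruction of a four-state character.

    With the default unit costs this is Fitch parsimony; passing a custom
    4x4 ``cost_matrix`` (rows: parent state, columns: child state, order
    ABSENT/SINGLE/MULTIPLE/PSEUDOGENE) switches to generalized Sankoff
    parsimony.
    """
    character.validate_against(tree)
    cm = _unit_cost_matrix() if cost_matrix is None else np.asarray(cost_matrix, float)
    if cm.shape != (4, 4):
        raise ValidationError("cost matrix must be 4x4")

    costs: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            vec = np.full(4, _BIG)
            vec[_STATE_INDEX[character.states[node.label]]] = 0.0
        else:
            vec = np.zeros(4)
            for child in node.children:
                cc = costs[child.id]
                # cost of child subtree given this node's state s:
                # min_t ( cm[s, t] + cc[t] )
                vec = vec + (cm + cc[None, :]).min(axis=1)
        costs[node.id] = vec

    root_costs = costs[tree.root.id]
    score = float(root_costs.min())
    state_sets = {
        nid: frozenset(
            STATE_ORDER[i] for i in np.flatnonzero(vec <= vec.min() + 1e-9)
        )
        for nid, vec in costs.items()
    }
    return AncestralStateAssignment(
        gene=character.gene,
        score=int(round(score)),
        state_sets=state_sets,
        costs=costs,
        cost_matrix=cm,
    )


def resolve_polarity(
    assignment: AncestralStateAssignment, tree: TimeTree
) -> AncestralStateAssignment:
    """Resolve ambiguous ancestral states by explicit polarity rules.

    Top-down over the tree: at the root, absence is taken as primitive if the
    minimal set allows it; otherwise a single copy is preferred over multiple
    copies and over a pseudogene. At other nodes the parent's resolved state
    is inherited whenever parsimony allows; remaining ties fall back on the
    preference order ABSENT > SINGLE > PSEUDOGENE > MULTIPLE. Every choice is
    restricted to states preserving the minimum total cost, so the number of
    inferred changes equals the parsimony score. Idempotent.
    """
    cm = (
        assignment.cost_matrix
        if assignment.cost_matrix is not None
        else _unit_cost_matrix()
    )
    resolved: dict[int, State] = {}
    preference_resolved: set[int] = set()

    for node in tree.preorder():
        vec = assignment.costs[node.id]
        if node is tree.root:
            cand = vec
        else:
            parent_state = resolved[node.parent.id]
            cand = vec + cm[_STATE_INDEX[parent_state], :]
        best = cand.min()
        minimizers = {STATE_ORDER[i] for i in np.flatnonzero(cand <= best + 1e-9)}
        # restrict to the node's minimal state set where possible, so the
        # choice stays within the Fitch up-pass set (classical refinement)
        decision = minimizers & assignment.state_sets[node.id] or minimizers
        if len(decision) == 1:
            resolved[node.id] = next(iter(decision))
            continue
        if node is tree.root:
            # quoted rules: absence primitive; else single copy primitive
            choice = next(s for s in PREFERENCE_ORDER if s in decision)
            covered_by_quoted_rules = State.ABSENT in decision or (
                State.SINGLE in decision
                and (State.MULTIPLE in decision or State.PSEUDOGENE in decision)
            )
            if not covered_by_quoted_rules:
                preference_resolved.add(node.id)
            resolved[node.id] = choice
        else:
            parent_state = resolved[node.parent.id]
            if parent_state in decision:
                resolved[node.id] = parent_state
            else:
                resolved[node.id] = next(
                    s for s in PREFERENCE_ORDER if s in decision
                )
                preference_resolved.add(node.id)

    return replace(
        assignment,
        resolved=resolved,
        preference_resolved=preference_resolved,
    )


def infer_events(
    tree: TimeTree,
    resolved: AncestralStateAssignment,
    gene: Optional[str] = None,
) -> list[EventRecord]:
    """Type every state change along a branch as a gain/duplication/
    pseudogenization/loss event.

    Pseudogene reactivation (PSEUDOGENE -> functional) is biologically
    implausible; it is counted as a gain and a ``UserWarning`` is emitted.
    """
    if resolved.resolved is None:
        raise ValidationError("resolve_polarity must be applied before infer_events")
    gene = gene or resolved.gene
    events: list[EventRecord] = []
    for node in tree.preorder():
        if node is tree.root:
            continue
        ps = resolved.resolved[node.parent.id]
        cs = resolved.resolved[node.id]
        if ps is cs:
            continue
        etype = EVENT_TABLE[(ps, cs)]
        if (ps, cs) in _NONCANONICAL:
            kind = (
                "pseudogene reactivation"
                if (ps, cs) in _REACTIVATIONS
                else "appearance as a pseudogene"
            )
            warnings.warn(
                f"{gene}: {kind} inferred on branch {node.id} (counted as gain)",
                UserWarning,
                stacklevel=2,
            )
        events.append(
            EventRecord(
                gene=gene,
                branch=node.id,
                event_type=etype,
                parent_state=ps,
                child_state=cs,
            )
        )
    return events


_PRESENT = (State.SINGLE, State.MULTIPLE)


def applicability(
    tree: TimeTree,
    resolved: AncestralStateAssignment,
    clade: str | Node,
    event_type: EventType,
) -> bool:
    """Could an event of this type have occurred for this gene in this clade?

    Gain is applicable iff the gene is absent at the node just below which
    the clade's stem branch starts (the stem-parent). Duplication,
    pseudogenization and loss are applicable iff the gene is present
    (single or multiple functional copies) at the stem-parent or anywhere
    within the clade.
    """
    if resolved.resolved is None:
        raise ValidationError("resolve_polarity must be applied first")
    top = tree.clade_node(clade)
    stem_parent = top.parent
    anchor = stem_parent if stem_parent is not None else top
    anchor_state = resolved.resolved[anchor.id]
    if event_type is EventType.GAIN:
        return anchor_state is State.ABSENT
    if anchor_state in _PRESENT:
        return True
    return any(
        resolved.resolved[n.id] in _PRESENT for n in tree.clade_nodes(top)
    )
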