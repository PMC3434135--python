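"""Synthetic data with the statistical structure the pipeline assumes.

Provides the packaged 19-species time-calibrated vertebrate tree, a
continuous-time Markov simulator of gene-content evolution (gain,
duplication, pseudogenization, loss) with exact event logs, Brownian-motion
continuous traits with optional clade mean shifts, and clade-enriched
signature matrices for the parsimony clustering tests.

All generators are deterministic given the mandatory seed.

The packaged tree's divergence times are stated approximations assembled
from standard calibration literature (root bony-vertebrate split ~430 Ma,
amphibian-amniote split 350 Ma, bird crown 100 Ma, sampled placental crown
97 Ma, teleost crown 250 Ma, ...); analyses should rely on its ordinal
properties (e.g. teleost phylogenetic diversity exceeding the eutherian
one), not on exact values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .characters import EVENT_TABLE, EventRecord, EventType, GeneStateCharacter, State
from .errors import ValidationError
from .signatures import MISSING, SIGNATURE_STATES, SignatureMatrix
from .tree import Node, TimeTree, read_newick

__all__ = [
    "SimulationConfig",
    "TrueHistory",
    "reference_tree",
    "simulate_gene_content",
    "simulate_brownian_trait",
    "equal_ancestor_null_trait",
    "make_signature_fixture",
    "random_bifurcating_tree",
]

#: default per-gene event rates, per Myr. Chosen to yield on the order of a
#: hundred events for 69 genes over the ~2900-Myr reference tree, matching
#: the scale of the study system (dozens of duplications/pseudogenizations
#: across 69 genes and 19 species).
DEFAULT_RATES: dict[EventType, float] = {
    EventType.GAIN: 1.0e-4,
    EventType.DUPLICATION: 1.5e-4,
    EventType.PSEUDOGENIZATION: 1.0e-4,
    EventType.LOSS: 1.0e-4,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic generators. ``seed`` is mandatory."""

    seed: int
    rates: dict[EventType, float] = field(default_factory=lambda: dict(DEFAULT_RATES))
    clade_rate_multipliers: dict[str, float] = field(default_factory=dict)
    n_genes: int = 69
    root_state: State = State.SINGLE
    sigma2: float = 1e-4          # Brownian rate per Myr (trait variance units)
    root_value: float = 0.3       # plausible proportion of selected genes
    clade_shifts: dict[str, float] = field(default_factory=dict)
    clip_to_unit: bool = False    # off for null calibration, on for proportions
    missing_fraction: float = 0.05
    enrichment: float = 0.8
    clade_profiles: dict[str, str] = field(
        default_factory=lambda: {"Teleostei": "POSSEL", "Eutheria": "DUP"}
    )

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is mandatory (no silent nondeterminism)")
        for et, r in self.rates.items():
            if r < 0:
                raise ValidationError(f"negative rate for {et}")
        if self.sigma2 < 0:
            raise ValidationError("sigma2 must be >= 0")

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Load a config from a YAML or JSON file.

        Keys mirror the dataclass fields; ``rates`` uses the event-type names
        (gain, duplication, pseudogenization, loss) and ``root_state`` the
        state names (ABSENT, SINGLE, MULTIPLE, PSEUDOGENE).
        """
        import json

        text = open(path, "r", encoding="utf-8").read()
        if str(path).endswith(".json"):
            raw = json.loads(text)
        else:
            import yaml

            raw = yaml.safe_load(text)
        if "rates" in raw:
            by_name = {et.value: et for et in EventType}
            raw["rates"] = {by_name[k]: float(v) for k, v in raw["rates"].items()}
        if "root_state" in raw:
            raw["root_state"] = State[raw["root_state"]]
        return cls(**raw)


@dataclass
class TrueHistory:
    """Exact record of what a generator did."""

    # per gene: list of (branch child-node id, event type, time from branch top)
    events: dict[str, list[tuple[int, EventType, float]]] = field(default_factory=dict)
    node_states: dict[str, dict[int, State]] = field(default_factory=dict)
    node_values: dict[int, float] = field(default_factory=dict)
    clipped_tips: list[str] = field(default_factory=list)


def reference_tree() -> TimeTree:
    """The packaged 19-species time-calibrated bony-vertebrate tree.

    Five teleosts, *Xenopus*, two birds and eleven mammals, with named
    internal nodes (Teleostei, Aves, Eutheria, Tetrapoda, Amniota, ...).
    Branch lengths in Myr.
    """
    text = (
        resources.files("fertevol.data").joinpath("reference_tree.nwk").read_text("utf-8")
    )
    return read_newick(text)


# ------------------------------------------------------------------ content


def _branch_rates(
    tree: TimeTree, config: SimulationConfig
) -> dict[int, dict[EventType, float]]:
    """Per-branch rate table after applying clade multipliers (stem included)."""
    out = {n.id: dict(config.rates) for n in tree.nodes}
    for clade, mult in config.clade_rate_multipliers.items():
        top = tree.clade_node(clade)
        for node in tree.clade_nodes(top):
            for et in out[node.id]:
                out[node.id][et] = config.rates[et] * mult
    return out


#: transitions available from each state, typed by the event algebra
_TRANSITIONS: dict[State, list[tuple[EventType, State]]] = {
    State.ABSENT: [(EventType.GAIN, State.SINGLE)],
    State.SINGLE: [
        (EventType.DUPLICATION, State.MULTIPLE),
        (EventType.PSEUDOGENIZATION, State.PSEUDOGENE),
        (EventType.LOSS, State.ABSENT),
    ],
    State.MULTIPLE: [
        (EventType.PSEUDOGENIZATION, State.PSEUDOGENE),
        (EventType.LOSS, State.ABSENT),
    ],
    State.PSEUDOGENE: [(EventType.LOSS, State.ABSENT)],
}


def simulate_gene_content(
    tree: TimeTree, config: SimulationConfig
) -> tuple[list[GeneStateCharacter], TrueHistory]:
    """Evolve gene-content states along the tree as a continuous-time Markov
    jump process with exponential waiting times, returning tip states and the
    exact event log.

    Transitions: gain ABSENT->SINGLE, duplication SINGLE->MULTIPLE,
    pseudogenization SINGLE/MULTIPLE->PSEUDOGENE, loss (any present state)
    ->ABSENT. Clade rate multipliers scale all rates on the clade's branches,
    stem included.
    """
    rng = np.random.default_rng(config.seed)
    if config.root_state is State.ABSENT and all(r == 0 for r in config.rates.values()):
        warnings.warn(
            "all rates zero with an absent root: nothing can ever happen",
            UserWarning,
            stacklevel=2,
        )
    branch_rates = _branch_rates(tree, config)
    characters: list[GeneStateCharacter] = []
    history = TrueHistory()

    for g in range(config.n_genes):
        gene = f"gene{g:04d}"
        node_states: dict[int, State] = {}
        events: list[tuple[int, EventType, float]] = []
        for node in tree.preorder():
            if node is tree.root:
                node_states[node.id] = config.root_state
                continue
            state = node_states[node.parent.id]
            t = 0.0
            rates_here = branch_rates[node.id]
            while True:
                moves = [
                    (et, target, rates_here[et])
                    for et, target in _TRANSITIONS[state]
                    if rates_here[et] > 0
                ]
                total = sum(r for _, _, r in moves)
                if total == 0:
                    break
                t += rng.exponential(1.0 / total)
                if t >= node.length:
                    break
                probs = np.array([r for _, _, r in moves]) / total
                idx = rng.choice(len(moves), p=probs)
                et, state = moves[idx][0], moves[idx][1]
                events.append((node.id, et, t))
            node_states[node.id] = state
        tip_states = {
            leaf.label: node_states[leaf.id] for leaf in tree.leaves()
        }
        characters.append(GeneStateCharacter(gene=gene, states=tip_states))
        history.events[gene] = events
        history.node_states[gene] = node_states
    return characters, history


def true_event_records(history: TrueHistory) -> list[EventRecord]:
    """Flatten a gene-content history into EventRecord objects.

    The parent/child states attached to each record are the canonical
    transition for the event type (e.g. SINGLE->MULTIPLE for a duplication);
    recovery tests compare (branch, event type) pairs.
    """
    out: list[EventRecord] = []
    for gene, events in history.events.items():
        for branch, et, _t in events:
            # reconstruct before/after states from the transition algebra
            before, after = _states_for(et)
            out.append(
                EventRecord(
                    gene=gene,
                    branch=branch,
                    event_type=et,
                    parent_state=before,
                    child_state=after,
                )
            )
    return out


def _states_for(et: EventType) -> tuple[State, State]:
    for (a, b), t in EVENT_TABLE.items():
        if t is et:
            return a, b
    raise KeyError(et)


# ------------------------------------------------------------------ traits


def simulate_brownian_trait(
    tree: TimeTree, config: SimulationConfig
) -> tuple[dict[str, float], TrueHistory]:
    """Brownian-motion trait on the tree: increments ~ N(0, sigma2 * length).

    ``clade_shifts`` adds a fixed mean shift to the increment on the named
    clade's stem branch (inherited by everything below). With
    ``clip_to_unit`` the tip values are clipped into [0, 1] (recorded in the
    history), emulating proportions; clipping is off by default so that null
    simulations stay exactly Brownian.
    """
    rng = np.random.default_rng(config.seed)
    shift_nodes: dict[int, float] = {}
    for clade, delta in config.clade_shifts.items():
        shift_nodes[tree.clade_node(clade).id] = delta

    values: dict[int, float] = {}
    history = TrueHistory()
    for node in tree.preorder():
        if node is tree.root:
            values[node.id] = config.root_value
            continue
        incr = rng.normal(0.0, np.sqrt(config.sigma2 * node.length)) if config.sigma2 > 0 else 0.0
        incr += shift_nodes.get(node.id, 0.0)
        values[node.id] = values[node.parent.id] + incr
    history.node_values = dict(values)

    trait: dict[str, float] = {}
    for leaf in tree.leaves():
        v = values[leaf.id]
        if config.clip_to_unit:
            clipped = min(max(v, 0.0), 1.0)
            if clipped != v:
                history.clipped_tips.append(leaf.label)
            v = clipped
        trait[leaf.label] = float(v)
    return trait, history


def equal_ancestor_null_trait(
    tree: TimeTree,
    config: SimulationConfig,
    clade_a: str,
    clade_b: str,
) -> tuple[dict[str, float], float]:
    """Brownian trait conditioned on equal true ancestral values of two clades.

    Simulates unconditional Brownian motion and then applies the exact
    Gaussian conditioning on the linear constraint a_A = a_B (the difference
    of the true values at the two clade ancestors): every tip is corrected by
    Cov(tip, a_A - a_B) / Var(a_A - a_B) times the observed difference. The
    result is a draw from the Brownian law given that the two clade-ancestral
    values coincide — the null of "no difference between clades" for
    calibration studies of the CI-overlap test.

    Returns the conditioned trait and the (shared) true ancestral value.
    """
    node_a = tree.clade_node(clade_a)
    node_b = tree.clade_node(clade_b)
    if node_a is node_b:
        raise ValidationError("clades must differ")
    depth: dict[int, float] = {tree.root.id: 0.0}
    for n in tree.preorder():
        if n is not tree.root:
            depth[n.id] = depth[n.parent.id] + n.length

    def root_path(node: Node) -> dict[int, float]:
        out: dict[int, float] = {}
        m: Optional[Node] = node
        while m is not None:
            out[m.id] = depth[m.id]
            m = m.parent
        return out

    path_a, path_b = root_path(node_a), root_path(node_b)
    d_a, d_b = depth[node_a.id], depth[node_b.id]
    shared_ab = max(
        (min(da, path_b[i]) for i, da in path_a.items() if i in path_b),
        default=0.0,
    )
    var_c = d_a + d_b - 2 * shared_ab  # per unit sigma2
    if var_c <= 0:
        raise ValidationError("nested clades share their full root path")

    def shared_len(leaf: Node, path: dict[int, float], d_node: float) -> float:
        m: Optional[Node] = leaf
        while m is not None:
            if m.id in path:
                return min(depth[m.id], d_node)
            m = m.parent
        return 0.0

    cov_c = {
        lf.label: shared_len(lf, path_a, d_a) - shared_len(lf, path_b, d_b)
        for lf in tree.leaves()
    }
    trait, history = simulate_brownian_trait(tree, config)
    c = history.node_values[node_a.id] - history.node_values[node_b.id]
    conditioned = {sp: v - cov_c[sp] * c / var_c for sp, v in trait.items()}
    shared_value = history.node_values[node_a.id] - d_a * c / var_c
    return conditioned, shared_value


# --------------------------------------------------------------- signatures

#: baseline cell-state frequencies outside enriched clades
_BASELINE = {
    "NO_EVENT": 0.72,
    "DUP": 0.08,
    "POSSEL": 0.08,
    "DUP_POSSEL": 0.02,
    "PSEUDO": 0.05,
    "NO_GENE": 0.05,
}


def make_signature_fixture(config: SimulationConfig) -> SignatureMatrix:
    """Signature matrix with clade-homogeneous enrichments on the reference
    tree.

    Each gene is assigned (round-robin) to one clade in ``clade_profiles``;
    cells of species inside that clade take the profile state with
    probability ``enrichment`` and otherwise draw from the baseline
    distribution, like every outside cell. Cells are independently replaced
    by MISSING with probability ``missing_fraction``. ``enrichment=0`` gives
    an exchangeable (signal-free) matrix.
    """
    if not 0 <= config.enrichment <= 1:
        raise ValidationError("enrichment must be in [0, 1]")
    if not 0 <= config.missing_fraction < 1:
        raise ValidationError("missing_fraction must be in [0, 1)")
    rng = np.random.default_rng(config.seed)
    tree = reference_tree()
    species = tree.leaf_labels
    clade_members = {
        clade: set(tree.leafset(tree.clade_node(clade)))
        for clade in config.clade_profiles
    }
    base_states = list(_BASELINE)
    base_probs = np.array(list(_BASELINE.values()))
    base_probs = base_probs / base_probs.sum()
    profiles = list(config.clade_profiles.items())

    cells: dict[str, list[str]] = {sp: [] for sp in species}
    genes = [f"sig{g:03d}" for g in range(config.n_genes)]
    for gi, _gene in enumerate(genes):
        clade, prof_state = profiles[gi % len(profiles)] if profiles else (None, None)
        for sp in species:
            if (
                clade is not None
                and sp in clade_members[clade]
                and rng.random() < config.enrichment
            ):
                state = prof_state
            else:
                state = base_states[rng.choice(len(base_states), p=base_probs)]
            if rng.random() < config.missing_fraction:
                state = MISSING
            cells[sp].append(state)
    df = pd.DataFrame.from_dict(cells, orient="index", columns=genes)
    df.index.name = "species"
    return SignatureMatrix(df)


# ------------------------------------------------------------------- trees


def random_bifurcating_tree(
    n_leaves: int, seed: int, mean_branch: float = 1.0
) -> TimeTree:
    """Random bifurcating tree by sequential random joins, with exponential
    branch lengths (testing utility; not a biological model of cladogenesis).
    """
    if n_leaves < 2:
        raise ValidationError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    nodes = [Node(label=f"t{i}", length=float(rng.exponential(mean_branch)) + 1e-3)
             for i in range(n_leaves)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node(length=float(rng.exponential(mean_branch)) + 1e-3)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = Node(length=0.0)
    root.add_child(nodes[0])
    root.add_child(nodes[1])
    return TimeTree(root)
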