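"""Tabular I/O: gene-state matrices, traits, events, clade definitions.

All tabular formats are TSV with a header row. Gene-state matrices have
genes as rows and species as columns; cells are ``0`` (absent), ``1``
(single), ``2+`` (multiple) or ``P`` (pseudogene), optionally suffixed with
``:<count>`` for an explicit copy number (e.g. ``2+:14``).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .characters import EventRecord, EventType, GeneStateCharacter, State
from .errors import ValidationError
from .tree import TimeTree

__all__ = [
    "read_gene_states",
    "write_gene_states",
    "read_trait",
    "write_trait",
    "write_events",
    "read_events",
    "read_clades",
]

_STATE_BY_CODE = {s.value: s for s in State}


def _parse_cell(cell: str, gene: str, species: str) -> tuple[State, int | None]:
    cell = str(cell).strip()
    count = None
    if ":" in cell:
        code, count_str = cell.split(":", 1)
        try:
            count = int(count_str)
        except ValueError as exc:
            raise ValidationError(
                f"{gene}/{species}: bad copy count {count_str!r}"
            ) from exc
    else:
        code = cell
    state = _STATE_BY_CODE.get(code)
    if state is None:
        raise ValidationError(f"{gene}/{species}: unknown state code {code!r}")
    return state, count


def read_gene_states(path) -> list[GeneStateCharacter]:
    """Read a genes x species state matrix from TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    out = []
    for gene, row in df.iterrows():
        states: dict[str, State] = {}
        counts: dict[str, int] = {}
        for species, cell in row.items():
            state, count = _parse_cell(cell, str(gene), str(species))
            states[str(species)] = state
            if count is not None:
                counts[str(species)] = count
        out.append(
            GeneStateCharacter(
                gene=str(gene), states=states, copy_counts=counts or None
            )
        )
    return out


def write_gene_states(characters: Sequence[GeneStateCharacter], path) -> None:
    species: list[str] = sorted({sp for ch in characters for sp in ch.states})
    rows = {}
    for ch in characters:
        row = []
        for sp in species:
            cell = ch.states[sp].value
            if ch.copy_counts and sp in ch.copy_counts:
                cell += f":{ch.copy_counts[sp]}"
            row.append(cell)
        rows[ch.gene] = row
    df = pd.DataFrame.from_dict(rows, orient="index", columns=species)
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def read_trait(path) -> dict[str, float]:
    """Read species<TAB>value trait observations (header row required)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValidationError("trait TSV needs species and value columns")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))


def write_trait(trait: Mapping[str, float], path, value_name: str = "value") -> None:
    df = pd.DataFrame(
        {"species": list(trait), value_name: [trait[k] for k in trait]}
    )
    df.to_csv(path, sep="\t", index=False)


def write_events(events: Iterable[EventRecord], tree: TimeTree, path) -> None:
    """Events TSV: gene, branch (child-node id and label), event type, states."""
    rows = [
        {
            "gene": ev.gene,
            "branch": ev.branch,
            "branch_label": tree.node_by_id(ev.branch).label or "",
            "event_type": ev.event_type.value,
            "parent_state": ev.parent_state.value,
            "child_state": ev.child_state.value,
        }
        for ev in events
    ]
    pd.DataFrame(
        rows,
        columns=[
            "gene",
            "branch",
            "branch_label",
            "event_type",
            "parent_state",
            "child_state",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_events(path) -> list[EventRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    etypes = {e.value: e for e in EventType}
    return [
        EventRecord(
            gene=row.gene,
            branch=int(row.branch),
            event_type=etypes[row.event_type],
            parent_state=_STATE_BY_CODE[str(row.parent_state)],
            child_state=_STATE_BY_CODE[str(row.child_state)],
        )
        for row in df.itertuples()
    ]


def read_clades(path) -> dict[str, list[str]]:
    """Clade definition TSV: columns ``clade`` and ``species``, one row per
    member species."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"clade", "species"} <= set(df.columns):
        raise ValidationError("clade TSV needs 'clade' and 'species' columns")
    out: dict[str, list[str]] = {}
    for row in df.itertuples():
        out.setdefault(row.clade, []).append(row.species)
    return out
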