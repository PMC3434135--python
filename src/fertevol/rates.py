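"""Per-clade event rates normalized by phylogenetic diversity, and the
phylogeny-informed exact binomial test of clade independence.

The rate of an event type in a clade is::

    rate = n_events / PD / (n_applicable / n_total)

where PD is the clade's sampled phylogenetic diversity in Myr (stem branch
included) and the final factor corrects for genes in which the event could
not occur in that clade (e.g. a gene primitively absent from teleosts cannot
be duplicated there, but it can appear).

Two clades are compared under the null hypothesis that events are
clade-independent: each event falls in clade A with probability

    p0 = PD_A * g_A / (PD_A * g_A + PD_B * g_B)

(the product of lineage-Myr exposure and genes at risk), and the observed
split of events is assessed with a two-sided exact binomial test using the
minimum-likelihood ("small-p") convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy import stats

from .characters import (
    AncestralStateAssignment,
    EventRecord,
    EventType,
    applicability,
)
from .errors import DegenerateNullError, UndefinedRateError, ValidationError
from .tree import TimeTree

__all__ = [
    "EventTally",
    "BinomialCladeTest",
    "event_rate",
    "tally_events",
    "rate_table",
    "clade_binomial_test",
    "compare_clades_events",
]


@dataclass(frozen=True)
class EventTally:
    """Counts and exposure underlying one clade x event-type rate."""

    clade: str
    event_type: EventType
    n_events: int
    pd: float              # sampled phylogenetic diversity, Myr, stem included
    n_applicable: int      # genes in which this event type could occur here
    n_total: int           # genes in the study

    def __post_init__(self) -> None:
        if self.pd <= 0:
            raise ValidationError("phylogenetic diversity must be positive")
        if not 0 <= self.n_applicable <= self.n_total:
            raise ValidationError("0 <= n_applicable <= n_total violated")
        if self.n_events < 0:
            raise ValidationError("negative event count")


def event_rate(tally: EventTally) -> float:
    """Events per Myr per applicable-gene fraction.

    Raises :class:`UndefinedRateError` when no gene is applicable: the event
    cannot occur in the clade and its rate is not-applicable rather than 0.
    """
    if tally.n_applicable == 0:
        raise UndefinedRateError(
            f"{tally.event_type.value} cannot occur in {tally.clade}: "
            "no applicable genes"
        )
    return tally.n_events / tally.pd / (tally.n_applicable / tally.n_total)


def tally_events(
    tree: TimeTree,
    events: Iterable[EventRecord],
    assignments: Mapping[str, AncestralStateAssignment],
    clade: str,
    event_type: EventType,
    n_total: Optional[int] = None,
) -> EventTally:
    """Tally one event type within one named clade (stem branch included).

    ``assignments`` maps gene name to its resolved reconstruction and is used
    both to attribute branches and to count applicable genes.
    """
    top = tree.clade_node(clade)
    n = sum(
        1
        for ev in events
        if ev.event_type is event_type
        and tree.branch_in_clade(tree.node_by_id(ev.branch), top)
    )
    n_applicable = sum(
        1
        for assignment in assignments.values()
        if applicability(tree, assignment, clade, event_type)
    )
    return EventTally(
        clade=clade,
        event_type=event_type,
        n_events=n,
        pd=tree.phylogenetic_diversity(clade, include_stem=True),
        n_applicable=n_applicable,
        n_total=n_total if n_total is not None else len(assignments),
    )


def rate_table(
    tree: TimeTree,
    events: Iterable[EventRecord],
    assignments: Mapping[str, AncestralStateAssignment],
    clades: Sequence[str],
    n_total: Optional[int] = None,
) -> pd.DataFrame:
    """Rates for every clade x event type, one row each.

    Rates with zero applicable genes are reported as NA (the event cannot
    occur there), never as 0.
    """
    events = list(events)
    rows = []
    for clade in clades:
        for etype in EventType:
            tally = tally_events(tree, events, assignments, clade, etype, n_total)
            try:
                rate = event_rate(tally)
            except UndefinedRateError:
                rate = float("nan")
            rows.append(
                {
                    "clade": clade,
                    "event_type": etype.value,
                    "n_events": tally.n_events,
                    "pd_myr": tally.pd,
                    "n_applicable": tally.n_applicable,
                    "n_total": tally.n_total,
                    "rate": rate,
                }
            )
    return pd.DataFrame(rows)


_SOURCE_STATES = {
    EventType.GAIN: ("ABSENT",),
    EventType.DUPLICATION: ("SINGLE",),
    EventType.PSEUDOGENIZATION: ("SINGLE", "MULTIPLE"),
    EventType.LOSS: ("SINGLE", "MULTIPLE", "PSEUDOGENE"),
}


def estimate_global_rates(
    tree: TimeTree,
    events: Iterable[EventRecord],
    assignments: Mapping[str, AncestralStateAssignment],
) -> dict[EventType, float]:
    """Whole-tree per-gene event rates (events per Myr) from a reconstruction.

    For each event type the exposure is the summed branch length (over genes
    and branches) during which the reconstructed parent state permits the
    event (e.g. a gene must be single-copy for a duplication). The rate is
    the inferred event count divided by that exposure; types with zero
    exposure get NaN.
    """
    counts = {et: 0 for et in EventType}
    for ev in events:
        counts[ev.event_type] += 1
    exposure = {et: 0.0 for et in EventType}
    for assignment in assignments.values():
        if assignment.resolved is None:
            raise ValidationError("assignments must be polarity-resolved")
        for node in tree.nodes:
            if node.parent is None:
                continue
            parent_state = assignment.resolved[node.parent.id].name
            for et, sources in _SOURCE_STATES.items():
                if parent_state in sources:
                    exposure[et] += node.length
    return {
        et: (counts[et] / exposure[et] if exposure[et] > 0 else float("nan"))
        for et in EventType
    }


@dataclass(frozen=True)
class BinomialCladeTest:
    """Result of the exposure-weighted exact binomial clade test."""

    k_a: int
    k_b: int
    p0: float       # null probability that an event falls in clade A
    p_value: float


def clade_binomial_test(
    k_a: int,
    k_b: int,
    pd_a: float,
    pd_b: float,
    g_a: int,
    g_b: int,
    alternative: str = "two-sided",
) -> BinomialCladeTest:
    """Exact binomial test that events split between two clades by exposure.

    The null weight of each clade is the product of its phylogenetic
    diversity (Myr) and its applicable-gene count. The two-sided p-value sums
    P(X = i) over all outcomes no more probable than the observed one
    (minimum-likelihood convention, as in common exact-binomial calculators).
    """
    if pd_a <= 0 or pd_b <= 0:
        raise ValidationError("phylogenetic diversities must be positive")
    if g_a < 0 or g_b < 0:
        raise ValidationError("applicable-gene counts must be non-negative")
    if k_a < 0 or k_b < 0 or k_a + k_b < 1:
        raise ValidationError("need at least one event")
    w_a = pd_a * g_a
    w_b = pd_b * g_b
    if w_a + w_b == 0:
        raise DegenerateNullError("zero total exposure: p0 undefined")
    p0 = w_a / (w_a + w_b)
    res = stats.binomtest(k_a, n=k_a + k_b, p=p0, alternative=alternative)
    return BinomialCladeTest(k_a=k_a, k_b=k_b, p0=p0, p_value=res.pvalue)


def compare_clades_events(
    tree: TimeTree,
    events: Iterable[EventRecord],
    assignments: Mapping[str, AncestralStateAssignment],
    clade_a: str,
    clade_b: str,
    n_total: Optional[int] = None,
) -> pd.DataFrame:
    """Pairwise clade comparison of every event type (one test per type).

    Event types with at least one event in either clade are tested; others
    get an NA p-value. No multiplicity correction is applied.
    """
    events = list(events)
    rows = []
    for etype in EventType:
        ta = tally_events(tree, events, assignments, clade_a, etype, n_total)
        tb = tally_events(tree, events, assignments, clade_b, etype, n_total)
        if ta.n_events + tb.n_events >= 1 and ta.n_applicable + tb.n_applicable > 0:
            test = clade_binomial_test(
                ta.n_events, tb.n_events, ta.pd, tb.pd, ta.n_applicable, tb.n_applicable
            )
            p0, pval = test.p0, test.p_value
        else:
            p0, pval = float("nan"), float("nan")
        rows.append(
            {
                "clade_a": clade_a,
                "clade_b": clade_b,
                "event_type": etype.value,
                "k_a": ta.n_events,
                "k_b": tb.n_events,
                "p0": p0,
                "p_value": pval,
            }
        )
    return pd.DataFrame(rows)
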