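"""Data model and tabular I/O for dyadic dominance-interaction records.

Each record is one observed dyadic dominance interaction: an actor, a
recipient, the interaction type, its a-priori cost category, and the set of
individuals present in the (sub)group when the interaction took place. The
present set is what makes the opportunity-constrained permutation null
possible, so it is required on every event.

Conventions: for aggressive interactions the actor is the winner and the
recipient the loser; for submissive interactions the actor is the subordinate
individual performing the signal (and hence the loser of the underlying
dominance relationship).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, ValidationError

__all__ = [
    "HIGHER_COST",
    "LOWER_COST",
    "SUBMISSIVE",
    "CATEGORIES",
    "CATEGORY_BY_TYPE",
    "AGGRESSIVE_CATEGORIES",
    "InteractionEvent",
    "InteractionDataset",
    "SplitResult",
    "read_interactions",
    "write_interactions",
    "split_dataset",
    "directed_dyad_counts",
]

HIGHER_COST = "higher_cost_aggressive"
LOWER_COST = "lower_cost_aggressive"
SUBMISSIVE = "submissive"
CATEGORIES = (HIGHER_COST, LOWER_COST, SUBMISSIVE)
AGGRESSIVE_CATEGORIES = (HIGHER_COST, LOWER_COST)

# A-priori cost classification of the eight interaction types: grabs/spins
# and chases involve contact or sustained sprinting (higher cost); pecks,
# displacements and gapes are momentary and contact-free or near so (lower
# cost); submissive crouches/caresses signal subordinate status.
CATEGORY_BY_TYPE: Mapping[str, str] = {
    "SPI": HIGHER_COST,
    "TAI": HIGHER_COST,
    "CHA": HIGHER_COST,
    "PEC": LOWER_COST,
    "DIS": LOWER_COST,
    "GAP": LOWER_COST,
    "SUV": SUBMISSIVE,
    "SUB": SUBMISSIVE,
}

_LIST_SEP = ";"
_COLUMNS = ("event_id", "order", "group_id", "actor", "recipient",
            "type_code", "category", "present")


@dataclass(frozen=True)
class InteractionEvent:
    """One dyadic dominance interaction with subgroup context."""

    event_id: str
    order: int
    group_id: str
    actor: str
    recipient: str
    type_code: str
    category: str
    present: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "present", frozenset(self.present))
        self.validate()

    def validate(self) -> None:
        eid = self.event_id

        def bad(rule: str) -> ValidationError:
            return ValidationError(f"event {eid!r}: {rule}")

        if self.order < 0:
            raise bad("order must be a non-negative integer")
        if self.actor == self.recipient:
            raise bad("actor and recipient must differ")
        if self.type_code not in CATEGORY_BY_TYPE:
            raise bad(f"unknown type_code {self.type_code!r}")
        expected = CATEGORY_BY_TYPE[self.type_code]
        if self.category != expected:
            raise bad(
                f"category {self.category!r} inconsistent with type_code "
                f"{self.type_code!r} (expected {expected!r})"
            )
        if self.actor not in self.present:
            raise bad("actor must be in the present set")
        if self.recipient not in self.present:
            raise bad("recipient must be in the present set")
        if len(self.present) < 2:
            raise bad("present set must contain at least two individuals")


@dataclass(frozen=True)
class InteractionDataset:
    """An ordered collection of interaction events.

    Events are kept sorted by ``order`` (stable: ties keep input sequence).
    ``individuals`` is the union of all actors, recipients and present sets.
    """

    events: tuple = ()
    individuals: frozenset = field(init=False)

    def __post_init__(self):
        evs = tuple(sorted(self.events, key=lambda e: e.order))
        seen = set()
        for e in evs:
            if e.event_id in seen:
                raise ValidationError(f"duplicate event_id {e.event_id!r}")
            seen.add(e.event_id)
        inds = set()
        for e in evs:
            inds.add(e.actor)
            inds.add(e.recipient)
            inds |= e.present
        object.__setattr__(self, "events", evs)
        object.__setattr__(self, "individuals", frozenset(inds))

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def filter(self, group_id: str | None = None,
               category: str | None = None) -> "InteractionDataset":
        """Restrict to one group and/or one cost category."""
        evs = self.events
        if group_id is not None:
            evs = tuple(e for e in evs if e.group_id == group_id)
        if category is not None:
            if category not in CATEGORIES:
                raise ParameterError(f"unknown category {category!r}")
            evs = tuple(e for e in evs if e.category == category)
        return InteractionDataset(evs)

    @property
    def groups(self) -> tuple:
        return tuple(sorted({e.group_id for e in self.events}))

    @property
    def categories(self) -> tuple:
        return tuple(c for c in CATEGORIES
                     if any(e.category == c for e in self.events))

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "event_id": e.event_id,
                "order": e.order,
                "group_id": e.group_id,
                "actor": e.actor,
                "recipient": e.recipient,
                "type_code": e.type_code,
                "category": e.category,
                "present": _LIST_SEP.join(sorted(e.present)),
            }
            for e in self.events
        ]
        return pd.DataFrame(rows, columns=list(_COLUMNS))


@dataclass(frozen=True)
class SplitResult:
    """A random partition of a dataset into hierarchy and strategy subsets."""

    hierarchy_subset: InteractionDataset
    strategy_subset: InteractionDataset
    hier_fraction: float
    seed: int | None = None


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() == ".tsv" else ","


def read_interactions(path) -> InteractionDataset:
    """Read a delimited-text interaction table (.csv comma / .tsv tab).

    Required columns: event_id, order, group_id, actor, recipient, type_code,
    present (``;``-joined id list). The category column is optional and is
    derived from type_code when absent.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path), dtype=str,
                         keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file, header required") from exc
    required = [c for c in _COLUMNS if c != "category"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    events = []
    for _, row in df.iterrows():
        try:
            order = int(row["order"])
        except ValueError as exc:
            raise FormatError(
                f"{path}: event {row['event_id']!r}: non-integer order "
                f"{row['order']!r}"
            ) from exc
        type_code = row["type_code"]
        if "category" in df.columns and row["category"]:
            category = row["category"]
        else:
            if type_code not in CATEGORY_BY_TYPE:
                raise ValidationError(
                    f"event {row['event_id']!r}: unknown type_code "
                    f"{type_code!r}"
                )
            category = CATEGORY_BY_TYPE[type_code]
        present = frozenset(p for p in row["present"].split(_LIST_SEP) if p)
        events.append(
            InteractionEvent(
                event_id=row["event_id"],
                order=order,
                group_id=row["group_id"],
                actor=row["actor"],
                recipient=row["recipient"],
                type_code=type_code,
                category=category,
                present=present,
            )
        )
    return InteractionDataset(tuple(events))


def write_interactions(ds: InteractionDataset, path) -> None:
    """Write a dataset as delimited text; round-trips through read_interactions."""
    path = Path(path)
    for ind in ds.individuals:
        if _LIST_SEP in ind:
            raise ValidationError(
                f"individual id {ind!r} contains the list delimiter "
                f"{_LIST_SEP!r} and cannot be serialized"
            )
    df = ds.to_dataframe()
    df.to_csv(path, sep=_sep_for(path), index=False)


def split_dataset(ds: InteractionDataset, hier_fraction: float,
                  rng: Union[int, np.random.Generator]) -> SplitResult:
    """Uniformly partition a dataset into hierarchy and strategy subsets.

    The hierarchy subset gets round(hier_fraction * n) events (half-up
    rounding), drawn uniformly without replacement; both subsets keep the
    original order values.
    """
    if not 0.0 < hier_fraction < 1.0:
        raise ParameterError(
            f"hier_fraction must be in (0, 1), got {hier_fraction}"
        )
    if len(ds) < 2:
        raise ParameterError("dataset must contain at least 2 events to split")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = np.random.default_rng(rng)
    n = len(ds)
    n_hier = int(math.floor(hier_fraction * n + 0.5))
    idx = gen.permutation(n)
    hier_idx = set(idx[:n_hier].tolist())
    hier = tuple(e for i, e in enumerate(ds.events) if i in hier_idx)
    strat = tuple(e for i, e in enumerate(ds.events) if i not in hier_idx)
    return SplitResult(
        hierarchy_subset=InteractionDataset(hier),
        strategy_subset=InteractionDataset(strat),
        hier_fraction=hier_fraction,
        seed=int(seed) if seed is not None else None,
    )


def directed_dyad_counts(ds_or_events, individuals: Iterable | None = None
                         ) -> pd.DataFrame:
    """Directed interaction counts: counts.loc[a, b] = # events actor a → recipient b.

    Counts are generally asymmetric within a dyad. ``individuals`` may widen
    the index to include individuals with zero interactions (e.g. the full
    dataset's id universe when counting on a subset).
    """
    events: Sequence[InteractionEvent]
    if isinstance(ds_or_events, InteractionDataset):
        events = ds_or_events.events
        base = ds_or_events.individuals
    else:
        events = tuple(ds_or_events)
        base = set()
        for e in events:
            base.add(e.actor)
            base.add(e.recipient)
    ids = sorted(set(base) | (set(individuals) if individuals else set()))
    idx = {v: i for i, v in enumerate(ids)}
    mat = np.zeros((len(ids), len(ids)), dtype=np.int64)
    for e in events:
        mat[idx[e.actor], idx[e.recipient]] += 1
    return pd.DataFrame(mat, index=ids, columns=ids)


def events_replace_recipients(events: Sequence[InteractionEvent],
                              recipients: Sequence[str]) -> tuple:
    """Return events with recipients replaced (used by the permutation null)."""
    return tuple(replace(e, recipient=r) for e, r in zip(events, recipients))
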