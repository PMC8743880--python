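"""Shared fixtures: small hand-built datasets and simulated ground truth."""

import numpy as np
import pytest

from domstrat import (
    ABMConfig,
    Hierarchy,
    InteractionDataset,
    InteractionEvent,
    simulate_dataset,
)


def make_event(event_id, actor, recipient, present=None, order=0,
               group_id="g1", type_code="CHA"):
    """Terse event builder; present defaults to {actor, recipient}."""
    from domstrat import CATEGORY_BY_TYPE

    if present is None:
        present = {actor, recipient}
    return InteractionEvent(
        event_id=event_id,
        order=order,
        group_id=group_id,
        actor=actor,
        recipient=recipient,
        type_code=type_code,
        category=CATEGORY_BY_TYPE[type_code],
        present=frozenset(present),
    )


@pytest.fixture
def ev():
    return make_event


@pytest.fixture
def tiny_dataset():
    """Three events among three individuals: A->B twice, B->A once."""
    return InteractionDataset((
        make_event("e1", "A", "B", {"A", "B", "C"}, order=0),
        make_event("e2", "A", "B", {"A", "B"}, order=1),
        make_event("e3", "B", "A", {"A", "B", "C"}, order=2),
    ))


@pytest.fixture
def transitive_dataset():
    """A beats B, B beats C, A beats C, ten times each: forced order A>B>C."""
    events = []
    k = 0
    for actor, recip in (("A", "B"), ("B", "C"), ("A", "C")):
        for _ in range(10):
            events.append(make_event(f"e{k}", actor, recip, order=k))
            k += 1
    return InteractionDataset(tuple(events))


def identity_hierarchy(n):
    """Hierarchy whose ranks are known by construction (id iXXX has rank XXX)."""
    from domstrat.abm import individual_id

    ids = tuple(individual_id(r) for r in range(1, n + 1))
    scores = {individual_id(r): float(n - r) for r in range(1, n + 1)}
    return Hierarchy(ids=ids, rank={individual_id(r): r
                                    for r in range(1, n + 1)},
                     mean_score=scores)


@pytest.fixture
def true_hierarchy():
    return identity_hierarchy


@pytest.fixture(scope="session")
def abm_random_500():
    """Well-sampled strategy-free simulation (~50 participations/individual)."""
    return simulate_dataset(ABMConfig(n_subgroups=500, seed=7))


@pytest.fixture(scope="session")
def abm_assorted_100():
    """Rank-assorted, strategy-free simulation at the default scenario size."""
    return simulate_dataset(ABMConfig(assorted=True, seed=3))
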