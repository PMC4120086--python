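"""Collapsing species-level WGD estimates into independent events.

The same ancient polyploidization is often dated in several descendant
species.  For the clustering analyses each historical event must be
counted once: species estimates are grouped by a curated event map, the
anchor-based estimate is preferred per species (peak-based only where no
anchor estimate exists), and the event age is the arithmetic mean of the
chosen per-species estimates.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ParameterError

__all__ = [
    "SpeciesEstimate",
    "WGDEvent",
    "attach_event_ids",
    "deduplicate_events",
    "window_filter",
]

logger = logging.getLogger(__name__)

_SOURCE_PREFERENCE = {"anchor": 0, "peak_based": 1}


@dataclasses.dataclass(frozen=True)
class SpeciesEstimate:
    """A species-level WGD age estimate from one selection route."""

    species: str
    event_id: str
    source: str
    age: float
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if self.source not in _SOURCE_PREFERENCE:
            raise ParameterError(f"unknown source {self.source!r}")
        if self.age < 0:
            raise ParameterError("age must be non-negative")


@dataclasses.dataclass(frozen=True)
class WGDEvent:
    """An independent WGD event with its consensus age (mya)."""

    event_id: str
    member_species: tuple[str, ...]
    age: float
    sources_used: tuple[str, ...]
    excluded: bool = False


def attach_event_ids(
    estimates: Iterable,
    event_map: Mapping[str, str],
    exclude_flags: Mapping[str, bool] | None = None,
) -> list[SpeciesEstimate]:
    """Join species estimates with a curated species -> event assignment.

    ``estimates`` may be SpeciesEstimate objects (their event_id is
    replaced) or objects with ``species``, ``source`` and an age-like
    attribute (``age`` or ``mode``).  Species absent from the map are
    dropped with a logged warning — event membership is curation, not
    something inferred here.
    """
    out = []
    for est in estimates:
        species = est.species
        if species not in event_map:
            logger.warning("species %s missing from event map; dropped", species)
            continue
        age = getattr(est, "age", None)
        if age is None:
            age = est.mode
        out.append(
            SpeciesEstimate(
                species=species,
                event_id=str(event_map[species]),
                source=est.source,
                age=float(age),
                ci_low=getattr(est, "ci_low", None),
                ci_high=getattr(est, "ci_high", None),
            )
        )
    return out


def deduplicate_events(estimates: Sequence[SpeciesEstimate]) -> list[WGDEvent]:
    """Collapse species-level estimates into one entry per WGD event.

    Within each event, one estimate is chosen per member species — the
    anchor-based one if present, else the peak-based one — and the event
    age is the arithmetic mean of the chosen estimates.  Output is sorted
    by age ascending; the operation is idempotent and invariant to the
    input order.
    """
    by_event: dict[str, dict[str, SpeciesEstimate]] = {}
    for est in estimates:
        if not est.event_id:
            raise ParameterError(f"estimate for {est.species} lacks an event id")
        chosen = by_event.setdefault(est.event_id, {})
        current = chosen.get(est.species)
        if current is None or (
            _SOURCE_PREFERENCE[est.source] < _SOURCE_PREFERENCE[current.source]
        ):
            chosen[est.species] = est

    events = []
    for event_id in sorted(by_event):
        chosen = by_event[event_id]
        members = tuple(sorted(chosen))
        ages = np.array([chosen[s].age for s in members])
        sources = tuple(chosen[s].source for s in members)
        events.append(
            WGDEvent(
                event_id=event_id,
                member_species=members,
                age=float(ages.mean()),
                sources_used=sources,
            )
        )
    events.sort(key=lambda e: (e.age, e.event_id))
    logger.info(
        "deduplicated %d species estimates into %d independent events",
        len(estimates),
        len(events),
    )
    return events


def window_filter(
    events: Sequence[WGDEvent], t_min: float = 0.0, t_max: float = 100.0
) -> list[WGDEvent]:
    """Keep events with t_min <= age <= t_max (closed interval).

    The endpoints are closed by convention: an event dated exactly at the
    window edge is kept.  The number of removed events is logged.
    """
    if not t_min < t_max:
        raise ParameterError("window requires t_min < t_max")
    kept = [e for e in events if t_min <= e.age <= t_max]
    removed = len(events) - len(kept)
    if removed:
        logger.info(
            "window filter [%g, %g] removed %d of %d events",
            t_min,
            t_max,
            removed,
            len(events),
        )
    return kept
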