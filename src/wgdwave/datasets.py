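"""Bundled reference inputs for the plant WGD clustering analysis.

The package ships a compact compendium describing 31 species-level WGD age
estimates across 41 green-plant species, the curated assignment of those
estimates to 20 independent WGD events, and a dated ultrametric species
tree from which the lineages-through-time null model is derived.

All three files are labelled *synthetic*: they are curated stand-ins
assembled from published plant WGD datings and standard angiosperm
divergence times, not a transcription of any single published table.  A
handful of species values are exact published numbers (the four Faboideae
estimates, the poplar estimate, and the apple/pear pair); the remainder
are representative literature values.  The files exist so that the full
event-level analysis — deduplication, clustering test, mixture modelling —
runs end to end on realistically structured data.
"""

from __future__ import annotations

from importlib import resources

import dendropy

from . import io as wio
from .events import SpeciesEstimate, WGDEvent, attach_event_ids, deduplicate_events

__all__ = [
    "load_species_estimates",
    "load_event_map",
    "load_species_tree",
    "load_events",
    "POPULUS_FOSSIL_MIN_MYA",
    "POPULUS_WGD_ESTIMATE_MYA",
    "KPG_BOUNDARY_MYA",
]

# Oldest known Populus leaf fossils (Green River Formation, Middle Eocene)
# set a minimum age for the Populus/Salix lineage; the salicoid WGD predates
# that divergence, so the fossil bounds the WGD age from below.
POPULUS_FOSSIL_MIN_MYA = 47.4
POPULUS_WGD_ESTIMATE_MYA = 34.7
KPG_BOUNDARY_MYA = 66.0

_DATA = resources.files(__package__) / "data"


def _data_path(name: str):
    return _DATA / name


def load_species_estimates() -> list[SpeciesEstimate]:
    """The 31 species-level WGD age estimates (see module docstring)."""
    with resources.as_file(_data_path("species_estimates_synthetic.tsv")) as p:
        return wio.read_species_estimates(p)


def load_event_map() -> tuple[dict[str, str], dict[str, bool]]:
    """Curated species -> independent-event assignment and exclude flags.

    The banana (Musa) event carries an exclude flag: its single Ks peak
    most likely merges two WGDs in close succession, so robustness runs
    repeat the analyses without it.
    """
    with resources.as_file(_data_path("event_map_synthetic.tsv")) as p:
        return wio.read_event_map(p)


def load_species_tree() -> dendropy.Tree:
    """Dated ultrametric 41-species chronogram (branch lengths in my)."""
    with resources.as_file(_data_path("species_tree_synthetic.nwk")) as p:
        return wio.read_tree(p)


def load_events(drop_excluded: bool = False) -> list[WGDEvent]:
    """The independent WGD events after deduplication.

    Anchor-based estimates are preferred per species and shared WGDs are
    averaged over their descendant species.  With ``drop_excluded`` the
    flagged events (Musa) are removed for robustness analyses.
    """
    estimates = load_species_estimates()
    event_map, exclude_flags = load_event_map()
    estimates = attach_event_ids(estimates, event_map)
    events = deduplicate_events(estimates)
    events = [
        WGDEvent(
            event_id=e.event_id,
            member_species=e.member_species,
            age=e.age,
            sources_used=e.sources_used,
            excluded=exclude_flags.get(e.event_id, False),
        )
        for e in events
    ]
    if drop_excluded:
        events = [e for e in events if not e.excluded]
    return events
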