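"""End-to-end pipeline: selection -> consensus -> events -> clustering -> mixture."""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from . import clustering as clu
from . import consensus as cons
from . import events as ev
from . import io as wio
from . import ks
from . import mixture as mix
from .errors import ParameterError, WgdwaveError

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


class _Stage:
    """Context wrapper that names the failing stage in errors."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            raise WgdwaveError(f"stage {self.name!r} failed: {exc}") from exc
        logger.info("stage %s: done", self.name)
        return False


def run_pipeline(config: wio.PipelineConfig) -> dict:
    """Run every configured stage and return one machine-readable report.

    Preconditions are checked before any computation: the event map and
    species tree are required (the event-level analyses are the point of
    the pipeline), plus either per-homeolog age samples or ready-made
    species-level estimates.  All seeds, counts and statistics appear in
    the report so a rerun with the same config is reproducible.
    """
    config.validate()
    if config.event_map is None:
        raise ParameterError("config lacks an event map (required)")
    if config.species_tree is None:
        raise ParameterError("config lacks a dated species tree (required)")
    if config.age_samples is None and config.species_estimates is None:
        raise ParameterError(
            "config needs either age_samples or species_estimates"
        )

    report: dict[str, Any] = {
        "version": __version__,
        "config": _jsonable(dataclasses.asdict(config)),
        "stages": {},
    }
    seeds = config.seeds

    # -- optional: anchor homeolog selection from a Ks table ---------------
    if config.ks_table is not None:
        with _Stage("select"):
            tables = config.ks_table
            if isinstance(tables, str):
                tables = {"unknown": tables}
            selection = {}
            for species, path in tables.items():
                table = wio.read_ks_table(path)
                win = config.peak_windows.get(
                    species, config.peak_windows.get("default")
                )
                if win is None:
                    raise ParameterError(
                        f"no peak window configured for species {species!r}"
                    )
                window = ks.PeakWindow(*win)
                hs = ks.select_anchor_homeologs(table, window, species=species)
                selection[species] = {
                    "pairs_read": int(len(table)),
                    "pairs_accepted": len(hs),
                    "window": [window.ks_low, window.ks_high],
                }
            report["stages"]["select"] = selection

    # -- consensus ages from per-homeolog samples ---------------------------
    consensus_rows = []
    if config.age_samples is not None:
        with _Stage("consensus"):
            samples = wio.read_age_samples(config.age_samples)
            for s in samples:
                est = cons.consensus_estimate(
                    s,
                    n_bootstrap=config.n_bootstrap,
                    seed=seeds.get("bootstrap"),
                    n_grid=config.kde_grid_size,
                )
                consensus_rows.append(est)
            report["stages"]["consensus"] = {
                "n_sample_sets": len(samples),
                "estimates": [_jsonable(e) for e in consensus_rows],
                "seed": seeds.get("bootstrap"),
                "n_bootstrap": config.n_bootstrap,
            }

    # -- species estimates -> independent events ----------------------------
    with _Stage("events"):
        event_map, exclude_flags = wio.read_event_map(config.event_map)
        if config.species_estimates is not None:
            estimates = wio.read_species_estimates(config.species_estimates)
        else:
            estimates = consensus_rows
        estimates = ev.attach_event_ids(estimates, event_map)
        events = ev.deduplicate_events(estimates)
        t_min, t_max = config.window
        events_in_window = ev.window_filter(events, t_min, t_max)
        report["stages"]["events"] = {
            "n_estimates": len(estimates),
            "n_events": len(events),
            "n_events_in_window": len(events_in_window),
            "events": [_jsonable(e) for e in events_in_window],
            "excluded_flagged": sorted(exclude_flags),
        }

    # -- clustering test ----------------------------------------------------
    with _Stage("cluster-test"):
        tree = wio.read_tree(config.species_tree)
        ltt = clu.ltt_from_tree(tree, window=tuple(config.window), dt=config.ltt_dt)
        result = clu.clustering_p_value(
            events_in_window,
            ltt,
            n_samples=config.n_null_samples,
            seed=seeds.get("clustering"),
            kind=config.statistic_kind,
        )
        report["stages"]["cluster_test"] = _jsonable(result)

    # -- Gaussian mixture over event ages -----------------------------------
    with _Stage("mixture"):
        ages = [e.age for e in events_in_window]
        best, table = mix.select_by_aic(
            ages, m_candidates=config.m_candidates, seed=seeds.get("mixture")
        )
        report["stages"]["mixture"] = {
            "best": _jsonable(best),
            "table": table.to_dict(orient="records"),
            "seed": seeds.get("mixture"),
        }
        flagged = [e.event_id for e in events_in_window if e.event_id in exclude_flags]
        if flagged and len(events_in_window) - len(flagged) >= max(config.m_candidates):
            robust = mix.refit_excluding(
                events_in_window,
                flagged,
                m_candidates=config.m_candidates,
                seed=seeds.get("mixture"),
            )
            report["stages"]["mixture"]["robustness_excluding"] = {
                "excluded": robust["excluded"],
                "best": _jsonable(robust["reduced"]["best"]),
                "table": robust["reduced"]["table"].to_dict(orient="records"),
            }

    return report


def write_report(report: dict, path) -> None:
    import json

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
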