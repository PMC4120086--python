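"""File formats: TSV tables, newick trees, YAML pipeline configuration.

All tables are UTF-8, tab-separated, header required, '.' decimal.  Ages
are million years before present (increasing into the past); Ks is
unitless.  Readers validate schemas and report malformed rows with their
1-based file line numbers; writers produce files whose round trip through
the matching reader is the identity.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

from .consensus import AgeSampleSet, ConsensusEstimate
from .errors import ParameterError, SchemaError
from .events import SpeciesEstimate, WGDEvent
from .ks import HomeologSet

__all__ = [
    "read_ks_table",
    "write_ks_table",
    "read_homeolog_sets",
    "write_homeolog_sets",
    "read_age_samples",
    "write_age_samples",
    "read_species_estimates",
    "write_species_estimates",
    "write_consensus_estimates",
    "read_event_map",
    "write_event_map",
    "read_events",
    "write_events",
    "read_tree",
    "write_tree",
    "PipelineConfig",
]


def _read_tsv(path, required: Sequence[str], numeric: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    for col in numeric:
        if col not in df.columns:
            continue
        raw = df[col].astype(str).str.strip()
        converted = pd.to_numeric(raw.mask(raw == ""), errors="coerce")
        bad = converted.isna() & (raw != "")
        if bad.any():
            lines = [int(i) + 2 for i in df.index[bad][:5]]  # +1 header, +1 1-based
            raise SchemaError(
                f"{path}: non-numeric values in column {col!r} at line(s) {lines}"
            )
        df[col] = converted
    return df


# -- Ks pair tables ---------------------------------------------------------


def read_ks_table(path) -> pd.DataFrame:
    """Read a duplicate-pair Ks table (gene_a, gene_b, ks[, segment_id])."""
    df = _read_tsv(path, required=("gene_a", "gene_b", "ks"), numeric=("ks",))
    if "segment_id" not in df.columns:
        df["segment_id"] = ""
    if (df["ks"] < 0).any():
        raise SchemaError(f"{path}: negative Ks values")
    if (df["gene_a"] == df["gene_b"]).any():
        raise SchemaError(f"{path}: self-pairs (gene_a == gene_b)")
    key = df.apply(lambda r: tuple(sorted((r["gene_a"], r["gene_b"]))), axis=1)
    if key.duplicated().any():
        lines = [int(i) + 2 for i in df.index[key.duplicated()][:5]]
        raise SchemaError(f"{path}: duplicate unordered gene pairs at line(s) {lines}")
    return df


def write_ks_table(table: pd.DataFrame, path) -> None:
    cols = ["gene_a", "gene_b", "ks", "segment_id"]
    extra = [c for c in table.columns if c not in cols]
    table.loc[:, cols + extra].to_csv(path, sep="\t", index=False)


# -- Homeolog sets ----------------------------------------------------------


def write_homeolog_sets(sets: Sequence[HomeologSet], path) -> None:
    rows = []
    for hs in sets:
        for (a, b), prov in zip(hs.pairs, hs.provenance):
            rows.append(
                {
                    "species": hs.species,
                    "source": hs.source,
                    "gene_a": a,
                    "gene_b": b,
                    "provenance": prov,
                }
            )
    pd.DataFrame(
        rows, columns=["species", "source", "gene_a", "gene_b", "provenance"]
    ).to_csv(path, sep="\t", index=False)


def read_homeolog_sets(path) -> list[HomeologSet]:
    df = _read_tsv(
        path,
        required=("species", "source", "gene_a", "gene_b", "provenance"),
        numeric=(),
    )
    sets = []
    for (species, source), group in df.groupby(["species", "source"], sort=True):
        sets.append(
            HomeologSet(
                species=species,
                source=source,
                pairs=[(a, b) for a, b in zip(group["gene_a"], group["gene_b"])],
                provenance=list(group["provenance"]),
            )
        )
    return sets


# -- Absolute age samples ----------------------------------------------------


def write_age_samples(samples: Sequence[AgeSampleSet], path) -> None:
    rows = []
    for s in samples:
        for i, age in enumerate(s.ages):
            rows.append(
                {
                    "species": s.species,
                    "source": s.source,
                    "orthogroup_id": f"{s.species}_{s.source}_og{i + 1}",
                    "age_mya": age,
                }
            )
    pd.DataFrame(
        rows, columns=["species", "source", "orthogroup_id", "age_mya"]
    ).to_csv(path, sep="\t", index=False)


def read_age_samples(path) -> list[AgeSampleSet]:
    df = _read_tsv(
        path,
        required=("species", "source", "orthogroup_id", "age_mya"),
        numeric=("age_mya",),
    )
    samples = []
    for (species, source), group in df.groupby(["species", "source"], sort=True):
        samples.append(
            AgeSampleSet(
                species=species,
                source=source,
                ages=group["age_mya"].to_numpy(dtype=float),
            )
        )
    return samples


# -- Species-level estimates and events --------------------------------------


def write_species_estimates(estimates: Sequence[SpeciesEstimate], path) -> None:
    rows = [
        {
            "species": e.species,
            "event_id": e.event_id,
            "source": e.source,
            "age": e.age,
            "ci_low": "" if e.ci_low is None else e.ci_low,
            "ci_high": "" if e.ci_high is None else e.ci_high,
        }
        for e in estimates
    ]
    pd.DataFrame(
        rows, columns=["species", "event_id", "source", "age", "ci_low", "ci_high"]
    ).to_csv(path, sep="\t", index=False)


def read_species_estimates(path) -> list[SpeciesEstimate]:
    df = _read_tsv(
        path,
        required=("species", "source", "age"),
        numeric=("age", "ci_low", "ci_high"),
    )
    if df.duplicated(subset=["species", "source"]).any():
        raise SchemaError(f"{path}: duplicate (species, source) rows")
    if "event_id" not in df.columns:
        df["event_id"] = ""
    out = []
    for _, r in df.iterrows():
        out.append(
            SpeciesEstimate(
                species=r["species"],
                event_id=str(r["event_id"]),
                source=r["source"],
                age=float(r["age"]),
                ci_low=None if pd.isna(r.get("ci_low", np.nan)) else float(r["ci_low"]),
                ci_high=None
                if pd.isna(r.get("ci_high", np.nan))
                else float(r["ci_high"]),
            )
        )
    return out


def write_consensus_estimates(estimates: Sequence[ConsensusEstimate], path) -> None:
    rows = [
        {
            "species": e.species,
            "source": e.source,
            "n": e.n,
            "mode": e.mode,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "bandwidth": e.bandwidth,
        }
        for e in estimates
    ]
    pd.DataFrame(
        rows,
        columns=["species", "source", "n", "mode", "ci_low", "ci_high", "bandwidth"],
    ).to_csv(path, sep="\t", index=False)


def read_consensus_estimates(path) -> list[ConsensusEstimate]:
    df = _read_tsv(
        path,
        required=("species", "source", "n", "mode", "ci_low", "ci_high", "bandwidth"),
        numeric=("n", "mode", "ci_low", "ci_high", "bandwidth"),
    )
    return [
        ConsensusEstimate(
            mode=float(r["mode"]),
            ci_low=float(r["ci_low"]),
            ci_high=float(r["ci_high"]),
            n=int(r["n"]),
            bandwidth=float(r["bandwidth"]),
            n_bootstrap=0,
            species=r["species"],
            source=r["source"],
        )
        for _, r in df.iterrows()
    ]


def read_event_map(path) -> tuple[dict[str, str], dict[str, bool]]:
    """Read the curated species -> event assignment.

    Returns ``(event_map, exclude_flags)`` where ``exclude_flags`` marks
    events to drop in robustness runs (e.g. a WGD suspected to merge two
    separate events).
    """
    df = _read_tsv(path, required=("species", "event_id"), numeric=())
    if df.duplicated(subset=["species"]).any():
        raise SchemaError(f"{path}: a species is assigned to two events")
    event_map = dict(zip(df["species"], df["event_id"]))
    flags: dict[str, bool] = {}
    if "exclude_flag" in df.columns:
        for event_id, group in df.groupby("event_id"):
            values = {v.strip().lower() for v in group["exclude_flag"]}
            flags[event_id] = bool(values & {"1", "true", "yes"})
    return event_map, {k: v for k, v in flags.items() if v}


def write_event_map(
    event_map: dict[str, str], path, exclude_flags: dict[str, bool] | None = None
) -> None:
    exclude_flags = exclude_flags or {}
    rows = [
        {
            "species": species,
            "event_id": event_id,
            "exclude_flag": "1" if exclude_flags.get(event_id) else "0",
        }
        for species, event_id in sorted(event_map.items())
    ]
    pd.DataFrame(rows, columns=["species", "event_id", "exclude_flag"]).to_csv(
        path, sep="\t", index=False
    )


def write_events(events: Sequence[WGDEvent], path) -> None:
    rows = [
        {
            "event_id": e.event_id,
            "age": e.age,
            "n_members": len(e.member_species),
            "member_species": ";".join(e.member_species),
            "sources_used": ";".join(e.sources_used),
        }
        for e in events
    ]
    pd.DataFrame(
        rows,
        columns=["event_id", "age", "n_members", "member_species", "sources_used"],
    ).to_csv(path, sep="\t", index=False)


def read_events(path) -> list[WGDEvent]:
    df = _read_tsv(
        path,
        required=("event_id", "age", "n_members", "member_species", "sources_used"),
        numeric=("age",),
    )
    return [
        WGDEvent(
            event_id=r["event_id"],
            member_species=tuple(r["member_species"].split(";")),
            age=float(r["age"]),
            sources_used=tuple(r["sources_used"].split(";")),
        )
        for _, r in df.iterrows()
    ]


# -- Trees -------------------------------------------------------------------


def read_tree(path) -> dendropy.Tree:
    """Read a newick tree; every non-root branch must carry a length."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"file not found: {path}")
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.edge.length is None:
            raise SchemaError(
                f"{path}: tree has branches without lengths; branch lengths "
                "are required (they carry the time scale)"
            )
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(tree.as_string(schema="newick", suppress_rooting=True))


# -- Pipeline configuration ---------------------------------------------------


@dataclasses.dataclass
class PipelineConfig:
    """Paths, windows, constants and seeds for a full pipeline run.

    All randomness flows from the per-stage seeds recorded here; no stage
    reads entropy from the environment.  The config round-trips through
    YAML losslessly.
    """

    ks_table: str | None = None
    gene_trees: str | None = None
    age_samples: str | None = None
    species_estimates: str | None = None
    species_tree: str | None = None
    event_map: str | None = None
    peak_windows: dict = dataclasses.field(default_factory=dict)
    statistic_kind: str = "median_pairwise"
    n_bootstrap: int = 1000
    n_null_samples: int = 1_000_000
    m_candidates: list = dataclasses.field(default_factory=lambda: [1, 2, 3])
    window: list = dataclasses.field(default_factory=lambda: [0.0, 100.0])
    ltt_dt: float = 0.1
    kde_grid_size: int = 2**14
    seeds: dict = dataclasses.field(
        default_factory=lambda: {
            "selection": 1,
            "bootstrap": 2,
            "clustering": 3,
            "mixture": 4,
        }
    )

    def validate(self) -> "PipelineConfig":
        if self.statistic_kind not in ("median_pairwise", "median_nearest_neighbor"):
            raise ParameterError(f"unknown statistic_kind {self.statistic_kind!r}")
        if len(self.window) != 2 or not self.window[0] < self.window[1]:
            raise ParameterError("window must be [t_min, t_max] with t_min < t_max")
        if self.n_bootstrap < 1 or self.n_null_samples < 1:
            raise ParameterError("replicate counts must be positive")
        return self

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw).validate()
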