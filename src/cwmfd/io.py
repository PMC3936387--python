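"""Readers and writers for every table the pipeline touches.

All tabular I/O is comma-delimited UTF-8 CSV with a header row, decimal
points and empty strings for missing values. CSVs round floats to 4
decimals; JSON carries full precision. Every result directory gets a
manifest recording the files written, the seed and a config hash, so a
run can be regenerated exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .design import Design
from .functional_metrics import SpeciesPool
from .microcosm_analysis import MicrocosmRecord

__all__ = [
    "read_trait_table",
    "write_trait_table",
    "read_abundances",
    "write_abundances",
    "read_microcosms",
    "read_microcosms_wide",
    "write_microcosms_wide",
    "read_design",
    "write_design",
    "load_config",
    "write_results",
]

TRAIT_COLUMNS = [
    "species_id",
    "fresh_body_mass_mg",
    "consumption_rate_mg_ind_day",
    "consumption_sd",
]


def read_trait_table(path: str | Path) -> SpeciesPool:
    """Read a species trait CSV into a validated pool.

    Required columns: ``species_id, fresh_body_mass_mg,
    consumption_rate_mg_ind_day, consumption_sd`` (units are asserted via
    the header names). Errors name the offending column, row or id.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"trait table {path} is empty") from None
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trait table {path} missing columns: {missing}")
    for col in TRAIT_COLUMNS[1:]:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"trait table {path}: non-numeric {col!r} in row {row} "
                f"(species_id={df.loc[row, 'species_id']!r})"
            )
        df[col] = pd.to_numeric(df[col])
    dupes = df.loc[df["species_id"].duplicated(), "species_id"].tolist()
    if dupes:
        raise ValueError(f"trait table {path}: duplicated species_id {dupes}")
    return SpeciesPool.from_frame(df)


def write_trait_table(pool: SpeciesPool, path: str | Path) -> None:
    pool.to_frame().to_csv(path, index=False)


def read_abundances(path: str | Path) -> dict[str, dict[str, int]]:
    """Read a long abundance CSV (assemblage_id, species_id, count)."""
    df = pd.read_csv(path)
    required = {"assemblage_id", "species_id", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"abundance table {path} missing columns: {sorted(missing)}")
    out: dict[str, dict[str, int]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.assemblage_id), {})[str(row.species_id)] = int(row.count)
    return out


def write_abundances(
    assemblages: Mapping[str, Mapping[str, int]], path: str | Path
) -> None:
    rows = [
        {"assemblage_id": aid, "species_id": sp, "count": int(n)}
        for aid, counts in assemblages.items()
        for sp, n in counts.items()
        if n > 0
    ]
    pd.DataFrame(rows, columns=["assemblage_id", "species_id", "count"]).to_csv(
        path, index=False
    )


def _records_from_frames(counts: pd.DataFrame, litter: pd.DataFrame) -> list[MicrocosmRecord]:
    litter = litter.set_index("microcosm_id")
    grouped: dict[str, dict] = {}
    for row in counts.itertuples(index=False):
        g = grouped.setdefault(
            str(row.microcosm_id),
            {"assemblage_id": str(row.assemblage_id), "start": {}, "dead": {}},
        )
        g["start"][str(row.species_id)] = int(row.start_count)
        g["dead"][str(row.species_id)] = int(row.dead_count)
    records = []
    for mid in litter.index.astype(str):
        g = grouped.get(mid, {"assemblage_id": "blank", "start": {}, "dead": {}})
        li = litter.loc[mid]
        records.append(
            MicrocosmRecord(
                microcosm_id=mid,
                assemblage_id=g["assemblage_id"],
                start_counts=g["start"],
                dead_counts=g["dead"],
                litter_initial_mg=float(li["litter_initial_mg"]),
                litter_final_mg=float(li["litter_final_mg"]),
                duration_days=float(li["duration_days"]),
            )
        )
    return records


def read_microcosms(
    counts_path: str | Path, litter_path: str | Path
) -> list[MicrocosmRecord]:
    """Read the two-table microcosm dialect.

    ``counts_path``: microcosm_id, assemblage_id, species_id, start_count,
    dead_count (one row per species per microcosm; animal-free units may
    be absent here). ``litter_path``: microcosm_id, litter_initial_mg,
    litter_final_mg, duration_days.
    """
    return _records_from_frames(pd.read_csv(counts_path), pd.read_csv(litter_path))


def read_microcosms_wide(path: str | Path) -> list[MicrocosmRecord]:
    """Read the single-file microcosm dialect.

    Columns: microcosm_id, assemblage_id, litter_initial_mg,
    litter_final_mg, duration_days plus start_<species> and dead_<species>
    count columns.
    """
    df = pd.read_csv(path)
    sp_ids = [c[len("start_"):] for c in df.columns if c.startswith("start_")]
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        start = {sp: int(d[f"start_{sp}"]) for sp in sp_ids if d[f"start_{sp}"] > 0}
        dead = {sp: int(d[f"dead_{sp}"]) for sp in sp_ids if sp in start}
        records.append(
            MicrocosmRecord(
                microcosm_id=str(d["microcosm_id"]),
                assemblage_id=str(d["assemblage_id"]),
                start_counts=start,
                dead_counts=dead,
                litter_initial_mg=float(d["litter_initial_mg"]),
                litter_final_mg=float(d["litter_final_mg"]),
                duration_days=float(d["duration_days"]),
            )
        )
    return records


def write_microcosms_wide(
    records: Sequence[MicrocosmRecord], path: str | Path
) -> None:
    sp_ids = sorted({sp for r in records for sp in r.start_counts})
    rows = []
    for r in records:
        row = {
            "microcosm_id": r.microcosm_id,
            "assemblage_id": r.assemblage_id,
            "litter_initial_mg": round(r.litter_initial_mg, 4),
            "litter_final_mg": round(r.litter_final_mg, 4),
            "duration_days": r.duration_days,
        }
        for sp in sp_ids:
            row[f"start_{sp}"] = int(r.start_counts.get(sp, 0))
            row[f"dead_{sp}"] = int(r.dead_counts.get(sp, 0))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_design(path: str | Path) -> Design:
    return Design.from_json(Path(path).read_text(encoding="utf-8"))


def write_design(design: Design, path: str | Path) -> None:
    Path(path).write_text(design.to_json(), encoding="utf-8")


def load_config(path: str | Path | None, overrides: Mapping | None = None) -> dict:
    """Load a YAML key-value config file; CLI overrides take precedence."""
    cfg: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a mapping")
        cfg.update(loaded)
    if overrides:
        cfg.update({k: v for k, v in overrides.items() if v is not None})
    return cfg


def _config_hash(config) -> str:
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclasses.asdict(config)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    seed: int | None = None,
    config=None,
) -> dict:
    """Write result tables as 4-decimal CSVs plus a provenance manifest.

    Returns the manifest (also written to ``manifest.json``): file list,
    seed, config hash and package version.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for name, df in tables.items():
        path = out / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.4f")
        files.append(path.name)
    manifest = {
        "version": __version__,
        "seed": seed,
        "config_hash": _config_hash(config) if config is not None else None,
        "files": files,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2), encoding="utf-8"
    )
    return manifest
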