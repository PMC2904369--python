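"""Readers and writers for maps, cross data and results.

File dialects
-------------
* Map: CSV with header ``marker,chromosome,position_cM``; free-form
  chromosome names; positions must increase within a chromosome.
* Cross: CSV with header ``family,individual,phenotype,<marker1>,...``;
  genotypes coded ``11|12|22|NA`` (1 and 2 are the two inbred founder
  alleles, e.g. 1 = C57BL/6J "B", 2 = 129X1/SvJ "S" in the mouse example);
  family coded 1-4 in mother-first mating-type order
  (Aa x Aa, Aa x aA, aA x Aa, aA x aA).
* Results: JSON for structured fits/peaks, TSV for LR profiles and power
  tables; every run writes a manifest recording config, seed and versions.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .emfit import CrossDataset
from .linkage import MISSING, VALID_GENOTYPES, MarkerMap

MAP_COLUMNS = ["marker", "chromosome", "position_cM"]


def read_map(path: str | Path) -> MarkerMap:
    """Load a linkage map from CSV, validating headers and monotone positions."""
    df = pd.read_csv(path, dtype={"marker": str, "chromosome": str})
    missing = set(MAP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing map columns {sorted(missing)}")
    if df["marker"].duplicated().any():
        dups = df.loc[df["marker"].duplicated(), "marker"].tolist()
        raise ValueError(f"{path}: duplicate marker names {dups}")
    return MarkerMap.from_table(df["marker"], df["chromosome"],
                                df["position_cM"].astype(float))


def write_map(marker_map: MarkerMap, path: str | Path) -> None:
    rows = [
        {"marker": n, "chromosome": c, "position_cM": p}
        for c in marker_map.chromosomes
        for n, p in zip(marker_map.names[c], marker_map.positions[c])
    ]
    pd.DataFrame(rows, columns=MAP_COLUMNS).to_csv(path, index=False)


def read_cross(path: str | Path, marker_map: MarkerMap) -> CrossDataset:
    """Load genotypes and phenotypes for the four families.

    Validates genotype codes cell by cell; errors name the offending row
    (1-based, excluding the header) and column.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["family", "individual", "phenotype"]
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    marker_cols = [c for c in df.columns if c not in required]
    unknown = set(marker_cols) - set(marker_map.marker_names)
    if unknown:
        raise ValueError(f"{path}: markers not on the map: {sorted(unknown)}")

    try:
        family = df["family"].astype(int).to_numpy() - 1
    except ValueError as e:
        raise ValueError(f"{path}: non-integer family code: {e}") from None
    if family.min() < 0 or family.max() > 3:
        raise ValueError(f"{path}: family codes must be 1-4")
    try:
        phenotype = df["phenotype"].astype(float).to_numpy()
    except ValueError as e:
        raise ValueError(f"{path}: non-numeric phenotype: {e}") from None

    valid = set(VALID_GENOTYPES) | {MISSING, ""}
    geno = df[marker_cols].copy()
    for col in marker_cols:
        bad = ~geno[col].isin(valid)
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1
            raise ValueError(
                f"{path}: invalid genotype {geno[col].iloc[row - 1]!r} "
                f"at row {row}, column {col!r}")
        geno[col] = geno[col].replace("", MISSING).astype(object)
    return CrossDataset(marker_map=marker_map, family=family,
                        phenotype=phenotype, genotypes=geno,
                        individual=df["individual"].to_numpy())


def write_cross(data: CrossDataset, path: str | Path) -> None:
    out = pd.DataFrame({
        "family": data.family + 1,
        "individual": data.individual,
        "phenotype": data.phenotype,
    })
    for col in data.genotypes.columns:
        out[col] = data.genotypes[col].values
    out.to_csv(path, index=False)


def write_json(obj: Any, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_manifest(out_dir: str | Path, config: dict, seed: int | None) -> Path:
    """Record the run configuration, seed and versions alongside outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config,
        "seed": seed,
        "versions": {
            "iqtlmap": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path = out_dir / "manifest.json"
    write_json(manifest, path)
    return path
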