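"""Readers and writers for the on-disk formats.

Tile-level matrices live in one HDF5 container per dataset, with one group
per slide holding ``features`` (n_tiles x d) and ``coords`` (n_tiles x 2);
group attributes carry patient and cohort identity.  Everything
human-readable is TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .types import ExpressionMatrix, SuperTileBag, TileBag


# ---------------------------------------------------------------- bag HDF5

def write_bags(path: str | Path, bags: list[TileBag]) -> None:
    with h5py.File(path, "w") as f:
        for bag in bags:
            g = f.create_group(bag.slide_id)
            g.attrs["patient_id"] = bag.patient_id
            g.attrs["cohort"] = bag.cohort
            g.create_dataset("features", data=bag.features, track_times=False)
            g.create_dataset("coords", data=np.asarray(bag.coords), track_times=False)


def read_bags(path: str | Path) -> list[TileBag]:
    bags = []
    with h5py.File(path, "r") as f:
        for slide_id in sorted(f.keys()):
            g = f[slide_id]
            bags.append(TileBag(
                slide_id=slide_id,
                patient_id=str(g.attrs["patient_id"]),
                cohort=str(g.attrs["cohort"]),
                coords=g["coords"][()],
                features=g["features"][()],
            ))
    return bags


def write_supertile_bags(path: str | Path, sbags: list[SuperTileBag]) -> None:
    with h5py.File(path, "w") as f:
        for sb in sbags:
            g = f.create_group(sb.slide_id)
            g.attrs["patient_id"] = sb.patient_id
            g.attrs["cohort"] = sb.cohort
            g.create_dataset("features", data=sb.features, track_times=False)
            g.create_dataset("sizes", data=sb.sizes, track_times=False)
            g.create_dataset("cluster_of_tile", data=sb.cluster_of_tile, track_times=False)


def read_supertile_bags(path: str | Path) -> list[SuperTileBag]:
    out = []
    with h5py.File(path, "r") as f:
        for slide_id in sorted(f.keys()):
            g = f[slide_id]
            out.append(SuperTileBag(
                slide_id=slide_id,
                patient_id=str(g.attrs["patient_id"]),
                cohort=str(g.attrs["cohort"]),
                cluster_of_tile=g["cluster_of_tile"][()],
                features=g["features"][()],
                sizes=g["sizes"][()],
            ))
    return out


def append_tile_scores(path: str | Path, slide_id: str,
                       gene_ids: list[str], tile_scores: np.ndarray) -> None:
    """Append per-tile score columns under ``tile_scores/<gene>``."""
    with h5py.File(path, "a") as f:
        g = f.require_group(slide_id).require_group("tile_scores")
        for j, gene in enumerate(gene_ids):
            if gene in g:
                del g[gene]
            g.create_dataset(gene, data=tile_scores[:, j], track_times=False)


# ------------------------------------------------------------------- TSVs

def write_expression(path: str | Path, mat: ExpressionMatrix) -> None:
    mat.raw.to_csv(path, sep="\t", index_label="sample_id")


def read_expression(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return ExpressionMatrix(df)


def write_manifest(path: str | Path, manifest: pd.DataFrame) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"slide_id", "patient_id", "cohort"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    return df


def write_patient_labels(path: str | Path, labels: pd.DataFrame) -> None:
    labels.to_csv(path, sep="\t", index=False)


def read_patient_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "patient_id" not in df.columns or "label" not in df.columns:
        raise ValueError("patient label table needs patient_id and label columns")
    return df


def write_tile_labels(path: str | Path,
                      labels: dict[str, np.ndarray],
                      coords: dict[str, np.ndarray]) -> None:
    """Per-tile ground-truth labels as TSV (slide_id, x, y, value)."""
    rows = []
    for slide_id, vals in labels.items():
        xy = coords[slide_id]
        for (x, y), v in zip(xy.tolist(), np.asarray(vals).tolist()):
            rows.append({"slide_id": slide_id, "x": x, "y": y, "value": v})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_tile_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"slide_id", "x", "y", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"tile label table must have columns {sorted(required)}")
    return df


def write_gene_list(path: str | Path, genes: list[str]) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines()
            if line.strip()]


# -------------------------------------------------------------------- GMT

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(path: str | Path, sets: dict[str, list[str]]) -> None:
    lines = [f"{name}\tna\t" + "\t".join(genes) for name, genes in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------------------- JSON

def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
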