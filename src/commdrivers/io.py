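"""Reading and writing the package's tabular formats.

All tables are UTF-8, tab-separated ('.' decimal); the first column holds
the site or species identifier.  Community tables are sites × species;
block tables are sites × variables; the block map assigns every predictor
variable to exactly one named block.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BlockCollection, SiteSpeciesMatrix
from .exceptions import AlignmentError, MappingError, ParseError
from .synthetic import GroundTruth


def _read_table(path: Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, encoding="utf-8")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: empty data section")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicated row label {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ParseError(f"{path}: duplicated column {dup!r}")
    return df


def _numeric(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    try:
        return df.astype(float)
    except (TypeError, ValueError):
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any() and not df[col].isna().any():
                row = df.index[coerced.isna().argmax()]
                raise ParseError(
                    f"{path}: non-numeric cell at row {row!r}, column {col!r}"
                )
        raise ParseError(f"{path}: non-numeric data")


def read_species_meta(path) -> pd.DataFrame:
    """Species metadata TSV: species_id, trophic_group, guild, host_genera."""
    path = Path(path)
    meta = pd.read_csv(path, sep="\t", index_col=0, encoding="utf-8",
                       keep_default_na=False)
    for col in ("trophic_group", "guild"):
        if col not in meta.columns:
            raise ParseError(f"{path}: missing metadata column {col!r}")
    if "host_genera" not in meta.columns:
        meta["host_genera"] = ""
    return meta


def read_community(path, meta_path) -> SiteSpeciesMatrix:
    """Read a site × species table and join the species metadata."""
    path = Path(path)
    df = _numeric(_read_table(path), path)
    meta = read_species_meta(meta_path)
    missing = [s for s in df.columns if s not in meta.index]
    if missing:
        raise ParseError(f"{path}: species missing from metadata: {missing[:5]}")
    return SiteSpeciesMatrix(df, meta.loc[meta.index.isin(df.columns)])


def write_community(m: SiteSpeciesMatrix, path) -> None:
    m.data.to_csv(path, sep="\t", encoding="utf-8", index_label="site_id")


def write_species_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", encoding="utf-8", index_label="species_id")


def read_blocks(blocks_dir, blockmap_path) -> BlockCollection:
    """Read predictor tables from a directory and group them per the map.

    The block map is a two-column table (variable, block).  A data variable
    absent from the map, or mapped twice, is a mapping error; blocks mapped
    to no present variable are dropped with a warning.
    """
    blocks_dir = Path(blocks_dir)
    bmap = pd.read_csv(blockmap_path, sep="\t", encoding="utf-8")
    if not {"variable", "block"} <= set(bmap.columns):
        raise MappingError(f"{blockmap_path}: needs 'variable' and 'block' columns")
    if bmap["variable"].duplicated().any():
        dup = bmap["variable"][bmap["variable"].duplicated()].iloc[0]
        raise MappingError(f"variable {dup!r} listed twice in the block map")
    frames = []
    for f in sorted(blocks_dir.glob("*.tsv")):
        frames.append(_numeric(_read_table(f), f))
    if not frames:
        raise ParseError(f"no *.tsv block tables in {blocks_dir}")
    sites = list(frames[0].index)
    for f in frames[1:]:
        if list(f.index) != sites:
            raise AlignmentError("block tables do not share the site set")
    data = pd.concat(frames, axis=1)
    if data.columns.duplicated().any():
        dup = data.columns[data.columns.duplicated()][0]
        raise MappingError(f"variable {dup!r} appears in several block tables")
    assign = dict(zip(bmap["variable"], bmap["block"]))
    unmapped = [v for v in data.columns if v not in assign]
    if unmapped:
        raise MappingError(f"variables absent from the block map: {unmapped[:5]}")
    blocks: dict[str, list[str]] = {}
    for name in dict.fromkeys(bmap["block"]):  # preserve map order
        cols = [v for v in data.columns if assign[v] == name]
        if not cols:
            warnings.warn(f"block {name!r} has no variables present; dropped")
            continue
        blocks[name] = cols
    return BlockCollection({name: data.loc[:, cols] for name, cols in blocks.items()})


def write_blocks(env: BlockCollection, out_dir) -> None:
    out_dir = Path(out_dir)
    bdir = out_dir / "blocks"
    bdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, df in env.blocks.items():
        df.to_csv(bdir / f"{name}.tsv", sep="\t", encoding="utf-8",
                  index_label="site_id")
        rows.extend({"variable": v, "block": name} for v in df.columns)
    pd.DataFrame(rows).to_csv(out_dir / "blockmap.tsv", sep="\t",
                              encoding="utf-8", index=False)


def write_truth(truth: GroundTruth, path) -> None:
    payload = {
        "block_effect_shares": truth.block_effect_shares,
        "coupling_strength": truth.coupling_strength,
        "planted_pairs": [list(p) for p in truth.planted_pairs],
        "seed": truth.seed,
        "block_gradients": truth.block_gradients,
        "latent_gradients": truth.latent_gradients.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def write_simulation(env, plants, hoppers, truth, out_dir) -> None:
    """Persist a simulated study: communities, blocks, metadata, truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_community(plants, out_dir / "plants.tsv")
    write_community(hoppers, out_dir / "leafhoppers.tsv")
    write_blocks(env, out_dir)
    meta = pd.concat([plants.meta, hoppers.meta])
    write_species_meta(meta, out_dir / "species_meta.tsv")
    write_truth(truth, out_dir / "truth.json")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def write_json(payload: dict, path) -> None:
    Path(path).write_text(
        json.dumps(payload, indent=1, sort_keys=True, default=_json_default,
                   allow_nan=True)
    )
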