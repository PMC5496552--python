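"""Core in-memory containers: community matrices, occurrence matrices, predictor blocks.

All containers wrap :class:`pandas.DataFrame` objects and validate their
structural invariants on construction.  Orientation conventions:

* :class:`SiteSpeciesMatrix` — sites in rows, species in columns (the usual
  community-ecology layout for ordination).
* :class:`OccurrenceMatrix` — species in rows, sites in columns (the usual
  layout for co-occurrence null models).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, InvalidSpecError

TROPHIC_GROUPS = ("plant", "leafhopper")
GUILDS = ("generalist", "specialist", "none")


def _check_unique(labels: Iterable, what: str) -> None:
    labels = list(labels)
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if list(labels).count(x) > 1})
        raise InvalidSpecError(f"duplicate {what}: {dupes[:5]}")


def genus_of(species_id: str) -> str:
    """Genus token of a species identifier ("Genus epithet" or "Genus_epithet")."""
    return str(species_id).replace("_", " ").split()[0]


@dataclass
class SiteSpeciesMatrix:
    """Site × species abundance (or cover) table with per-species metadata.

    Parameters
    ----------
    data
        Numeric DataFrame, sites in rows, species in columns, values >= 0.
    meta
        DataFrame indexed by species id with columns ``trophic_group``
        (``plant``/``leafhopper``), ``guild`` (``generalist``/``specialist``/
        ``none``) and ``host_genera`` (list of genus names, may be empty).
    """

    data: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "site ids")
        _check_unique(self.data.columns, "species ids")
        values = self.data.to_numpy(dtype=float)
        if values.size and np.nanmin(values) < 0:
            raise InvalidSpecError("abundance values must be nonnegative")
        missing = [s for s in self.data.columns if s not in self.meta.index]
        if missing:
            raise InvalidSpecError(f"species without metadata: {missing[:5]}")
        bad = set(self.meta.loc[list(self.data.columns), "trophic_group"]) - set(
            TROPHIC_GROUPS
        )
        if bad:
            raise InvalidSpecError(f"unknown trophic_group values: {sorted(bad)}")

    # -- convenience accessors -------------------------------------------------
    @property
    def site_ids(self) -> list:
        return list(self.data.index)

    @property
    def species_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_sites(self) -> int:
        return self.data.shape[0]

    @property
    def n_species(self) -> int:
        return self.data.shape[1]

    def occupancy(self) -> pd.Series:
        """Number of sites where each species is present (value > 0)."""
        return (self.data > 0).sum(axis=0)

    def subset_species(self, species: Iterable) -> "SiteSpeciesMatrix":
        species = [s for s in self.species_ids if s in set(species)]
        return SiteSpeciesMatrix(
            self.data.loc[:, species], self.meta.loc[self.meta.index.isin(species)]
        )

    def with_values(self, values: np.ndarray) -> "SiteSpeciesMatrix":
        return SiteSpeciesMatrix(
            pd.DataFrame(values, index=self.data.index, columns=self.data.columns),
            self.meta,
        )


@dataclass
class OccurrenceMatrix:
    """Binary species × sites presence–absence matrix.

    ``provenance`` optionally records, per species row, the trophic group and
    guild it came from (used by the pairwise co-occurrence submatrices).
    """

    data: pd.DataFrame
    provenance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "species ids")
        _check_unique(self.data.columns, "site ids")
        values = self.data.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise InvalidSpecError("occurrence cells must be 0 or 1")
        self.data = self.data.astype(np.uint8)
        if self.provenance is not None:
            missing = [s for s in self.data.index if s not in self.provenance.index]
            if missing:
                raise InvalidSpecError(f"species without provenance: {missing[:5]}")

    @property
    def species_ids(self) -> list:
        return list(self.data.index)

    @property
    def site_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=np.uint8)

    @property
    def row_totals(self) -> np.ndarray:
        return self.values.sum(axis=1).astype(np.int64)

    @property
    def column_totals(self) -> np.ndarray:
        return self.values.sum(axis=0).astype(np.int64)

    @property
    def n_species(self) -> int:
        return self.data.shape[0]

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]


@dataclass
class BlockCollection:
    """Ordered collection of named predictor blocks over a common site set."""

    blocks: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.blocks:
            raise InvalidSpecError("a BlockCollection needs at least one block")
        _check_unique(self.blocks.keys(), "block names")
        sites = None
        seen_vars: list = []
        for name, df in self.blocks.items():
            if df.shape[1] == 0:
                raise InvalidSpecError(f"block {name!r} has no variables")
            if sites is None:
                sites = list(df.index)
            elif list(df.index) != sites:
                raise AlignmentError(
                    f"block {name!r} does not share the common site set"
                )
            seen_vars.extend(df.columns)
        _check_unique(seen_vars, "variable labels across blocks")

    @property
    def names(self) -> list[str]:
        return list(self.blocks)

    @property
    def site_ids(self) -> list:
        return list(next(iter(self.blocks.values())).index)

    @property
    def K(self) -> int:
        return len(self.blocks)

    @property
    def P(self) -> int:
        return sum(df.shape[1] for df in self.blocks.values())

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def variable_labels(self) -> list[str]:
        out: list[str] = []
        for df in self.blocks.values():
            out.extend(df.columns)
        return out

    def block_of(self) -> list[str]:
        """Block name for each variable, in concatenation order."""
        out: list[str] = []
        for name, df in self.blocks.items():
            out.extend([name] * df.shape[1])
        return out

    def concat(self) -> pd.DataFrame:
        return pd.concat(self.blocks.values(), axis=1)

    def arrays(self) -> list[np.ndarray]:
        return [df.to_numpy(dtype=float) for df in self.blocks.values()]

    def subset(self, keep: Mapping[str, Iterable[str]]) -> "BlockCollection":
        """Restrict each block to the listed variables; drop blocks not in ``keep``."""
        blocks = {}
        for name, cols in keep.items():
            cols = [c for c in self.blocks[name].columns if c in set(cols)]
            if cols:
                blocks[name] = self.blocks[name].loc[:, cols]
        return BlockCollection(blocks)
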