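"""Response transforms, rarity filtering and pairwise-submatrix assembly.

Plant cover is log(1+x)-transformed to damp highly abundant species;
animal counts are Hellinger-transformed (square root of relative abundance
per site), which tempers both extreme values and double absences.  Species
present in fewer than ``min_sites`` sites are removed before analysis.  For
the pairwise co-occurrence step two stacked presence–absence submatrices
are assembled: generalist consumers with the most widespread plants (G–C)
and specialist consumers with their (possibly congeneric) host plants (S–H).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import OccurrenceMatrix, SiteSpeciesMatrix, genus_of
from .exceptions import AlignmentError, DomainError, InvalidParameterError


def log_transform_cover(m: SiteSpeciesMatrix, base: float | None = None) -> SiteSpeciesMatrix:
    """Cell-wise log(1 + x); natural log by default, ``base`` configurable."""
    values = m.values
    if values.size and values.min() < 0:
        raise DomainError("negative cover value")
    out = np.log1p(values)
    if base is not None:
        if base <= 0 or base == 1:
            raise InvalidParameterError("log base must be positive and != 1")
        out = out / np.log(base)
    return m.with_values(out)


def hellinger_transform(m: SiteSpeciesMatrix) -> SiteSpeciesMatrix:
    """sqrt of within-site relative abundance; all-zero sites stay zero."""
    values = m.values
    if values.size and values.min() < 0:
        raise DomainError("negative abundance value")
    sums = values.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.sqrt(np.where(sums > 0, values / np.where(sums > 0, sums, 1.0), 0.0))
    return m.with_values(out)


def occupancy_filter(m: SiteSpeciesMatrix, min_sites: int = 5) -> SiteSpeciesMatrix:
    """Keep species present (value > 0) in at least ``min_sites`` sites."""
    if min_sites < 0:
        raise InvalidParameterError("min_sites must be >= 0")
    occ = m.occupancy()
    keep = [s for s in m.species_ids if occ[s] >= min_sites]
    if not keep:
        warnings.warn("occupancy filter removed every species")
        return SiteSpeciesMatrix(m.data.iloc[:, :0], m.meta.iloc[:0])
    return m.subset_species(keep)


def to_presence_absence(m: SiteSpeciesMatrix) -> OccurrenceMatrix:
    """Binary species × sites matrix (1 iff abundance > 0), with provenance."""
    pa = (m.data.to_numpy(dtype=float) > 0).astype(np.uint8).T
    data = pd.DataFrame(pa, index=m.species_ids, columns=m.site_ids)
    prov = m.meta.loc[m.species_ids, ["trophic_group", "guild"]].copy()
    return OccurrenceMatrix(data, provenance=prov)


@dataclass
class CommonPlantRule:
    """Selection rule for the "most widespread and abundant" plants: rank by
    occupancy, break ties by total abundance (when available), keep ``top_n``."""

    top_n: int = 88


@dataclass
class PairMatrices:
    gc: OccurrenceMatrix | None
    sh: OccurrenceMatrix | None
    unmatched: list[str] = field(default_factory=list)


def build_pair_matrices(
    plants: OccurrenceMatrix,
    hoppers: OccurrenceMatrix,
    meta: pd.DataFrame,
    hosts: pd.DataFrame | None = None,
    common_rule: CommonPlantRule | None = None,
    abundance: pd.DataFrame | None = None,
) -> PairMatrices:
    """Assemble the G–C and S–H pairwise submatrices.

    Parameters
    ----------
    plants, hoppers
        Presence–absence matrices over the same site set.
    meta
        Species metadata with ``guild`` (generalist/specialist/none) and
        ``trophic_group``.
    hosts
        Specialist → host association table with columns ``leafhopper_id``,
        ``host_genus`` and optional ``host_species``; when None, the
        ``host_genera`` metadata column is used genus-level only.
    common_rule
        How many top-ranked plants count as "common".
    abundance
        Optional site × plant abundance frame for the occupancy tie-break.

    A specialist whose host matches no plant at species or genus level is
    recorded in the ``unmatched`` report and left out of S–H.
    """
    if list(plants.site_ids) != list(hoppers.site_ids):
        raise AlignmentError("plant and leafhopper matrices must share sites")
    common_rule = common_rule or CommonPlantRule()

    guild = meta["guild"]
    generalists = [s for s in hoppers.species_ids if guild.get(s) == "generalist"]
    specialists = [s for s in hoppers.species_ids if guild.get(s) == "specialist"]

    # --- common plants: occupancy rank, total-abundance tie-break ----------
    occ = pd.Series(plants.row_totals, index=plants.species_ids)
    if abundance is not None:
        tot = abundance.sum(axis=0).reindex(plants.species_ids).fillna(0.0)
    else:
        tot = pd.Series(0.0, index=plants.species_ids)
    order = sorted(
        plants.species_ids, key=lambda s: (-occ[s], -tot[s], str(s))
    )
    common = order[: common_rule.top_n]

    gc = _stack(plants, hoppers, common, generalists)

    # --- specialist hosts ---------------------------------------------------
    plant_set = set(map(str, plants.species_ids))
    plant_genera: dict[str, list[str]] = {}
    for s in plants.species_ids:
        plant_genera.setdefault(genus_of(s), []).append(s)

    host_rows: dict[str, list[tuple[str | None, str]]] = {}
    if hosts is not None and len(hosts):
        for _, row in hosts.iterrows():
            host_rows.setdefault(str(row["leafhopper_id"]), []).append(
                (
                    str(row["host_species"])
                    if "host_species" in hosts.columns
                    and pd.notna(row.get("host_species"))
                    else None,
                    str(row["host_genus"]),
                )
            )

    matched_hosts: list[str] = []
    kept_specialists: list[str] = []
    unmatched: list[str] = []
    for sp in specialists:
        assoc = host_rows.get(str(sp))
        if assoc is None:
            genera = meta.loc[sp, "host_genera"]
            if isinstance(genera, str):
                genera = [g for g in genera.split(",") if g]
            assoc = [(None, g) for g in (genera or [])]
        found: list[str] = []
        for species_name, genus in assoc:
            if species_name and species_name in plant_set:
                found.append(species_name)  # exact species match first
            elif genus in plant_genera:
                found.extend(plant_genera[genus])  # congeneric fallback
        if found:
            kept_specialists.append(sp)
            matched_hosts.extend(found)
        else:
            unmatched.append(str(sp))
    host_plants = [s for s in plants.species_ids if s in set(matched_hosts)]

    sh = _stack(plants, hoppers, host_plants, kept_specialists)
    return PairMatrices(gc=gc, sh=sh, unmatched=unmatched)


def _stack(
    plants: OccurrenceMatrix,
    hoppers: OccurrenceMatrix,
    plant_rows: list,
    hopper_rows: list,
) -> OccurrenceMatrix | None:
    frames, provs = [], []
    for occ, rows in ((hoppers, hopper_rows), (plants, plant_rows)):
        if rows:
            frames.append(occ.data.loc[rows])
            if occ.provenance is not None:
                provs.append(occ.provenance.loc[rows])
    if not frames:
        return None
    data = pd.concat(frames, axis=0)
    prov = pd.concat(provs, axis=0) if provs else None
    return OccurrenceMatrix(data, provenance=prov)
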