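"""Per-zone taxon and area statistics: richness, areas, Venn partition, families.

Zone membership comes from the cleaned zone map (observed + imputed +
island-rule cells); presence information exists only for surveyed cells, so
richness and per-cell richness are computed over each zone's surveyed cells
while areas count every assigned cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .grid import PresenceAbsenceMatrix
from .regionalize import ZoneMap


@dataclass
class ZonePartition:
    """Venn regions: zone subset (sorted tuple) -> set of taxa found in
    exactly those zones.  Only nonempty regions are stored."""

    regions: dict[tuple[int, ...], set[str]]
    zones: list[int]

    def region(self, *zones: int) -> set[str]:
        return self.regions.get(tuple(sorted(zones)), set())

    def common_taxa(self) -> set[str]:
        """Taxa present in every zone."""
        return self.region(*self.zones)

    def specific_taxa(self, zone: int) -> set[str]:
        """Taxa present in exactly one zone."""
        return self.region(zone)

    def sizes(self) -> dict[tuple[int, ...], int]:
        return {s: len(t) for s, t in self.regions.items()}


def zone_stats(pa: PresenceAbsenceMatrix, zm: ZoneMap) -> pd.DataFrame:
    """Table of per-zone area, richness and mean per-cell richness +- SE.

    SE is the sample standard deviation (ddof=1) of per-cell richness over
    the zone's surveyed cells, divided by sqrt(n).  A final ``Total`` row
    aggregates over all assigned cells.
    """
    if zm.grid.n_cells != pa.grid.n_cells:
        raise ValueError("zone map grid inconsistent with matrix grid")
    area = zm.grid.cell_area()
    row_sums = pa.values.sum(axis=1)
    zones = zm.zones
    if not zones:
        raise ValueError("zone map has no assigned cells")
    total_cells = int(zm.assigned.sum())
    rows = []
    for z in zones + ["Total"]:
        in_zone = zm.assigned if z == "Total" else (zm.labels == z)
        n_cells = int(in_zone.sum())
        if n_cells == 0:
            raise ValueError(f"zone {z} has no cells")
        sv = in_zone & pa.surveyed
        richness = int((pa.values[sv].sum(axis=0) > 0).sum())
        cell_rich = row_sums[sv].astype(float)
        n = cell_rich.size
        mean = float(cell_rich.mean()) if n else float("nan")
        se = float(cell_rich.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        rows.append(
            {
                "zone": z,
                "n_cells": n_cells,
                "area_km2": n_cells * area,
                "area_pct": 100.0 * n_cells / total_cells,
                "richness": richness,
                "mean_cell_richness": mean,
                "se_cell_richness": se,
            }
        )
    return pd.DataFrame(rows).set_index("zone")


def venn_partition(pa: PresenceAbsenceMatrix, zm: ZoneMap) -> ZonePartition:
    """Partition taxa by the exact set of zones they occur in.

    A taxon belongs to region S iff the set of zones whose (surveyed) cells
    contain it is exactly S.  Taxa absent from every assigned cell are
    excluded; the regions are disjoint and cover all included taxa.
    """
    zones = zm.zones
    if len(zones) < 2:
        raise ValueError("Venn partition needs at least 2 zones")
    presence_by_zone = {}
    for z in zones:
        sv = (zm.labels == z) & pa.surveyed
        presence_by_zone[z] = pa.values[sv].sum(axis=0) > 0
    regions: dict[tuple[int, ...], set[str]] = {}
    for t, name in enumerate(pa.taxa):
        subset = tuple(z for z in zones if presence_by_zone[z][t])
        if subset:
            regions.setdefault(subset, set()).add(name)
    return ZonePartition(regions=regions, zones=zones)


def specific_family_counts(
    partition: ZonePartition, taxonomy: Mapping[str, str]
) -> pd.DataFrame:
    """Family tallies of each zone's specific taxa, sorted descending.

    Taxa without a taxonomy entry (or with an empty family) count under
    ``Unknown``.  Returns a long table (zone, family, count).
    """
    rows = []
    for z in partition.zones:
        counts: dict[str, int] = {}
        for taxon in partition.specific_taxa(z):
            fam = taxonomy.get(taxon, "") or "Unknown"
            counts[fam] = counts.get(fam, 0) + 1
        for fam in sorted(counts, key=lambda f: (-counts[f], f)):
            rows.append({"zone": z, "family": fam, "count": counts[fam]})
    return pd.DataFrame(rows, columns=["zone", "family", "count"])


def partition_to_csv(partition: ZonePartition, path: str | Path) -> None:
    """Venn regions as CSV: zone-subset bitmask, size, semicolon taxa list."""
    rows = []
    for subset in sorted(partition.regions):
        taxa = sorted(partition.regions[subset])
        mask = sum(1 << (partition.zones.index(z)) for z in subset)
        rows.append(
            {
                "zones": "+".join(str(z) for z in subset),
                "bitmask": mask,
                "size": len(taxa),
                "taxa": ";".join(taxa),
            }
        )
    pd.DataFrame(rows, columns=["zones", "bitmask", "size", "taxa"]).to_csv(
        path, index=False
    )
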