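"""Synthetic landscapes with known zone structure, for end-to-end testing.

The generator builds a rectangular grid partitioned into K contiguous zones
(latitudinal bands, or seeded Voronoi patches for a less regular geometry)
and a species pool of three kinds:

* core species occurring everywhere with probability ``p_core`` (the shared
  flora that makes zones overlap, as real regional floras do);
* zone-specific species occurring with high probability ``p_in`` inside
  their home zone and low ``p_out`` elsewhere (the signal that makes zones
  recoverable);
* gradient species whose occupancy follows a logistic response to the
  south-north (row) axis, creating smooth assemblage turnover that is not
  aligned with any single zone boundary.

Sampling effort is heterogeneous: a fraction of cells is never surveyed
(yielding empty matrix rows, as urban cells do in real specimen data), and
each surveyed cell receives a Poisson number of specimen records drawn from
its locally occupying species.  Per-cell environmental tables (monthly
temperatures with a seasonal cycle plus a latitudinal lapse, an opposing
precipitation gradient, and zone-correlated categorical classes) accompany
the records.  Everything is deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import GridSpec, OccurrenceRecord
from .regionalize import UNASSIGNED, ZoneMap

#: Cell area matching an ~11.2 km x 13.9 km survey cell.
DEFAULT_CELL_AREA_KM2 = 11.2 * 13.9

_FAMILIES = [
    "Asteraceae", "Poaceae", "Cyperaceae", "Fabaceae", "Rosaceae",
    "Orchidaceae", "Lamiaceae", "Ranunculaceae", "Apiaceae", "Brassicaceae",
    "Caryophyllaceae", "Ericaceae", "Liliaceae", "Polygonaceae", "Salicaceae",
]

_CATEGORICAL_CLASSES = {
    "parent_material": ["acidic_rock", "metamorphic_rock", "sedimentary_rock", "volcanic_ash"],
    "topography": ["mountain", "hill", "pediment", "lava_terrace"],
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a synthetic landscape.

    Defaults describe a strong-signal landscape: a 26 x 30 grid (~780
    cells) in four latitudinal bands, 200 core species at occupancy 0.5,
    40 specific species per zone at 0.8 inside / 0.02 outside, 30 gradient
    species, 10% of cells unsurveyed, ~400 specimens per surveyed cell (the
    sampling intensity of a dense national specimen survey).
    """

    n_rows: int = 26
    n_cols: int = 30
    k_zones: int = 4
    zone_geometry: str = "bands"  # or "voronoi"
    n_core: int = 200
    n_specific_per_zone: int = 40
    n_gradient: int = 30
    p_core: float = 0.5
    p_in: float = 0.8
    p_out: float = 0.02
    gradient_steepness: float = 0.5
    effort_mean: float = 400.0
    frac_unsurveyed: float = 0.1
    islands: Mapping[str, Sequence[int]] | None = None
    seed: int = 0

    def __post_init__(self):
        for name in ("p_core", "p_in", "p_out", "frac_unsurveyed"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.k_zones < 2:
            raise ValueError("k_zones must be >= 2")
        if self.p_in <= self.p_out:
            raise ValueError("p_in must exceed p_out for recoverable zones")
        if self.zone_geometry not in ("bands", "voronoi"):
            raise ValueError(f"unknown zone_geometry {self.zone_geometry!r}")


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated landscape."""

    grid: GridSpec
    zone: np.ndarray  # true zone label per cell, 1..k_true
    k_true: int
    species: pd.DataFrame  # taxon, family, kind, home_zone
    occupancy: np.ndarray  # (n_cells, n_species) binary, species in taxon order
    surveyed: np.ndarray  # planned survey mask
    env: pd.DataFrame  # cell_id, t01..t12, mat, precip, categorical columns

    def zone_map(self) -> ZoneMap:
        """The truth as a fully observed zone map (for recovery scoring)."""
        prov = np.full(self.grid.n_cells, "observed", dtype=object)
        return ZoneMap(labels=self.zone.copy(), provenance=prov, grid=self.grid)


def _zone_labels(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    n_cells = cfg.n_rows * cfg.n_cols
    rows = np.arange(n_cells) // cfg.n_cols
    if cfg.zone_geometry == "bands":
        # contiguous latitudinal bands of near-equal height, zone 1 southernmost
        edges = np.linspace(0, cfg.n_rows, cfg.k_zones + 1)
        labels = np.searchsorted(edges[1:-1], rows, side="right") + 1
    else:
        cols = np.arange(n_cells) % cfg.n_cols
        seeds = rng.choice(n_cells, size=cfg.k_zones, replace=False)
        sr, sc = seeds // cfg.n_cols, seeds % cfg.n_cols
        d2 = (rows[:, None] - sr[None, :]) ** 2 + (cols[:, None] - sc[None, :]) ** 2
        labels = d2.argmin(axis=1) + 1
    labels = labels.astype(int)
    k = cfg.k_zones
    if cfg.islands:
        for name in sorted(cfg.islands):
            k += 1
            labels[np.asarray(list(cfg.islands[name]), dtype=int)] = k
    return labels


def _species_table(cfg: SyntheticConfig, k_true: int, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for i in range(cfg.n_core):
        rows.append((f"core_{i:04d}", "core", 0))
    for z in range(1, k_true + 1):
        for i in range(cfg.n_specific_per_zone):
            rows.append((f"zone{z}_sp{i:03d}", "specific", z))
    for i in range(cfg.n_gradient):
        rows.append((f"grad_{i:04d}", "gradient", 0))
    df = pd.DataFrame(rows, columns=["taxon", "kind", "home_zone"])
    df["family"] = rng.choice(_FAMILIES, size=len(df))
    df = df.sort_values("taxon", ignore_index=True)
    return df[["taxon", "family", "kind", "home_zone"]]


def _occupancy(
    cfg: SyntheticConfig,
    zone: np.ndarray,
    species: pd.DataFrame,
    rng: np.random.Generator,
) -> np.ndarray:
    n_cells = zone.size
    rows = np.arange(n_cells) // cfg.n_cols
    p = np.empty((n_cells, len(species)))
    n_grad = int((species["kind"] == "gradient").sum())
    # spread gradient species midpoints across the row axis, alternate direction
    mids = np.linspace(0.1, 0.9, max(n_grad, 1)) * (cfg.n_rows - 1)
    g = 0
    for s, (kind, home) in enumerate(zip(species["kind"], species["home_zone"])):
        if kind == "core":
            p[:, s] = cfg.p_core
        elif kind == "specific":
            p[:, s] = np.where(zone == home, cfg.p_in, cfg.p_out)
        else:
            sign = 1.0 if g % 2 == 0 else -1.0
            z = sign * cfg.gradient_steepness * (rows - mids[g])
            p[:, s] = 1.0 / (1.0 + np.exp(-z))
            g += 1
    return (rng.random(p.shape) < p).astype(np.uint8)


def _environment(
    cfg: SyntheticConfig, zone: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    n_cells = zone.size
    rows = np.arange(n_cells) // cfg.n_cols
    lat_frac = rows / max(cfg.n_rows - 1, 1)  # 0 at south, 1 at north
    # mean annual temperature: ~14 degC in the south falling to ~8 in the north
    mat = 14.0 - 6.0 * lat_frac + rng.normal(0.0, 0.3, n_cells)
    months = np.arange(1, 13)
    seasonal = 12.0 * np.cos(2.0 * np.pi * (months - 7.5) / 12.0)  # peak Jul/Aug
    T = mat[:, None] + seasonal[None, :] + rng.normal(0.0, 0.4, (n_cells, 12))
    precip = 1600.0 - 500.0 * lat_frac + rng.normal(0.0, 60.0, n_cells)
    env = pd.DataFrame(T, columns=[f"t{m:02d}" for m in months])
    env.insert(0, "cell_id", np.arange(n_cells))
    env["mat"] = T.mean(axis=1)
    env["precip"] = precip
    for var, classes in _CATEGORICAL_CLASSES.items():
        # zone-correlated class: 60% chance of the zone's signature class
        signature = [(z - 1) % len(classes) for z in zone]
        draw = rng.random(n_cells)
        pick = rng.integers(0, len(classes), n_cells)
        idx = np.where(draw < 0.6, signature, pick)
        env[var] = [classes[i] for i in idx]
    return env


def generate(
    config: SyntheticConfig,
) -> tuple[list[OccurrenceRecord], SyntheticTruth]:
    """Draw one landscape: occurrence records plus the underlying truth.

    Occupancy is Bernoulli per (cell, species) according to the species
    kind; each surveyed cell then yields ``N ~ Poisson(effort_mean)``
    specimen records sampled uniformly with replacement from the species
    occupying it (a cell with no occupants yields none), with coordinates
    uniform within the cell.
    """
    rng = np.random.default_rng(config.seed)
    grid = GridSpec(
        x_min=0.0,
        y_min=0.0,
        cell_w=1.0,
        cell_h=1.0,
        n_cols=config.n_cols,
        n_rows=config.n_rows,
        cell_area_km2=DEFAULT_CELL_AREA_KM2,
    )
    zone = _zone_labels(config, rng)
    k_true = int(zone.max())
    species = _species_table(config, k_true, rng)
    occupancy = _occupancy(config, zone, species, rng)
    env = _environment(config, zone, rng)

    n_cells = grid.n_cells
    n_unsurveyed = int(round(config.frac_unsurveyed * n_cells))
    surveyed = np.ones(n_cells, dtype=bool)
    if n_unsurveyed:
        surveyed[rng.choice(n_cells, size=n_unsurveyed, replace=False)] = False

    taxa = species["taxon"].to_numpy()
    families = dict(zip(species["taxon"], species["family"]))
    records: list[OccurrenceRecord] = []
    for cell in range(n_cells):
        if not surveyed[cell]:
            continue
        occupants = np.flatnonzero(occupancy[cell])
        n_draw = int(rng.poisson(config.effort_mean))
        if occupants.size == 0 or n_draw == 0:
            continue
        chosen = rng.choice(occupants, size=n_draw, replace=True)
        r, c = grid.cell_rowcol(cell)
        xs = grid.x_min + (c + rng.random(n_draw)) * grid.cell_w
        ys = grid.y_min + (r + rng.random(n_draw)) * grid.cell_h
        for s, x, y in zip(chosen, xs, ys):
            t = taxa[s]
            records.append(
                OccurrenceRecord(taxon=t, family=families[t], lon=float(x), lat=float(y))
            )
    truth = SyntheticTruth(
        grid=grid,
        zone=zone,
        k_true=k_true,
        species=species,
        occupancy=occupancy,
        surveyed=surveyed,
        env=env,
    )
    return records, truth


def adjusted_rand_index(labels_a: Sequence[int], labels_b: Sequence[int]) -> float:
    """Chance-corrected pair-counting agreement between two labelings.

    ARI = (Index - E[Index]) / (Max - E[Index]) over the contingency table
    of the two partitions; 1 for identical partitions (up to renaming), ~0
    for independent ones.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("labelings must be 1-d and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    sum_comb = sum(comb(int(x), 2) for x in table.ravel())
    sum_a = sum(comb(int(x), 2) for x in table.sum(axis=1))
    sum_b = sum(comb(int(x), 2) for x in table.sum(axis=0))
    total = comb(n, 2)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_comb - expected) / (max_index - expected))


def recovery_report(est: ZoneMap, truth: SyntheticTruth) -> dict:
    """Score an estimated zone map against the generating truth.

    Computed on cells assigned in both maps; the confusion table's columns
    are greedily matched to maximize the diagonal.
    """
    both = est.assigned & (truth.zone != UNASSIGNED)
    a = truth.zone[both]
    b = est.labels[both]
    ari = adjusted_rand_index(a, b)
    true_zones = sorted(np.unique(a).tolist())
    est_zones = sorted(np.unique(b).tolist())
    table = pd.DataFrame(
        0, index=true_zones, columns=est_zones, dtype=int
    )
    for t, e in zip(a, b):
        table.loc[t, e] += 1
    # greedy match: repeatedly take the largest remaining entry
    matched: dict[int, int] = {}
    work = table.copy()
    while not work.empty and work.shape[1] > 0 and work.to_numpy().max() > 0:
        flat = work.stack()
        t, e = flat.idxmax()
        matched[int(e)] = int(t)
        work = work.drop(index=t, columns=e)
        if work.empty or work.shape[1] == 0:
            break
    order = [e for e in est_zones if e in matched]
    order += [e for e in est_zones if e not in matched]
    table = table[order]
    return {
        "ari": ari,
        "k_true": truth.k_true,
        "k_selected": len(est_zones),
        "n_cells_scored": int(both.sum()),
        "confusion": table,
        "matching": matched,
    }
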