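"""End-to-end orchestration with a structured config and stable artifacts.

A single top-level seed is expanded into per-stage seeds so the entire run
(rasterize -> train -> regionalize -> diagnose -> environment comparison)
is bit-reproducible; every run writes a manifest recording the config
snapshot, the seeds and a hash of each output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .grid import GridSpec, read_occurrences, rasterize
from .som import init_codebook, save_model, train
from .regionalize import (
    apply_island_rule,
    cells_to_zones,
    codebook_distances,
    complete_linkage,
    cut_tree,
    impute_empty_cells,
    merge_tree_to_csv,
    relabel_by_area,
    select_k,
    selection_to_csv,
    zone_map_to_csv,
)
from .diagnostics import (
    partition_to_csv,
    specific_family_counts,
    venn_partition,
    zone_stats,
)
from .climate import add_kira_indices, composition_ratio, one_way_anova, tukey_hsd, zone_groups
from .synthetic import SyntheticConfig, generate, recovery_report

log = logging.getLogger(__name__)

_STAGES = ("simulate", "som", "islands")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Structured run configuration (normally loaded from YAML)."""

    occurrences: str | None = None  # path; None -> simulate
    environment: str | None = None  # per-cell environment CSV
    grid: Mapping[str, Any] | None = None  # GridSpec fields
    simulate: Mapping[str, Any] | None = None  # SyntheticConfig overrides
    lattice_rows: int = 9
    lattice_cols: int = 9
    som: Mapping[str, Any] = field(default_factory=dict)  # schedule overrides
    k_min: int = 2
    k_max: int = 15
    impute: bool = True
    islands: Mapping[str, list[int]] | None = None
    continuous_variables: list[str] = field(
        default_factory=lambda: ["mat", "precip", "wi", "ci"]
    )
    categorical_variables: list[str] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _stage_seeds(seed: int) -> dict[str, int]:
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, 2**31 - 1, size=len(_STAGES))
    return {name: int(v) for name, v in zip(_STAGES, draws)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _island_cells(
    spec: Mapping[str, Any], grid: GridSpec
) -> dict[str, list[int]]:
    """Island groups from config: explicit indices, [start, end] ranges, or
    {rows: [r0, r1], cols: [c0, c1]} bounding boxes (inclusive)."""
    out: dict[str, list[int]] = {}
    for name, entry in spec.items():
        if isinstance(entry, Mapping):
            r0, r1 = entry["rows"]
            c0, c1 = entry["cols"]
            cells = [
                r * grid.n_cols + c
                for r in range(r0, r1 + 1)
                for c in range(c0, c1 + 1)
            ]
        elif len(entry) == 2 and all(isinstance(v, int) for v in entry) and entry[0] <= entry[1]:
            cells = list(range(entry[0], entry[1] + 1))
        else:
            cells = [int(v) for v in entry]
        out[name] = cells
    return out


def run_all(
    config: PipelineConfig, out_dir: str | Path, seed: int | None = None
) -> dict:
    """Execute every stage and return the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    seeds = _stage_seeds(seed)
    manifest: dict[str, Any] = {
        "seed": seed,
        "stage_seeds": seeds,
        "version": __version__,
        "python": sys.version.split()[0],
        "config": asdict(config),
        "files": {},
    }
    truth = None
    env = None

    # -- inputs ------------------------------------------------------------
    if config.occurrences is None:
        sim_kwargs = dict(config.simulate or {})
        sim_kwargs.setdefault("seed", seeds["simulate"])
        try:
            sim_cfg = SyntheticConfig(**sim_kwargs)
        except (TypeError, ValueError) as e:
            raise PipelineError("simulate", str(e))
        records, truth = generate(sim_cfg)
        grid = truth.grid
        env = truth.env
        from .grid import write_occurrences

        write_occurrences(records, out / "occurrences.csv")
        truth.env.to_csv(out / "environment.csv", index=False)
        truth.species.to_csv(out / "species_registry.csv", index=False)
        pd.DataFrame(
            {"cell_id": np.arange(grid.n_cells), "true_zone": truth.zone}
        ).to_csv(out / "true_zones.csv", index=False)
        log.info("simulated %d records on a %dx%d grid", len(records), grid.n_rows, grid.n_cols)
    else:
        occ_path = Path(config.occurrences)
        if not occ_path.exists():
            raise PipelineError("rasterize", f"occurrences path not found: {occ_path}")
        if config.grid is None:
            raise PipelineError("rasterize", "grid spec required with real occurrences")
        grid = GridSpec(**config.grid)
        records = read_occurrences(occ_path)
        if config.environment is not None:
            env_path = Path(config.environment)
            if not env_path.exists():
                raise PipelineError("env", f"environment path not found: {env_path}")
            env = pd.read_csv(env_path)

    # -- rasterize ---------------------------------------------------------
    try:
        pa = rasterize(records, grid)
    except ValueError as e:
        raise PipelineError("rasterize", str(e))
    grid.to_json(out / "grid.json")
    pa.to_wide_csv(out / "presence_absence.csv")
    pa.to_triplet_csv(out / "presence_absence_triplets.csv")

    # -- train -------------------------------------------------------------
    model = init_codebook(pa, config.lattice_rows, config.lattice_cols, seeds["som"])
    for key, val in (config.som or {}).items():
        if not hasattr(model, key):
            raise PipelineError("train", f"unknown SOM setting {key!r}")
        setattr(model, key, val)
    fit = train(model, pa)
    save_model(fit.model, out / "som_model.json")
    pd.DataFrame(
        {"epoch": np.arange(1, len(fit.qe_history) + 1), "qe": fit.qe_history}
    ).to_csv(out / "qe_history.csv", index=False)

    # -- regionalize -------------------------------------------------------
    dist = codebook_distances(fit.model)
    tree = complete_linkage(dist)
    merge_tree_to_csv(tree, out / "merge_tree.csv")
    sel = select_k(tree, dist, config.k_min, min(config.k_max, tree.n_leaves))
    selection_to_csv(sel, out / "silhouette.csv")
    node_labels = cut_tree(tree, sel.k_star)
    zm = cells_to_zones(fit, node_labels, pa)
    if config.impute:
        zm = impute_empty_cells(zm)
    if config.islands:
        zm = apply_island_rule(zm, _island_cells(config.islands, grid))
    zm = relabel_by_area(zm)
    zone_map_to_csv(zm, out / "zone_map.csv")

    # -- diagnose ----------------------------------------------------------
    stats_df = zone_stats(pa, zm)
    stats_df.to_csv(out / "zone_stats.csv")
    summary: dict[str, Any] = {
        "k_selected": sel.k_star,
        "max_mean_silhouette": max(sel.silhouettes),
        "n_zones": len(zm.zones),
    }
    if len(zm.zones) >= 2:
        part = venn_partition(pa, zm)
        partition_to_csv(part, out / "venn_regions.csv")
        taxonomy = {r.taxon: r.family for r in records}
        specific_family_counts(part, taxonomy).to_csv(
            out / "specific_families.csv", index=False
        )
        summary["common_taxa"] = len(part.common_taxa())
        summary["specific_taxa"] = {
            str(z): len(part.specific_taxa(z)) for z in part.zones
        }
    if truth is not None:
        rep = recovery_report(zm, truth)
        rep["confusion"].to_csv(out / "confusion.csv")
        summary["recovery_ari"] = rep["ari"]
        summary["k_true"] = rep["k_true"]

    # -- environment comparison --------------------------------------------
    if env is not None and len(zm.zones) >= 2:
        env_table = add_kira_indices(env) if "t01" in env.columns else env.copy()
        env_table.to_csv(out / "environment_with_indices.csv", index=False)
        report: dict[str, Any] = {}
        for var in config.continuous_variables:
            if var not in env_table.columns:
                continue
            groups = zone_groups(env_table, zm, var)
            arrays = [g for g in groups.values() if g.size >= 2]
            if len(arrays) < 2:
                continue
            try:
                an = one_way_anova(arrays)
                tk = tukey_hsd(arrays)
            except ValueError as e:
                raise PipelineError("env", f"{var}: {e}")
            zones = [z for z, g in groups.items() if g.size >= 2]
            report[var] = {
                "F": an.F,
                "df": [an.df_between, an.df_within],
                "p": an.p,
                "letters": {str(z): tk.letters[i] for i, z in enumerate(zones)},
            }
        (out / "anova_tukey.json").write_text(json.dumps(report, indent=2) + "\n")
        cats = config.categorical_variables or [
            c for c in ("parent_material", "topography") if c in env_table.columns
        ]
        for var in cats:
            composition_ratio(env_table, zm, var).to_csv(out / f"composition_{var}.csv")
        summary["anova"] = {v: report[v]["p"] for v in report}

    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
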