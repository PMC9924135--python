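"""End-to-end orchestration with stable on-disk interfaces.

``run_pipeline`` chains the stages — load/rasterize ranges, clean the
metaweb, prune every local network, tabulate mismatch statistics, validate
against occurrence pixels, optionally run the prey-mobility buffer — and
writes every intermediate artifact to the output directory so partial
reruns and inspection are possible:

- ``richness.asc`` / ``proportion_remaining.asc`` — study-area rasters;
- ``adjusted/<species>.asc`` — trophically adjusted presence layers;
- ``per_cell.csv`` — local-network accounting per occupied cell;
- ``range_loss.csv`` / ``overlap_pairs.csv`` / ``species_table.csv``;
- ``validation.csv`` and ``buffer_recovery.json`` when occurrences are given;
- ``summary.json`` — headline statistics;
- ``run_config.json`` — the configuration, verbatim, for provenance.

Rasters are ESRI ASCII grids georeferenced to the shared GridSpec.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path

from .errors import ConfigurationError
from .gridspace import (
    GridSpec,
    LayerStack,
    PresenceLayer,
    count_networks,
    rasterize_polygons,
    read_ascii_grid,
    read_geojson_layers,
    richness_map,
    write_ascii_grid,
)
from .localwebs import network_summaries, per_cell_table, prune_stack
from .metaweb import Metaweb, normalize_name, read_metaweb, remove_self_loops
from .mismatch import overlap_scatter, range_loss_table, species_table
from .occurrences import (
    buffer_recovery,
    clean_occurrences,
    load_occurrences,
    pixelize,
    validate,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_stack", "write_stack"]


@dataclass
class RunConfig:
    """File paths and options for one pipeline run."""

    layers_dir: str | None = None  # directory of per-species .asc grids
    polygons: str | None = None  # GeoJSON FeatureCollection alternative
    species_property: str = "species"
    touch: bool = False  # any-intersection rasterization instead of cell-center
    edges_csv: str | None = None
    roles_csv: str | None = None
    occurrences_csv: str | None = None
    min_year: int = 2001
    buffer_predator: str | None = None
    buffer_radius_km: float = 50.0
    lon_min: float = -20.0
    lon_max: float = 55.0
    lat_min: float = -35.0
    lat_max: float = 40.0
    resolution: float = 0.5
    out_dir: str = "metarange_out"
    seed: int = 0

    def gridspec(self) -> GridSpec:
        return GridSpec(
            self.lon_min, self.lon_max, self.lat_min, self.lat_max, self.resolution
        )


def _safe_name(species_id: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]+", "_", species_id)


def write_stack(stack: LayerStack, directory: str | Path) -> None:
    """Write one ASCII grid per layer into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for ly in stack.layers:
        write_ascii_grid(str(directory / f"{_safe_name(ly.species_id)}.asc"), ly.grid, stack.spec)


def load_stack(directory: str | Path, spec: GridSpec | None = None) -> LayerStack:
    """Load a stack from a directory of per-species ASCII grids.

    The species id is the file stem (underscores become spaces).  All grids
    must agree on geometry; ``spec``, when given, is enforced.
    """
    directory = Path(directory)
    layers = []
    for path in sorted(directory.glob("*.asc")):
        grid, gspec = read_ascii_grid(str(path))
        if spec is None:
            spec = gspec
        elif gspec != spec:
            raise ConfigurationError(f"{path}: grid geometry differs from the others")
        layers.append(PresenceLayer(path.stem.replace("_", " "), grid > 0, spec))
    if spec is None:
        raise ConfigurationError(f"no .asc layers found in {directory}")
    return LayerStack(spec, layers)


def _reconcile(stack: LayerStack, web: Metaweb) -> LayerStack:
    """Match stack species to metaweb species by normalized name."""
    canon = {normalize_name(s): s for s in web.species_ids}
    layers, orphans = [], []
    for ly in stack.layers:
        target = canon.get(normalize_name(ly.species_id))
        if target is None:
            orphans.append(ly.species_id)
        else:
            layers.append(PresenceLayer(target, ly.grid, stack.spec))
    if orphans:
        raise ConfigurationError(
            f"stack species absent from the metaweb (after name normalization): "
            f"{sorted(orphans)}"
        )
    return LayerStack(stack.spec, layers)


def run_pipeline(
    config: RunConfig,
    stack: LayerStack | None = None,
    web: Metaweb | None = None,
) -> Path:
    """Run every stage and return the output directory.

    ``stack`` and ``web`` may be passed in memory (the synthetic path);
    otherwise they are loaded from the configured files.  Deterministic for
    fixed inputs and config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2) + "\n"
    )
    spec = config.gridspec() if stack is None else stack.spec

    if stack is None:
        if config.layers_dir:
            stack = load_stack(config.layers_dir, spec)
        elif config.polygons:
            geoms = read_geojson_layers(config.polygons, config.species_property)
            stack = rasterize_polygons(geoms, spec, touch=config.touch)
        else:
            raise ConfigurationError("no range input: set layers_dir or polygons")
    if web is None:
        if not (config.edges_csv and config.roles_csv):
            raise ConfigurationError("no metaweb input: set edges_csv and roles_csv")
        web = read_metaweb(config.edges_csv, config.roles_csv)
    web = remove_self_loops(web)
    stack = _reconcile(stack, web)

    rich = richness_map(stack)
    write_ascii_grid(str(out / "richness.asc"), rich, spec)
    logger.info("stack: %d species, %d occupied cells", len(stack), count_networks(stack))

    pruned = prune_stack(stack, web)
    write_stack(pruned.adjusted, out / "adjusted")
    cells = per_cell_table(pruned)
    cells.to_csv(out / "per_cell.csv", index=False)
    prop = rich.astype(float)
    prop[:] = -9999.0
    for s in pruned.per_cell:
        prop[s.cell] = s.proportion_remaining
    write_ascii_grid(str(out / "proportion_remaining.asc"), prop, spec)

    loss = range_loss_table(pruned, web)
    loss.to_csv(out / "range_loss.csv", index=False)
    overlap_scatter(stack, web).to_csv(out / "overlap_pairs.csv", index=False)
    species_table(stack, web).to_csv(out / "species_table.csv", index=False)

    summary: dict = {"network_summaries": network_summaries(pruned)}
    summary["n_networks"] = count_networks(stack)
    summary["n_species"] = len(stack)
    summary["n_edges"] = web.L

    if config.occurrences_csv:
        records = load_occurrences(config.occurrences_csv)
        cleaned = clean_occurrences(records, spec, min_year=config.min_year)
        gbif_layers = pixelize(cleaned, spec)
        canon = {normalize_name(s): s for s in stack.species_ids}
        rows = []
        for name, layer in gbif_layers.items():
            target = canon.get(normalize_name(name))
            if target is None or layer.range_size == 0:
                continue
            rec = validate(layer, stack[target], pruned.adjusted[target])
            rows.append(
                {
                    "species_id": target,
                    "n_gbif_pixels": rec.n_gbif_pixels,
                    "prop_in_original": rec.prop_in_original,
                    "prop_in_adjusted": rec.prop_in_adjusted,
                    "delta": rec.delta,
                }
            )
        import pandas as pd

        vdf = pd.DataFrame(
            rows,
            columns=[
                "species_id", "n_gbif_pixels", "prop_in_original",
                "prop_in_adjusted", "delta",
            ],
        )
        vdf.to_csv(out / "validation.csv", index=False)
        if len(vdf):
            summary["validation"] = {
                "n_species_validated": int(len(vdf)),
                "mean_prop_in_original": float(vdf["prop_in_original"].mean()),
                "mean_prop_in_adjusted": float(vdf["prop_in_adjusted"].mean()),
                "mean_delta": float(vdf["delta"].mean()),
            }

        if config.buffer_predator:
            target = canon.get(normalize_name(config.buffer_predator))
            if target is None:
                raise ConfigurationError(
                    f"buffer predator {config.buffer_predator!r} not in the stack"
                )
            removed = PresenceLayer(
                target, stack[target].grid & ~pruned.adjusted[target].grid, spec
            )
            prey_names = {normalize_name(p) for p in web.prey_of(target)}
            prey_records = cleaned[
                cleaned["species"].map(normalize_name).isin(prey_names)
            ]
            if removed.range_size:
                pts, area = buffer_recovery(
                    removed, prey_records, config.buffer_radius_km, spec
                )
                report = {
                    "predator": target,
                    "radius_km": config.buffer_radius_km,
                    "removed_cells": removed.range_size,
                    "n_prey_points": int(len(prey_records)),
                    "frac_prey_points_in_removed_area": pts,
                    "frac_removed_area_recovered": area,
                }
            else:
                report = {
                    "predator": target,
                    "radius_km": config.buffer_radius_km,
                    "removed_cells": 0,
                    "note": "no range was removed for this predator",
                }
            (out / "buffer_recovery.json").write_text(json.dumps(report, indent=2) + "\n")
            summary["buffer_recovery"] = report

    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return out
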