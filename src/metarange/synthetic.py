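"""Synthetic landscapes, metawebs, and occurrence samples with ground truth.

The generator emulates the real pipeline inputs (expert range maps, a
two-level mammal metaweb, point-occurrence downloads) so every stage is
testable without external data:

- ranges are unions of rasterized disks with controllable radius
  distribution;
- the metaweb has carnivores preying on herbivores, with optional
  carnivore->carnivore edges (directed from higher to lower carnivore
  index, so trophic chains are acyclic);
- each carnivore's range is built to contain a *planted* fraction of
  prey-free cells, giving an exact ground-truth value for its relative
  range loss;
- occurrence points are sampled inside true-range cells with a detection
  probability, plus out-of-range false positives, a fraction teleported
  into the null-island box, and record years straddling 2000.

Identical config + seed gives bit-identical outputs.

The module also bundles a Serengeti mammal-web fixture: the 32 published
species with their roles, groups, and out/in degrees.  Only the degree
sequence of the 84-interaction web is published, not the edge list, so the
fixture synthesizes a synthetic degree-faithful topology (greedy,
deterministic); degrees match the published table exactly, edge identity
does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FeasibilityError
from .gridspace import GridSpec, LayerStack, PresenceLayer
from .metaweb import Metaweb, SpeciesRecord

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "generate_scenario",
    "generate_occurrences",
    "serengeti_fixture",
    "SERENGETI_SPECIES",
]


@dataclass
class ScenarioConfig:
    """Knobs of one synthetic study, all deterministic under ``seed``.

    ``planted_mismatch`` is the fraction of each carnivore's range cells
    guaranteed to be prey-free (a scalar, or one value per carnivore);
    ``out_degree`` draws are uniform on ``[out_degree_min, out_degree_max]``
    unless ``specialist_gradient`` is set, in which case carnivore *i* gets
    ``i + 1`` prey — the design that probes the generality-vs-loss relation
    at fixed range sizes.
    """

    # grid: a 60x60 southern-African window clear of the null-island box
    lon_min: float = 10.0
    lon_max: float = 40.0
    lat_min: float = -25.0
    lat_max: float = 5.0
    resolution: float = 0.5
    # community
    n_herbivores: int = 14
    n_carnivores: int = 6
    # range model: disks, radii in cells
    radius_mean: float = 8.0
    radius_sd: float = 2.0
    disks_per_species: int = 1
    # metaweb
    out_degree_min: int = 1
    out_degree_max: int = 8
    specialist_gradient: bool = False
    cc_edge_prob: float = 0.0
    # planted range mismatch per carnivore; None -> natural disk ranges
    # whose mismatch emerges from where prey happen to sit
    planted_mismatch: float | list[float] | None = 0.3
    # occurrence model
    detection_prob: float = 0.3
    false_positive_rate: float = 0.05
    null_island_fraction: float = 0.02
    year_min: int = 1995
    year_max: int = 2020
    points_per_species: int | None = None  # None: one Bernoulli trial per range cell
    seed: int = 0

    def gridspec(self) -> GridSpec:
        return GridSpec(
            self.lon_min, self.lon_max, self.lat_min, self.lat_max, self.resolution
        )

    def mismatch_for(self, carnivore_index: int) -> float | None:
        m = self.planted_mismatch
        if m is None:
            return None
        value = m[carnivore_index] if isinstance(m, (list, tuple)) else m
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"planted_mismatch must be in [0, 1], got {value}")
        return float(value)


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    true_mismatch: dict[str, float]
    metaweb: Metaweb
    stack: LayerStack
    occurrence_labels: pd.DataFrame | None = None


def _disk_cells(spec: GridSpec, rng: np.random.Generator,
                radius_mean: float, radius_sd: float, n_disks: int) -> np.ndarray:
    """Boolean grid: union of disks with random centers, radii in cell units."""
    rows = np.arange(spec.n_rows)[:, None]
    cols = np.arange(spec.n_cols)[None, :]
    grid = np.zeros(spec.shape, dtype=bool)
    for _ in range(n_disks):
        r0 = rng.integers(0, spec.n_rows)
        c0 = rng.integers(0, spec.n_cols)
        radius = max(0.5, rng.normal(radius_mean, radius_sd))
        grid |= (rows - r0) ** 2 + (cols - c0) ** 2 <= radius**2
    return grid


def _planted_carnivore_range(
    spec: GridSpec,
    rng: np.random.Generator,
    prey_union: np.ndarray,
    target_size: int,
    mismatch: float,
) -> tuple[np.ndarray, float]:
    """Build a range with an exact prey-free fraction.

    Picks ``n_out = round(mismatch * target_size)`` cells outside the prey
    union and the rest inside it, both taken nearest-first from a random
    anchor cell so the range stays compact.  Returns the grid and the
    realized mismatch ``n_out / target_size``.
    """
    in_cells = np.flatnonzero(prey_union.ravel())
    out_cells = np.flatnonzero(~prey_union.ravel())
    # a predator range cannot use more in-union (or out-of-union) cells than
    # exist; shrink the target size so the planted fraction stays exact
    if mismatch < 1.0:
        target_size = min(target_size, int(len(in_cells) / (1.0 - mismatch)))
    if mismatch > 0.0:
        target_size = min(target_size, int(len(out_cells) / mismatch))
    if target_size < 1:
        raise FeasibilityError(
            f"cannot plant mismatch {mismatch}: {len(in_cells)} cells inside / "
            f"{len(out_cells)} outside the prey union on this grid"
        )
    n_out = round(mismatch * target_size)
    n_in = target_size - n_out
    if len(in_cells) < n_in or len(out_cells) < n_out:
        raise FeasibilityError(
            f"cannot plant mismatch {mismatch} for a range of {target_size} cells: "
            f"{len(in_cells)} cells inside / {len(out_cells)} outside the prey union"
        )
    r0 = rng.integers(0, spec.n_rows)
    c0 = rng.integers(0, spec.n_cols)
    rows, cols = np.divmod(np.arange(spec.n_rows * spec.n_cols), spec.n_cols)
    dist = (rows - r0) ** 2 + (cols - c0) ** 2
    order = np.argsort(dist, kind="stable")
    in_mask = prey_union.ravel()[order]
    chosen = np.concatenate([order[in_mask][:n_in], order[~in_mask][:n_out]])
    grid = np.zeros(spec.n_rows * spec.n_cols, dtype=bool)
    grid[chosen] = True
    return grid.reshape(spec.shape), n_out / target_size


def generate_scenario(config: ScenarioConfig) -> tuple[LayerStack, Metaweb, GroundTruth]:
    """Generate a landscape + metaweb with planted per-predator mismatch.

    Herbivore ranges are disk unions.  Carnivores are built in index order;
    optional carnivore->carnivore edges point from higher to lower index so
    every prey range already exists when a predator range is planted.  Each
    carnivore range contains exactly ``round(m * size)`` prey-free cells,
    recorded in the ground truth as its realized mismatch fraction.
    """
    spec = config.gridspec()
    rng = np.random.default_rng(config.seed)
    herb_ids = [f"h{i:02d}" for i in range(config.n_herbivores)]
    carn_ids = [f"c{i:02d}" for i in range(config.n_carnivores)]
    species = [SpeciesRecord(s, "herbivore", group="herbivores") for s in herb_ids] + [
        SpeciesRecord(s, "carnivore", group="carnivores") for s in carn_ids
    ]

    # metaweb first: prey sets decide where carnivore ranges may sit
    edges: set[tuple[str, str]] = set()
    for i, c in enumerate(carn_ids):
        if config.specialist_gradient:
            k = min(i + 1, config.n_herbivores)
        else:
            k = int(
                rng.integers(
                    min(config.out_degree_min, config.n_herbivores),
                    min(config.out_degree_max, config.n_herbivores) + 1,
                )
            )
        prey = rng.choice(config.n_herbivores, size=k, replace=False)
        edges.update((c, herb_ids[j]) for j in prey)
        for j in range(i):  # acyclic carnivore->carnivore layer
            if rng.random() < config.cc_edge_prob:
                edges.add((c, carn_ids[j]))
    web = Metaweb(species=species, edges=edges)

    layers: dict[str, np.ndarray] = {}
    for h in herb_ids:
        layers[h] = _disk_cells(
            spec, rng, config.radius_mean, config.radius_sd, config.disks_per_species
        )
    true_mismatch: dict[str, float] = {}
    for i, c in enumerate(carn_ids):
        prey_union = np.zeros(spec.shape, dtype=bool)
        for p in sorted(web.prey_of(c)):
            prey_union |= layers[p]
        mismatch = config.mismatch_for(i)
        if mismatch is None:
            grid = _disk_cells(
                spec, rng, config.radius_mean, config.radius_sd,
                config.disks_per_species,
            )
            layers[c] = grid
            n = int(grid.sum())
            true_mismatch[c] = float((grid & ~prey_union).sum() / n) if n else 0.0
        else:
            target = int(
                _disk_cells(spec, rng, config.radius_mean, config.radius_sd, 1).sum()
            )
            layers[c], realized = _planted_carnivore_range(
                spec, rng, prey_union, max(target, 1), mismatch
            )
            true_mismatch[c] = realized

    stack = LayerStack(
        spec, [PresenceLayer(s, layers[s], spec) for s in herb_ids + carn_ids]
    )
    return stack, web, GroundTruth(true_mismatch, web, stack)


def generate_occurrences(
    stack: LayerStack, config: ScenarioConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample labelled occurrence records from the true ranges.

    For each species, every true-range cell yields one record with the
    detection probability (or ``points_per_species`` uniform draws over
    range cells, when set); false positives land uniformly on out-of-range
    cells at ``false_positive_rate`` per range cell.  A
    ``null_island_fraction`` of all records is teleported into the +-2
    degree box around (0, 0); years are uniform on
    ``[year_min, year_max]``.

    Returns ``(records, labels)``: records has the canonical occurrence
    columns; labels adds ``in_range`` and ``teleported`` flags, row-aligned.
    """
    spec = stack.spec
    rng = np.random.default_rng([config.seed, 7919])
    rows_out = []
    for ly in stack.layers:
        cells = np.flatnonzero(ly.grid.ravel())
        others = np.flatnonzero(~ly.grid.ravel())
        if config.points_per_species is not None:
            chosen = rng.choice(cells, size=config.points_per_species, replace=True) \
                if len(cells) else np.array([], dtype=int)
        else:
            chosen = cells[rng.random(len(cells)) < config.detection_prob]
        n_fp = rng.binomial(len(cells), config.false_positive_rate) if len(others) else 0
        fp = rng.choice(others, size=min(n_fp, len(others)), replace=False) \
            if n_fp else np.array([], dtype=int)
        for flat, in_range in [(chosen, True), (fp, False)]:
            for cell in flat:
                r, c = divmod(int(cell), spec.n_cols)
                lon = spec.lon_min + (c + rng.random()) * spec.resolution
                lat = spec.lat_max - (r + rng.random()) * spec.resolution
                teleported = rng.random() < config.null_island_fraction
                if teleported:
                    lon = rng.uniform(-2.0, 2.0)
                    lat = rng.uniform(-2.0, 2.0)
                rows_out.append(
                    {
                        "species": ly.species_id,
                        "lon": lon,
                        "lat": lat,
                        "year": int(rng.integers(config.year_min, config.year_max + 1)),
                        "in_range": in_range,
                        "teleported": teleported,
                    }
                )
    labels = pd.DataFrame(
        rows_out, columns=["species", "lon", "lat", "year", "in_range", "teleported"]
    )
    records = labels[["species", "lon", "lat", "year"]].copy()
    return records, labels


# ---------------------------------------------------------------------------
# Serengeti mammal-web fixture (degree-faithful synthetic topology)
# ---------------------------------------------------------------------------

#: (species, group, role, out_degree, in_degree) for the 32 published mammals.
SERENGETI_SPECIES: list[tuple[str, str, str, int, int]] = [
    ("Acinonyx jubatus", "Large carnivores", "carnivore", 8, 1),
    ("Crocuta crocuta", "Large carnivores", "carnivore", 12, 1),
    ("Lycaon pictus", "Large carnivores", "carnivore", 14, 0),
    ("Panthera leo", "Large carnivores", "carnivore", 18, 0),
    ("Panthera pardus", "Large carnivores", "carnivore", 22, 0),
    ("Canis aureus", "Small carnivores", "carnivore", 4, 1),
    ("Canis mesomelas", "Small carnivores", "carnivore", 1, 1),
    ("Caracal caracal", "Small carnivores", "carnivore", 4, 0),
    ("Leptailurus serval", "Small carnivores", "carnivore", 1, 1),
    ("Damaliscus lunatus", "Small herbivores", "herbivore", 0, 4),
    ("Hippopotamus amphibius", "Small herbivores", "herbivore", 0, 0),
    ("Kobus ellipsiprymnus", "Small herbivores", "herbivore", 0, 4),
    ("Ourebia ourebi", "Small herbivores", "herbivore", 0, 5),
    ("Pedetes capensis", "Small herbivores", "herbivore", 0, 2),
    ("Phacochoerus africanus", "Small herbivores", "herbivore", 0, 5),
    ("Redunca redunca", "Small herbivores", "herbivore", 0, 5),
    ("Rhabdomys pumilio", "Small herbivores", "herbivore", 0, 5),
    ("Tragelaphus oryx", "Small herbivores", "herbivore", 0, 2),
    ("Tragelaphus scriptus", "Small herbivores", "herbivore", 0, 3),
    ("Aepyceros melampus", "Large grazers", "herbivore", 0, 5),
    ("Alcelaphus buselaphus", "Large grazers", "herbivore", 0, 4),
    ("Connochaetes taurinus", "Large grazers", "herbivore", 0, 6),
    ("Equus quagga", "Large grazers", "herbivore", 0, 5),
    ("Eudorcas thomsonii", "Large grazers", "herbivore", 0, 6),
    ("Nanger granti", "Large grazers", "herbivore", 0, 6),
    ("Heterohyrax brucei", "Hyraxes", "herbivore", 0, 1),
    ("Procavia capensis", "Hyraxes", "herbivore", 0, 1),
    ("Giraffa camelopardalis", "Others", "herbivore", 0, 1),
    ("Loxodonta africana", "Others", "herbivore", 0, 0),
    ("Madoqua kirkii", "Others", "herbivore", 0, 7),
    ("Papio anubis", "Others", "herbivore", 0, 1),
    ("Syncerus caffer", "Others", "herbivore", 0, 1),
]


def serengeti_fixture() -> Metaweb:
    """The 32-species Serengeti mammal web with a degree-faithful edge set.

    Roles, groups, and out/in degrees follow the published species table;
    since the published source gives only the degree sequence, edges are
    synthesized greedily (predators in descending generality; prey taken
    from the species with the largest unmet predator count, ties broken by
    table order, self-loops excluded).  The construction is deterministic
    and realizes the full degree sequence exactly: 84 edges over 23
    herbivores and 9 carnivores.
    """
    species = [
        SpeciesRecord(name, role=role, group=group, name=name)
        for name, group, role, _, _ in SERENGETI_SPECIES
    ]
    order = {name: i for i, (name, *_rest) in enumerate(SERENGETI_SPECIES)}
    out_demand = {name: o for name, _, _, o, _ in SERENGETI_SPECIES}
    in_demand = {name: i for name, _, _, _, i in SERENGETI_SPECIES}
    edges: set[tuple[str, str]] = set()
    predators = sorted(
        (n for n, d in out_demand.items() if d > 0),
        key=lambda n: (-out_demand[n], order[n]),
    )
    for pred in predators:
        candidates = sorted(
            (n for n in in_demand if in_demand[n] > 0 and n != pred),
            key=lambda n: (-in_demand[n], order[n]),
        )
        need = out_demand[pred]
        if len(candidates) < need:
            raise FeasibilityError(
                f"degree sequence infeasible at predator {pred!r}: needs {need} prey, "
                f"{len(candidates)} species still have unmet predator counts"
            )
        for prey in candidates[:need]:
            edges.add((pred, prey))
            in_demand[prey] -= 1
    return Metaweb(species=species, edges=edges)
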