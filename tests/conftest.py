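"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from metarange.gridspace import GridSpec, LayerStack, PresenceLayer
from metarange.metaweb import Metaweb, SpeciesRecord


@pytest.fixture
def default_spec() -> GridSpec:
    """The 150x150 African study grid (0.5 degrees)."""
    return GridSpec()


@pytest.fixture
def small_spec() -> GridSpec:
    """A 6x8 grid for hand-checkable fixtures."""
    return GridSpec(lon_min=0.0, lon_max=8.0, lat_min=0.0, lat_max=6.0, resolution=1.0)


@pytest.fixture
def chain_web() -> Metaweb:
    """A -> B -> C with A, B carnivores and C an herbivore."""
    return Metaweb(
        species=[
            SpeciesRecord("A", "carnivore"),
            SpeciesRecord("B", "carnivore"),
            SpeciesRecord("C", "herbivore"),
        ],
        edges={("A", "B"), ("B", "C")},
    )


def random_web(rng: np.random.Generator, n_species: int, edge_prob: float = 0.35) -> Metaweb:
    """Random two-level web: carnivores may prey on anything but themselves."""
    roles = ["herbivore" if rng.random() < 0.5 else "carnivore" for _ in range(n_species)]
    if "herbivore" not in roles:
        roles[int(rng.integers(n_species))] = "herbivore"
    ids = [f"s{i}" for i in range(n_species)]
    species = [SpeciesRecord(i, r) for i, r in zip(ids, roles)]
    edges = {
        (ids[i], ids[j])
        for i in range(n_species)
        for j in range(n_species)
        if i != j and roles[i] == "carnivore" and rng.random() < edge_prob
    }
    return Metaweb(species=species, edges=edges)


def random_stack(
    rng: np.random.Generator, web: Metaweb, spec: GridSpec, fill: float = 0.4
) -> LayerStack:
    """Independent Bernoulli presence grids for every web species."""
    return LayerStack(
        spec,
        [
            PresenceLayer(s, rng.random(spec.shape) < fill, spec)
            for s in web.species_ids
        ],
    )


def oracle_retained(present: set[str], web: Metaweb) -> set[str]:
    """Brute-force path enumeration: retained species of one local web.

    Depth-first search over predator->prey edges restricted to present
    species, succeeding on reaching any present herbivore.  Independent of
    the reachability implementation under test.
    """
    basal = {s for s in present if web.role_of(s) == "herbivore"}

    def reaches_basal(s: str, visited: frozenset[str]) -> bool:
        for prey in web.prey_of(s) & present:
            if prey in basal:
                return True
            if prey not in visited and reaches_basal(prey, visited | {prey}):
                return True
        return False

    return basal | {s for s in present - basal if reaches_basal(s, frozenset({s}))}
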