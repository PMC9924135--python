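"""Per-pixel local food webs and basal-reachability pruning.

Each occupied grid cell induces a *local network*: the metaweb subgraph on
the species co-occurring there.  A species is ecologically supported in a
cell iff it is basal (an herbivore, whose plant resources are assumed
ubiquitous) or it has a directed predator->prey path, through species
present in that same cell, ending at a present basal species.  Cells where
a predator lacks any such path are treated as data-deficient for that
predator and removed from its adjusted range.

The rule is reachability, not one-hop: a carnivore preying only on other
carnivores is retained whenever one of its present prey-carnivores is
itself connected.  Pruning is a single static sweep per cell, not an
iterated extinction cascade, and cells are processed independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyStudyAreaError, UnknownSpeciesError
from .gridspace import LayerStack, PresenceLayer
from .metaweb import Metaweb, basal_set

__all__ = [
    "LocalWebSummary",
    "PrunedStack",
    "retained_species",
    "prune_stack",
    "network_summaries",
    "per_cell_table",
]


@dataclass
class LocalWebSummary:
    """Present/retained accounting for one occupied cell."""

    cell: tuple[int, int]
    present: set[str]
    retained: set[str]
    carnivores_present: int = 0
    carnivores_retained: int = 0

    def __post_init__(self) -> None:
        if not self.retained <= self.present:
            raise ValueError(f"cell {self.cell}: retained set is not a subset of present")

    @property
    def proportion_remaining(self) -> float:
        return len(self.retained) / len(self.present)


@dataclass
class PrunedStack:
    """Original and trophically adjusted stacks plus per-cell summaries."""

    original: LayerStack
    adjusted: LayerStack
    per_cell: list[LocalWebSummary]


def retained_species(present: set[str], web: Metaweb) -> set[str]:
    """Species of ``present`` with a trophic path to a present basal species.

    A species is retained iff it is a present herbivore, or some directed
    predator->prey path through present species reaches a present herbivore.
    Computed as graph reachability on the induced subgraph.
    """
    unknown = present - set(web.species_ids)
    if unknown:
        raise UnknownSpeciesError(f"species not in metaweb: {sorted(unknown)}")
    basal_present = basal_set(web) & present
    if not basal_present:
        return set()
    sub = web.to_digraph().subgraph(present)
    retained = set(basal_present)
    for s in present - basal_present:
        if basal_present & nx.descendants(sub, s):
            retained.add(s)
    return retained


def prune_stack(stack: LayerStack, web: Metaweb) -> PrunedStack:
    """Apply :func:`retained_species` to every occupied cell of the stack.

    Implemented as a vectorized boolean fixpoint over layers, which is
    equivalent to per-cell reachability: herbivore support maps start as the
    herbivore presence grids, then each carnivore's support map is the
    intersection of its presence with the union of its prey's support maps,
    iterated to stability (at most one sweep per trophic chain link).
    """
    missing = set(stack.species_ids) - set(web.species_ids)
    if missing:
        raise ConfigurationError(
            f"stack species absent from the metaweb: {sorted(missing)}"
        )
    ids = stack.species_ids
    idx = {s: i for i, s in enumerate(ids)}
    present = stack.as_array()
    basal = basal_set(web)

    supported = np.zeros_like(present)
    for s in ids:
        if s in basal:
            supported[idx[s]] = present[idx[s]]
    prey_in_stack = {s: [idx[q] for q in web.prey_of(s) if q in idx] for s in ids}
    carnivores = [s for s in ids if s not in basal]
    changed = True
    while changed:
        changed = False
        for s in carnivores:
            if not prey_in_stack[s]:
                continue  # no prey in the stack: never supported
            new = present[idx[s]] & supported[prey_in_stack[s]].any(axis=0)
            if not np.array_equal(new, supported[idx[s]]):
                supported[idx[s]] = new
                changed = True

    adjusted = LayerStack(
        stack.spec,
        [PresenceLayer(s, supported[idx[s]], stack.spec) for s in ids],
    )

    role = {s: web.role_of(s) for s in ids}
    per_cell = []
    rows, cols = np.nonzero(present.any(axis=0))
    for r, c in zip(rows.tolist(), cols.tolist()):
        pres = {s for s in ids if present[idx[s], r, c]}
        kept = {s for s in ids if supported[idx[s], r, c]}
        per_cell.append(
            LocalWebSummary(
                cell=(r, c),
                present=pres,
                retained=kept,
                carnivores_present=sum(role[s] == "carnivore" for s in pres),
                carnivores_retained=sum(role[s] == "carnivore" for s in kept),
            )
        )
    return PrunedStack(original=stack, adjusted=adjusted, per_cell=per_cell)


def network_summaries(pruned: PrunedStack) -> dict[str, float]:
    """Headline statistics over occupied cells (the "local networks").

    Keys:

    - ``n_networks`` — occupied cells;
    - ``frac_with_path`` — share of networks with >= 1 retained species;
    - ``mean_disconnected`` / ``median_disconnected`` — per-network fraction
      of species lacking a path to a basal species (1 - proportion
      remaining);
    - ``frac_fully_disconnected`` — networks where nothing is retained;
    - ``min_richness`` / ``max_richness`` / ``mean_richness`` — species
      counts per network.
    """
    cells = pruned.per_cell
    if not cells:
        raise EmptyStudyAreaError("no cell contains any species")
    disconnected = np.array([1.0 - s.proportion_remaining for s in cells])
    richness = np.array([len(s.present) for s in cells])
    any_retained = np.array([len(s.retained) > 0 for s in cells])
    return {
        "n_networks": len(cells),
        "frac_with_path": float(any_retained.mean()),
        "mean_disconnected": float(disconnected.mean()),
        "median_disconnected": float(np.median(disconnected)),
        "frac_fully_disconnected": float((~any_retained).mean()),
        "min_richness": int(richness.min()),
        "max_richness": int(richness.max()),
        "mean_richness": float(richness.mean()),
    }


def per_cell_table(pruned: PrunedStack) -> pd.DataFrame:
    """Per-cell summary as a DataFrame (one row per occupied cell)."""
    spec = pruned.original.spec
    rows = []
    for s in pruned.per_cell:
        lon, lat = spec.cell_center(*s.cell)
        rows.append(
            {
                "row": s.cell[0],
                "col": s.cell[1],
                "lon_center": lon,
                "lat_center": lat,
                "n_present": len(s.present),
                "n_retained": len(s.retained),
                "proportion_remaining": s.proportion_remaining,
            }
        )
    return pd.DataFrame(rows)
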