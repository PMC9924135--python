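"""Directed predator->prey metaweb with species roles.

The metaweb pools every potential feeding link among the regional species.
Edges point from predator to prey.  Plants are implicit: herbivores are
treated as *basal* because their plant resources are assumed ubiquitous, so
a trophic path is complete as soon as it reaches a present herbivore.

Species names are matched by a normalized form (trimmed, case-insensitive,
underscores treated as spaces); no taxonomic-backbone resolution is done.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .errors import UndefinedStatisticError, UnknownSpeciesError

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesRecord",
    "Metaweb",
    "normalize_name",
    "remove_self_loops",
    "connectance",
    "degrees",
    "basal_set",
    "read_metaweb",
    "write_metaweb",
]

ROLES = ("carnivore", "herbivore")


def normalize_name(name: str) -> str:
    """Canonical species key: trimmed, lower-case, underscores = spaces."""
    return " ".join(name.strip().replace("_", " ").lower().split())


@dataclass(frozen=True)
class SpeciesRecord:
    """One species of the pool with its trophic role and optional group label."""

    species_id: str
    role: str
    group: str | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(
                f"species {self.species_id!r}: role must be one of {ROLES}, "
                f"got {self.role!r}"
            )


@dataclass
class Metaweb:
    """Directed predator->prey graph over a species pool.

    ``edges`` are ordered ``(predator_id, prey_id)`` pairs; every endpoint
    must be a registered species.  Herbivores are expected to have zero
    out-degree within the mammal web (their plant prey are implicit); a
    violation is logged as a warning, not an error.
    """

    species: list[SpeciesRecord]
    edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = [sp.species_id for sp in self.species]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate species ids in metaweb")
        known = set(ids)
        for pred, prey in self.edges:
            if pred not in known or prey not in known:
                raise UnknownSpeciesError(
                    f"edge ({pred!r}, {prey!r}) references an unregistered species"
                )
        for sp in self.species:
            if sp.role == "herbivore" and any(p == sp.species_id for p, _ in self.edges):
                logger.warning(
                    "herbivore %r has outgoing (prey) edges within the mammal web",
                    sp.species_id,
                )

    @property
    def S(self) -> int:
        return len(self.species)

    @property
    def L(self) -> int:
        return len(self.edges)

    @property
    def species_ids(self) -> list[str]:
        return [sp.species_id for sp in self.species]

    def role_of(self, species_id: str) -> str:
        for sp in self.species:
            if sp.species_id == species_id:
                return sp.role
        raise UnknownSpeciesError(f"unknown species {species_id!r}")

    def prey_of(self, predator_id: str) -> set[str]:
        if predator_id not in set(self.species_ids):
            raise UnknownSpeciesError(f"unknown species {predator_id!r}")
        return {q for p, q in self.edges if p == predator_id}

    def predators_of(self, prey_id: str) -> set[str]:
        if prey_id not in set(self.species_ids):
            raise UnknownSpeciesError(f"unknown species {prey_id!r}")
        return {p for p, q in self.edges if q == prey_id}

    def to_digraph(self) -> nx.DiGraph:
        """networkx view with predator->prey edge direction and role attributes."""
        g = nx.DiGraph()
        for sp in self.species:
            g.add_node(sp.species_id, role=sp.role, group=sp.group)
        g.add_edges_from(self.edges)
        return g


def remove_self_loops(web: Metaweb) -> Metaweb:
    """Drop (x, x) edges (cannibalistic links), preserving everything else.

    Self-loops are informative but would make a cannibal its own trophic
    anchor, so they are removed before any pruning.
    """
    loops = {(p, q) for p, q in web.edges if p == q}
    if loops:
        logger.info("removed %d self-loop(s): %s", len(loops), sorted(p for p, _ in loops))
    return Metaweb(species=list(web.species), edges=set(web.edges) - loops)


def connectance(web: Metaweb, exclude_self_loops: bool = False) -> float:
    """Directed connectance L / S**2.

    With ``exclude_self_loops=True`` the alternative L / (S * (S - 1)) is
    returned instead.
    """
    if web.S == 0:
        raise UndefinedStatisticError("connectance is undefined for an empty web")
    if exclude_self_loops:
        if web.S == 1:
            raise UndefinedStatisticError(
                "loop-free connectance is undefined for a single-species web"
            )
        return web.L / (web.S * (web.S - 1))
    return web.L / web.S**2


def degrees(web: Metaweb) -> pd.DataFrame:
    """Out-degree (generality, number of prey) and in-degree (vulnerability).

    Returns one row per species in pool order, columns
    ``species_id, out_degree, in_degree``.
    """
    out = {sp.species_id: 0 for sp in web.species}
    inn = {sp.species_id: 0 for sp in web.species}
    for pred, prey in web.edges:
        out[pred] += 1
        inn[prey] += 1
    return pd.DataFrame(
        {
            "species_id": list(out),
            "out_degree": list(out.values()),
            "in_degree": [inn[s] for s in out],
        }
    )


def basal_set(web: Metaweb) -> set[str]:
    """Species treated as directly connected to primary producers.

    Basal status follows the *role* attribute (herbivore), not out-degree,
    so isolated herbivores are retained everywhere while a hypothetical
    prey-less carnivore is prunable.
    """
    return {sp.species_id for sp in web.species if sp.role == "herbivore"}


# ---------------------------------------------------------------------------
# CSV interfaces: edge list `predator,prey`; role table `species,role[,group]`.
# ---------------------------------------------------------------------------

def read_metaweb(edges_path: str, roles_path: str) -> Metaweb:
    """Load a metaweb from an edge-list CSV and a species-role CSV.

    Species names in both files are matched through :func:`normalize_name`;
    the role table defines the canonical spelling.
    """
    roles = pd.read_csv(roles_path)
    required = {"species", "role"}
    if not required <= set(roles.columns):
        raise ValueError(f"{roles_path}: needs columns {sorted(required)}")
    species = []
    canon: dict[str, str] = {}
    for _, row in roles.iterrows():
        sid = str(row["species"]).strip()
        canon[normalize_name(sid)] = sid
        group = row.get("group")
        species.append(
            SpeciesRecord(
                species_id=sid,
                role=str(row["role"]).strip().lower(),
                group=None if pd.isna(group) else str(group),
            )
        )
    edges_df = pd.read_csv(edges_path)
    if not {"predator", "prey"} <= set(edges_df.columns):
        raise ValueError(f"{edges_path}: needs columns ['predator', 'prey']")
    edges = set()
    for _, row in edges_df.iterrows():
        pred = canon.get(normalize_name(str(row["predator"])))
        prey = canon.get(normalize_name(str(row["prey"])))
        if pred is None or prey is None:
            raise UnknownSpeciesError(
                f"edge ({row['predator']!r}, {row['prey']!r}) references a species "
                f"absent from {roles_path}"
            )
        edges.add((pred, prey))
    return Metaweb(species=species, edges=edges)


def write_metaweb(web: Metaweb, edges_path: str, roles_path: str) -> None:
    pd.DataFrame(sorted(web.edges), columns=["predator", "prey"]).to_csv(
        edges_path, index=False
    )
    pd.DataFrame(
        {
            "species": [sp.species_id for sp in web.species],
            "role": [sp.role for sp in web.species],
            "group": [sp.group for sp in web.species],
        }
    ).to_csv(roles_path, index=False)
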