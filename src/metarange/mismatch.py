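"""Range-mismatch statistics: overlap index, relative range loss, generality.

Geographic overlap between two species is measured as ``a / (a + c)``,
where ``a`` counts cells where both are present and ``c`` counts cells
where only the *focal* species is present.  The index runs from 0 (no
co-occurrence) to 1 (focal range fully inside the other's range), and the
direction matters: predator-focal and prey-focal similarities are the two
axes of the pairwise-overlap scatter.

Relative range loss for a predator is ``(original - adjusted) / original``
range size in cells, joined with its generality (out-degree).  All
statistics are pixel-based: the rasterized range is the denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .errors import GridMismatchError, UndefinedStatisticError, UnknownSpeciesError
from .gridspace import LayerStack, PresenceLayer
from .localwebs import PrunedStack
from .metaweb import Metaweb, basal_set, degrees

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapStats",
    "RangeLossRecord",
    "overlap",
    "prey_union_coverage",
    "predator_union_coverage",
    "range_loss_table",
    "overlap_scatter",
    "species_table",
]


@dataclass(frozen=True)
class OverlapStats:
    """Directed geographic overlap of a focal species with another."""

    focal_id: str
    other_id: str
    a: int  # cells where both are present
    c: int  # cells where only the focal is present

    @property
    def similarity(self) -> float:
        return self.a / (self.a + self.c)


@dataclass(frozen=True)
class RangeLossRecord:
    """Original vs. trophically adjusted range size for one predator."""

    species_id: str
    original_size: int
    adjusted_size: int
    out_degree: int

    @property
    def relative_loss(self) -> float:
        if self.original_size == 0:
            raise UndefinedStatisticError(
                f"{self.species_id!r}: relative loss undefined for an empty range"
            )
        return (self.original_size - self.adjusted_size) / self.original_size


def overlap(focal: PresenceLayer, other: PresenceLayer) -> OverlapStats:
    """a/(a+c) overlap with ``focal`` as the focal species."""
    if focal.spec != other.spec:
        raise GridMismatchError("overlap requires layers on the same GridSpec")
    if focal.range_size == 0:
        raise UndefinedStatisticError(
            f"{focal.species_id!r}: similarity undefined for an empty focal range"
        )
    a = int((focal.grid & other.grid).sum())
    c = int((focal.grid & ~other.grid).sum())
    return OverlapStats(focal.species_id, other.species_id, a, c)


def prey_union_coverage(predator_id: str, stack: LayerStack, web: Metaweb) -> float:
    """Fraction of the predator's range cells holding at least one of its prey."""
    return _union_coverage(predator_id, web.prey_of(predator_id), stack)


def predator_union_coverage(prey_id: str, stack: LayerStack, web: Metaweb) -> float:
    """Fraction of the prey's range cells holding at least one of its predators."""
    return _union_coverage(prey_id, web.predators_of(prey_id), stack)


def _union_coverage(focal_id: str, partners: set[str], stack: LayerStack) -> float:
    if focal_id not in stack:
        raise UnknownSpeciesError(f"{focal_id!r} has no layer in the stack")
    focal = stack[focal_id]
    if focal.range_size == 0:
        raise UndefinedStatisticError(
            f"{focal_id!r}: coverage undefined for an empty range"
        )
    union = None
    for pid in sorted(partners):
        if pid not in stack:
            continue
        g = stack[pid].grid
        union = g.copy() if union is None else (union | g)
    if union is None:
        return 0.0
    return int((focal.grid & union).sum()) / focal.range_size


def range_loss_table(pruned: PrunedStack, web: Metaweb) -> pd.DataFrame:
    """One row per carnivore: original/adjusted sizes, relative loss, generality.

    Sorted by out-degree then species id.  Carnivores with an empty original
    range get ``relative_loss`` NaN.
    """
    deg = degrees(web).set_index("species_id")["out_degree"]
    basal = basal_set(web)
    rows = []
    for ly in pruned.original.layers:
        if ly.species_id in basal:
            continue
        adj = pruned.adjusted[ly.species_id]
        orig = ly.range_size
        rows.append(
            {
                "species_id": ly.species_id,
                "original_size": orig,
                "adjusted_size": adj.range_size,
                "relative_loss": (orig - adj.range_size) / orig if orig else float("nan"),
                "out_degree": int(deg[ly.species_id]),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["out_degree", "species_id"])
        .reset_index(drop=True)
    )


def overlap_scatter(
    stack: LayerStack, web: Metaweb, drop_zero: bool = False
) -> pd.DataFrame:
    """Pairwise overlap table: one row per metaweb edge with nonempty layers.

    Columns: predator, prey, ``predator_focal_similarity`` (x-axis of the
    pairwise scatter) and ``prey_focal_similarity`` (y-axis).  Edges whose
    predator or prey layer is empty are dropped with a log note; with
    ``drop_zero=True`` pairs that never co-occur are dropped too.
    """
    rows = []
    for pred, prey in sorted(web.edges):
        if pred not in stack or prey not in stack:
            continue
        if stack[pred].range_size == 0 or stack[prey].range_size == 0:
            logger.info(
                "overlap_scatter: dropping edge (%s, %s) with an empty range", pred, prey
            )
            continue
        pf = overlap(stack[pred], stack[prey]).similarity
        qf = overlap(stack[prey], stack[pred]).similarity
        if drop_zero and pf == 0.0 and qf == 0.0:
            continue
        rows.append(
            {
                "predator": pred,
                "prey": prey,
                "predator_focal_similarity": pf,
                "prey_focal_similarity": qf,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "predator",
            "prey",
            "predator_focal_similarity",
            "prey_focal_similarity",
        ],
    )


def species_table(stack: LayerStack, web: Metaweb) -> pd.DataFrame:
    """Species descriptor table: degrees, range size, prey/predator coverage.

    One row per metaweb species (in pool order): out/in degree, rasterized
    range size in cells, proportion of range occupied by prey (consumers
    only) and by predators (species with predators only); proportions are
    NaN where undefined, mirroring the dashes of a printed species table.
    """
    deg = degrees(web)
    rows = []
    for _, d in deg.iterrows():
        sid = d["species_id"]
        size = stack[sid].range_size if sid in stack else 0
        prey_cov = pred_cov = float("nan")
        if size > 0 and d["out_degree"] > 0:
            prey_cov = prey_union_coverage(sid, stack, web)
        if size > 0 and d["in_degree"] > 0:
            pred_cov = predator_union_coverage(sid, stack, web)
        rows.append(
            {
                "species_id": sid,
                "out_degree": int(d["out_degree"]),
                "in_degree": int(d["in_degree"]),
                "range_size": size,
                "prop_range_with_prey": prey_cov,
                "prop_range_with_predators": pred_cov,
            }
        )
    return pd.DataFrame(rows)
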