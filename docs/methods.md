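# Methods

## The model

A regional species pool is described by two data sources: per-species
geographic ranges and a directed metaweb of potential predator→prey
links. Stacking the rasterized ranges yields, for every grid cell, the
set of species whose ranges cover it; the induced metaweb subgraph on
that set is the cell's *local network*.

The consistency rule is: **a species is ecologically supported in a cell
iff it has a directed trophic path, within that cell's community, to a
basal species.** Herbivores are treated as basal — their plant resources
are assumed present across their ranges, because savannah plants are
functionally redundant, herbivores are broad plant generalists, and
global plant range maps are largely unavailable. A carnivore is
supported iff some predator→prey path through co-occurring, themselves
supported species reaches a present herbivore (full reachability, not one
hop: a carnivore preying only on carnivores is kept when a present
prey-carnivore is itself connected). Cells where a species is present
but unsupported are removed from its *adjusted* range; the per-species
difference is the range mismatch attributed to missing distribution or
interaction data.

Assumptions and consequences:

- pruning is a single static reachability sweep per cell, not a dynamic
  extinction cascade; cells are independent (no neighborhood rescue);
- herbivores are immune: their adjusted ranges equal their originals;
- adjusted ⊆ original everywhere, so occurrence agreement with the
  adjusted range can only be equal or lower than with the original —
  both facts are asserted at run time;
- self-loops (cannibalism) are removed before pruning, otherwise a
  cannibal would anchor itself;
- basal status follows the herbivore *role*, not out-degree zero, so
  isolated herbivores are retained while a prey-less carnivore is
  prunable.

Implementation: per-cell retention is exposed as graph reachability
(`retained_species`, networkx descendants on the induced subgraph); the
stack-level sweep (`prune_stack`) uses an equivalent vectorized boolean
fixpoint over layers (herbivore support = presence; carnivore support =
presence ∧ union of prey support; iterate to stability). Tests check
both routes against a brute-force path-enumeration oracle on all present
subsets of random webs with ≤ 8 species.

## Grid and rasterization

One `GridSpec` (WGS84 lon/lat, default 35°S–40°N × 20°W–55°E at 0.5°,
150×150 cells) is shared by every layer. Row 0 is the northern edge,
column 0 the western edge; cells are half-open `[west, east) ×
(south, north]`, so each in-extent point maps to exactly one cell. A cell
is present when the species polygon covers its *center* (deterministic and
resolution-consistent; an any-intersection `touch` option exists because
published analyses rarely state their inclusion rule). No reprojection is
done — all statistics are cell counts on the geographic grid — and
antimeridian-crossing inputs are rejected rather than guessed at.
Polygons are read from GeoJSON; rasters are exchanged as ESRI ASCII
grids, a plain-text format any GIS reads.

## Statistics

- **Overlap** `a/(a+c)`: `a` = cells shared by the pair, `c` = cells
  where only the focal species occurs; directional (predator-focal vs.
  prey-focal). Undefined for an empty focal range; pairs with an empty
  layer are dropped from the pairwise table with a log note.
- **Prey-union coverage**: fraction of a predator's range cells holding
  ≥ 1 of its prey (the union, not a mean of pairwise overlaps — the union
  reading is the one consistent with a predator that loses its whole
  range when no prey overlaps it, and with full coverage for herbivores
  blanketed by predators).
- **Relative range loss** `(original − adjusted)/original`, in cells,
  per carnivore, joined with out-degree (generality). For a predator
  with only herbivore prey this equals `1 − prey-union coverage` exactly.
- **Local-network summaries** over occupied cells: share of networks with
  ≥ 1 supported species, mean/median per-network disconnected fraction,
  share fully disconnected, richness range. Empty cells are excluded
  from every denominator ("networks" = occupied cells). Note the two
  shares ("≥ 1 species with a path" and "only disconnected mammals") are
  exact complements over occupied cells here; published figures computed
  on external data do not always complement, suggesting differing
  denominators that cannot be reconstructed — this package reports both
  over one explicit denominator instead.
- **Validation**: occurrence records are filtered (coordinates present;
  inside the extent; outside the closed ±2° null-island box; year ≥ 2001
  — "after 2000" is read strictly, and both the box and `min_year` are
  configurable since the published choices are ambiguous), then binned to
  presence pixels to cancel repeated sampling. For each species,
  `prop_in_X = |occurrence pixels ∩ X| / |occurrence pixels|` for the
  original and adjusted ranges; proportions are counted over the whole
  raster extent.
- **Prey-mobility buffer**: for one predator's removed area, the share of
  prey occurrence points whose cell lies inside it, and the share of
  removed cells within a great-circle radius (haversine, R = 6371 km, to
  cell centers) of ≥ 1 prey point. The radius default is 50 km; no
  published value exists for it, so it is always echoed in the output
  metadata, and published buffer percentages tied to external occurrence
  extracts are not desk-reproducible targets.

## Synthetic study conditions

The generator emulates the pipeline's real inputs with known ground
truth; identical config + seed gives bit-identical outputs.

- **Landscape**: default 60×60 window (10–40°E × 25°S–5°N at 0.5°),
  deliberately clear of the null-island box so only planted errors fall
  there. Ranges are unions of rasterized disks (default one disk, radius
  ~ N(8, 2²) cells, uniform random center). Disks were chosen over,
  e.g., thresholded Gaussian fields because overlap bookkeeping stays
  analytic and shape realism is irrelevant to the pipeline's arithmetic.
- **Community**: 14 herbivores + 6 carnivores by default (20 species);
  carnivore out-degree uniform on [1, 8] with prey drawn uniformly;
  optional carnivore→carnivore edges (off by default, so
  loss = 1 − prey-union coverage holds exactly; when enabled they point
  from higher to lower carnivore index, keeping chains acyclic and
  well-ordered for construction). The `specialist_gradient` flag instead
  gives carnivore *i* exactly *i + 1* prey at fixed equal range sizes, to
  probe the generality-vs-loss relation.
- **Planted mismatch**: each carnivore's range is assembled from
  `round(m·n)` cells outside and `n − round(m·n)` cells inside its prey
  union (nearest-first from a random anchor, so ranges stay compact),
  default m = 0.3 — mid-scale between published extremes of ~0 (the most
  generalist large predators) and 1 (complete range loss). The realized
  fraction is recorded as ground truth; the target size is capped by the
  available in-/out-of-union cells so the fraction stays exact. With
  `planted_mismatch: null` ranges are plain disks and the mismatch is
  whatever emerges.
- **Occurrences**: one Bernoulli(detection = 0.3) record per true-range
  cell, uniform within the cell; false positives at rate 0.05 per range
  cell on out-of-range cells; 2 % of records teleported into the
  null-island box; years uniform on 1995–2020, straddling the temporal
  filter. Labels record every planted violation.

What the generator does *not* emulate: environmental niches, spatial
sampling bias along roads/borders, taxonomic name drift, polygon
digitization artifacts, temporal range shifts. Passing tests therefore
demonstrate the pipeline's arithmetic and invariants, not robustness to
those real-data pathologies.

## Serengeti fixture

The 32 published mammals (23 herbivores, 9 carnivores) with their groups
and out/in degrees are bundled; only the degree sequence of the
84-interaction web is published, so the fixture synthesizes a
**degree-faithful, topology-agnostic** edge set: predators in descending
generality each take prey from the species with the largest unmet
predator count (ties by table order, self-loops excluded). The greedy
construction is deterministic, succeeds on the published sequence, and
reproduces every out/in degree exactly — but edge identities are
synthetic, and analyses that depend on the true topology should not use
it.

## Problem sizes and numerical choices

The acceptance script runs the Serengeti descriptors (instant), one
end-to-end synthetic study on the full 150×150 grid with 32 species,
20-seed planted-mismatch recovery on the 60×60 default, and the 20-seed
specialist-gradient correlation — a few seconds in total on one CPU;
these sizes exercise every stage at full default scale while keeping the
whole run trivially repeatable. Statistics are exact cell counts and
ratios (no floating-point accumulation beyond means/medians);
reachability fixpoints terminate in at most one sweep per chain link;
ties in the greedy fixture and nearest-first cell choice are broken by
fixed orderings so every output is stable across runs.

## Known limitations

- The published continental-scale percentages depend on proprietary
  range polygons and a dated occurrence extract and cannot be recomputed
  here; the synthetic analogues share the machinery, not the data.
- Name matching is normalized-string equality; no taxonomic backbone.
- No interaction weights, no fractional (area-weighted) presence, no
  extinction dynamics, no plant nodes.
- Validation proportions treat every occurrence pixel equally; spatial
  sampling bias in real occurrence data is not corrected, only
  deduplicated per pixel.
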