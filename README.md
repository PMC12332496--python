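# geoschemes

A reference library and CLI for a hierarchical marine geographic scheme:
named, coded polygonal *geounits* for recording species distributions at
sea, built to parallel the terrestrial WGSRPD standard used in botany.

Marine biodiversity databases (WoRMS-style registers, the older faunistic
literature) hold two kinds of distribution statements: georeferenced points
and imprecise text such as "recorded from Costa Rica". Both need a shared,
strictly hierarchical set of recording units to be stored, compared and
rolled up into checklists. This package implements that scheme's machinery:

- **`geoschemes.codes`** — the code grammar and label syntax. Marine codes
  are alphanumeric and disjoint from the terrestrial ones by shape: a
  single ocean letter (`R`, `A`, `I`, `P`, `S`) at level 1, letter+digit
  (`A1`) at level 2, two letters+digit (`CR1`, coastal) or
  letter+digit+letter (`A9B`, high seas) at level 3, and `XXX-YY` at level
  4, with `XXX-OO` marking a level-4 unit coincident with its level-3
  parent. Labels follow fixed templates ("France – Bay of Biscay",
  "Martinique EEZ", "AB4 – Angola Basin").
- **`geoschemes.registry`** — loading (CSV/JSON/spreadsheet with a
  column-mapping config), indexing, validation (strict 4-level nesting,
  the `-OO` convention, the reserved high-seas country code `QP`,
  one country per basic recording unit, terrestrial-code collisions),
  censuses and subtree queries.
- **`geoschemes.geometry`** — polygon services: ellipsoidal (WGS84) area
  and arc-length measurement, nesting validation, polygon splitting along
  divider polylines, partition at a depth threshold, overlap-claim
  trifurcation, point location with a deterministic boundary tie-break,
  antimeridian normalization, GeoJSON I/O.
- **`geoschemes.builder`** — the unit-construction cascade: keep an EEZ
  whole if it is not too large and lies in a single sea area; otherwise
  split by the sea-area layer; otherwise adopt a regional scheme
  (MSFD/IMCRA-style); otherwise split along ecoregion boundaries.
  Discontinuous EEZs are split into their parts, overlapping claims become
  a separate geounit, and each ocean's high seas are built from province
  templates split at the 3500 m depth contour (abyssal `AB` / bathyal `BY`
  sectors).
- **`geoschemes.occurrences`** — the end use: assign Darwin Core-style
  occurrence records to geounits (points to a single basic recording unit
  and its ancestor chain; country-only records to all of that country's
  units, flagged imprecise) and roll checklists up to any level.
- **`geoschemes.synthworld`** — a deterministic toy planet (rectilinear
  coastlines, analytic areas) whose fictional states exercise every
  structural case: a two-ocean country, a discontinuous EEZ, an
  overlapping claim, an antimeridian unit, oversized EEZs with ecoregion
  or regional-scheme subdivisions, and the two classic topologies (a small
  EEZ straddling two sea areas; a country whose sea-area split is
  unwanted). It emits source layers plus a ground-truth manifest.

## Worked example

```python
from geoschemes import (WorldSpec, generate_world, world_build_config,
                        build_world, level_counts, validate_registry)

spec = WorldSpec(seed=42)                      # the synthetic toy planet
layers, manifest = generate_world(spec)
result = build_world(layers, world_build_config(spec))
reg = result.registry

census = level_counts(reg)
print(census.by_level)                         # {1: 2, 2: 5, 3: 15, 4: 21}
print(census.coincident_pairs)                 # 10
print(validate_registry(reg).passed)           # True
print(reg["A9B-AB"].label)                     # BY1 – Central Atlantis Ridge
```

The toy planet builds into 2 oceans, 5 ocean subdivisions (two coastal
belts per populated sea plus one high-seas unit per ocean), 15 level-3
groupings and 21 basic recording units; 10 level-3 units are coincident
with their single level-4 child (`-OO` codes) and the other 5 group the
remaining 11 units. Assigning 300 seeded occurrence records (70% points,
30% country-level text) and rolling up to level 2:

```python
from geoschemes.synthworld import generate_occurrences
from geoschemes.occurrences import (read_occurrences, assign_all,
                                    build_checklist, checklist_report_csv)
import io

occ, truth = generate_occurrences(manifest, 300, point_fraction=0.7, seed=42)
records, _ = read_occurrences(io.StringIO(occ.to_csv(index=False)))
lookup = {v: k for k, v in manifest.country_names.items()}
assignments = assign_all(records, reg, lookup)
cl = build_checklist(assignments, reg, 2)
print(checklist_report_csv(cl, "P1")[:120])
# taxon,status,n_sources
# Abyssina australis,confirmed,4
# Abyssina borealis,imprecise,1
# Abyssina communis,imprecise,3
```

`confirmed` marks point-based presences; `imprecise` marks taxa known for
the unit only through country-level records. Presence is always
existential: a listed taxon occurs *somewhere* in the unit.

The same steps are available from the shell:

```sh
geoschemes synthworld --seed 42 --out world/
geoschemes build --layers world/ --out built/
geoschemes validate --registry built/registry.csv
geoschemes stats --registry built/registry.csv
geoschemes code parse A9B-AB
geoschemes assign --registry built/registry.csv --geometry built/level4.geojson \
    --occurrences world/occurrences.csv --out assignments.csv
```

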