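# Methods

## The scheme

The package implements a four-level hierarchical set of marine recording
units modelled on the terrestrial WGSRPD standard. Level 1 units are the
oceans; level 2 units subdivide each ocean into coastal regions plus one
high-seas unit; level 3 units either coincide with a single level-4 unit or
group several of them; level 4 units — "basic recording units" — are the
finest polygons in which occurrences are recorded. Hierarchy is strict:
the boundary of any unit coincides with the union of its children's
boundaries, with no overlaps or gaps, so that any roll-up (a checklist at
level 2, say) is an exact set union over the level-4 data. Presence in a
unit is existential: a record "in unit X" means *somewhere* in X, never
everywhere in X.

Coastal level-4 units derive from national jurisdictional waters
(understood broadly as the 200 NM EEZ; extended continental-shelf claims
are excluded). High-seas units derive from deep-sea biogeographic
provinces partitioned at the 3500 m depth contour: basins deeper than
3500 m ("AB" sectors) and seafloor elevations shallower than it ("BY"
sectors). Overlapping claims between two states become a separate unit so
that areas tile without double counting; high-seas units carry the
reserved ISO 3166 alpha-2 code `QP`, overlap units the reserved,
user-assignable value `ZZ` (a provisional choice — the standard itself
does not fix a country code for overlap units; the claimants are named in
the label).

## Code grammar

The marine and terrestrial code systems must share one namespace without
collisions. Terrestrial codes are one digit (level 1), two digits (level
2), three letters (level 3) and `XXX-YY` (level 4). Marine codes are
therefore: one ocean letter from {R, A, I, P, S} (level 1), ocean
letter + digit (level 2), two letters + digit for coastal level 3 —
the digit is what makes a three-character code marine — and ocean
letter + digit + letter for high-seas level 3 (the level-2 code plus a
discriminating letter). Level 4 appends `-YY`, with `-OO` reserved for a
level-3 unit's single child. These productions are mutually exclusive by
shape; the test suite proves it by enumerating every alphanumeric string
of length 1–3. Which digit a given level-2 unit receives, and which
diagnostic letters a level-4 suffix uses, are data in the registry table,
not derivable facts; the builder's own allocation (below) exists only so
that desk-scale worlds get deterministic codes.

Labels use an en-dash separator (" – "); the comparator
(`normalize_label`) folds hyphen/en-dash and whitespace variants, since
label sources are inconsistent in this respect. Codes are upper-case on
output and case-insensitive on input.

## The construction cascade

For each EEZ, after splitting discontinuous claims into their connected
parts (parts touching across the antimeridian count as one), the builder
decides per part:

1. **KEEP_EEZ** — the part is not too large and intersects exactly one
   sea area;
2. **SPLIT_IHO** — otherwise, split by the sea-area layer, provided every
   piece is within the size threshold and the country is not flagged as
   unwantedly split by that layer (the configuration flag models cases
   where the sea-area scheme severs gulfs from their parent sea);
3. **SPLIT_REGIONAL** — otherwise, adopt the country's regional scheme
   (MSFD/IMCRA-style subunits that exactly tile the EEZ) where one exists;
4. **SPLIT_MEOW** — otherwise, split along the ecoregion divider lines.

"Not too large" is a judgement call in the source material, so the size
threshold is a parameter (`SourceLayers.size_threshold_km2`); the toy
world uses 2,000,000 km², roughly five times the global scheme's mean
coastal-unit area (~363,000 km²), which reproduces the intended decision
for every toy case. Ad-hoc published subdivisions can be supplied as
explicit override polygons per country; they are configuration, never
inferred.

Overlapping claims are resolved before the cascade: each claimant keeps
its exclusive part (which then runs through the cascade normally) and the
intersection becomes one overlap-claim unit.

High-seas units are built per ocean: the high-seas polygon is the ocean
minus all claims; each province template is clipped to it (removing parts
of the deep sea lying inside EEZs) and partitioned at the depth threshold.
A template may contribute a deep unit, a shallow unit, or both. Templates
must cover the high seas without material overlap or the build fails.

Higher levels are unions of their members, with boundaries adjusted to the
nearest level-4 limit: a unit straddling a draft ocean or sea boundary is
assigned wholly to the side holding the larger share of its area (ties
break to the lexicographically smallest key), never split. Code
allocation is deterministic: level-2 digits per ocean follow sea-area
name order with 9 reserved for the high seas; level-3 digits per country
and level-4 suffixes follow west-to-east then south-to-north centroid
order; `AB`/`BY` sector numbers follow ocean-letter then template order.

## Geometry and measurement

Topology is planar in lon/lat (plate carrée): unit boundaries are defined
in coordinate space, so intersections and splits are exact. Measurement
is ellipsoidal: for a region bounded by lon/lat-straight edges,

    A = ∮ G(φ) dλ,   G(φ) = a²(1−e²)/2 · [ sinφ/(1−e²sin²φ)
                                           + (1/2e)·ln((1+e sinφ)/(1−e sinφ)) ],

evaluated by 8-point Gauss–Legendre quadrature on sub-edges of at most one
degree — exact to machine precision for this smooth integrand (the whole
ellipsoid evaluates to its closed-form area to 15 digits). The test suite
cross-checks against an independent dense-triangulation oracle (midpoint
rule over recursively subdivided triangles) at 0.01% on random polygons.
Meridian arcs are computed by direct quadrature of the meridional radius
of curvature. The 5° grid-cell figure quoted for comparison with
data-driven atlases (556 × 553 km) is the arc of the parallel at the
cell's mid-latitude (2.5°) by 5° of meridian; `arc_lengths` separately
returns the strict equatorial arc (556.6 km for 5°).

Polygons crossing the antimeridian are stored split at ±180°; a unit's
geometry is the union of its parts, and discontinuity detection merges
parts that touch across the seam. Datum offsets of regional source
frames (ETRS89/GDA94 vs WGS84, decimetre–metre scale) are ignored.

Numerical conventions: the nesting/partition tolerance is 1e−6 relative
area (the standard demands exact coincidence; 1e−6 absorbs floating-point
set-operation noise and is asserted on every split, trifurcation and
depth clip). Depth is positive metres downward and "deep" means strictly
greater than the 3500 m threshold; the threshold contour is taken from the
depth field rasterised at its own resolution, so the dividing line is
accurate to one grid cell while the two parts always union exactly to the
input. Points on a shared unit boundary are assigned to the
lexicographically smallest code. All outputs are sorted by code; nothing
depends on input order.

## Occurrence assignment

Coordinates win over country text. A point inside a unit yields a
confirmed assignment with the full ancestor chain (a conflict with a
differently-named country is flagged, not fatal); a point inside no unit
falls back to its country, flagged; a record with only a country resolves
to all of that country's level-4 units, flagged imprecise. Country names
resolve through an explicit lookup table only — no fuzzy matching, since a
silently misassigned historical name is worse than an unresolved record.
Records with neither coordinates nor country are kept as unresolvable;
rows lacking a scientific name or with out-of-range coordinates are
skipped and counted. Depth is carried through but never used for
assignment: the scheme deliberately records geography, not habitat, and
the field is a hook for future water-column schemes. In checklists a
taxon both confirmed and imprecise in a unit reports as confirmed.
Imprecise country-level records propagate along primary parent chains
only; alternative parents are stored but never used for roll-up.

## The synthetic world

The generator emulates, with rectilinear coastlines and closed-form areas,
every structural condition the builder must handle: two oceans split at
120°E/60°W (optionally a third, circumpolar, south of 70°S), two sea
areas per ocean split at 20°N, and nine fictional states — a two-sea
small state, a state whose sea-area split is flagged unwanted, a
discontinuous island state (with land holes inside its EEZ), an oversized
state split by ecoregion lines, a two-ocean state, a regional-scheme
state, an overlapping pair, and an antimeridian state (a minimal
three-state preset yields the 2/3/4/6 fixture used in small tests). Depth
profiles are uniform (5000 m), a linear east-west ramp crossing 3500 m at
lon ≈ 21.6° (for testing the contour against its analytic position), and
the default ridge (a 2000 m band at 85–95°E on a 5000 m plain, aligned to
the 1° raster so expectations are exact). The manifest freezes the
expected registry rows, builder decisions, analytic unit geometries and
areas, so builder tests compare against hand-specified expectations
rather than the builder's own output; occurrence generation records the
source unit of every sampled point as ground truth.

What the toy world does *not* emulate: real coastlines and bathymetry,
map-scale sliver geometries, datum noise, or the data volume of the
global scheme (hundreds of units, multi-million-vertex polygons). Passing
tests therefore demonstrate the correctness of the rules and the
numerics, not robustness to malformed real-world shapefiles — topology
repair is explicitly out of scope. Strict builder idempotence (re-feeding
built units as claims) does not hold in general either: a piece produced
by an ecoregion split may straddle two sea areas and would be re-split by
the sea-area rule; determinism (identical inputs give identical outputs)
is what the suite asserts.

Problem sizes used by the test suite and the acceptance script — a
21-unit world, 300–500 occurrence records, 50 random polygons for the
area cross-check — are the package's chosen desk-scale conditions; every
quantity they produce is recomputed at run time.

## Known limitations

- The global registry table of the published standard is third-party data
  and is not shipped; the census test runs only once a user vendors it.
  The reader (spreadsheet + column-mapping configuration) is exercised on
  synthetic tables.
- Polygon I/O is GeoJSON (and CSV rasters for depth); there is no ESRI
  shapefile writer.
- No support for map projections beyond WGS84 lon/lat, no topology repair,
  no taxon-name resolution, and no alternative water-column (pelagic)
  level-3/4 scheme — the geographic scheme records the benthos-anchored
  units only.
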