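# Methods

## Model and assumptions

The unit of analysis is one homecare recipient depending on externally
powered medical equipment, living inside a predicted tsunami inundation
area. The evacuation chain is assumed to be: a visiting nurse departs the
nearest visiting-nurse station by car, reaches the home, performs the
bed-to-wheelchair transfer, and pushes the wheelchair to the nearest
eligible welfare evacuation shelter. The model is deterministic and
per-recipient; nurses are never shared between recipients, congestion and
one-way restrictions are ignored, and the recipient always cooperates.

The time budget is

    t_total = d_station / v_nurse + t_transfer + d_shelter / v_walk
    margin  = T_arrival − t_total

with all arithmetic at full float precision; rounding is applied only at
display (0.1 min in the base table, whole minutes in the sensitivity
tables, half away from zero).

### Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `nurse_speed` | 360 | m/min | nurse's car, station → home (average urban speed) |
| `transfer_time` | 4.9 | min | nurse-assisted bed → wheelchair transfer |
| `walk_speed` | 33.3 | m/min | wheelchair push, home → shelter |
| `snap_tolerance` | 1.0 | m | endpoint merge radius when building the road graph |

The walking speed deserves a note: the survey it comes from is usually
quoted as 1.88 km/h (= 31.33 m/min), but the case-study table is computed
with 33.3 m/min exactly — e.g. a 4,543-m route is printed as 136.4 min,
which is 4543/33.3, not 4543/31.33 (= 145.0). This package uses
33.3 m/min as the base value; 31.33 is reachable through the parameter.

### Hazard fields

Two polygon layers: inundation-level zones (ordinal 1–3) and 30-cm
arrival-time zones (minutes until a 30-cm flow depth arrives — the
evacuation deadline, evaluated at the *assigned shelter's* location).
Containment is boundary-inclusive: a site exactly on a zone edge is inside
it, so a shelter on the boundary cannot silently escape classification.
Overlapping zones resolve conservatively — maximum level, minimum arrival
time. A point outside every arrival zone has no deadline; its margin and
delayed flag are undefined and it is excluded from delayed counts but kept
in percentage denominators.

### Assignment rules

"Nearest" is always network distance (Dijkstra on the road graph), never
straight-line. Ties break toward the lexicographically smallest facility
id, and among equal-length routes the lexicographically smallest node
sequence is returned, so runs are bit-reproducible. Shelters in level-3
zones are removed from candidacy before the nearest search; if no eligible
shelter is reachable the recipient is reported *unassignable* and the run
continues. Off-network sites are routed from their nearest graph node; the
site-to-node offset is a diagnostic and is never added to route distance,
keeping distances comparable with route-only GIS measurements.

### Delayed-escape classification

Base case: delayed iff margin < 0 (strict). Sensitivity tables: margins
are displayed in whole minutes and a displayed 0 counts as delayed
(rounded margin ≤ 0). The two conventions are deliberate and match the
published tables' footnotes; `classify_delayed` exposes both.

### Sensitivity analysis

Each of the four parameters (nurse speed, transfer time, walk speed,
arrival time) is varied to 0.5× and 2.0× of base. Adversity is
parameter-specific: slow speeds, long transfer, short arrival. The
multi-way grid enumerates all 16 combinations as scenarios A–P, nested
nurse speed (slow, fast) → transfer (long, short) → walk speed
(slow, fast) → arrival (short, long), so A is all-adverse and P
all-favourable. Delayed percentages use the full inundation-area cohort
(21 in the case study) as denominator, including recipients with undefined
arrival — the only convention that reproduces the published percentages
(e.g. 17/21 = 81.0%).

## The packaged case study and its discrepancies

The packaged table transcribes the published per-recipient inputs of the
Kochi cohort: 21 recipients, station distances 56–2,694 m, shelter
distances 265–4,543 m, arrival times in {35, 50, 60} min with four
recipients outside the arrival field. Reproducing the published outputs
from these inputs gives:

* every base-table time column (nurse leg, walk leg, total) to ±0.05 min;
* the base margin for nine rows; the other eight printed margins disagree
  with the stated formula (arrival − total) by 1–22.5 min. The published
  headline of eight base-case delayed escapes is therefore not recoverable
  from the formula, which yields seven (the largest single disagreement:
  one recipient printed at −8.2 min computes to +14.3). This package
  follows the formula.
* the complete one-way table — all 136 margin cells, delayed counts
  (7, 7, 7, 7, 12, 4, 14, 4) and percentages;
* the multi-way table in all cells except two (recipient 27, scenarios C
  and D, each off by one displayed minute from the formula — consistent
  with intermediate rounding in the original spreadsheet), and all 16
  delayed counts and percentages.

The `tsunevac reproduce` command recomputes and checks all of the above.

## Synthetic scenarios

The generator emulates the study area's structure, not its geography: a
grid road network (250-m spacing over a 5 × 5 km extent, 10% random edge
dropout, redrawn until connected), a straight coastline at y = 0, and
shore-parallel hazard bands — inundation levels 3/2/1 out to 800, 1,800 and
3,000 m inland, and 35/50/60-min arrival bands out to 1,200, 2,400 and
3,600 m, giving the monotone coast-to-inland arrival structure of a
advancing tsunami. Default cohort sizes mirror the study (21 recipients,
9 stations, 33 shelters), and recipients are placed only at nodes whose
network distances to the nearest station and nearest eligible shelter fall
in the observed ranges (50–2,700 m and 300–4,600 m). All draws come from
one numpy generator keyed by the seed, in fixed order, so outputs are
byte-reproducible.

What the synthetic city does **not** emulate: real street topology and
density gradients, bathymetry-driven arrival fields, clustered housing,
shelter capacity, or geocoding error. Passing tests on synthetic scenarios
therefore demonstrate the pipeline's correctness and its invariants
(shelter rule, dominance, determinism), not predictive accuracy for any
real city.

## Numerical choices

* Display rounding is half away from zero (`decimal` quantisation on the
  float's shortest decimal representation); this is the only rule
  consistent with the published tables.
* Road-edge weights are Euclidean arc lengths of the polylines; degenerate
  polylines (zero length, self-loops after snapping) are dropped with a
  warning; parallel edges keep the shorter geometry.
* Shortest-path tie-breaks and facility-id tie-breaks are lexicographic,
  making every result deterministic without a seed.
* Geographic (lon/lat) input is rejected at read time: all model
  arithmetic is metres/minutes, and inputs must arrive in a projected
  planar CRS.

## Problem sizes

Tests run the routing oracle on 1,000 random graphs of ≤ 8 nodes against
exhaustive path enumeration, the containment oracle on 1,000 random points
against a winding-number check, and the full pipeline over 100 synthetic
seeds; these sizes give exhaustive coverage of the small-graph space and
tight Monte-Carlo coverage of the geometric predicates while keeping the
suite fast.

## Known limitations

Single nurse per recipient and no scheduling; no congestion or road
blockage; walking speed independent of load and terrain; arrival fields
treated as exact; shelter capacity unmodelled. These mirror the scope of
the underlying evacuation model.
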