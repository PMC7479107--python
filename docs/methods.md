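# Methods

## Scope and model

`windfauna` scores the prospective impact of one wind farm on each
flying species recorded at its site. The score is a deterministic
multi-criteria index, not a probabilistic collision-rate model: it
combines farm geometry, layout and location with species traits into a
single comparable number per species,

```
AS_i = WF · (SS_i + VS_i),        AS_i ∈ (0, 40].
```

Band-style blade-passage collision models, GIS distance computation and
population-viability consequences are out of scope.

## Farm constant WF = VWF + UF

**Turbine incidence.** Each turbine's hazard footprint is the frontal
area AFM = a + b − c: the rotor disc a = πr², the triangle
b = (sin 60°·r)(L − cos 60°·r) swept between the blades and the ground
when a blade leans 60° off the tower, minus the overlap
c = πr²/3 − (sin 60°·r)(cos 60°·r). The trigonometric constants are
exact (sin 60° = √3/2, cos 60° = 1/2). The tower must be taller than
the blades (L > r); other geometries are rejected as invalid rather
than clipped, which also keeps the triangle above ground. The area is
scaled by the blade-rotation score BRS = 1 + log(SB): hazard grows with
rotor speed but saturates, so a logarithmic ramp is used. The log base
is 10, kept as a module constant (`LOG_BASE`) rather than a CLI option:
base 10 keeps BRS in roughly 1–2.3 for realistic 1–20 rpm rotors, and
makes the decade points (1, 10, 100 rpm → 1, 2, 3) easy to reason
about. Speeds below 1 rpm produce BRS < 1 — allowed, since the formula
is defined there, but logged as a warning because operating rotors turn
faster and the score then damps the area.

**Farm value.** VWF = (Σᵢ Nᵢ·WTᵢ / AWF)^(1/F). Heterogeneous farms sum
count × incidence over turbine models. AWF is the frontal ("vertical
rectangle") area, summed over rows; it can be supplied directly or
derived from per-row widths × (L + r) of the tallest turbine. The
quotient is capped at 1 *before* the F-th root — the cap expresses
that the hazard area cannot exceed the area the farm occupies, a
statement about the quotient — and since x^(1/F) ≤ 1 for x ≤ 1 the cap
survives exponentiation. More rows push a sub-unit value toward 1: a
multi-row farm is harder to cross.

**Location value.** UF = VI + ZS + MP + PWF, four subscores each capped
at 0.25 so UF ≤ 1:

| component | rule | default-relevant choices |
|---|---|---|
| VI | min(fog-day fraction, 0.25) | cap, not 0.25 × fraction (see below) |
| ZS | < 10 km → 0.25; 10–50 km → 0.15; beyond/absent → 0 | boundaries in the lower-risk bin |
| MP | on a migratory pass → 0.25 else 0 | — |
| PWF | nearest farm < 3 km → 0.25; 3–5 → 0.15; 5–10 → 0.10; ≥ 10 → 0; each additional farm adds its bin value; total capped at 0.25 | boundaries in the farther bin |

Two genuinely open design points, decided once and centralised so they
are trivially changeable:

* VI is defined as a raw frequency with a separately stated maximum;
  we read that as a cap (`min`), not a rescaling. Under a rescaling a
  site fogbound half the year would score 0.125 instead of 0.25, which
  understates a hazard the component exists to flag.
* The PWF increment rule for additional farms can, read literally,
  exceed the component's own ceiling and hence push UF above 1; we cap
  the component at 0.25, preserving UF ≤ 1 which the model states
  unconditionally.

Distance-bin boundaries (10, 50, 3, 5 km) fall in the lower-risk bin,
matching the "between X and Y" phrasing of the mid bins.

## Species sensitivity SS (max 10)

* **Morphological (max 1):** small 1, medium 0.75, large 0.5, with the
  turtledove and heron as reference sizes. Small species score highest
  because they resist blade-wake turbulence least. Bats use the same
  schema (typically `small`).
* **Seasonality (max 1):** 0.083 per month of presence; 12 months is
  special-cased to exactly 1.0 (12 × 0.083 = 0.996 — the per-month rate
  and the sedentary maximum are both kept as stated, and the sedentary
  case wins).
* **Phenology (max 1):** breeding only 0.75, passage only 0.5, winter
  only 0.25, two or more periods 1.0, absent 0. A single undivided
  "passage" period is used (no prenuptial/postnuptial split).
* **Flight height (max 1):** the turbine dimensions stratify the air
  column into Zone I [0, L−r) below the rotor (0.5), Zone II
  [L−r, L+r] rotor-swept (1.0) and Zone III above (0). A species'
  height interval is intersected with the three zones and the highest
  value among non-empty intersections is taken — a deterministic,
  conservative stand-in for "the more frequent and riskier zone" when
  no frequency data exist; an optional modal height overrides the
  interval. In farms mixing turbine models a species is scored against
  each model's zones and the highest sensitivity kept.
* **Flight type (max 0.5):** direct 0.25, indirect/cycloid/soaring 0.5.
* **Flock size (max 1):** 1 → 0.25, 2–5 → 0.5, 6–10 → 0.75, >10 → 1.
* **Historical (max 2):** usual 2, medium 1, scarce 0.5, none 0; a
  study-frequency percentage maps >30 % → usual, 15–30 % → medium,
  1–15 % → scarce, <1 % → none, with 15 and 30 in the lower bin. A
  categorical record overrides a percentage when both are given.
* **Demographic (max 2.5):** strategy K 0.5 / R 0.2, plus the species'
  presence share and individual share of the community survey (each ≤ 1
  and summing to 1 across the community). A species absent from the
  survey is rejected rather than guessed — its shares are undefined.

## Species value VS (max 10)

Red-Book threat value (CR 9, E 8, V 6, NT 4, DD 2, LC/NE/NC 1) plus 1
when the species has hunting, management or cultural (socioeconomic)
interest.

## Classes and ranking

Class boundaries are printed with a 0.1 gap (5 / 5.1, …), an artefact
of one-decimal reporting; the implementation uses half-open intervals
(0, 5], (5, 10], (10, 20], (20, 40] so every value in (0, 40] receives
exactly one class. Values below the nominal floor of 1 — practically
unreachable in the field but producible by the formula — are classified
Class I with a logged warning, not rejected; values above 40 are
errors. The weighted valuation divides each AS by the community
maximum: it is scale-free, order-preserving, and ties share the top
weight of 1.

## Synthetic data

The fixture generator (`windfauna.fixtures`) emulates a temperate
onshore wind farm and the community a pre-construction survey would
record: one turbine model per farm with blades 20–60 m, hub heights
10–80 m above the blade length (so L > r holds by construction),
5–20 rpm, 5–30 turbines in 1–4 rows at 200 m spacing with the frontal
area derived from the layout; a 360-day observation year with 0–120 fog
days; and species whose traits are drawn independently from realistic
category frequencies (60 % small, passage/breeding-dominated phenology,
flocks mostly small, 55 % least-concern with rare CR/E, 20 %
socioeconomic interest). Surveys give every species at least one
presence.

What the generator does **not** emulate: trait correlations (real
soaring species are large, K-strategists and often threatened — traits
here are independent), abundance structure (no log-series skew),
heterogeneous farms, or any collision outcome data. Passing tests on
these fixtures therefore demonstrate that the arithmetic, caps and
classifications behave as specified across the input space — not that
the index predicts field mortality.

All randomness flows through one seeded `numpy` generator; the scoring
pipeline itself is deterministic, so fixed seeds give byte-identical
fixture files and reports.

## Numerical and interface choices

* Pure `float` arithmetic; no tolerances are needed anywhere in the
  pipeline — the only approximate comparisons live in the tests.
* Rotor speed is taken in rpm as given; no unit conversion.
* Categorical inputs are case-insensitive in the file loaders but
  canonical in the in-memory types; farm files are YAML validated with
  file:line references and stable error codes, tables are UTF-8 CSV
  with a header row and "." decimals.
* Reports carry a `schema_version` field; weights are rounded to three
  decimals in the human-readable table only.
* The acceptance script redraws the cap-saturating farm geometry from
  the seeded ranges on every run (5–30 turbines); the reported ceilings
  are invariants of the model, so problem size is immaterial and kept
  at desk scale.

## Known limitations

* The index is ordinal: a species at AS 28 is not "twice as affected"
  as one at 14.
* Flight-height scoring without frequency data always takes the
  riskiest overlapped zone, biasing wide-interval species upward.
* The demographic subscore depends on survey composition, so adding a
  species to a survey changes every other species' shares and hence
  their SS.
* Cumulative multi-farm effects enter only through the PWF proximity
  bins.
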