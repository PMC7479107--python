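# windfauna

Multi-criteria scoring of the impact a wind farm has on the flying fauna
(birds and bats) present at its site.

Siting decisions for wind farms need a way to compare, species by
species, how badly a particular turbine layout in a particular place
would affect the local bird and bat community. `windfauna` implements a
deterministic desk-scale scoring model for exactly that audience —
environmental-impact assessors, wind operators and regulators ranking
candidate sites or layouts before construction.

## The model

For every species *i* present at the site the package computes an
**affection index**

```
AS_i = WF · (SS_i + VS_i)
```

on a nominal 1–40 scale, where:

* **WF = VWF + UF ∈ (0, 2]** is the wind-farm constant.
  * **VWF = ((Σ N·WT) / AWF)^(1/F)** is the farm value: summed turbine
    incidence over the frontal area AWF occupied by the farm's F rows,
    with the quotient capped at 1. Each turbine's incidence is
    **WT = AFM · BRS**, where AFM = a + b − c is the closed-form hazard
    area (rotor disc a = πr², blade–ground triangle
    b = (sin 60°·r)(L − cos 60°·r), minus their overlap
    c = πr²/3 − (sin 60°·r)(cos 60°·r); r = blade length, L = tower
    height) and BRS = 1 + log₁₀(rotor rpm).
  * **UF = VI + ZS + MP + PWF ∈ [0, 1]** is the location value:
    low-visibility-day frequency, proximity to sensitive areas,
    presence on a migratory pass and proximity to neighbouring farms,
    each capped at 0.25.
* **SS ∈ (0, 10]** is the species sensitivity: morphological (size
  class, max 1), ethological (seasonality, phenology, flight height
  against the turbine's vertical risk zones, flight type, flock size,
  max 4.5), historical (prior collision record, max 2) and demographic
  (K/R strategy plus the species' frequency and abundance shares of the
  community survey, max 2.5) subscores.
* **VS ∈ [1, 10]** is the species value: Red-Book threat category
  (CR 9, E 8, V 6, NT 4, DD 2, LC/NE/NC 1) plus 1 for socioeconomic
  interest.

Two valuations are reported: the **Total Valuation** maps AS to four
sensitivity classes (I ≤ 5 low, II ≤ 10 sensitive, III ≤ 20 very
sensitive, IV ≤ 40 extremely sensitive) and the **Weighted Valuation**
divides every AS by the community maximum so the most affected species
scores exactly 1.

## Worked example

The repository ships a reference farm (ten turbines with 40 m blades,
80 m towers, 10 rpm, in one 2000 m row; fog on 36 of 360 days, a
sensitive area at 30 km, on a migratory pass, one neighbouring farm at
7 km) and a three-species community:

```sh
windfauna assess \
  --farm src/windfauna/data/example_farm.yaml \
  --species src/windfauna/data/example_species.csv \
  --survey src/windfauna/data/example_survey.csv \
  --out report --format both
```

prints

```
farm: VWF=0.5102 UF=0.6000 WF=1.1102
       species    SS  VS        AS class  weighted
Falco naumanni 5.748 7.0 14.152738   III     1.000
   Gyps fulvus 8.050 1.0 10.047245   III     0.710
 Turdus merula 4.900 1.0  6.550137    II     0.463
```

Reading it: each turbine's hazard area is 6122.31 m² and its incidence
12244.63; ten of them over a 240 000 m² frontal rectangle give a farm
value of 0.5102, and the location context adds 0.60, so every species'
(SS + VS) total is multiplied by 1.1102. The lesser kestrel combines a
moderate sensitivity (5.748) with a high conservation value (Vulnerable
plus a recovery plan, 7), lands in Class III (very sensitive) and is
the most affected species (weight 1); the blackbird, a low-flying,
solitary, unthreatened resident, is Class II.

`windfauna classify 15.3` prints the class of a bare index value,
`windfauna explain` breaks a species' SS into its eight subscores, and
`windfauna fixtures --seed 42` writes a seeded synthetic
farm/species/survey triple for experimentation.

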