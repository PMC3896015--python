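# bycatchrisk

Predicting where and when satellite-tracked marine megafauna are most likely
to be caught incidentally by industrial longline fisheries.

Fisheries bycatch is a leading source of mortality for leatherback turtles
and other wide-ranging pelagic vertebrates, but observed bycatch records are
sparse, voluntary and unevenly reported. When direct observations are
missing, risk can still be mapped by combining three ingredients that *are*
available: satellite tracks of the animals, publicly reported gridded
fishing effort (hooks per 5°×5° cell per quarter), and gear-specific
relative capture probabilities. `bycatchrisk` implements that pipeline for
two-population telemetry studies (e.g. the genetically distinct East Pacific
and West Pacific leatherback nesting populations) and ships a seeded
synthetic-data generator so every stage can be exercised and validated
end-to-end with known ground truth.

## The model

**Use intensity.** Daily state-space-filtered positions are pooled across
years onto a 5°×5° grid × four annual quarters. Because tracks end at
staggered times, the position of individual *i* of population *j* at
relative track day *t* is weighted by the inverse of the number of animals
still transmitting:

```
ω_it = 1 / n_jt ,        n_jt = #{ individuals of population j with a day-t position }
```

so every tracking day contributes total weight 1 per population. Beyond a
threshold day *T_j* — the 85th percentile of the population's position-day
distribution — positions keep the threshold-day weight `1 / n_{j,T_j}`,
which stops the tail of the single longest track from dominating. Within
each quarter, the population with fewer raw positions is inflated by the
ratio *x/y* of the larger to the smaller count so the two populations
contribute equally. Positions that fall strictly inside satellite gaps
longer than 20 days are removed first.

**Gear-adjusted effort.** Shallow billfish sets catch epipelagic turtles far
more often than deep tuna sets. From per-set capture rates (0.0246 vs
0.0048 turtles/set) and typical set sizes (850 vs 1124 hooks), the relative
catchability index is

```
c = (0.0246 / 850) / (0.0048 / 1124) ≈ 6.8
```

Raw hooks in cell *i*, quarter *t* are converted to tuna-hook equivalents
using the billfish share *p(i,t)* of the catch by weight as a proxy for the
share of effort targeting billfish:

```
E(i,t) = hooks(i,t) · [ p(i,t)·c + (1 − p(i,t)) ]
```

**Interaction index.** Both surfaces are normalized to relative
probabilities (each sums to 1 over all cells and all four quarters), and
the bycatch-risk surface is their normalized product:

```
I(i,t) = P_turtle(i,t) · P_effort(i,t) / Σ_{i,t} P_turtle · P_effort
```

which again sums to one, so values are comparable across seasons. The index
ranks relative risk; it does not predict absolute bycatch counts.

## Worked example

Run the whole pipeline on the `planted_hotspot` scenario — a synthetic
world with one cell-quarter where both turtle occupancy and fishing effort
are elevated, recorded as ground truth:

```
$ bycatchrisk run --scenario planted_hotspot --seed 7 --outdir out
{
  "EP": {
    "n_cell_quarters": 163,
    "top_hotspot": {
      "rank": 1.0,
      "lat_lo": -15.0,
      "lon_lo": 255.0,
      "quarter": 3.0,
      "value": 0.6232819334880573
    }
  }
}
```

The rank-1 hotspot is the cell with south-west corner 15°S, 255°E
(= 105°W) in quarter 3 (July–September), carrying 62.3% of the total
relative bycatch risk — exactly the planted cell-quarter written to
`out/truth.json`. The computed catchability index (6.78, logged and stored
in `out/manifest.json`) and the full hotspot ranking are in
`out/hotspots_EP.csv`:

```
rank  lat_lo  lon_lo  quarter    value
   1   -15.0   255.0        3 0.623282
   2   -15.0   255.0        4 0.031225
   3   -20.0   275.0        4 0.016446
```

All intermediates (tracks, hooks, catch, use surfaces, effective effort,
interaction surfaces as CSV and GeoJSON) are plain text under `out/`, and
`out/manifest.json` records the configuration and SHA-256 checksums; a
rerun with the same seed and config is bit-identical. The stages are also
available as individual subcommands (`simulate`, `preprocess`, `use`,
`effort`, `interact`, `report`) operating on the serialized intermediates.

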