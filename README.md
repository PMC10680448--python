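# reefguest

Bipartite network analysis for sponge host–guest interactions on tropical
coral reefs.

Reef sponges shelter a large fauna of arthropods, annelids, fishes,
molluscs, echinoderms and cnidarians.  Recorded host–guest associations
form a bipartite network in which a handful of generalist sponges
concentrate most links while many species host only one to three guests.
`reefguest` is a library and command-line tool for ecologists who want to
quantify, for such a network:

- **network-level structure** — nestedness (NODF, 0–100) and Barber's
  bipartite modularity *Q*, optimised by simulated annealing, each tested
  against an ensemble of random matrices that conserve the network's
  dimensions and number of links (a marginal-conserving curveball model is
  available for sensitivity analysis);
- **species-level importance** — seven complementary structural
  descriptors per host sponge (degree *k*, betweenness, closeness, Katz
  centrality, among-module connectivity *c*, within-module standardized
  degree *z*, and nestedness contribution *cn*), collapsed by principal
  coordinate ordination into a single index PCO1^½ (axis-1 score,
  zero-shifted and square-rooted);
- **trait models** — a log-link Poisson-family GLM of importance on
  accumulated geographic area (the summed, reef-cropped 10 m² buffers
  around a species' occurrence records, in km²), one-way ANOVAs across
  functional morphologies (Crust-like, Massive, Cup-like, Erect) and
  taxonomic orders, and a meta-analysis screen of publication effort
  across marine ecoregions (logit proportions, ML τ², Cochran Q,
  Thompson–Sharp regression test).

A first-class synthetic-data generator produces complete input bundles
(interaction CSV, trait CSV, occurrence CSV, reef GeoJSON) with planted
nested-and-modular structure, so every stage is testable end to end without
any download.

## Worked example

Simulate a study-scale network and analyse its structure:

```bash
reefguest simulate --seed 3 --out sim/
reefguest structure --interactions sim/interactions.csv \
    --n-null 200 --steps 50000 --seed 1 --out struct/
```

The structure command prints (abridged):

```json
{
  "nodf": {
    "observed": 5.4465,
    "null_mean": 3.8375,
    "null_sd": 0.1176,
    "z": 13.6815,
    "p": 0.00498,
    "n_null": 200,
    "model": "fill"
  },
  "Q": 0.533,
  "n_modules": 38
}
```

The observed NODF (5.45) sits far above the mean of the 200 fill-conserving
null matrices (3.84 ± 0.12, z ≈ 13.7), so the simulated network is
significantly nested — the planted degree gradient is detected; p is
reported with the (r+1)/(n+1) continuity correction, so its floor here is
1/201.  The annealed modularity Q ≈ 0.53 indicates strong block structure
on top of the nested gradient, as in the planted configuration.

The full pipeline (descriptors, importance, areas, trait models) runs with:

```bash
reefguest analyze --interactions sim/interactions.csv \
    --traits sim/traits.csv --occurrences sim/occurrences.csv \
    --reefs sim/reefs.geojson --n-null 200 --cni-n-rand 150 \
    --seed 1 --out run/
```

which writes `run/summary.json` (network metrics, GLM, ANOVAs, publication
bias), `run/species_table.csv` (per-sponge descriptors, PCO1, importance,
accumulated area, traits) and `run/manifest.json` (config, seeds, input
digests — re-running with the same manifest reproduces the outputs).

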