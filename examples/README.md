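# Input template

`comparison_table_template.csv` shows the study-comparison CSV schema read by
`detectcomp run --input ...` and by `detectcomp.read_comparisons`.

One row = one population observed by one method. Columns:

| column | meaning |
|---|---|
| `population_id` | identifies the population; rows sharing it are paired across methods |
| `order`,`family`,`genus`,`species` | taxonomy used to build the surrogate phylogeny |
| `realm` | biogeographic realm: `australian`, `nearctic`, `neotropical`, or `palearctic` |
| `site_area_km2` | study-site area in km² (positive; may be left empty) |
| `body_mass_kg` | species body mass in kg (positive; may be left empty) |
| `method` | `live_trap`, `camera`, or `genetic` |
| `camera_analysis` | `spatial` or `random` for camera rows; empty/`none` otherwise |
| `tissue` | `hair` or `scat` for genetic rows; empty/`none` otherwise |
| `n_individuals` | count of distinct individuals detected; positive, may be a real number when derived from density × area |

Counts derived from a reported density are `density × area` (see
`detectcomp.count_from_density`) and are deliberately not rounded.
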