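# CSV schemas (version 1)

All files are comma-separated, UTF-8, with a header row and dot decimal
separator. Unknown columns are ignored with a warning; missing required
columns are a schema error. Booleans are written `True`/`False` (also
accepted: `1/0`, `yes/no`). Empty fields mean "not reported".

## observations.csv

One row per source x country-year x group cell. Individual-level sources
also have a row here (their metadata); their measurements live in
`individuals.csv`, linked by `source_id`.

| column | type | notes |
|---|---|---|
| source_id | text | stable identifier of the survey/source |
| country | text | ISO3-style country code |
| year | decimal | survey fieldwork midpoint |
| group | enum | `children`, `pregnant`, `non_pregnant`, `women_combined` |
| coverage | enum | `national`, `subnational` |
| n_regions_covered | int | required when subnational |
| data_form | enum | `summary`, `individual` |
| n | int | sample size of the cell |
| mean_hb | g/L | summary form; must lie in (40, 190) |
| sd_hb | g/L | optional, > 0 |
| prev_anaemia | proportion | optional, [0, 1] |
| prev_severe | proportion | optional, [0, 1] |
| altitude_adjusted | bool | sea-level-equivalent values already |
| smoking_adjusted | bool | informational only; no post-adjustment |
| age_range_matches | bool | true iff source covers 6-59 months / 15-49 years exactly |
| pregnant_fraction | proportion | `women_combined` rows only |

## individuals.csv

| column | type | notes |
|---|---|---|
| source_id | text | joins to observations.csv |
| country | text | |
| year | decimal | |
| group | enum | as above (women's rows are re-classified by gestational age) |
| hb | g/L | measured haemoglobin |
| altitude_m | metres | optional; enables individual altitude adjustment |
| gestational_weeks | weeks | optional, [0, 44]; pregnancy means strictly > 8 |
| age | months (children) / years (women) | optional |
| cluster_id | text | optional |

## covariates.csv

Complete for every modelled country-year. `hb_disorder_prev` must be
constant over time within a country.

columns: `country, year, maternal_education (years), urban_prop,
abs_latitude (degrees), hb_disorder_prev, mean_bmi (kg/m2), mean_waz (Z)`

## regions.csv

columns: `country, region` — every country maps to exactly one region.

## population.csv

columns: `country, year, group, population` (persons; > 0). Groups are the
three estimate groups (`children`, `pregnant`, `non_pregnant`).

## altitude_bands.csv

columns: `country, band_midpoint_m, population_share` — the population
distribution over altitude bands; shares sum to 1 within a country.

## truth.csv (emitted by the simulator only)

columns: `country, year, group, true_mean, true_prev, true_severe_prev` —
ground truth of the synthetic world for parameter-recovery checks.
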