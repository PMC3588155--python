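# Cohort TSV schema

UTF-8, tab-separated, header row, one row per tumour.  The missing token is
always `NA`.  Columns may appear in any order; all are mandatory (a column
that was never measured is present and entirely `NA`).

| column | values | meaning |
|---|---|---|
| `tumour_id` | unique string | tumour identifier |
| `cin` | 1 / 0 / NA | chromosomal instability call (altered / wild-type / missing) |
| `msi` | 1 / 0 / NA | microsatellite instability call |
| `kras`, `nras`, `braf`, `pik3ca`, `tp53`, `fbxw7` | 1 / 0 / NA | somatic mutation calls |
| `loh5q`, `loh17p`, `loh18q` | 1 / 0 / NA | loss of heterozygosity calls |
| `sex` | `male` / `female` | |
| `age` | years, 3 decimals | age at presentation, > 0 |
| `site` | `proximal` / `distal` / NA | tumour location |
| `stage` | `II` / `III` | AJCC stage (binary in this cohort) |
| `grade` | `well` / `moderate` / `poor` / NA | differentiation; ordered well < moderate < poor when used as a score |
| `arm` | `rofecoxib` / `placebo` | trial randomization arm |
| `chemo`, `radio` | 1 / 0 / NA | adjuvant chemo- / radiotherapy flags |
| `dfs_years` | years ≥ 0, 3 decimals | disease-free-survival time |
| `dfs_event` | 1 / 0 / NA | 1 = relapse/death, 0 = censored |
| `group` | `1`..`7` / `unclassifiable` / NA | molecular group label (output of the classifier, or the generator's truth) |

Molecular calls use 1/0 to mirror the red/blue binary encoding of the
two-way cluster heatmap.  Lines starting with `#` are ignored.  Loading
reports row count and per-column missingness, and never silently drops
rows.
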