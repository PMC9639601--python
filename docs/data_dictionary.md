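# Data dictionary

All tables are plain CSV (Parquet works equally through pandas); dates
are ISO-8601 (`YYYY-MM-DD`). Identifiers are opaque strings.

## practices.csv

| column | type | description |
|---|---|---|
| practice_id | str | unique practice identifier |

## gps.csv

| column | type | description |
|---|---|---|
| gp_id | str | unique GP (provider) identifier |
| practice_id | str | practice the GP works in (FK practices) |

## patients.csv

| column | type | description |
|---|---|---|
| patient_id | str | unique patient identifier |
| practice_id | str | registered practice (FK practices) |
| age_band | str | age at baseline: `18-29`, `30-39`, `40-49`, `50-59`, `60-69`, `70-79`, `80+` (`<18` allowed for patients excluded on age); a `birth_year` integer column may be supplied instead |
| sex | str | `female` / `male` |
| ethnicity | str | resolved ethnicity label (main 11-category or disaggregated scheme); alternatively supply `ethnicity_obs_primary` / `ethnicity_obs_hospital` columns holding lists of `(date, category)` observations for in-pipeline harmonization |
| imd_quintile | str | residential deprivation quintile `Q1` (least deprived) … `Q5` (most deprived) |
| exit_date | date or empty | deregistration/death date; empty = registered through window end |
| registration_date | date, optional | if present, must be on/before baseline for eligibility |
| quality_flag | bool, optional | if present, falsy rows are excluded as failing data-quality/linkage |

## conditions.csv

| column | type | description |
|---|---|---|
| patient_id | str | FK patients |
| condition | str | condition label (abstract; one row per patient-condition) |
| condition_class | str | `physical` / `mental` |
| onset_date | date | first record of the condition; counted at baseline if on/before it |

## consultations.csv

| column | type | description |
|---|---|---|
| patient_id | str | FK patients |
| practice_id | str | FK practices |
| gp_id | str | FK gps — the GP seen |
| date | date | consultation date |
| mode | str | `face_to_face`, `telephone`, `online`, `home_visit`, … (only the first three count by default) |

## cohort.csv (output)

One row per eligible patient: `patient_id`, `practice_id`, `age_band`,
`sex`, `ethnicity`, `imd_quintile`, `follow_up_years` (365.25-day
years), `n_consultations` (qualifying events in window),
`ltc_count`, `ltc_category` (`0-1`, `2+ physical`, `2+ mental`,
`physical+mental`), `upc`, `coc` (full precision).

## coefficients.csv (output)

Long format: `model_id`, `outcome`, `covariate`, `level`, `estimate`,
`se`, `ci_low`, `ci_high`, `pvalue`, `significant`, `n_patients`,
`converged`. Reference levels are absorbed and absent.
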