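# File formats

## Procedure CSV (input to `analyze` / `convert`, output of `synth`)

Long format, one row per dosimeter reading — six rows per procedure
(procedure metadata repeated on each row):

| column | type | notes |
|---|---|---|
| `procedure_id` | str | groups the six readings |
| `profession` | enum | `intensive_care_physician`, `pediatrician`, `radiological_technologist` |
| `practice` | enum | `assisted_ventilation`, `head_holding`, `observation` |
| `area` | enum | `I`, `II` (adjacent to gantry), `III` (distant) |
| `tube_voltage_kVp` | float | |
| `tube_current_mA` | float | |
| `ctdi_vol_mGy` | float | ≥ 0 |
| `dlp_mGy_cm` | float | ≥ 0 |
| `extension_tube` | bool | `True`/`False` |
| `placement` | enum | `inside` / `outside` the safety glasses |
| `side` | enum | `left` / `right` |
| `orientation` | enum | `vertical` / `horizontal` for inside readings, `none` for outside |
| `air_kerma_mGy` | float | ≥ 0 |

Each procedure must supply exactly the six slots: inside left/right ×
vertical/horizontal, outside left/right. Schema violations are reported
with line numbers; `--skip-bad` drops offending procedures instead of
aborting.

## Curtain CSV (optional input to `analyze --curtain-csv`)

Columns `without_mSv`, `with_mSv`: paired phantom Hp(3) measurements
without/with the protective curtain, one row per repeat.

## DRL CSV (input to `drl`)

Columns `exam_label`, `metric` (`CTDIvol` or `DLP`), `facility_median`,
`drl_value`. Output adds an `exceeds` flag (strict `>`).

## Report

`analyze` writes `json` (nested sections: `vh_ratio`, `bilateral_ratio`,
`by_profession`, `by_area`, `compliance`, `glasses`, `extension_tube`,
`curtain`, `combined_measures`, `warnings`), `csv` (flattened key/value
rows) or `markdown`. Floats carry 4 significant digits; printed-style
integer percents appear alongside raw fractions.

## Bundled reference tables

`src/ctlensdose/data/*.csv`, columns `energy_keV,value`;
`manifest.json` lists quantity, units, interpolation rule and source for
each (the Hp(3)/Ka table is a synthetic reconstruction — see
`docs/methods.md`).
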