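# Data schemas

## SamplingRecord CSV

One row per chamber deployment pair (NEE + ER at one collar position).
Lines starting with `#` are treated as comments.

| column        | type   | units        | constraints                                  |
|---------------|--------|--------------|----------------------------------------------|
| `point_id`    | str    | —            | unique within an analysis set (pseudoreplicates rejected) |
| `day`         | int    | day of year  | 0–365                                        |
| `hour`        | float  | h            | `hour + minute/60`, in [0, 24)               |
| `ER`          | float  | µmol/m²/s    | ≥ 0 by convention; violations flagged        |
| `NEE`         | float  | µmol/m²/s    | any sign                                     |
| `GPP`         | float  | µmol/m²/s    | ≤ 0 by convention; violations flagged        |
| `Ta`          | float  | °C           | air temperature (NEE window)                 |
| `Ts`          | float  | °C           | soil temperature                             |
| `rs`          | float  | W/m²         | > 0 (polar-day campaigns never reach zero)   |
| `RH`          | float  | %            | relative humidity                            |
| `Pr`          | float  | hPa          | air pressure                                 |
| `VWC`         | float  | %            | volumetric soil water content                |
| `GFC`         | float  | fraction     | in [0, 1]                                    |
| `cover_class` | str    | —            | one of `V`, `NV`, `MIX`, `BS`                |
| `species`     | str    | —            | `CX`, `DR`, `SL`, `SX`, `SI` or `none`       |

Rows violating a range constraint are quarantined (removed and logged with a
machine-readable reason code); a missing column or duplicate `point_id` is a
hard error.  `validate_records` adds a boolean `sign_flag` column marking
sign-convention violations, which are kept.

The truth CSV written by `tundraflux simulate` carries `point_id`,
`ER_true`, `GPP_true`, `NEE_true` (µmol/m²/s, `NEE_true = ER_true +
GPP_true` exactly), `GFC_true`, `cover_class`, `species`.

## Chamber trace CSV + YAML sidecar

`<name>.csv`: columns `time_s` (s, strictly increasing, ≥ 5 samples),
`co2_ppm` (µmol/mol).  `<name>.yaml`:

```yaml
point_id: P0012
mode: transparent        # or darkened
geometry:                # optional; defaults shown
  collar_area_cm2: 661.0
  chamber_height_cm: 10.0
  extra_headspace_cm3: 0.0
ambient:
  ta_c: 10.0
  pr_hpa: 1013.0
```

## GFC CSV

`image_id, gfc, green_pixels, roi_pixels`; `gfc = green_pixels /
roi_pixels` in [0, 1].

## Report parameter naming

ER models: `a0 … am` (µmol/m²/s, in the order of the spec's driver list),
`b0` (°C⁻¹), with `Q10 = exp(10·b0)`.  GPP models report both the
table-style parameters `F` (µmol/m²/s), `alpha0` (µmol/W/s), `A0 … Am`,
`B0 …` (dimensionless) under the A-block-mean = 1 normalisation, and the
identifiable parametrisation `rho = F/alpha0` (W/m²), `P_i = F·A_i`
(µmol/m²/s), `Q_j = F²·B_j`, plus the reference-irradiance responses
`R_i = P_i·rs_ref/(rho + rs_ref)` at `rs_ref = 400 W/m²`.
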