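# File formats

All positions are micrometres. Track times are minutes; waveform times are
seconds. Coordinates are in the pattern's frame with the pattern centre at
the origin.

## Tracks CSV (`mpq synth tracks`, `mpq tracks ...`)

One row per cell per frame.

| column  | type  | unit | meaning                                  |
|---------|-------|------|------------------------------------------|
| cell_id | str/int | —  | track identifier                         |
| frame   | int   | —    | frame index, 0-based                     |
| t_min   | float | min  | timestamp (uniform spacing per cell)     |
| x_um    | float | μm   | x position                               |
| y_um    | float | μm   | y position                               |
| region  | str   | —    | optional: `centre` / `perimeter` / empty |

## Nuclei CSV (`mpq synth colony`, `mpq spatial ...`)

One row per nucleus. `x_um`/`y_um` are required; the rest are used where
the operation needs them.

| column          | type  | unit | meaning                                |
|-----------------|-------|------|----------------------------------------|
| nucleus_id      | int   | —    | identifier                              |
| x_um, y_um      | float | μm   | centroid                                |
| major_um        | float | μm   | longest axis                            |
| minor_um        | float | μm   | shortest axis                           |
| orientation_rad | float | rad  | long-axis orientation in [0, π)         |
| region          | str   | —    | generator label: `inner`/`band`/`outer` |
| `<marker>`      | bool  | —    | one column per marker (e.g. `OCT4`, `EdU`) |

## Image stacks

Multi-page TIFF (float32 grayscale) or a directory of numbered PNG/TIFF
frames; frame rate (frames/s) and pixel size (μm/pixel) are supplied in
the config or on the command line, not embedded in the file.

## Waveform CSV (`mpq beat analyze`)

| column               | type  | unit  | meaning                        |
|----------------------|-------|-------|--------------------------------|
| t_s                  | float | s     | frame-pair midpoint time       |
| mean_speed_um_per_s  | float | μm/s  | spatial mean speed (NaN if no confident block) |
| valid                | int   | —     | 1 when at least one confident block |

## Heatmap CSV

A headerless matrix of per-block maximum speeds (μm/s) on the block grid,
row i / column j matching the block centres reported by the library.

## Profile CSV (`mpq spatial profile`)

Columns `thickness`, `intensity` and optional `normalizer`; the fitted
response is `intensity / normalizer`.

## Pipeline report (`mpq run`)

A single JSON document: `provenance` (config SHA-256, seed, package
version), one entry per stage with `status` (`ok` / `skipped` / `failed`)
and the stage's results, and a top-level `ok` flag. Serialisation is
canonical (sorted keys), so identical inputs and config give byte-identical
reports.

## Run config (YAML)

Sections `geometry`, `tracks`, `contraction` plus `seed`, `stages`,
`output_dir`; every field is validated at load time and all violations are
reported at once. `mpq init-config --out config.yaml` writes the defaults.
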