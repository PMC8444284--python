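# File formats

All files are plain text. Times are days since barcoding (day 0 = the day
the founding cells were sorted); rates are events per day; state labels are
strings, never positional integers.

## Count table (long-format TSV) — the native interchange format

Columns, in order:

| column      | type   | meaning                                   |
|-------------|--------|-------------------------------------------|
| `time_days` | float  | sampling day                              |
| `barcode`   | string | clone identifier                          |
| `state`     | string | transcriptional state label               |
| `count`     | int    | harvested cells for this (time, barcode, state) |
| `condition` | string | experimental condition (e.g. `untreated`) |

Zero counts are omitted. Harvest fractions `eta` per time point are *not*
stored in the table; they are supplied in the fit/bootstrap config
(`etas: {7.0: 0.8, ...}`) or in the simulator's JSON sidecar
(`<output>.json`: seed, times, fractions, version).

## Per-cell table (TSV)

Columns `cell_id, barcode, state, time_days[, condition]`; one row per
cell. `cell_id` must be unique. Aggregated internally to a count table.

## Matrix CSV

Square CSV with state labels as both header row and index column.
Orientation: **column = source state, row = destination state** — entry
(i, j) is the rate of switching from state j to state i; column sums are
net growth rates.

## Network exports

* TSV with columns `source, target, rate_per_day` (one edge per row);
* GraphML with the edge attribute `rate_per_day`.

## Gene signatures (GMT)

Standard GMT: `name <tab> description <tab> gene1 <tab> gene2 ...`.

## Expression input

Either a 10x-style MTX triplet in one directory (`matrix.mtx`,
`features.tsv` with the gene id in the first tab-separated field,
`barcodes.tsv` with one cell id per line), or a dense genes x cells TSV
with gene ids in the first column and cell ids in the header.

## Configs and reports

Configs are YAML (or JSON) mappings; every command derives all randomness
from the single `seed` key. Reports are JSON; matrices inside reports are
nested lists in the CSV orientation above.
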