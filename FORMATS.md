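# File formats

All tables are TSV with a header row; gate boundaries are stored in
linear fluorescence units (0 and `inf` mark semibounded edges).

## Gate sidecar

One row per gate, ordered:

| column | meaning |
|---|---|
| `gate` | 1-based gate index |
| `lower` | lower boundary L_j |
| `upper` | upper boundary U_j |
| `T` *(fraction tables)* | fraction of all sorted cells in gate j (sums to 1) |
| `h` *(count tables)* | total sorted cells in gate j |

## Gate-fraction table

One row per variant: `variant_id`, then `t_1 .. t_m` — the fraction of
the variant's reads in each gate.  Every row must sum to 1 within 1e−6;
offending rows are rejected with their line numbers.

## Read-count table

One row per variant: `variant_id`, optional `seq`, then `r_1 .. r_m` —
raw read counts per gate.  The sidecar's `h` column supplies the
per-gate sorted-cell totals used for depth factors d_j = h_j / Σ_i r_ij.

## Sequences

FASTA (uppercase ACGT); record ids become variant ids.

## Activity models

Additive table: `position` (1-based), `base`, `H`.  Interaction table:
`p1`, `q1`, `p2`, `q2`, `J`, one row per unordered pair.

## Run configuration

YAML with keys `seed`, `gamma`, and a `qc` block
(`reads_min`, `single_gate_max`, `two_gate_max`, `censor_max`,
`dkl_max_bits`).
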