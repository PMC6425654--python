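# tetradose

Automated allele-dosage calling (0–4) for biallelic SNP markers in
autotetraploids from two-channel array intensities.

For each marker the B-allele signal fraction `s_b / (s_a + s_b)` is
arcsine-square-root transformed and a five-component normal mixture is
fitted by EM. Component means and the common variance are shared across
all subpopulations in the dataset, while each subpopulation's mixing
proportions follow its own regime:

* **p_free** — unconstrained (any panel),
* **p_HW** — tetraploid Hardy–Weinberg, `Binomial(4, p)` with only the
  allele frequency estimated (association panels),
* **p_fixed** — held at a known parental dosage (replicated parents with
  external dosage information),
* **p_F1** — the tetrasomic segregation ratio implied by the current
  modal dosages of the two linked parent populations (full-sib
  families; random bivalent pairing, no double reduction).

Mean positions may additionally be constrained through a dose-response
curve with per-channel background and optional curvature (equal/unequal
background × linear/quadratic), capturing the asymmetric, compressed
ratio ranges real arrays produce. Every mean constraint is crossed with
the applicable proportion regimes — including, when parental dosage
priors are supplied, both prior-using and prior-free variants, so
incorrect priors can be outvoted — and the converged fit with the lowest
BIC is selected. Thinly fitted extreme components (< 2.5% of samples
next to a neighbour holding > 15%) trigger a four-component re-fit that
is kept only if it improves the BIC. Samples are called where the
maximum posterior reaches the call threshold (default 0.75); markers are
rejected when more than 25% of samples stay uncalled or more than 90% of
calls land in a single dosage class (peak threshold 0.9).

Called markers with a full-sib family are quality-checked by comparing
the offspring dosage distribution against the expected segregation of
all 15 unordered parental dosage combinations (minimum Pearson
chi-squared); a marker "matches" when the best-fitting combination
equals the parents' own called dosages.

## CLI

Generate a synthetic dataset (one full-sib family with replicated
parents plus a Hardy–Weinberg panel, mirroring the benchmark layout):

```sh
tetradose simulate --out-dir sim --n-markers 20 --f1-size 200 \
    --panel-size 60 --seed 1
```

Call dosages (writes `scores.tsv`, `models.tsv`, `match_reports.tsv`,
`qc_summary.tsv`):

```sh
tetradose call sim/signals.tsv sim/populations.tsv \
    --priors sim/priors.tsv --out-dir calls
```

Re-run the parent–offspring match check on existing calls:

```sh
tetradose qc calls/scores.tsv sim/populations.tsv --out-dir qc
```

All thresholds (`--call-threshold`, `--peak-threshold`, …) are exposed as
flags and may also be given in a YAML file via `--config-file`; flags
win. Add `--plot` to `call` for per-marker histograms with the fitted
densities.

### File formats

All inputs/outputs are UTF-8 delimited text (TSV/CSV autodetected) with
a header row. Signal tables are either long format
(`marker_id, sample_id, signal_a, signal_b` or
`marker_id, sample_id, ratio`) or wide format (one row per marker, one
ratio column per sample). The population file lists
`#population <id> <type> [links]` directives (types: `panel_HW`,
`panel_free`, `F1` with two comma-separated parent population ids,
`parent`) above a two-column `sample_id / population_id` table. The
priors file has columns `marker_id, population_id, dosage`.

## Layout

| module | contents |
|---|---|
| `tetradose.datamodel` | core types, ratio transform, validation |
| `tetradose.io` | delimited-text readers/writers |
| `tetradose.segregation` | gamete/F1/Hardy–Weinberg dosage distributions |
| `tetradose.em` | constrained five-component mixture EM |
| `tetradose.calling` | model grid, BIC selection, re-evaluation, calling |
| `tetradose.qc` | parent–offspring chi-squared matching, run summary |
| `tetradose.simulate` | synthetic dataset generator |
| `tetradose.batch` / `tetradose.cli` | batch driver and command line |
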