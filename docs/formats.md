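# File formats

All files are plain delimited text (tab-separated unless noted) or JSON.
Multi-valued cells are joined with `|`. Identifiers are opaque strings.

## Inputs

### Report table (`reports.tsv`)

One spontaneous report per row. Duplicate `report_id`s are legal on read;
deduplication keeps the latest `receipt_date` (ties: last row wins).

| column | content |
|---|---|
| `report_id` | primary report identifier |
| `receipt_date` | ISO-8601 date |
| `drugs` | `\|`-joined drug identifiers (non-empty) |
| `ades` | `\|`-joined adverse-event identifiers (non-empty) |

### Drug-attribute table (`drug_attributes.tsv`)

| column | content |
|---|---|
| `drug` | drug identifier |
| `fingerprint` | fixed-length 0/1 string (chemical fingerprint bits) |
| `targets` | `\|`-joined protein-target identifiers |
| `taxonomy` | hierarchical classification code (ATC-like) |

### Training pairs (`training_pairs.tsv`)

Known drug–ADE associations at training time: columns `drug`, `ade`.

### Reference set (`reference_set.tsv`)

Labeled evaluation pairs: columns `drug`, `ade`, `label` with label in
{`positive`, `negative`} (`pos`/`neg`/`1`/`0`/`true`/`false` accepted on
read). Duplicate (drug, ade) keys are rejected.

## `icpnm simulate` outputs

The four tables above plus `manifest.json`: the full simulation
configuration, the ground-truth pairs with their reporting-rate ratios,
the confounded and clean null pairs, and the training-edge count.

## `icpnm score` outputs

### `scores_<METHOD>.tsv` (one per method)

| column | content |
|---|---|
| `drug`, `ade` | the pair |
| `method` | PRR, ROR, IC, EBGM or ICPNM |
| `point` | statistic on its natural scale (empty if unscorable) |
| `lower95` | signalling lower bound (PRR025/ROR025/IC05/EB05/IC_PNM_05) |
| `upper95` | upper bound (empty for ICPNM, which defines no upper bound) |
| `is_signal` | the method's conventional threshold applied to `lower95` |

### `icpnm_components.tsv` (when ICPNM is scored)

Per scored pair: `p_a_given_d` (network-model probability), `p_a`
(PS-adjusted marginal), `c_ij`, `icpnm`, `icpnm_05`, `is_signal`.

### `pnm_model.json`

The fitted network model: intercept, per-feature coefficients, selected
feature names, AIC, 10-fold CV AUC, training size, seed, standard errors.

### `run_manifest.json`

Seed, methods, package version, report count, training-edge count and the
PS options used — enough to reproduce the run.

## `icpnm evaluate` outputs

* `performance.tsv` — per method: `auc`, `youden_sensitivity`,
  `youden_specificity`, `youden_index`, `coverage` (fraction of reference
  pairs the method scored).
* `threshold_sweep.tsv` — per method × threshold: `sensitivity`,
  `specificity`, `ppv` (empty when no predicted positives).
* `method_agreement.tsv` (two or more methods) — per method pair:
  `top<K>_overlap`, `pearson`, `spearman`.
* `evaluation.json` — the performance table in machine-readable form.

## Exit codes

0 success · 2 configuration error · 3 data error · 4 numerical failure.
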