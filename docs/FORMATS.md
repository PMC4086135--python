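# File formats

Every format read or written by the `chempred` CLI and library.  All files
are plain text; TSV files carry a header row unless noted.

## Structures

* **SMILES file** (`.smi`): one molecule per line, `SMILES[<TAB>id]`.
  Lines starting with `#` and blank lines are ignored.  Missing ids become
  `line<N>`.
* **SDF / MOL V2000** (`.sdf`, `.mol`): standard multi-record SDF.  Record
  name (`_Name`) is used as the source id; all SD properties are kept as
  metadata.  Written SDFs of standardized compounds carry `canonical_id`
  (standard InChI) and `provenance_ids` (semicolon-joined) properties.

## Tables

* **Standardized compounds TSV**: `canonical_id`, `canonical_smiles`,
  `provenance_ids` (semicolon-joined source ids).
* **ATC label TSV**: `compound_id`, `atc_codes` (semicolon-joined
  7-character WHO codes, pattern letter-digit-digit-letter-letter-digit-digit).
* **Interaction table TSV**: `compound_id`, `smiles`, `target_id`,
  `binding_type`, `affinity_nM`.  Affinities must already be in nM.
* **Rejects report TSV**: `compound_id`, `target_id`, `reason` with reason
  codes `binding_type`, `affinity`, `parse_error`, `target_too_small`.
* **Fingerprint cache TSV**: `canonical_id`, `kind`, `bits` (sorted,
  comma-joined set-bit positions), `nbits` (0 = sparse/unfolded).
* **Fragment cache TSV**: `parent_id`, `fragment_smiles` (one row per
  fragment).
* **Evaluation bin table TSV**: `score_range`, `hits`, `misses`,
  `prediction_rate` — ten equal consensus-score bins over [0, 1].

## Directories

* **ATC library directory** (`build-atc-db`): `compounds.tsv`,
  `atc_codes.tsv`, `fingerprints.tsv`, `fragments.tsv`, `config.json`.
* **Target database directory** (`build-target-db`): one subdirectory per
  target with `ligands.tsv`; `targets.json` (per-target `n_ligands`,
  `self_raw_score`, `n_self_pairs`, `lambda`); `rejects.tsv`;
  `config.json`; after `calibrate`, `background.json`
  (`mu`, `sigma`, `n_samples`, `seed`).

## JSON results

All JSON is written with sorted keys and 2-space indentation and echoes the
scientific configuration (`config`) of the run.  Output paths are never part
of the echo, so identically seeded runs in different directories are
byte-identical.

* **classify**: `query`, `predicted_class`, `consensus_score`,
  `decision_path`, `per_method.{2d,fragment,3d}` with `predicted_class`,
  `top_score` and the top-5 `top_similar` references.
* **evaluate**: `mode`, `accuracy`, `n_queries`, `recall_at_k`,
  `bin_table`.
* **predict-targets**: `query`, ranked `predictions` (`target_id`,
  `raw_score`, `z_score`, `weighted_z`, `e_value`, `n_contributing`),
  `background`.
* **superpose**: `a`, `b`, `score_3d`, `n_conformers`.

## Configuration (YAML)

`RunConfig` keys with defaults: `tanimoto_threshold: 0.45`,
`affinity_max: 10000`, `min_ligands: 5`, `max_conformers: 100`,
`max_pair_distance: 1.0`, `e_max: 1.0`, `atc_level: 2`,
`lambda_form: stated_range`, `threshold_2d: 0.45`,
`threshold_fragment: 0.45`, `threshold_3d: 0.30`, `keep_stereo: false`,
`neutralize_charges: true`, `seed: 2014`.  Command-line flags override file
values.

## Fixture outputs (`make-fixtures`)

* `atc`: `library.smi`, `atc_codes.tsv`, `similarity_check.tsv`
  (pairwise within/cross Tanimoto table), `verification.json`
  (separation summary).
* `targets`: `interactions.tsv`, `holdout_queries.smi`,
  `holdout_labels.tsv`, `decoys.smi`, `reject_manifest.json` (the rows
  curation must reject, with reasons).
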