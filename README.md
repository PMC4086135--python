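# chempred

Ligand-based drug classification and target prediction from chemical
similarity.

Given a query small molecule, the package answers two questions that come up
constantly in early drug discovery and repositioning:

1. **What kind of drug does this look like?** — predict the compound's WHO
   ATC class by comparing it against a labeled reference drug library with
   three independent similarity methods and combining their votes
   (`chempred.atc_classifier`).
2. **What proteins might it bind?** — rank protein targets by the
   statistical significance of the query's similarity to each target's known
   ligands (`chempred.target_predictor`).

Both pipelines rest on the similar-property principle: structurally similar
molecules tend to share biological activity.

## Methods in brief

**Consensus ATC classification.** Every compound is standardized (largest
covalent fragment, salts and explicit hydrogens removed, charges
neutralized, InChI identity) and compared to the reference library by

* *2D similarity*: Tanimoto coefficient `|A∩B|/|A∪B|` on unfolded
  extended-connectivity fingerprints of diameter 4 (ECFP4-style circular
  environments); 166-key structural keys and a hashed path fingerprint are
  available as alternative backends for method comparison;
* *fragment similarity*: molecules are decomposed into ring-centered
  fragments by the linker rule (acyclic atoms between ring systems are
  deleted, substituents stay with their ring); the n×m fragment Tanimoto
  matrix is searched for the optimal one-to-one assignment and the score is
  the assignment sum divided by min(n, m);
* *3D similarity*: up to 100 low-energy conformers per molecule are aligned
  by center of mass and principal axes of inertia, atom pairs are mapped
  nearest-first under a distance threshold over the four sign-flip
  orientations, and each conformer pair is scored
  `3D-score = N_S / max(N_A, N_B) · exp(−rmsd)`.

Each method nominates the ATC class of its top-ranked reference drug.  If at
least two methods agree, that class is the prediction; otherwise the method
clearing its score threshold by the largest margin decides, and a query with
no method above threshold stays unclassified.

**Statistical target prediction.** A target set A is the curated collection
of ligands with measured binding (IC50/Ki/KD ≤ 10 000 nM, ≥ 5 distinct
ligands).  The query's raw score against A is the sum of Tanimoto
coefficients ≥ 0.45 over A's ligands; significance is measured by the
background-calibrated, size-corrected Z-score

```
Z_A = ((raw_A / N_A) − μ) · N_A^0.335 / σ
```

with (μ, σ) estimated from decoy compounds scored against every target set.
A per-target diversity weight λ_A (≈1 for chemically uniform sets, ≫1 for
diverse ones) rescales Z before ranking, and the E-value
`E = n_targets · exp(−Z)` flags predictions indistinguishable from chance
(E > 1).

## Worked example

Build a small synthetic reference library (two congeneric series with
planted ATC labels) and classify a novel congener that is *not* in the
library:

```sh
chempred make-fixtures atc --out fix --seed 7 --n-series 2 --series-size 5
chempred build-atc-db --in fix/library.smi --atc fix/atc_codes.tsv --out lib
printf 'CCCOc1cc(F)nc2ccccc12\tnovel_quinoline\n' > novel.smi
chempred classify --query novel.smi --library lib --level 1 \
    --max-conformers 3 --json novel.json
```

`novel.json` (trimmed):

```json
{
  "consensus_score": 0.593,
  "decision_path": "three_agree",
  "per_method": {
    "2d":       {"predicted_class": "A", "top_score": 0.639},
    "fragment": {"predicted_class": "A", "top_score": 0.639},
    "3d":       {"predicted_class": "A", "top_score": 0.503}
  },
  "predicted_class": "A",
  "query": "CCCOc1cc(F)nc2ccccc12"
}
```

All three methods retrieve a quinoline-series drug as the nearest reference
compound, so the query is assigned that series' class "A" unanimously with a
consensus score of 0.593 (the mean of the three top similarities — well
below 1 because the propoxy congener is new to the library).

Target prediction on the synthetic interaction database:

```sh
chempred make-fixtures targets --out tfix --seed 7
chempred build-target-db --interactions tfix/interactions.tsv --out tdb
chempred calibrate --db tdb --decoys tfix/decoys.smi --seed 7
head -1 tfix/holdout_queries.smi > q.smi
chempred predict-targets --query q.smi --db tdb --json targets.json
```

The held-out ligand recovers its true target at rank 1:

```json
{
  "query": "FC(F)(F)Cc1cc(Cl)c2ccccc2n1",
  "predictions": [
    {
      "target_id": "TGT00",
      "raw_score": 14.05,
      "z_score": 31.43,
      "weighted_z": 25.59,
      "e_value": 7.7e-11,
      "n_contributing": 25
    }
  ],
  "background": {"mu": 0.0126, "sigma": 0.0514}
}
```

All 25 of TGT00's ligands exceed the 0.45 similarity threshold
(`n_contributing`), the Z-score is 31 background standard deviations above
random, and the E-value says such a hit is never expected by chance in a
10-target database.

## Layout

```
src/chempred/
  compound_model.py    parsing, standardization, InChI deduplication
  fingerprints.py      circular / structural-key / path fingerprints, Tanimoto
  fragmenter.py        linker-rule fragmentation, assignment similarity
  superposer.py        conformers, inertial-frame 3D superposition
  atc_classifier.py    per-method ranking, consensus rule, evaluation harness
  target_predictor.py  curation, raw/Z/λ/E statistics, target ranking
  fixtures.py          deterministic synthetic chemistry generators
  cli.py               `chempred` command-line entry point
docs/methods.md        modeling assumptions, parameters, design choices
docs/FORMATS.md        every file format read or written
```
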