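# holopls

Ligand-based binary-activity classification built on molecular-hologram
fingerprints and PLS-DA, with a single-descriptor threshold rule and a
two-stage integrative classifier.

## What's inside

| Module | Purpose |
| --- | --- |
| `holopls.molecule_io` | SMILES/SDF reading, salt-stripping standardization, circular (ECFP-style) fingerprints, Tanimoto MaxMin diversity selection |
| `holopls.hologram` | Connected-subgraph fragment enumeration, canonical fragment keys under distinction flags (A/B/C/D/H), CRC-32 bin hashing into fixed-length count vectors |
| `holopls.plsda` | NIPALS PLS1 on a 0/1 response with auto-scaling, stratified 10-fold CV component selection, JSON model round-trip |
| `holopls.feature_selection` | Stepwise linear regression with partial-F entry (p ≤ 0.02) and removal (p ≥ 0.10) tests |
| `holopls.rule_integrative` | Threshold-rule classifier (default: descriptor > −0.1 ⇒ class 1), rule calibration, and PLS-DA + rule integration (`deploy` ambiguity-band mode and label-aware `oracle_eval` mode) |
| `holopls.metrics_eval` | ACC / SEN / SPE / MCC from confusion counts, repeated random-split robustness evaluation |
| `holopls.contribution_map` | Per-atom contribution scores from PLS coefficients spread over fragment occurrences |
| `holopls.synthetic_fixtures` | Seeded generator for labeled synthetic molecules (aromatic vs aliphatic scaffolds) and class-shifted surrogate descriptor tables |

## CLI

`holopls` (or `python -m holopls.cli`) exposes the pipeline:

```bash
# generate a seeded synthetic dataset (SMILES + labels + descriptor table)
holopls fixtures --seed 17 --n-per-class 200 --out data/

# train a hologram PLS-DA model (defaults: fragment size 5-8, distinctions A/C, 353 bins)
holopls train data/molecules.smi --labels data/labels.csv --seed 17 --out model/

# predict and evaluate
holopls predict data/molecules.smi --model model/model.json \
    --hologram-config model/hologram_config.json --out pred/
holopls evaluate --pred pred/predictions.csv --labels data/labels.csv --out eval/

# metrics straight from confusion counts
holopls evaluate --counts "TP=327,TN=116,FP=18,FN=173"

# threshold rule: calibrate or apply fixed
holopls rule --table data/descriptors.csv --column BV12_DRY_surrogate \
    --labels data/labels.csv --out rule/

# two-stage integrative classification
holopls integrate data/molecules.smi --model model/model.json \
    --hologram-config model/hologram_config.json \
    --table data/descriptors.csv --column BV12_DRY_surrogate \
    --mode deploy --delta 0.15 --out integ/

# per-atom contribution maps
holopls contributions data/molecules.smi --model model/model.json \
    --hologram-config model/hologram_config.json --out contrib/

# parameter sweeps over the distinction / fragment-size grids
holopls sweep data/molecules.smi --labels data/labels.csv --grid size --out sweep/
```

Other subcommands: `standardize`, `select-diverse`, `hologram`, `stepwise`.
Every artifact-producing run drops a `run_config.json` snapshot so it can
be replayed.

## Notes on semantics

* Fragments are connected **vertex-induced** subgraphs of the heavy-atom
  graph (H-explicit graph when flag `H` is active); enumeration is exact
  and checked against a brute-force oracle in the tests.
* Fragment keys always encode element and formal charge; flags add
  aromaticity (`A`), bond orders (`B`), parent heavy-degree (`C`),
  donor/acceptor classification (`D`), or explicit hydrogens (`H`).
  Keys hash into bins `1..L` via CRC-32 (IEEE) mod `L`.
* `oracle_eval` integration is label-aware by construction and therefore
  only valid for evaluation; `deploy` mode is the label-blind variant
  that re-assigns only score-ambiguous compounds.
* Auto-scaling uses ddof=1; zero-variance columns are dropped.
  Prediction scores at the class cutoff go to class 1; rule values at the
  threshold go to class 0 (strict inequality).
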