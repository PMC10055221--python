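# predstack

Stacking and evaluation of per-residue amino-acid predictor panels.

Four base models (two "structure"-type, two "sequence"-type) each emit a
20-way probability distribution over the canonical amino acids for every
residue site. `predstack` provides:

- **formats_io** — readers/writers for the prediction-table TSV dialect
  (`protein_id  position  model_id  p_A ... p_Y`), labels tables, FASTA,
  RCSB-style homology-cluster lists, and the training-set curation filters
  (homology exclusion, length cap, protonation flag).
- **synthetic** — a seeded simulator producing labeled proteins (sequence,
  RSA, burial, amino-acid class) and four predictor outputs with
  configurable per-class×burial skill, Beta-distributed confidence, decoy
  kernels, and within-type correlation via shared-latent thresholding.
- **combiner** — the combined stacking network (80 → 120 → 60 → 20, relu +
  softmax) trained from scratch in numpy with Adam (lr 1e-4, categorical
  cross-entropy, 150 epochs by default), plus the probability-averaging and
  max-vote ensemble baselines.
- **evaluation** — per-protein accuracy, pooled per-class accuracy, Pearson
  correlation of per-protein accuracies, the five-way agreement taxonomy
  (ALL / STRUCTURE_ONLY / SEQUENCE_ONLY / MIXED / NONE) against the
  combined model, and 2D RSA-vs-confidence histograms with count bands.
- **rsa** — Shrake–Rupley solvent-accessible surface area from PDB
  coordinates (deterministic golden-spiral test points, probe 1.4 Å,
  960 points by default) normalized by per-residue max-ASA constants.
- **pipeline / cli** — end-to-end orchestration with homology-aware
  protein-level train/test splitting, manifests, and full seeded
  determinism.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (random-chance
baseline, stacking dominance on the complementary panel, correlation
recovery, oracle equivalences, agreement totality, byte-level determinism,
class-skill pattern).

## CLI

```sh
predstack simulate --n-proteins 50 --seed 1 \
    --out-predictions pred.tsv --out-labels labels.tsv
predstack train --predictions pred.tsv --labels labels.tsv --out model.npz
predstack predict --model model.npz --predictions pred.tsv --out combined.tsv
predstack evaluate --predictions pred.tsv --labels labels.tsv --out report/
predstack rsa --pdb protein.pdb --out rsa.tsv
predstack run --config run.yaml --seed 7 --out out/   # end to end
```

A run config is a YAML mapping, e.g.

```yaml
panel: default        # or an inline panel config / omit and set table paths
n_proteins: 100
test_fraction: 0.2
train: {epochs: 150, batch_size: 128}
seed: 7
```

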